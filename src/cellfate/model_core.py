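"""Deterministic three-state cell-fate transition model.

A population of cells is partitioned into proliferating (P), differentiated
(D) and dead (N, cumulative) compartments.  Single cells switch fate with
constant per-day intensities (a continuous-time Markov assumption), which at
the population level gives the linear ODE system

    dP/dt = (alpha - beta - d1) P + gamma D
    dD/dt = beta P - (gamma + d2) D
    dN/dt = d1 P + d2 D

where alpha is the proliferation rate, beta the differentiation rate, gamma
the de-differentiation rate, and d1/d2 the death rates of proliferating and
differentiated cells (all 1/day).  Because (P, D) decouple from N, the living
subsystem is governed by a 2x2 Metzler matrix whose spectrum is always real;
the dominant eigenvalue is the Malthus coefficient, the asymptotic exponential
growth (or extinction) rate of the surviving population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateParams",
    "StateVector",
    "Trajectory",
    "AnalyticSolution",
    "CriticalPointClass",
    "DegenerateSpectrumError",
    "NumericalFailureError",
    "build_system_matrix",
    "eigenvalues",
    "solve_ode",
    "analytic_solution",
    "malthus_coefficient",
    "classify_critical_point",
]

#: Relative spectral-gap threshold below which the two eigenvalues are
#: treated as repeated and the analytic path refuses to proceed.
_DEGENERACY_RTOL = 1e-10


class DegenerateSpectrumError(ValueError):
    """Raised when the 2x2 system matrix has (numerically) repeated
    eigenvalues, so the two-mode closed form is ill-conditioned.  Callers
    should fall back to the numeric integrator."""


class NumericalFailureError(RuntimeError):
    """Raised when the ODE integrator fails or returns non-finite values."""


@dataclass(frozen=True)
class RateParams:
    """The five single-cell fate-transition rates, in 1/day.

    alpha : proliferation rate of P cells
    beta  : differentiation rate (P -> D)
    gamma : de-differentiation rate (D -> P)
    d1    : death rate of proliferating cells
    d2    : death rate of differentiated cells
    """

    alpha: float
    beta: float
    gamma: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "d1", "d2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"rate {name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"rate {name!r} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.d1, self.d2])

    @classmethod
    def from_array(cls, arr) -> "RateParams":
        a = np.asarray(arr, dtype=float)
        if a.shape != (5,):
            raise ValueError(f"expected 5 rates, got shape {a.shape}")
        return cls(*a.tolist())


@dataclass(frozen=True)
class StateVector:
    """Mean cell densities (cells/mm^2): P proliferating, D differentiated,
    N cumulative dead."""

    P: float
    D: float
    N: float = 0.0

    def __post_init__(self) -> None:
        if self.P < 0 or self.D < 0 or self.N < 0:
            raise ValueError(f"densities must be >= 0, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.D, self.N])


@dataclass
class Trajectory:
    """Time series of mean densities on a day grid."""

    times: np.ndarray
    P: np.ndarray
    D: np.ndarray
    N: np.ndarray
    condition: str | None = None
    replicate: int | None = None

    def to_frame(self):
        """Tidy representation; round-off negatives are clipped to zero
        here, at reporting time only."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "day": self.times,
                "P": np.clip(self.P, 0.0, None),
                "D": np.clip(self.D, 0.0, None),
                "N": np.clip(self.N, 0.0, None),
            }
        )
        if self.condition is not None:
            df["condition"] = self.condition
        if self.replicate is not None:
            df["replicate"] = self.replicate
        return df

    def states(self) -> np.ndarray:
        """(n_times, 3) array of (P, D, N)."""
        return np.column_stack([self.P, self.D, self.N])


def build_system_matrix(params: RateParams) -> np.ndarray:
    """2x2 matrix A governing the living subsystem d(P,D)/dt = A (P,D).

    A = [[alpha - beta - d1, gamma], [beta, -(gamma + d2)]].  Off-diagonal
    entries are non-negative (Metzler), so the spectrum is real.
    """
    return np.array(
        [
            [params.alpha - params.beta - params.d1, params.gamma],
            [params.beta, -(params.gamma + params.d2)],
        ]
    )


def eigenvalues(params: RateParams) -> tuple[float, float]:
    """Both eigenvalues of A, dominant first, via the quadratic formula.

    For a Metzler matrix the discriminant p^2 - 4q = (a11 - a22)^2 + 4*b*c
    is non-negative, so both roots are real.
    """
    A = build_system_matrix(params)
    p = A[0, 0] + A[1, 1]
    q = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    disc = p * p - 4.0 * q
    # non-negative by the Metzler structure; clamp round-off
    root = math.sqrt(max(disc, 0.0))
    return (p + root) / 2.0, (p - root) / 2.0


def _eigenvector(A: np.ndarray, lam: float) -> np.ndarray:
    """Robust null-space direction of (A - lam I) for a 2x2 matrix."""
    cand1 = np.array([A[0, 1], lam - A[0, 0]])  # from row 1
    cand2 = np.array([lam - A[1, 1], A[1, 0]])  # from row 2
    v = cand1 if np.linalg.norm(cand1) >= np.linalg.norm(cand2) else cand2
    nrm = np.linalg.norm(v)
    if nrm == 0.0:  # diagonal matrix with lam on both rows cannot reach here
        v = np.array([1.0, 0.0]) if abs(A[0, 0] - lam) <= abs(A[1, 1] - lam) else np.array([0.0, 1.0])
        nrm = 1.0
    return v / nrm


@dataclass
class AnalyticSolution:
    """Closed-form solution of the linear model with distinct eigenvalues.

    (P, D)(t) = c1 v1 e^{l1 t} + c2 v2 e^{l2 t}; the dead compartment follows
    by quadrature,

        N(t) = N0 + sum_i w_i (e^{l_i t} - 1)/l_i,   w_i = c_i (d1 v_i,P + d2 v_i,D),

    with the i-th term replaced by w_i t when l_i = 0.
    """

    eig1: float
    eig2: float
    v1: np.ndarray
    v2: np.ndarray
    c1: float
    c2: float
    w1: float
    w2: float
    N0: float
    params: RateParams = field(repr=False)
    init: StateVector = field(repr=False)

    def _mode(self, lam: float, t: np.ndarray) -> np.ndarray:
        return np.exp(lam * t)

    def _quad(self, lam: float, t: np.ndarray) -> np.ndarray:
        """integral_0^t e^{lam s} ds, handling lam = 0."""
        if lam == 0.0:
            return np.asarray(t, dtype=float)
        return (np.exp(lam * np.asarray(t, dtype=float)) - 1.0) / lam

    def evaluate(self, times) -> Trajectory:
        t = np.asarray(times, dtype=float)
        e1, e2 = self._mode(self.eig1, t), self._mode(self.eig2, t)
        P = self.c1 * self.v1[0] * e1 + self.c2 * self.v2[0] * e2
        D = self.c1 * self.v1[1] * e1 + self.c2 * self.v2[1] * e2
        N = self.N0 + self.w1 * self._quad(self.eig1, t) + self.w2 * self._quad(self.eig2, t)
        return Trajectory(times=t, P=P, D=D, N=N)


def analytic_solution(params: RateParams, init: StateVector) -> AnalyticSolution:
    """Eigen-decomposition closed form for the linear model.

    Raises
    ------
    DegenerateSpectrumError
        If the two eigenvalues coincide to within relative tolerance; the
        caller should integrate numerically instead.
    """
    A = build_system_matrix(params)
    l1, l2 = eigenvalues(params)
    scale = max(1.0, abs(l1), abs(l2))
    if abs(l1 - l2) <= _DEGENERACY_RTOL * scale:
        raise DegenerateSpectrumError(
            f"repeated eigenvalue {l1:.6g}; closed form unavailable"
        )
    v1, v2 = _eigenvector(A, l1), _eigenvector(A, l2)
    V = np.column_stack([v1, v2])
    c = np.linalg.solve(V, np.array([init.P, init.D]))
    w1 = c[0] * (params.d1 * v1[0] + params.d2 * v1[1])
    w2 = c[1] * (params.d1 * v2[0] + params.d2 * v2[1])
    return AnalyticSolution(
        eig1=l1, eig2=l2, v1=v1, v2=v2, c1=float(c[0]), c2=float(c[1]),
        w1=float(w1), w2=float(w2), N0=init.N, params=params, init=init,
    )


def solve_ode(
    params: RateParams,
    init: StateVector,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Numerically integrate the three-compartment system on a day grid.

    ``times`` must be strictly increasing and start at 0.  The integrator is
    adaptive and stiffness-switching (LSODA); the system is linear so high
    precision is cheap.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a 1-d grid")
    if t[0] != 0.0:
        raise ValueError("times must start at 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    A = build_system_matrix(params)
    d1, d2 = params.d1, params.d2

    def rhs(_t, y):
        P, D, _N = y
        return (
            A[0, 0] * P + A[0, 1] * D,
            A[1, 0] * P + A[1, 1] * D,
            d1 * P + d2 * D,
        )

    if t.size == 1:  # grid is just t=0
        return Trajectory(times=t, P=np.array([init.P]), D=np.array([init.D]), N=np.array([init.N]))

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        init.as_array(),
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise NumericalFailureError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=t, P=sol.y[0], D=sol.y[1], N=sol.y[2])


def malthus_coefficient(params: RateParams) -> float:
    """Dominant eigenvalue of A: the asymptotic per-day growth rate of the
    surviving population (positive = divergence, negative = extinction)."""
    l1, _ = eigenvalues(params)
    return l1


@dataclass(frozen=True)
class CriticalPointClass:
    """Phase-portrait classification of the origin for the living subsystem."""

    discriminant: float
    trace: float
    determinant: float
    label: str  # stable_node | saddle | degenerate
    eig1: float
    eig2: float


def classify_critical_point(params: RateParams, eps: float = 1e-12) -> CriticalPointClass:
    """Classify the origin of the (P, D) phase plane.

    With non-negative rates the trace of A cannot be positive when its
    determinant is, so the only non-degenerate outcomes are an asymptotically
    stable node (both eigenvalues negative, extinction) and a saddle
    (opposite signs, unbounded growth along the dominant eigenvector).
    Eigenvalues within ``eps`` of zero, or a repeated root, are labelled
    ``degenerate``.
    """
    A = build_system_matrix(params)
    p = A[0, 0] + A[1, 1]
    q = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    disc = p * p - 4.0 * q
    l1, l2 = eigenvalues(params)
    if l1 < -eps and l2 < -eps:
        label = "stable_node"
    elif l1 > eps and l2 < -eps:
        label = "saddle"
    else:
        label = "degenerate"
    return CriticalPointClass(
        discriminant=disc, trace=p, determinant=q, label=label, eig1=l1, eig2=l2
    )
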