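"""Population-level response and heterogeneity metrics.

Heterogeneity of a cell population is summarised by the Shannon entropy of
the three fate fractions; the response of a population to a growth factor is
summarised by comparing its Malthus coefficient and its state fluxes (initial
or time-averaged net rates of change) against a matched control condition.
Plain effect sizes (Cohen's d, eta squared) support condition comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    DegenerateSpectrumError,
    RateParams,
    StateVector,
    Trajectory,
    analytic_solution,
    malthus_coefficient,
    solve_ode,
)

__all__ = [
    "FractionVector",
    "FluxSet",
    "ResponseIndices",
    "UndefinedEffectError",
    "shannon_entropy",
    "entropy_timecourse",
    "initial_flux",
    "mean_flux",
    "response_indices",
    "cohens_d",
    "eta_squared",
]

_SUM_TOL = 1e-8


class UndefinedEffectError(ValueError):
    """Raised when an effect size has a zero denominator."""


@dataclass(frozen=True)
class FractionVector:
    """Fractions of cells in each fate (proliferating, differentiated, dead)."""

    pP: float
    pD: float
    pN: float

    def __post_init__(self) -> None:
        for v in (self.pP, self.pD, self.pN):
            if not (0.0 <= v <= 1.0 + _SUM_TOL):
                raise ValueError(f"fractions must lie in [0, 1], got {self}")
        if abs(self.pP + self.pD + self.pN - 1.0) > _SUM_TOL:
            raise ValueError(f"fractions must sum to 1, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pP, self.pD, self.pN])


def shannon_entropy(frac: FractionVector, base: float | None = None) -> float:
    """Shannon entropy S = -sum p_i log p_i of the fate fractions.

    Natural log by default (max = ln 3 for the uniform three-state mix);
    ``base`` switches the logarithm.  The 0 log 0 term is 0.
    """
    p = frac.as_array()
    nz = p[p > 0.0]
    s = float(-(nz * np.log(nz)).sum())
    if base is not None:
        s /= math.log(base)
    return s


def _fractions(P: float, D: float, N: float) -> FractionVector:
    # round-off negatives from the solver are clipped at reporting time
    p = np.clip([P, D, N], 0.0, None)
    tot = p.sum()
    if tot <= 0.0:
        raise ValueError("all-zero state has undefined fate fractions")
    p = p / tot
    return FractionVector(*p.tolist())


def entropy_timecourse(traj: Trajectory, base: float | None = None) -> np.ndarray:
    """Entropy at each time point of a trajectory.

    Returns an array of shape (n_times, 2) with columns (day, S).
    """
    out = np.empty((traj.times.size, 2))
    for i, (t, P, D, N) in enumerate(zip(traj.times, traj.P, traj.D, traj.N)):
        out[i, 0] = t
        out[i, 1] = shannon_entropy(_fractions(P, D, N), base=base)
    return out


@dataclass(frozen=True)
class FluxSet:
    """Net fluxes of the three compartments (cells/mm^2/day).

    ``flavor`` is "initial" (rates at t = 0) or "mean" (time average over a
    horizon of ``horizon`` days).
    """

    JP: float
    JD: float
    JN: float
    flavor: str
    horizon: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {"P": self.JP, "D": self.JD, "N": self.JN}


def initial_flux(params: RateParams, init: StateVector) -> FluxSet:
    """Right-hand sides of the rate equations at t = 0."""
    JP = (params.alpha - params.beta - params.d1) * init.P + params.gamma * init.D
    JD = params.beta * init.P - (params.gamma + params.d2) * init.D
    JN = params.d1 * init.P + params.d2 * init.D
    return FluxSet(JP=JP, JD=JD, JN=JN, flavor="initial")


def mean_flux(params: RateParams, init: StateVector, T: float = 5.0) -> FluxSet:
    """Time-averaged fluxes (1/T) int_0^T J_X dt = (X(T) - X(0)) / T.

    T defaults to the 5-day observation horizon of a daily time-course
    experiment.
    """
    if T <= 0:
        raise ValueError(f"horizon T must be > 0, got {T}")
    try:
        end = analytic_solution(params, init).evaluate([0.0, T])
    except DegenerateSpectrumError:
        end = solve_ode(params, init, [0.0, T])
    JP = (end.P[-1] - init.P) / T
    JD = (end.D[-1] - init.D) / T
    JN = (end.N[-1] - init.N) / T
    return FluxSet(JP=JP, JD=JD, JN=JN, flavor="mean", horizon=T)


@dataclass(frozen=True)
class ResponseIndices:
    """Growth-factor response indices relative to a control condition.

    ``normalization`` is "ratio" (stimulated / control, neutral value 1) or
    "difference" (stimulated - control, neutral value 0).  Undefined entries
    (zero control denominator under ratio normalization) are NaN, never
    infinities.
    """

    R_lambda: float
    R_J0: dict[str, float]
    R_Jmean: dict[str, float]
    normalization: str
    horizon: float

    @property
    def neutral_value(self) -> float:
        return 1.0 if self.normalization == "ratio" else 0.0


def _normalize(num: float, den: float, normalization: str) -> float:
    if normalization == "ratio":
        if den == 0.0:
            return math.nan
        return num / den
    return num - den


def response_indices(
    params_gf: RateParams,
    params_ctl: RateParams,
    init: StateVector,
    T: float = 5.0,
    normalization: str = "ratio",
) -> ResponseIndices:
    """Compare a stimulated condition against its control.

    Three families of indices are computed from a shared initial condition:
    the Malthus-coefficient response, the initial-flux responses per state,
    and the mean-flux responses per state over horizon ``T``.
    """
    if normalization not in ("ratio", "difference"):
        raise ValueError(f"unknown normalization {normalization!r}")
    lam_gf = malthus_coefficient(params_gf)
    lam_ctl = malthus_coefficient(params_ctl)
    J0_gf, J0_ctl = initial_flux(params_gf, init), initial_flux(params_ctl, init)
    Jm_gf, Jm_ctl = mean_flux(params_gf, init, T), mean_flux(params_ctl, init, T)
    return ResponseIndices(
        R_lambda=_normalize(lam_gf, lam_ctl, normalization),
        R_J0={
            k: _normalize(J0_gf.as_dict()[k], J0_ctl.as_dict()[k], normalization)
            for k in ("P", "D", "N")
        },
        R_Jmean={
            k: _normalize(Jm_gf.as_dict()[k], Jm_ctl.as_dict()[k], normalization)
            for k in ("P", "D", "N")
        },
        normalization=normalization,
        horizon=T,
    )


def cohens_d(group_a, group_b, pooling: str = "mean_sd") -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    ``pooling="mean_sd"`` divides by the plain average of the two sample
    standard deviations; ``pooling="classic"`` uses the usual
    degrees-of-freedom-weighted pooled SD.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if pooling == "mean_sd":
        denom = (sa + sb) / 2.0
    elif pooling == "classic":
        denom = math.sqrt(((a.size - 1) * sa**2 + (b.size - 1) * sb**2) / (a.size + b.size - 2))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if denom == 0.0:
        raise UndefinedEffectError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / denom)


def eta_squared(groups) -> float:
    """Effect size eta^2 = S_B / S_T: the between-group sum of squares over
    the total sum of squares, for K groups of repeated measurements."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    allv = np.concatenate(gs)
    grand = allv.mean()
    s_t = float(((allv - grand) ** 2).sum())
    if s_t == 0.0:
        raise UndefinedEffectError("zero total sum of squares")
    s_b = float(sum(g.size * (g.mean() - grand) ** 2 for g in gs))
    return s_b / s_t
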