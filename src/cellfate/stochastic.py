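"""Exact stochastic simulation of the cell-fate scheme and mean-variance
(Taylor power-law) analysis.

The five fate transitions are first-order reaction channels

    P -> 2P (alpha),  P -> D (beta),  D -> P (gamma),
    P -> 0 counted into N (d1),  D -> 0 counted into N (d2),

simulated event-by-event with the Gillespie algorithm, with an absorbing
boundary once no living cells remain.  Ensembles of runs can randomise the
rate vector per run (truncated-normal) and/or the initial counts (lognormal);
the four combinations are the model variants used to discriminate the origin
of the empirical variance-mean power law V = a * M^b observed across
microscope fields.  A linear birth-death process with closed-form moments
serves as the analytic reference showing that constant initial conditions
alone drive the slope b to 2 at long times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import RateParams, StateVector

__all__ = [
    "VariantConfig",
    "MeanVarSeries",
    "PowerLawFit",
    "BirthDeathParams",
    "InsufficientDataError",
    "gillespie_run",
    "gillespie_ensemble_counts",
    "simulate_ensemble",
    "sample_truncated_normal",
    "sample_lognormal_init",
    "lognormal_meanvar",
    "fit_powerlaw",
    "fit_lognormal",
    "birthdeath_moments",
    "birthdeath_powerlaw_slope",
]


class InsufficientDataError(ValueError):
    """Raised when too few usable points remain for a fit."""


# ---------------------------------------------------------------------------
# single-run SSA


def gillespie_run(
    params: RateParams,
    init: StateVector,
    t_max: float,
    rng: np.random.Generator,
):
    """One exact sample path of the five-channel jump process.

    ``init`` is interpreted as integer counts.  Returns ``(times, states)``:
    event times (starting at 0) and the (P, D, N) counts after each event.
    The path is absorbed once P + D = 0.
    """
    P, D, N = (int(round(v)) for v in init.as_array())
    if min(P, D, N) < 0:
        raise ValueError("initial counts must be non-negative")
    times = [0.0]
    states = [(P, D, N)]
    t = 0.0
    a = params
    while True:
        props = (a.alpha * P, a.beta * P, a.gamma * D, a.d1 * P, a.d2 * D)
        atot = sum(props)
        if atot == 0.0:
            break
        t += rng.exponential(1.0 / atot)
        if t > t_max:
            break
        u = rng.random() * atot
        if u < props[0]:
            P += 1
        elif u < props[0] + props[1]:
            P -= 1
            D += 1
        elif u < props[0] + props[1] + props[2]:
            D -= 1
            P += 1
        elif u < props[0] + props[1] + props[2] + props[3]:
            P -= 1
            N += 1
        else:
            D -= 1
            N += 1
        times.append(t)
        states.append((P, D, N))
    return np.array(times), np.array(states, dtype=np.int64).reshape(-1, 3)


# ---------------------------------------------------------------------------
# vectorised ensemble SSA

def gillespie_ensemble_counts(
    rates: np.ndarray,
    init_counts: np.ndarray,
    days: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact SSA for many independent runs, recorded on a day grid.

    All channels are first order, so the whole ensemble can be advanced in
    lock-step with vectorised propensity updates; runs drop out of the active
    set once absorbed (no living cells) or past the horizon.

    Parameters
    ----------
    rates : (5, n_runs) per-run rate vectors (alpha, beta, gamma, d1, d2)
    init_counts : (3, n_runs) integer initial (P, D, N)
    days : increasing observation times, starting at 0

    Returns
    -------
    counts : (n_days, 3, n_runs) integer states at each observation day
    """
    rates = np.asarray(rates, dtype=float)
    days = np.asarray(days, dtype=float)
    n = rates.shape[1]
    P = np.asarray(init_counts[0], dtype=np.int64).copy()
    D = np.asarray(init_counts[1], dtype=np.int64).copy()
    N = np.asarray(init_counts[2], dtype=np.int64).copy()
    t = np.zeros(n)
    n_days = days.size
    t_max = days[-1]
    out = np.zeros((n_days, 3, n), dtype=np.int64)
    rec = np.zeros(n, dtype=np.int64)  # next day index to record per run
    days_ext = np.append(days, np.inf)
    active = np.arange(n)

    while active.size:
        al, be, ga, d1, d2 = (rates[k, active] for k in range(5))
        Pa, Da = P[active], D[active]
        a1 = al * Pa
        a2 = be * Pa
        a3 = ga * Da
        a4 = d1 * Pa
        a5 = d2 * Da
        atot = a1 + a2 + a3 + a4 + a5
        with np.errstate(divide="ignore"):
            dt = rng.exponential(1.0, active.size) / atot  # inf once absorbed
        t_new = t[active] + dt

        # record every day that falls before the next event (the state is
        # constant on [t, t_new))
        recA = rec[active].copy()
        while True:
            mask = days_ext[recA] < t_new
            if not mask.any():
                break
            sel = active[mask]
            di = recA[mask]
            out[di, 0, sel] = P[sel]
            out[di, 1, sel] = D[sel]
            out[di, 2, sel] = N[sel]
            recA[mask] += 1
        rec[active] = recA

        # apply the event for runs still inside the horizon
        ev = np.isfinite(t_new) & (t_new <= t_max)
        u = rng.random(active.size) * atot
        sel = active[ev]
        uu = u[ev]
        c1 = a1[ev]
        c2 = c1 + a2[ev]
        c3 = c2 + a3[ev]
        c4 = c3 + a4[ev]
        r1 = uu < c1
        r2 = ~r1 & (uu < c2)
        r3 = ~r1 & ~r2 & (uu < c3)
        r4 = ~r1 & ~r2 & ~r3 & (uu < c4)
        r5 = ~r1 & ~r2 & ~r3 & ~r4
        P[sel[r1]] += 1
        P[sel[r2]] -= 1
        D[sel[r2]] += 1
        D[sel[r3]] -= 1
        P[sel[r3]] += 1
        P[sel[r4]] -= 1
        N[sel[r4]] += 1
        D[sel[r5]] -= 1
        N[sel[r5]] += 1
        t[active] = t_new
        active = sel
    return out


# ---------------------------------------------------------------------------
# per-run randomisation (model variants)


def sample_truncated_normal(
    location: float,
    scale: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Normal(location, scale) restricted to [0, inf), renormalised."""
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    a = -location / scale
    return stats.truncnorm.rvs(a, np.inf, loc=location, scale=scale, size=size, random_state=rng)


def sample_lognormal_init(
    log_mean: float,
    log_sd: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """exp of a Normal(log_mean, log_sd) draw; degenerate at log_sd = 0."""
    if log_sd < 0:
        raise ValueError(f"log_sd must be >= 0, got {log_sd}")
    if log_sd == 0.0:
        out = np.full(size if size is not None else (), math.exp(log_mean))
        return float(out) if size is None else out
    return np.exp(rng.normal(log_mean, log_sd, size=size))


def lognormal_meanvar(log_mean: float, log_sd: float) -> tuple[float, float]:
    """Closed-form mean and variance of a lognormal with log-scale moments
    (log_mean, log_sd):  M = exp(mu + s^2/2),  V = M^2 (exp(s^2) - 1)."""
    if log_sd < 0:
        raise ValueError(f"log_sd must be >= 0, got {log_sd}")
    m = math.exp(log_mean + 0.5 * log_sd**2)
    v = m * m * (math.exp(log_sd**2) - 1.0)
    return m, v


@dataclass(frozen=True)
class VariantConfig:
    """One of the four model variants for ensemble simulation.

    variant 1: constant rates, lognormal initial counts
    variant 2: truncated-normal rates, constant initial counts
    variant 3: truncated-normal rates, lognormal initial counts
    variant 4: constant rates, constant initial counts

    ``trunc_scale_frac`` sets the truncated-normal scale as a fraction of
    each rate (location); ``init_log_sd`` is the log-scale SD of the initial
    count distribution (its log-mean is the log of the base initial count).
    """

    variant: int
    param_mode: str
    init_mode: str
    trunc_scale_frac: float = 0.2
    init_log_sd: float = 0.5

    _MODES = {
        1: ("constant", "lognormal"),
        2: ("truncated_normal", "constant"),
        3: ("truncated_normal", "lognormal"),
        4: ("constant", "constant"),
    }

    def __post_init__(self) -> None:
        if self.variant not in self._MODES:
            raise ValueError(f"variant must be 1-4, got {self.variant}")
        if (self.param_mode, self.init_mode) != self._MODES[self.variant]:
            raise ValueError(
                f"variant {self.variant} requires modes {self._MODES[self.variant]}, "
                f"got ({self.param_mode!r}, {self.init_mode!r})"
            )

    @classmethod
    def from_variant(cls, variant: int, **kwargs) -> "VariantConfig":
        pm, im = cls._MODES[variant]
        return cls(variant=variant, param_mode=pm, init_mode=im, **kwargs)


@dataclass
class MeanVarSeries:
    """Cross-run sample means and variances of the counts per (day, state)."""

    days: np.ndarray
    means: np.ndarray  # (n_days, 3)
    variances: np.ndarray  # (n_days, 3), unbiased
    n_runs: int
    zero_handling: str = "exclude"  # for downstream log-log fitting

    STATE_NAMES = ("P", "D", "N")

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, d in enumerate(self.days):
            for j, s in enumerate(self.STATE_NAMES):
                rows.append((d, s, self.means[i, j], self.variances[i, j], self.n_runs))
        return pd.DataFrame(rows, columns=["day", "state", "M", "V", "n"])

    def points(self, exclude_zeros: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (M, V) pairs, optionally dropping non-positive entries."""
        M = self.means.ravel()
        V = self.variances.ravel()
        if exclude_zeros:
            keep = (M > 0) & (V > 0)
            M, V = M[keep], V[keep]
        return M, V


def simulate_ensemble(
    variant: VariantConfig | int,
    base_params: RateParams,
    base_init: StateVector,
    n_runs: int,
    days,
    seed: int | np.random.Generator = 0,
) -> tuple[MeanVarSeries, np.ndarray]:
    """Simulate an ensemble of independent SSA runs under a model variant.

    Per-run rates are either the base rates (constant mode) or truncated
    normal draws located at the base rates; per-run initial living counts are
    either the base counts or lognormal draws whose median is the base
    count.  Returns the cross-run mean-variance series and the raw
    ``(n_days, 3, n_runs)`` count array.
    """
    if isinstance(variant, int):
        variant = VariantConfig.from_variant(variant)
    if n_runs < 2:
        raise ValueError("need at least 2 runs for variances")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)

    base = base_params.as_array()
    if variant.param_mode == "truncated_normal":
        rates = np.empty((5, n_runs))
        for k in range(5):
            scale = variant.trunc_scale_frac * base[k]
            if scale > 0:
                rates[k] = sample_truncated_normal(base[k], scale, rng, size=n_runs)
            else:  # degenerate scale: fall back to the constant rate
                rates[k] = base[k]
    else:
        rates = np.tile(base[:, None], (1, n_runs))

    init = np.empty((3, n_runs), dtype=np.int64)
    b0 = base_init.as_array()
    if variant.init_mode == "lognormal":
        for j in range(2):  # living states only; dead debris starts at its base count
            if b0[j] > 0:
                draws = sample_lognormal_init(math.log(b0[j]), variant.init_log_sd, rng, size=n_runs)
                init[j] = np.round(draws).astype(np.int64)
            else:
                init[j] = 0
        init[2] = int(round(b0[2]))
    else:
        init[0], init[1], init[2] = (int(round(v)) for v in b0)

    counts = gillespie_ensemble_counts(rates, init, days, rng)
    means = counts.mean(axis=2)
    variances = counts.var(axis=2, ddof=1)
    return (
        MeanVarSeries(days=days, means=means, variances=variances, n_runs=n_runs),
        counts,
    )


# ---------------------------------------------------------------------------
# power-law and lognormal fitting


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log V = log a + b log M (Taylor's law)."""

    a: float
    b: float
    r_squared: float
    n_points: int


def fit_powerlaw(series) -> PowerLawFit:
    """Fit V = a * M^b by ordinary least squares on the log-log points.

    ``series`` is a MeanVarSeries or an ``(M, V)`` pair of arrays.  Points
    with M <= 0 or V <= 0 are omitted before taking logs; at least three
    usable points are required.
    """
    if isinstance(series, MeanVarSeries):
        M, V = series.points(exclude_zeros=True)
    else:
        M, V = (np.asarray(x, dtype=float) for x in series)
        keep = (M > 0) & (V > 0)
        M, V = M[keep], V[keep]
    if M.size < 3:
        raise InsufficientDataError(f"need >= 3 positive (M, V) points, got {M.size}")
    x, y = np.log(M), np.log(V)
    b, loga = np.polyfit(x, y, 1)
    resid = y - (loga + b * x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(a=float(math.exp(loga)), b=float(b), r_squared=r2, n_points=int(M.size))


def fit_lognormal(samples) -> tuple[float, float, float]:
    """Moments of log(samples) plus a log-scale normality p-value.

    Zeros (and negatives) are excluded; at least 10 positive samples are
    required.  Returns (log_mean, log_sd, p_normality) where the p-value is
    from D'Agostino-Pearson's normality test on the log values.
    """
    x = np.asarray(samples, dtype=float)
    x = x[x > 0]
    if x.size < 10:
        raise InsufficientDataError(f"need >= 10 positive samples, got {x.size}")
    lx = np.log(x)
    log_sd = float(lx.std(ddof=1))
    if log_sd <= 1e-12 * max(1.0, abs(float(lx.mean()))):
        return float(lx.mean()), 0.0, 1.0
    _, p = stats.normaltest(lx)
    return float(lx.mean()), log_sd, float(p)


# ---------------------------------------------------------------------------
# birth-death analytic reference


@dataclass(frozen=True)
class BirthDeathParams:
    """Linear birth-death process: birth rate lam, death rate mu (1/day),
    integer initial count n0."""

    lam: float
    mu: float
    n0: int

    def __post_init__(self) -> None:
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be >= 0")
        if not (isinstance(self.n0, (int, np.integer)) and self.n0 > 0):
            raise ValueError(f"n0 must be a positive integer, got {self.n0!r}")


def birthdeath_moments(bd: BirthDeathParams, t):
    """Closed-form mean and variance of the count at time t.

    For lam != mu:  M = n0 e^{rt},  V = n0 (lam+mu)/(lam-mu) e^{rt}(e^{rt}-1)
    with r = lam - mu; the equal-rate limit is M = n0, V = 2 lam n0 t.
    """
    t = np.asarray(t, dtype=float)
    lam, mu, n0 = bd.lam, bd.mu, bd.n0
    if lam == mu:
        M = np.full_like(t, float(n0))
        V = 2.0 * lam * n0 * t
    else:
        r = lam - mu
        ert = np.exp(r * t)
        M = n0 * ert
        V = n0 * (lam + mu) / r * ert * (ert - 1.0)
    return M, V


def birthdeath_powerlaw_slope(bd: BirthDeathParams, t_grid) -> float:
    """OLS slope of log V against log M along a time sweep of the closed
    forms.  For lam > mu the slope tends to 2 as the sweep moves to long
    times (V becomes proportional to M^2)."""
    if not bd.lam > bd.mu:
        raise ValueError("requires lam > mu (growing population)")
    t = np.asarray(t_grid, dtype=float)
    t = t[t > 0]
    if t.size < 2:
        raise InsufficientDataError("need >= 2 positive time points")
    M, V = birthdeath_moments(bd, t)
    slope = float(np.polyfit(np.log(M), np.log(V), 1)[0])
    return slope
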