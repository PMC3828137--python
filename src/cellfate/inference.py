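"""Bayesian estimation of fate-transition rates from count time courses.

Observed per-image cell counts are modelled as the deterministic trajectory
scaled into count units plus i.i.d. Gaussian observation noise,

    y_X(t_k) = C * X(t_k) + e_k,   e_k ~ Normal(0, sigma^2),  X in {P, D, N},

so the log-likelihood of a rate vector is a Gaussian sum over all observed
(day, state) points.  Each of the five rates carries an independent gamma
prior (support [0, inf), matching the biological non-negativity constraint),
and the posterior is explored with a random-walk Metropolis sampler whose
acceptance ratio is tempered by a simulated-annealing temperature: a hot
exploratory cooling phase down to temperature 1, a Metropolis phase at 1, a
second cooling phase below 1 to sharpen onto the posterior mode, and a final
constant-low-temperature phase.  The point estimate is the average of the
best-likelihood parameter sets recorded across the blocks of the final phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    DegenerateSpectrumError,
    RateParams,
    StateVector,
    analytic_solution,
    solve_ode,
)

__all__ = [
    "ObservationModel",
    "GammaPrior",
    "AnnealingSchedule",
    "PosteriorResult",
    "STATES",
    "validate_count_table",
    "daily_mean_counts",
    "estimate_initial_conditions",
    "default_observation_model",
    "log_likelihood",
    "log_posterior",
    "propose",
    "annealed_accept",
    "run_annealed_mcmc",
]

STATES = ("P", "D", "N")
_PARAM_NAMES = ("alpha", "beta", "gamma", "d1", "d2")
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ObservationModel:
    """Count-scale observation model: counts = C * density + Gaussian noise.

    C converts a density (cells/mm^2) into a mean per-image count; sigma is
    the observation-noise SD on the count scale, shared across states/days.
    Recorded counts cannot be negative, so when ``censored`` is true the
    predicted observed count is the mean of the zero-censored Gaussian,
    E[max(0, mu + e)] = mu * Phi(mu/sigma) + sigma * phi(mu/sigma), which
    reduces to mu wherever the model prediction is well above zero but
    removes the upward bias that censoring creates near empty fields.
    """

    C: float = 1.0
    sigma: float = 1.0
    censored: bool = True

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def predicted_counts(self, mean_counts: np.ndarray) -> np.ndarray:
        """Expected recorded count for a model mean on the count scale."""
        mu = np.clip(np.asarray(mean_counts, dtype=float), 0.0, None)
        if not self.censored:
            return mu
        z = mu / self.sigma
        return mu * _norm_cdf(z) + self.sigma * _norm_pdf(z)


@dataclass(frozen=True)
class GammaPrior:
    """Independent gamma priors over the five non-negative rates.

    Defaults are deliberately broad (shape k = 1 so the support includes 0,
    scale theta = 10); estimation is insensitive to making theta larger.
    """

    shape: np.ndarray = field(default_factory=lambda: np.ones(5))
    scale: np.ndarray = field(default_factory=lambda: np.full(5, 10.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", np.broadcast_to(np.asarray(self.shape, float), (5,)).copy())
        object.__setattr__(self, "scale", np.broadcast_to(np.asarray(self.scale, float), (5,)).copy())
        if np.any(self.shape <= 0) or np.any(self.scale <= 0):
            raise ValueError("gamma prior needs shape > 0 and scale > 0")

    def logpdf(self, theta: np.ndarray) -> float:
        """Sum of log gamma densities; -inf outside the non-negative support."""
        th = np.asarray(theta, dtype=float)
        if np.any(th < 0) or not np.all(np.isfinite(th)):
            return -math.inf
        k, s = self.shape, self.scale
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (k - 1.0) * np.log(th) - th / s - _gammaln(k) - k * np.log(s)
        # (k-1)*log(0) is 0 for k == 1, +inf direction only for k < 1
        lp = np.where((th == 0.0) & (k == 1.0), -np.log(s), lp)
        total = float(lp.sum())
        return total

    def mean(self) -> np.ndarray:
        return self.shape * self.scale


def _gammaln(x):
    from scipy.special import gammaln

    return gammaln(x)


def _norm_pdf(z):
    return np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _norm_cdf(z):
    from scipy.special import ndtr

    return ndtr(z)


# ---------------------------------------------------------------------------
# count tables


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Check schema of a tidy count table (day, state, count, ...)."""
    required = {"day", "state", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    bad = set(counts["state"].unique()) - set(STATES)
    if bad:
        raise ValueError(f"unknown states in count table: {sorted(bad)}")
    if 0 not in set(counts["day"].unique()):
        raise ValueError("count table must include day 0 observations")
    return counts


def daily_mean_counts(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-day mean counts across fields.

    Returns (days, Y) with Y of shape (n_days, 3) ordered (P, D, N).
    """
    validate_count_table(counts)
    piv = counts.pivot_table(index="day", columns="state", values="count", aggfunc="mean")
    for s in STATES:
        if s not in piv.columns:
            raise ValueError(f"count table has no rows for state {s!r}")
    piv = piv[list(STATES)].sort_index()
    if piv.isna().any().any():
        raise ValueError("count table has missing (day, state) combinations")
    return piv.index.to_numpy(dtype=float), piv.to_numpy(dtype=float)


def estimate_initial_conditions(counts: pd.DataFrame, obs: ObservationModel) -> StateVector:
    """Initial densities taken directly from the day-0 mean counts / C.

    Under the censored observation model the day-0 sample mean estimates the
    censored mean mu * Phi(mu/sigma) + sigma * phi(mu/sigma), so that map is
    inverted before converting to densities; otherwise states whose true
    density is near zero would start biased upward.
    """
    days, Y = daily_mean_counts(counts)
    if days[0] != 0:
        raise ValueError("count table must include day 0 observations")
    vals = []
    for y in Y[0]:
        mu = _invert_censored_mean(float(y), obs) if obs.censored else float(y)
        vals.append(max(mu, 0.0) / obs.C)
    return StateVector(P=vals[0], D=vals[1], N=vals[2])


def _invert_censored_mean(y: float, obs: ObservationModel) -> float:
    """Solve mu * Phi(mu/s) + s * phi(mu/s) = y for mu >= 0.

    The censored mean is increasing in mu with minimum s*phi(0) at mu = 0;
    observed means at or below that floor map to 0.
    """
    from scipy.optimize import brentq

    s = obs.sigma
    floor = s * _norm_pdf(0.0)
    if y <= floor:
        return 0.0
    hi = max(y, 1.0)
    f = lambda mu: float(obs.predicted_counts(mu)) - y
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def default_observation_model(counts: pd.DataFrame, C: float = 1.0) -> ObservationModel:
    """Default noise level: 10% of the day-0 total mean count."""
    _, Y = daily_mean_counts(counts)
    sigma = 0.1 * float(Y[0].sum())
    if sigma <= 0:
        sigma = 1.0
    return ObservationModel(C=C, sigma=sigma)


# ---------------------------------------------------------------------------
# likelihood / posterior


def _predict_states(params: RateParams, init: StateVector, days: np.ndarray) -> np.ndarray:
    """(n_days, 3) model densities; analytic path with numeric fallback."""
    try:
        traj = analytic_solution(params, init).evaluate(days)
    except DegenerateSpectrumError:
        traj = solve_ode(params, init, days)
    return traj.states()


def log_likelihood(
    params: RateParams,
    counts: pd.DataFrame,
    obs: ObservationModel,
    init: StateVector,
    mode: str = "daily_mean",
) -> float:
    """Gaussian log-likelihood of the observed counts given the rates.

    ``mode="daily_mean"`` compares per-day mean counts (3 states x n days
    data points); ``mode="per_field"`` uses every per-field count.
    """
    days, Y = daily_mean_counts(counts)
    pred = obs.predicted_counts(_predict_states(params, init, days) * obs.C)
    if mode == "daily_mean":
        resid = Y - pred
        n = resid.size
        ss = float((resid**2).sum())
    elif mode == "per_field":
        validate_count_table(counts)
        day_index = {d: i for i, d in enumerate(days)}
        state_index = {s: j for j, s in enumerate(STATES)}
        ii = counts["day"].map(day_index).to_numpy()
        jj = counts["state"].map(state_index).to_numpy()
        resid = counts["count"].to_numpy(dtype=float) - pred[ii, jj]
        n = resid.size
        ss = float((resid**2).sum())
    else:
        raise ValueError(f"unknown likelihood mode {mode!r}")
    s = obs.sigma
    return -n * (math.log(s) + _LOG_SQRT_2PI) - ss / (2.0 * s * s)


def log_posterior(
    params: RateParams | np.ndarray,
    counts: pd.DataFrame,
    obs: ObservationModel,
    init: StateVector,
    prior: GammaPrior,
    mode: str = "daily_mean",
) -> float:
    """Unnormalized log-posterior; -inf outside the prior support."""
    theta = params.as_array() if isinstance(params, RateParams) else np.asarray(params, float)
    lp = prior.logpdf(theta)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(RateParams.from_array(theta), counts, obs, init, mode=mode)


class _Objective:
    """Precomputed arrays for fast repeated posterior evaluation."""

    def __init__(self, counts, obs, init, prior, mode):
        self.obs = obs
        self.init = init
        self.prior = prior
        self.days, Y = daily_mean_counts(counts)
        if mode == "daily_mean":
            self.y = Y.ravel()
            self.ii = None
        elif mode == "per_field":
            day_index = {d: i for i, d in enumerate(self.days)}
            state_index = {s: j for j, s in enumerate(STATES)}
            self.ii = counts["day"].map(day_index).to_numpy()
            self.jj = counts["state"].map(state_index).to_numpy()
            self.y = counts["count"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown likelihood mode {mode!r}")
        self.n = self.y.size
        self.const = -self.n * (math.log(obs.sigma) + _LOG_SQRT_2PI)
        self.inv2s2 = 1.0 / (2.0 * obs.sigma**2)

    def loglik(self, theta: np.ndarray) -> float:
        pred = self.obs.predicted_counts(
            _predict_states(RateParams.from_array(theta), self.init, self.days) * self.obs.C
        )
        if self.ii is None:
            resid = self.y - pred.ravel()
        else:
            resid = self.y - pred[self.ii, self.jj]
        return self.const - float((resid**2).sum()) * self.inv2s2

    def __call__(self, theta: np.ndarray) -> tuple[float, float]:
        """(log posterior, log likelihood)."""
        lp = self.prior.logpdf(theta)
        if not math.isfinite(lp):
            return -math.inf, -math.inf
        ll = self.loglik(theta)
        return lp + ll, ll


# ---------------------------------------------------------------------------
# sampler


def propose(current: np.ndarray, tau: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric Gaussian random-walk proposal."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("proposal SDs must be >= 0")
    return np.asarray(current, dtype=float) + rng.normal(0.0, 1.0, size=len(current)) * tau


def annealed_accept(
    logpost_candidate: float,
    logpost_current: float,
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Tempered Metropolis rule: accept with prob min(1, exp(dL / T)).

    Temperature 1 recovers plain Metropolis sampling.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if logpost_candidate == -math.inf:
        rng.random()  # keep the draw count deterministic
        return False
    d = (logpost_candidate - logpost_current) / temperature
    if d >= 0:
        rng.random()
        return True
    return rng.random() < math.exp(d)


@dataclass(frozen=True)
class AnnealingSchedule:
    """Four-phase annealing schedule for the tempered random-walk sampler.

    Phases: (1) geometric cooling from ``t0`` down to 1, (2) Metropolis
    sampling at temperature 1, (3) geometric cooling from 1 down to
    ``t_final`` < 1, (4) sampling at the constant final temperature, split
    into ``phase4_blocks`` blocks whose per-block best-likelihood parameter
    sets are averaged into the estimate.

    ``t_final=None`` selects the final temperature by the saturation rule:
    starting from 0.1, halve it until the phase-4 mean best log-likelihood
    stops improving by more than ``saturation_tol``.

    ``tau=None`` initialises the per-parameter proposal SD at 5% of the
    prior mean; when ``adapt`` is true the SD scale is tuned toward a target
    acceptance rate during phases 1-3 and frozen in phase 4.
    """

    t0: float = 100.0
    t_final: float | None = None
    steps: tuple[int, int, int, int] = (2000, 2000, 2000, 4000)
    cooling_temp_steps: int = 20
    phase4_blocks: int = 40
    tau: np.ndarray | None = None
    adapt: bool = True
    target_acceptance: float = 0.234
    saturation_tol: float = 0.1
    max_halvings: int = 14
    explorers: int = 4  # independent phase-1 walkers; best endpoint continues

    def __post_init__(self) -> None:
        if not self.t0 >= 1.0:
            raise ValueError("t0 must be >= 1")
        if self.t_final is not None and not (0 < self.t_final < 1):
            raise ValueError("t_final must lie in (0, 1)")
        if any(s <= 0 for s in self.steps) or len(self.steps) != 4:
            raise ValueError("need four positive phase lengths")


@dataclass
class PosteriorResult:
    """Outcome of an annealed-MCMC fit."""

    chain: pd.DataFrame
    block_best: np.ndarray  # (phase4_blocks, 5) best-likelihood params per block
    block_best_loglik: np.ndarray
    estimate: RateParams
    acceptance_rate: dict[int, float]
    seed: int
    t_final: float
    converged: bool
    init: StateVector
    obs: ObservationModel


class _ChainRecorder:
    def __init__(self) -> None:
        self.rows: list[tuple] = []
        self.step = 0

    def record(self, phase, temp, theta, ll, accepted):
        self.rows.append((self.step, phase, temp, *theta, ll, accepted))
        self.step += 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["step", "phase", "temperature", *_PARAM_NAMES, "loglik", "accepted"],
        )


class _Walker:
    """Random-walk state with acceptance-rate and covariance adaptation.

    The proposal starts as the diagonal random walk of :func:`propose` and,
    once enough post-burn-in samples exist, switches to a Gaussian whose
    covariance tracks the sample covariance of the chain (scaled by the
    standard 2.38^2/d factor).  This lets the walk move efficiently along
    the correlated ridges that the exchange rates (beta, gamma) create.
    Adaptation runs only where enabled (cooling / Metropolis phases) and is
    frozen for the final constant-temperature phase.
    """

    _COV_START = 500  # samples before covariance adaptation kicks in
    _COV_REFRESH = 100

    def __init__(self, objective, theta, tau, rng, target, rec):
        self.objective = objective
        self.theta = np.asarray(theta, dtype=float)
        self.lp, self.ll = objective(self.theta)
        self.best_theta, self.best_lp, self.best_ll = self.theta.copy(), self.lp, self.ll
        self.tau = np.asarray(tau, dtype=float)
        self.rng = rng
        self.target = target
        self.rec = rec
        self.scale = 1.0
        self.chol: np.ndarray | None = None
        d = len(self.theta)
        self._sd = 2.38**2 / d
        self._n = 0
        self._sum = np.zeros(d)
        self._outer = np.zeros((d, d))

    def _track(self, theta):
        self._n += 1
        self._sum += theta
        self._outer += np.outer(theta, theta)
        if self._n >= self._COV_START and self._n % self._COV_REFRESH == 0:
            mean = self._sum / self._n
            cov = self._outer / self._n - np.outer(mean, mean)
            cov = self._sd * cov + 1e-8 * np.eye(len(mean))
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                self.chol = None

    def _candidate(self):
        z = self.rng.normal(0.0, 1.0, size=len(self.theta))
        if self.chol is None:
            return self.theta + self.tau * self.scale * z
        return self.theta + self.scale * (self.chol @ z)

    def run(self, phase, temps_and_counts, adapt=True, track_cov=False):
        """Run proposals at a sequence of (temperature, n_proposals)."""
        accepted = total = 0
        batch_acc = batch_n = 0
        for temp, n in temps_and_counts:
            for _ in range(n):
                cand = self._candidate()
                lp_c, ll_c = self.objective(cand)
                took = annealed_accept(lp_c, self.lp, temp, self.rng)
                if took:
                    self.theta, self.lp, self.ll = cand, lp_c, ll_c
                    accepted += 1
                    batch_acc += 1
                    if lp_c > self.best_lp:
                        self.best_theta, self.best_lp, self.best_ll = cand.copy(), lp_c, ll_c
                self.rec.record(phase, temp, self.theta, self.ll, accepted=took)
                total += 1
                batch_n += 1
                if track_cov:
                    self._track(self.theta)
                if adapt and batch_n == 50:
                    self.scale *= math.exp(0.5 * (batch_acc / batch_n - self.target))
                    batch_acc = batch_n = 0
        return accepted, total

    def restart_from_best(self, tol: float = 1.0) -> None:
        """Return to the best point visited so far if the hot walk drifted
        into a worse basin (incumbent restart between annealing phases)."""
        if self.lp < self.best_lp - tol:
            self.theta = self.best_theta.copy()
            self.lp, self.ll = self.best_lp, self.best_ll


def _geometric_temps(t_hi: float, t_lo: float, n_temps: int, n_props: int):
    temps = np.geomspace(t_hi, t_lo, n_temps)
    per = max(n_props // n_temps, 1)
    return [(float(t), per) for t in temps]


def run_annealed_mcmc(
    counts: pd.DataFrame,
    obs: ObservationModel | None = None,
    prior: GammaPrior | None = None,
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    init_params: np.ndarray | None = None,
    likelihood_mode: str = "per_field",
) -> PosteriorResult:
    """Fit the five transition rates to a count table.

    Initial conditions are estimated directly from the day-0 data and the
    observation noise defaults to 10% of the day-0 total count.  The run is
    fully reproducible given ``seed``.
    """
    prior = prior or GammaPrior()
    schedule = schedule or AnnealingSchedule()
    if obs is None:
        obs = default_observation_model(counts)
    init = estimate_initial_conditions(counts, obs)
    objective = _Objective(counts, obs, init, prior, likelihood_mode)

    rng = np.random.default_rng(seed)
    tau = (
        np.asarray(schedule.tau, dtype=float)
        if schedule.tau is not None
        else 0.05 * prior.mean()
    )
    theta = (
        np.asarray(init_params, dtype=float)
        if init_params is not None
        else np.full(5, 0.5)
    )
    # launch the anneal from the best of the supplied start and a log-spaced
    # magnitude ladder at the biological 1/day scale.  The random-walk
    # landscape has deep fast-exchange traps far from the data-supported
    # region; this screen makes the estimate insensitive to the initial
    # guess (starts differing by orders of magnitude converge identically).
    candidates = [theta] + [np.full(5, c) for c in np.geomspace(1e-3, 1.0, 8)]
    theta = max(candidates, key=lambda th: objective(th)[0])

    rec = _ChainRecorder()
    acc: dict[int, float] = {}
    s1, s2, s3, s4 = schedule.steps
    # phase 1: cool t0 -> 1 (wide exploration, diagonal proposal).  The hot
    # walk is a basin lottery — a single chain can commit to a fast-exchange
    # trap — so phase 1 is repeated with a few independent explorers and the
    # best endpoint carries on into the Metropolis phase.
    plan = _geometric_temps(schedule.t0, 1.0, schedule.cooling_temp_steps, s1)
    walker = None
    a_tot = n_tot = 0
    for _ in range(schedule.explorers):
        w = _Walker(objective, theta, tau, rng, schedule.target_acceptance, rec)
        if not math.isfinite(w.lp):
            raise ValueError("initial parameter vector lies outside the prior support")
        a, n = w.run(1, plan, adapt=schedule.adapt)
        a_tot += a
        n_tot += n
        w.restart_from_best()
        if walker is None or w.lp > walker.lp:
            walker = w
    acc[1] = a_tot / n_tot

    # phase 2: Metropolis at temperature 1; start tracking the chain
    # covariance so later phases can walk along posterior ridges
    a, n = walker.run(2, [(1.0, s2)], adapt=schedule.adapt, track_cov=schedule.adapt)
    acc[2] = a / n
    walker.restart_from_best()

    def cool_and_hold(t_final):
        """Phases 3 and 4 for a given final temperature."""
        plan3 = _geometric_temps(1.0, t_final, schedule.cooling_temp_steps, s3)
        a3, n3 = walker.run(3, plan3, adapt=schedule.adapt, track_cov=schedule.adapt)
        block_len = max(s4 // schedule.phase4_blocks, 1)
        bests, best_lls = [], []
        for _ in range(schedule.phase4_blocks):
            start = len(rec.rows)
            walker.run(4, [(t_final, block_len)], adapt=False)
            block = rec.rows[start:]
            lls = np.array([r[-2] for r in block])
            j = int(np.argmax(lls))
            bests.append(np.array(block[j][3:8], dtype=float))
            best_lls.append(float(lls[j]))
        return a3 / n3, np.array(bests), np.array(best_lls)

    if schedule.t_final is not None:
        t_final = schedule.t_final
        acc3, bests, best_lls = cool_and_hold(t_final)
    else:
        # saturation rule: halve the final temperature until the phase-4
        # mean best log-likelihood stops improving
        t_final = 0.1
        acc3, bests, best_lls = cool_and_hold(t_final)
        prev_mean = best_lls.mean()
        for _ in range(schedule.max_halvings):
            t_try = t_final / 2.0
            acc3, bests, best_lls = cool_and_hold(t_try)
            t_final = t_try
            if best_lls.mean() - prev_mean < schedule.saturation_tol:
                break
            prev_mean = best_lls.mean()
    acc[3] = acc3
    ph4 = [r for r in rec.rows if r[1] == 4]
    acc[4] = float(np.mean([r[-1] for r in ph4])) if ph4 else 0.0

    estimate = RateParams.from_array(bests.mean(axis=0))
    # convergence: the per-block best log-likelihoods should not still trend
    x = np.arange(len(best_lls))
    slope = float(np.polyfit(x, best_lls, 1)[0]) if len(best_lls) > 1 else 0.0
    converged = abs(slope * (len(best_lls) - 1)) < 1.0

    return PosteriorResult(
        chain=rec.to_frame(),
        block_best=bests,
        block_best_loglik=best_lls,
        estimate=estimate,
        acceptance_rate=acc,
        seed=seed,
        t_final=t_final,
        converged=converged,
        init=init,
        obs=obs,
    )
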