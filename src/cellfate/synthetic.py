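"""Synthetic study-shaped datasets with known ground truth.

Emulates the design of a daily cell-counting experiment: three serum levels
(high, low, serum-free) crossed with three stimuli (control, EGF, NGF), daily
observations of ~30 microscope fields per dish over a week, and four
independent replicates.  Counts are generated either from the deterministic
model plus Gaussian observation noise on the count scale, or as independent
Gillespie realisations per field started from lognormally dispersed initial
counts.  The generating rates, initial state and noise level are returned
alongside every dataset so recovery can be scored.

The nine named rate presets are synthetic stand-ins chosen to encode the
qualitative biology of PC12 fate control: serum sustains proliferation (high
serum grows, serum-free declines), EGF raises the proliferation rate under
every serum level, NGF raises the differentiation rate under every serum
level, and heterogeneity (fate entropy) increases with time and with serum
deprivation.
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
from .stochastic import gillespie_ensemble_counts, sample_lognormal_init

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "SERUM_LEVELS",
    "STIMULI",
    "preset_conditions",
    "serum_family",
    "default_ground_truth",
    "generate_dataset",
]

SERUM_LEVELS = ("high", "low", "free")
STIMULI = ("control", "EGF", "NGF")


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the counting experiment."""

    conditions: tuple[tuple[str, str], ...] = tuple(
        (s, g) for s in SERUM_LEVELS for g in STIMULI
    )
    days: tuple[int, ...] = tuple(range(8))
    fields_per_day: int = 30
    replicates: int = 4
    field_area: float = 1.0  # mm^2 per imaged field

    def __post_init__(self) -> None:
        if self.fields_per_day < 1:
            raise ValueError("fields_per_day must be >= 1")
        if self.days[0] != 0:
            raise ValueError("observation days must start at 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters serialized alongside every dataset."""

    params: dict[tuple[str, str], RateParams]
    init: StateVector
    sigma: float
    C: float = 1.0
    init_log_sd: float = 0.5  # field-to-field dispersion of initial counts

    def to_dict(self) -> dict:
        return {
            "params": {
                f"{serum}:{stim}": vars(p) for (serum, stim), p in self.params.items()
            },
            "init": vars(self.init),
            "sigma": self.sigma,
            "C": self.C,
            "init_log_sd": self.init_log_sd,
        }


def preset_conditions() -> dict[tuple[str, str], RateParams]:
    """Nine named rate presets (serum level x stimulus), units 1/day.

    Synthetic values, constructed so that: the high-serum control grows
    (positive Malthus coefficient, doubling time ~1.3 days) while the
    serum-free control declines; EGF raises proliferation (and mildly
    differentiation) everywhere; NGF raises differentiation everywhere and
    proliferation only in the presence of serum; death rates rise as serum
    is withdrawn.
    """
    return {
        # serum: control
        ("high", "control"): RateParams(alpha=0.60, beta=0.05, gamma=0.30, d1=0.05, d2=0.20),
        ("low", "control"): RateParams(alpha=0.32, beta=0.14, gamma=0.05, d1=0.12, d2=0.08),
        ("free", "control"): RateParams(alpha=0.10, beta=0.12, gamma=0.04, d1=0.08, d2=0.05),
        # EGF: proliferation up at every serum level
        ("high", "EGF"): RateParams(alpha=0.75, beta=0.07, gamma=0.35, d1=0.04, d2=0.18),
        ("low", "EGF"): RateParams(alpha=0.45, beta=0.16, gamma=0.04, d1=0.11, d2=0.08),
        ("free", "EGF"): RateParams(alpha=0.16, beta=0.13, gamma=0.04, d1=0.09, d2=0.05),
        # NGF: differentiation up at every serum level
        ("high", "NGF"): RateParams(alpha=0.62, beta=0.15, gamma=0.28, d1=0.06, d2=0.15),
        ("low", "NGF"): RateParams(alpha=0.45, beta=0.40, gamma=0.04, d1=0.08, d2=0.05),
        ("free", "NGF"): RateParams(alpha=0.12, beta=0.22, gamma=0.07, d1=0.06, d2=0.04),
    }


def serum_family(stimulus: str, s: float, presets: dict | None = None) -> RateParams:
    """One-parameter family of conditions interpolating the serum presets.

    ``s`` runs from 0 (high serum, low heterogeneity) through 0.5 (low
    serum) to 1 (serum-free, high heterogeneity); rates are interpolated
    piecewise-linearly between the corresponding presets of ``stimulus``.
    Used to sweep growth-factor response indices against the heterogeneity
    of the control condition.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must lie in [0, 1], got {s}")
    presets = presets or preset_conditions()
    hi = presets[("high", stimulus)].as_array()
    lo = presets[("low", stimulus)].as_array()
    fr = presets[("free", stimulus)].as_array()
    if s <= 0.5:
        arr = hi + (s / 0.5) * (lo - hi)
    else:
        arr = lo + ((s - 0.5) / 0.5) * (fr - lo)
    return RateParams.from_array(arr)


def default_ground_truth() -> GroundTruth:
    """Default generating truth: preset rates, a proliferating-dominated
    initial field (30 proliferating, 1 differentiated, 0 dead cells), and
    observation noise at 10% of the initial total count."""
    init = StateVector(P=30.0, D=1.0, N=0.0)
    return GroundTruth(params=preset_conditions(), init=init, sigma=3.0)


def _trajectory_states(params: RateParams, init: StateVector, days: np.ndarray) -> np.ndarray:
    try:
        return analytic_solution(params, init).evaluate(days).states()
    except DegenerateSpectrumError:
        return solve_ode(params, init, days).states()


def generate_dataset(
    design: StudyDesign | None = None,
    truth: GroundTruth | None = None,
    mode: str = "ode_noise",
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a tidy count table under a study design.

    ``mode="ode_noise"``: per-field counts are the deterministic densities
    scaled to the count scale, plus i.i.d. Gaussian noise, floored at zero
    and rounded to integers.  ``mode="gillespie"``: every field is an
    independent exact SSA realisation whose initial living counts are
    lognormal around the truth (median = truth init).

    Returns (count table, ground truth).  Columns: day, state, count,
    field_id, condition, stimulus, replicate.
    """
    design = design or StudyDesign()
    truth = truth or default_ground_truth()
    rng = np.random.default_rng(seed)
    days = np.asarray(design.days, dtype=float)
    rows: list[tuple] = []
    area = design.field_area

    for serum, stim in design.conditions:
        params = truth.params[(serum, stim)]
        for rep in range(1, design.replicates + 1):
            if mode == "ode_noise":
                states = _trajectory_states(params, truth.init, days)  # densities
                mean_counts = truth.C * states * area  # (n_days, 3)
                noise = rng.normal(0.0, truth.sigma, size=(len(days), 3, design.fields_per_day))
                counts = np.round(np.clip(mean_counts[:, :, None] + noise, 0.0, None))
                counts = counts.astype(np.int64)
            elif mode == "gillespie":
                n = design.fields_per_day
                rates = np.tile(params.as_array()[:, None], (1, n))
                init = np.zeros((3, n), dtype=np.int64)
                b0 = truth.init.as_array() * truth.C * area
                for j in range(2):
                    if b0[j] > 0:
                        draws = sample_lognormal_init(
                            math.log(b0[j]), truth.init_log_sd, rng, size=n
                        )
                        init[j] = np.round(draws).astype(np.int64)
                init[2] = int(round(b0[2]))
                counts = gillespie_ensemble_counts(rates, init, days, rng)
            else:
                raise ValueError(f"unknown generation mode {mode!r}")
            for i, day in enumerate(design.days):
                for j, state in enumerate(("P", "D", "N")):
                    for f in range(design.fields_per_day):
                        rows.append(
                            (day, state, int(counts[i, j, f]), f + 1, serum, stim, rep)
                        )
    table = pd.DataFrame(
        rows,
        columns=["day", "state", "count", "field_id", "condition", "stimulus", "replicate"],
    )
    return table, truth
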