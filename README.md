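# cellfate

Markovian modelling of cell-fate dynamics in clonal cultures: how fast do
single cells proliferate, differentiate, de-differentiate and die, and how
does a growth factor shift those rates?

The package was built around the PC12-style neural-differentiation assay:
cells in a dish are classified daily into **proliferating (P)**,
**differentiated (D)** and **dead (N)** states by counting ~30 microscope
fields per day over a week, under different serum levels with or without a
growth factor (EGF or NGF). Only population counts are observed, yet the
quantity of interest is the set of *single-cell* transition rates.

## Model

Each cell switches fate independently with constant per-day intensities
(a continuous-time Markov chain), giving the population-level linear system

```
dP/dt = (α − β − d₁) P + γ D
dD/dt = β P − (γ + d₂) D
dN/dt = d₁ P + d₂ D
```

with proliferation α, differentiation β, de-differentiation γ, and death
rates d₁ (of P cells) and d₂ (of D cells), all in 1/day. The living
subsystem is governed by a 2×2 Metzler matrix, so its eigenvalues are real;
the dominant one is the **Malthus coefficient** λ_M (asymptotic growth if
positive, extinction if negative) and the phase portrait is either a stable
node or a saddle.

On top of this core the package provides:

- **`model_core`** — closed-form eigen-solution, stiff-capable numeric
  integration, Malthus coefficient, phase-portrait classification.
- **`metrics`** — Shannon entropy of the fate fractions (heterogeneity,
  0 … ln 3), initial and time-averaged state fluxes, growth-factor response
  indices versus a control condition, Cohen's *d* and η² effect sizes.
- **`inference`** — Bayesian estimation of the five rates from a count
  table: Gaussian observation model on the count scale (with a
  zero-censoring correction, since counts cannot be negative), independent
  gamma priors, and a random-walk Metropolis sampler tempered by a
  four-phase simulated-annealing schedule; the estimate averages the
  best-likelihood parameter sets of the final constant-temperature phase.
- **`stochastic`** — exact Gillespie simulation of the five reaction
  channels (vectorised over ensembles), the four model variants
  (constant/truncated-normal rates × constant/lognormal initial counts),
  Taylor power-law fitting `V = a·M^b` of the variance–mean relation across
  fields, lognormal diagnostics, and closed-form birth–death moments as an
  analytic reference.
- **`synthetic`** — study-shaped synthetic datasets (3 serum levels ×
  {control, EGF, NGF}, 30 fields/day, 8 days, 4 replicates) with known
  ground truth, plus nine qualitative rate presets.
- **`cellfate` CLI** — `synth`, `fit`, `metrics`, `simulate`, `powerlaw`,
  `pipeline` subcommands; every run writes a manifest with its seed.

## Worked example

Fit the rates of one synthetic low-serum condition and summarise the
population behaviour:

```python
import numpy as np
from cellfate import (RateParams, StateVector, run_annealed_mcmc,
                      malthus_coefficient, classify_critical_point,
                      entropy_timecourse, solve_ode, simulate_ensemble,
                      fit_powerlaw)
from cellfate.synthetic import StudyDesign, GroundTruth, generate_dataset

true = RateParams(alpha=0.55, beta=0.25, gamma=0.12, d1=0.10, d2=0.18)
truth = GroundTruth(params={("low", "control"): true},
                    init=StateVector(30, 1, 0), sigma=3.1)
design = StudyDesign(conditions=(("low", "control"),), days=tuple(range(8)),
                     fields_per_day=30, replicates=1)
table, _ = generate_dataset(design, truth, mode="ode_noise", seed=17)
res = run_annealed_mcmc(table, seed=4)

print("true rates: ", np.round(true.as_array(), 3))
print("estimate:   ", np.round(res.estimate.as_array(), 3))
lam = malthus_coefficient(res.estimate)
print("Malthus coefficient: %.3f /day (%s)" % (lam, classify_critical_point(res.estimate).label))
S = entropy_timecourse(solve_ode(res.estimate, truth.init, np.arange(8.0)))
print("fate entropy day 0 -> 7: %.3f -> %.3f (max ln 3 = 1.099)" % (S[0, 1], S[-1, 1]))
series, _ = simulate_ensemble(1, res.estimate, truth.init, 2000, np.arange(8.0), seed=2)
pl = fit_powerlaw(series)
print("variance-mean power law: b = %.2f, R^2 = %.3f" % (pl.b, pl.r_squared))
```

prints

```
true rates:  [0.55 0.25 0.12 0.1  0.18]
estimate:    [0.555 0.24  0.069 0.092 0.206]
Malthus coefficient: 0.254 /day (saddle)
fate entropy day 0 -> 7: 0.143 -> 1.038 (max ln 3 = 1.099)
variance-mean power law: b = 2.01, R^2 = 0.998
```

The fitted rates recover the generating ones (γ, the de-differentiation
rate, is the most weakly identified from daily counts; in the full study
design four replicates are fitted independently and averaged). The positive
Malthus coefficient says this population grows ~29% per day asymptotically;
the entropy time course shows heterogeneity rising from a nearly pure
proliferating population toward a three-way mix; and a stochastic ensemble
with lognormally dispersed initial counts reproduces a variance–mean power
law with slope near 2 (lognormal-dominated regime — within-dish branching
noise pulls the slope into the intermediate 1–2 band at higher growth).

The same pipeline from a shell:

```sh
cellfate synth --out runs/synth --seed 1 --mode gillespie
cellfate fit --counts runs/synth/counts.csv --out runs/fit --seed 1
cellfate metrics --estimates runs/fit/estimates.json --out runs/metrics
cellfate simulate --out runs/sim --variant 1 --runs 10000 --seed 1
cellfate powerlaw --counts runs/synth/counts.csv --out runs/powerlaw
```

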