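# Methods

## State-transition model

The population is partitioned into proliferating (P), differentiated (D)
and cumulatively dead (N) cells, with densities in cells/mm². Single cells
change state independently with constant intensities, so the mean densities
obey the linear system

    dP/dt = (α − β − d₁) P + γ D
    dD/dt = β P − (γ + d₂) D
    dN/dt = d₁ P + d₂ D

Assumptions: no cell–cell interaction or density dependence; differentiated
cells do not divide; de-differentiation occurs; dead-cell debris persists
(N is cumulative and non-decreasing). Rates are per day, matching daily
sampling; the observation window is days 0–7.

The living (P, D) subsystem has a Metzler matrix (non-negative off-diagonal
entries), so the discriminant of its characteristic polynomial is
non-negative and both eigenvalues are real: the origin is never a centre or
spiral. With non-negative rates the trace cannot be positive while the
determinant is, so the critical point is an asymptotically stable node
(extinction), a saddle (growth along the dominant eigenvector), or a
degenerate boundary case. The dominant eigenvalue is the Malthus
coefficient λ_M.

**Closed form.** With distinct eigenvalues l₁ ≠ l₂ and eigenvectors v₁, v₂,
(P, D)(t) = c₁v₁e^{l₁t} + c₂v₂e^{l₂t} with (c₁, c₂) solving the initial
condition, and by quadrature

    N(t) = N(0) + Σᵢ wᵢ (e^{lᵢt} − 1)/lᵢ,   wᵢ = cᵢ (d₁ v_{i,P} + d₂ v_{i,D}),

the i-th term degrading to wᵢ·t when lᵢ = 0. A repeated eigenvalue
(measure-zero for generic rates) raises `DegenerateSpectrumError` and
callers fall back to numeric integration — LSODA with rtol 1e-8 /
atol 1e-10; the system is linear and cheap, so precision is essentially
free. Round-off negatives are clipped only at reporting time, never inside
the solver state. Closed form and integrator agree to better than 1e-6
relative over the week for random rate sets, which the test suite asserts.

## Heterogeneity and response metrics

Fate heterogeneity is the Shannon entropy S = −Σ pᵢ ln pᵢ of the three fate
fractions (natural log by default; 0 for a pure population, ln 3 ≈ 1.099
for the uniform three-way mix; base is an option). Responses to a growth
factor are quantified against the matched control condition through three
families: the Malthus coefficient, the initial fluxes (the right-hand sides
at t = 0), and the horizon-averaged fluxes (X(T) − X(0))/T with T = 5 days
by default, the canonical experiment span. Both a ratio normalization
(stimulated/control, neutral value 1, the default) and a difference
normalization (neutral value 0) are provided and labelled in every output,
because either convention supports the qualitative orderings of interest;
zero control denominators yield NaN ("missing"), never infinities.

Effect sizes follow the conventions of the source assay: Cohen's *d* with
the *mean of the two sample SDs* in the denominator (the classic
pooled-variance form is an option) and η² = S_B/S_T from the between-group
and total sums of squares.

## Bayesian rate estimation

**Observation model.** A per-image count is y = C·X(t) + ε with
ε ~ N(0, σ²) i.i.d. across states, days and fields; C converts density to
a per-image count (1.0 for the synthetic designs, where field area is
1 mm²). σ is fixed, not sampled; the default is 10% of the day-0 total
count. Because a recorded count cannot be negative, the default model
predicts the zero-censored Gaussian mean
E[max(0, μ+ε)] = μΦ(μ/σ) + σφ(μ/σ), which equals μ wherever the model is
well above zero but removes the upward bias of censoring near empty
fields; `censored=False` restores the plain linear prediction. Initial
conditions are not inferred: they are taken directly from the day-0 means
(inverting the censored-mean map under the censored model).

**Likelihood granularity.** The default likelihood uses every per-field
count (3 states × 8 days × 30 fields). A `daily_mean` mode that compares
only the 24 per-day means is available; it is substantially less
informative and leaves the β–γ exchange ridge (fast P↔D cycling mimicking
slow cycling at the right equilibrium ratio) essentially unidentified, so
the per-field mode is the default.

**Prior.** Independent gamma densities per rate, shape k = 1 and scale
θ = 10 by default: support includes zero, nearly flat over the plausible
0–1/day range, and estimates are insensitive to raising θ further.

**Sampler.** Random-walk Metropolis with symmetric Gaussian proposals,
tempered by a temperature T in the acceptance ratio
min(1, exp(Δ log-posterior / T)), annealed in four phases:

1. geometric cooling from T₀ = 100 down to 1 (exploration);
2. Metropolis sampling at T = 1 (posterior conditioning);
3. geometric cooling from 1 to T_final < 1 (mode sharpening);
4. sampling at constant T_final, split into 40 blocks.

The estimate is the arithmetic mean of the per-block best-likelihood
parameter sets of phase 4. T_final is chosen by a saturation rule: starting
at 0.1 it is halved (phases 3–4 re-run) until the phase-4 mean best
log-likelihood stops improving by more than 0.1, up to 14 halvings. A
non-convergence flag is raised when the per-block best log-likelihoods
still trend (total drift beyond 1 log-unit over the blocks).

Three robustness mechanisms address the landscape's deep fast-exchange
traps, which a plain fixed-step walk falls into from unlucky hot-phase
excursions: (i) the proposal SD starts at 5% of the prior mean and a
scalar scale adapts toward 23.4% acceptance during phases 1–3, augmented
from phase 2 by Haario-style covariance adaptation (2.38²/d × chain
covariance) so the walk can travel along the correlated β–γ ridge — all
adaptation is frozen in phase 4; (ii) the anneal starts from the best of
the supplied initial vector and a log-spaced magnitude ladder between
10⁻³ and 1 per day, which makes estimates insensitive to starting values
orders of magnitude apart; (iii) phase 1 is repeated with four independent
walkers and the best endpoint continues, with an incumbent restart after
phases 1 and 2 if the chain sits more than one log-unit below the best
point it has visited. Runs are bitwise reproducible given the seed.

**Identifiability.** α and d₁ enter the living dynamics only through
α − d₁; the cumulative dead count disentangles them, which is why all
three states must be observed. γ is the weakest-identified rate at daily
resolution (its flux is small whenever D is small); in the full study
design each of the four replicates is fitted independently and the
estimates averaged, which brings the per-rate median relative error over
random rate sets in [0.05, 1]/day to within 20% (γ is the largest).

## Stochastic simulation and the variance–mean power law

The scheme has five first-order channels — P→2P (α), P→D (β), D→P (γ),
P→∅ (d₁) and D→∅ (d₂), deaths incrementing N — simulated exactly with the
Gillespie algorithm and an absorbing boundary at P + D = 0 (an absorbed
path keeps (0, 0, N) for the rest of the window). Because every channel is
first order, a whole ensemble advances in lock-step with vectorised
propensity updates; runs leave the active set when absorbed or past the
horizon, so the cost is proportional to the total number of events.

Four ensemble variants probe the origin of field-to-field dispersion:
per-run rates constant or truncated-normal (scale 20% of the rate by
default, configurable), crossed with per-run initial counts constant or
lognormal (log-scale SD 0.5 by default — a realistic field-to-field
dispersion for plated dishes; the log-mean is the log of the base count, so
the base is the median). Cross-run means M and unbiased variances V per
(day, state) are fitted by ordinary least squares on (log M, log V) —
Taylor's power law V = a·M^b — after excluding non-positive entries (zeros
carry no information on the log scale; raw moments remain available). OLS
rather than orthogonal regression is the conventional Taylor-law choice;
R² is reported so lack of fit is visible. Slope landmarks: b = 1 for
Poisson dispersion, b = 2 for exponential-like (and for lognormal with
constant log-scale SD, where V ∝ M² exactly); the constant-rate +
lognormal-initials variant produces intermediate slopes in (1, 2) at the
study scale because within-run branching noise (Poisson-like, slope-1)
mixes with between-run lognormal dispersion (slope-2). The linear
birth–death process with closed-form moments
M(t) = n₀e^{(λ−μ)t}, V(t) = n₀(λ+μ)/(λ−μ)·e^{(λ−μ)t}(e^{(λ−μ)t} − 1)
(λ = μ limit: M = n₀, V = 2λn₀t) is the analytic reference: its log–log
slope tends to 2 at long times, so constant initial conditions alone
cannot explain an intermediate slope.

Lognormality of simulated counts is assessed on the log scale with the
D'Agostino–Pearson normality test on dish-scale samples (n ≈ 300); at much
larger n the test resolves the small branching-noise departure from exact
lognormality, so dish-scale samples are the meaningful unit for the
"approximately lognormal" statement.

## Synthetic study designs

`synthetic.generate_dataset` emulates the counting experiment: 3 serum
levels × {control, EGF, NGF}, days 0–7, 30 fields/day, 4 replicates. Two
generation modes: `ode_noise` (per-field counts = deterministic prediction
+ Gaussian noise, floored at zero and rounded — the floor matches the
excess of zeros real count data shows near empty fields) and `gillespie`
(each field an independent SSA realisation from lognormally dispersed
initial counts). The generating truth (rates, initial state, σ, C,
dispersion) is returned with every table.

The nine rate presets are synthetic stand-ins encoding the qualitative
biology, not transcriptions of any measured values: high serum grows
(λ_M ≈ +0.52/day, doubling ≈ 1.3 days) while serum-free declines
(λ_M ≈ −0.02/day); EGF raises α under every serum level; NGF raises β under
every serum level (and γ falls under NGF at high serum, rises serum-free);
the death rate of proliferating cells rises as serum is withdrawn. They
were additionally constrained so that fate entropy is non-decreasing over
days 0–7 from the proliferating-dominated initial state (30, 1, 0), the
serum-free control is more heterogeneous than the high-serum control at
every day ≥ 1, and the NGF differentiation-flux response attains an
interior maximum along the piecewise-linear serum family
(`serum_family`, s = 0 high → 0.5 low → 1 free) — the moderate-heterogeneity
optimum that motivates the analysis. What passing tests show is therefore
that the *pipeline* recovers and reproduces these structures, not that any
particular rate value is biologically measured; real data bring additional
features the generator omits (cell clumping beyond lognormal initials,
classification error correlated across days, confluence effects late in
growth).

## Numerical choices and limitations

- Eigen-solution uses the quadratic formula with the discriminant clamped
  at zero; eigenvectors from the numerically larger row of (A − λI).
  Degeneracy threshold: relative spectral gap 1e-10.
- Entropy uses 0·ln 0 ≡ 0; fraction vectors must sum to 1 within 1e-8.
- The censored-mean inversion uses Brent root-finding; observed means at or
  below σφ(0) map to 0.
- Monte-Carlo test tolerances are expressed in standard errors (3 SE per
  comparison, with a small multiplicity allowance where hundreds of
  correlated comparisons are made at once); the SE of a sample variance is
  estimated from the fourth central moment.
- Problem sizes used throughout the test and reproduction scripts: 10⁴-run
  ensembles for moment checks, 2–3·10³-run ensembles for power-law fits,
  20 synthetic studies × 4 replicates for parameter recovery. These keep a
  full run in the minutes range on one CPU.
- The sampler estimates a posterior-mode-like point (tempered best-set
  average), not a full posterior summary; the phase-2 chain segment can be
  used for rough uncertainty but is not a converged posterior sample.
- No hierarchical pooling across replicates, no marginal-likelihood or
  model-comparison machinery, no multiple-testing correction — matching
  the analysis design this package reproduces.
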