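# Methods

## Model

A patient's hospital stay is the time to absorption of a continuous-time
Markov chain on four transient recovery phases (1 = most severe … 4 = mild
TIA only) and three absorbing discharge modes, always ordered (death,
nursing home, usual residence). The transient generator is upper-bidiagonal:
phase i can only progress to phase i+1 (rate λᵢ, defined for i = 1, 2) or
exit to one of the modes (rates μᵢ, νᵢ, ρᵢ). Phase 3 is the last common
recovery stage; phase 4 is reached only by mild TIAs and exits only to home
(μ₄ = ν₄ = 0, structural). The admission phase is determined by the
diagnosis — haemorrhagic → 1, cerebral infarction → 2, TIA → 3 or 4 with the
mild probability p(x) = exp{−exp(θ₀ + θ₁x)} at age x. Ages enter only
through p(x) and the progression intensities λᵢ(x) = exp(γᵢ + βᵢx);
mode-specific exit rates are age-independent. The model assumes
time-homogeneous rates within a phase (sojourns are exponential), no
censoring (every record ends in a discharge), and no covariates beyond age
and diagnosis.

### Parameters

| name | meaning | units | reference value |
|---|---|---|---|
| γ₁, β₁ | log-link coefficients of λ₁ (phase 1 → 2) | —, per year of age | 6.63570, −0.03652 |
| γ₂, β₂ | log-link coefficients of λ₂ (phase 2 → 3) | —, per year of age | −3.06931, 0.07153 |
| θ₀, θ₁ | cloglog coefficients of the mild-TIA probability | —, per year of age | −8.66118, 0.08801 |
| μ₁, μ₂, μ₃ | mortality rates by phase | per year | 22.10156, 2.48820, 1.56162 |
| ν₃ | nursing-home discharge rate, phase 3 | per year | 1.27849 |
| ρ₂, ρ₃, ρ₄ | home discharge rates by phase | per year | 11.76860, 3.41989, 63.92514 |
| ν₁, ν₂, ρ₁ | pruned in the revised model | per year | 0 (masked) |

All rates are per year. Stays are reported in days with
`days_per_year = 365.25`; this convention is fixed because it reproduces the
reference report tables at one decimal place (365.0 does too — the tables do
not distinguish the two), and it is exposed in the parameter config for
anyone whose source data uses a different convention. The `zero_mask`
mechanism pins rates at exactly zero so that masked values can never leak
into generators or likelihoods regardless of what is stored.

## Closed-form evaluation

Because **T** is upper-bidiagonal, exp(**T**y) has entries that are products
of progression rates with the symmetric hypoexponential kernels
K₁(s; a) = e^{−as}, K₂(s; a, b) = (e^{−as} − e^{−bs})/(b − a) and
K₃(s; a, b, c) (the divided differences of r ↦ e^{−rs} up to sign). These
kernels are evaluated in a shifted form that factors out the smallest rate,
which makes them immune to overflow and accurate under near-ties; when the
scaled gap between two rates falls below a relative tolerance of 1e-7 the
confluent (repeated-rate) limit is used instead. The switchover is
continuous to ~1e-12, which matters because the optimizer is free to wander
through rate ties. No general matrix exponential is used at runtime;
scipy's `expm` serves as an independent cross-check in the tests.

All KPI quantities follow from this: densities, distribution and survival
functions, the absorption matrix **P** = (−**T**)⁻¹**t**_A (computed by
triangular back-substitution, never a general inverse), overall and
destination-conditional means, mean residual stay, destination probabilities
given the incurred stay, and mode-specific sub-distribution functions
α′(I − exp(**T**y))**P**e_m. Report tables round half-up to one decimal;
unrounded values are always available.

A property worth noting: the death component of the
destination-given-incurred-stay vector is *not* monotone in the stay. It
declines steeply for haemorrhagic entries (survivors escape the
high-mortality phase 1) but rises for TIA and infarction entries, whose
surviving pool migrates toward phase 3, and for haemorrhagic entries it can
dip below the phase-3 limiting value μ₃/(μ₃+ν₃+ρ₃) before drifting back up.

## Likelihood

Each record contributes the joint density of its (LOS, mode) pair given its
type and age. With the admission phase known, this is a sum of at most three
terms — one per phase from which the stay could have ended — each a product
of progression rates, a kernel Kₖ in the phase total-exit rates, and the
mode-specific exit rate. TIA contributions are a two-component mixture over
the mild/severe entry routes, with the 0⁰ = 1 convention making the phase-4
term vanish for death and nursing-home discharges. Stays are stored in days
and converted to years exactly once, on ingestion.

Contributions are evaluated as log-sum-exp of per-term logs, so extreme
rate-times-stay products degrade gracefully: a stay that is merely
improbable keeps a finite log-density, and only a genuinely impossible
observation (e.g. a TIA death when p(x) = 1) yields −∞, which
`log_likelihood` passes through as an explicit flag. The likelihood is the
exact density (proportionality constant 1).

## Estimation

The staged backward procedure exploits the fact that each stroke type
identifies its admission phase: (1) TIA only → {θ₀, θ₁, μ₃, ν₃, ρ₃, ρ₄};
(2) infarction only, stage 1 fixed → {γ₂, β₂, μ₂, ν₂, ρ₂}; (3) joint TIA +
infarction update of all 11; (4) haemorrhagic only → {γ₁, β₁, μ₁, ν₁, ρ₁};
(5) all data, all unmasked parameters. Stage-1 starting values are
method-of-moments: the mild-TIA fraction from sub-7-day home discharges,
rates from inverse mode-specific mean stays; later stages start from the
preceding stages' estimates.

Numerical choices that matter:

* **Transformed scale.** Rates are optimized as logs (positivity, and a
  Wald test on the log scale is better behaved near zero); γ, β, θ are
  unconstrained. Each link intercept is reparameterized as the linear
  predictor at 70 years (γ + 70β). Without this centering the slope
  direction is ~75× steeper than the intercept's, and the very first
  quasi-Newton step can overshoot the slope to its bound, landing on the
  flat λ → ∞ plateau where the likelihood no longer depends on that
  phase's parameters at all. Reported estimates are always on the natural,
  uncentered scale.
* **Objective.** Negative log-likelihood per observation, so
  finite-difference gradients have the same accuracy at any cohort size.
  L-BFGS-B with ftol 1e-12 and projected-gradient tolerance 1e-8; bounds
  log-rate ∈ [−20, 9], centered intercept ∈ [−30, 12], slope ∈ [−1, 1].
  The final stage restarts from three jittered starting points (seeded) and
  keeps the best; identical seed, data and config give bit-identical
  results.
* **Uncertainty.** The observed information is recomputed deterministically
  as the central-difference Hessian of the log-likelihood on the transformed
  scale (steps 1e-4·(1+|x|)), inverted, and mapped to the natural scale by
  the delta method (which for the centered intercepts is a 2×2 block, not a
  diagonal). Non-positive-definite information — typical when a true-zero
  rate sits on the boundary — falls back to a pseudo-inverse with a warning
  flag.
* **Pruning.** A free rate is set to zero when its Wald p-value exceeds the
  threshold (default 0.90) *and* its estimate is below a floor of 0.1/yr;
  the floor prevents discarding a substantively large rate that merely has a
  wide interval. Pruning refuses any mask that would disconnect a phase
  from absorption (all of phase 3's exits, or ρ₄). The model is then
  refitted jointly with the enlarged mask.

On simulated cohorts of 5,000 patients the staged fit recovers the 13 free
parameters with calibrated uncertainty (pooled median |estimate − truth|/SE
≈ 0.66 over 20 replicates, against the half-normal reference 0.674). These
replicate counts and cohort sizes are the package's standard experiment
sizes, chosen to make the recovery and calibration checks statistically
informative while staying cheap.

## Synthetic cohorts

`simulate_cohort` draws records by forward simulation: competing exponential
sojourns and categorical exit causes, vectorized phase by phase. The default
configuration emulates the study cohort profile: n = 1,234, stroke-type mix
proportional to the published discharge counts by type (≈ 11% haemorrhagic,
56% infarction, 33% TIA), and a truncated-normal age distribution (mean 75,
sd 10, support [40, 100]) standing in for the unpublished age profile.
Stays are emitted as fractional days; an optional flag rounds to whole days
(minimum 1) to mimic administrative granularity.

What the simulator does *not* reproduce: the true age and age-by-type
structure of the source cohort, admission-date processes and occupancy
(there is no arrival model), secular changes in practice, the
"unspecified stroke type" admissions excluded from the model (unknown type
labels are rejected at parse time), and any model misspecification present
in real data. Passing recovery and calibration tests on these cohorts
therefore demonstrates internal consistency of likelihood, optimizer and
uncertainty — not that the model fits any particular hospital's data.

## Diagnostics

For each stroke type, discharge mode and age band (default [60,70), [70,80),
[80,90)), the cause-specific cumulative intensity is estimated two ways:
the Nelson–Aalen step function (increments dᵢ/nᵢ, variance Σdᵢ/nᵢ²,
log-transformed 95% limits so the lower bound stays positive), with
competing discharges treated as right-censoring — the standard
cause-specific construction — and the model curve Λ_m(t) = ∫₀ᵗ
[α′exp(**T**s)t_A e_m]/[α′exp(**T**s)1] ds, integrated on a trapezoid grid
refined until values change by < 1e-6, evaluated at the band's endpoints
and midpoint. The comparison grid is the observed event times (thinned to
60 quantile points), which avoids the degenerate pre-first-event region
where the nonparametric band has zero width. The summary statistic per cell
is the fraction of grid points at which the midpoint-age model curve lies
inside the 95% band; on data simulated from the fitted model the median
coverage across cells is ≥ 0.9 (null calibration). Evaluating the model at
the band midpoint ignores the age mixture within the band; the induced bias
is second-order in the band width and is part of what the coverage
statistic absorbs.

## Known limitations

* No censored stays, no gender or other covariates, no time-inhomogeneous
  rates, and no queueing/occupancy layer; these are outside the model.
* True-zero rates sit on the parameter boundary, so their Wald statistics
  are conservative rather than exactly normal; pruning decisions use them
  only in the direction (large p → prune) where this is safe.
* The diagnostic is a visual-band coverage summary, not a formal global
  test of fit.
* The reference parameter vector is reproduced from the published fit; the
  underlying hospital records are not available, so all estimation
  experiments run on synthetic cohorts.
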