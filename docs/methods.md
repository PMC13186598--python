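# Methods

## Scope and model

`slopebench` simulates steady-state, between-subject populations of three
motor-learning quantities — implicit recalibration *I*, explicit strategy
*E*, and total adaptation *A*, all in degrees of hand angle — and measures
how OLS regression slopes among them behave under benchmark tests of the
additivity assumption *A* = *I* + *E*. Trial-by-trial learning dynamics
(retention, error-sensitivity updates) are out of scope; only the
steady-state shared-error relation is modelled.

Three population constructions are provided, and in all three the additive
identity holds *exactly* (to the float, asserted in the test suite):

1. **Subtractive** — (A, E) drawn from a bivariate normal, I := A − E.
   Mirrors aim-report designs, where the derived variable is mathematically
   coupled to the measured ones. The stored total is re-expressed as
   I + E so the identity is exact in floating point; this differs from the
   sampled A by at most one rounding step and has no statistical effect.
2. **Independent** — (I, E) drawn from a bivariate normal, A := I + E.
3. **Shared-error** — E ~ N(μ_E, σ_E) per individual, I := p_i (r − E),
   independent Gaussian measurement noise added to each component,
   A_obs := I_obs + E_obs. The observed total is the sum of the *noisy*
   measures, mirroring how additivity is assessed from data; summing the
   noise-free components instead would change the E∼A and I∼A slopes from
   ≈(0.98, 0.02) to ≈(2.86, −1.86). Explicit draws are not truncated:
   negative aims are allowed, since truncation would bias the analytic
   slopes that serve as oracles.

## Closed-form oracles

`slopebench.theory` carries the expected slopes (see README for the
formulas). The subtractive and independent forms follow directly from
β = Cov(x, y)/Var(x). The shared-error closed forms are derived here by
covariance algebra on the generative model and are *gated behind an oracle
test*: they must agree with brute-force OLS on ≥10⁶ simulated participants
to within 3 Monte Carlo standard errors over 10 randomly drawn valid
parameter sets before anything else relies on them. The attenuation form is
the classical reliability ratio of errors-in-variables theory.

The e_on_a/i_on_a denominators vanish only when p_i = 1 with zero
measurement noise (observed total constant); this raises a domain error
rather than returning infinities.

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| Subtractive sweep moments | μ_A = 25°, σ_A = 2.5°, μ_E = 5°, σ_E = 2.5° | values approximating aim-report group statistics from the empirical literature |
| Sweep design | n = 25, 10,000 iterations, ρ ∈ [−0.9, 0.9] | n matches typical sample sizes; the 0.1 grid step is a package choice matching the visual density of the reference sweeps (endpoints only are stated there) |
| Benchmarks | −1 (subtractive), 0 (independent) | the slope values claimed to be diagnostic of additivity |
| Independent sweep ratios | σ_I/σ_E ∈ {0.5, 1.0, 2.0}, σ_E = 2.5° | spans the compression/amplification range; means default to 0° since slopes are location-invariant |
| Shared-error model | r = 30°, p_i = 0.65, E ~ N(12°, 4°), τ_I = 2°, τ_E = 4°, population 1,000, bootstrap 10,000 × n = 25 | p_i = 0.65 is consistent with empirical implicit-capacity estimates; τ_E > τ_I reflects the greater variability of aim reports |
| Loose-additivity base | σ_I = σ_E = 2.5°, ρ = −0.5, noise 0–5° in 0.5° steps on both components | ρ = −0.5 is the stated condition; base SDs are a package choice in the range used elsewhere and are exposed as config, not constants |
| CI method | t distribution, df = n − 2, two-sided | standard OLS practice; the rejection rule is CI exclusion, numerically equivalent to a two-sided t test of the benchmark |

## Numerical and design choices

* **Sampling.** Bivariate draws use the closed-form 2×2 Cholesky factor;
  |ρ| = 1 is an exact linear map of one normal draw, not a near-singular
  factorization, so the conceptual boundary cases are exact.
* **Seeding.** One master seed per experiment. Each condition derives an
  independent PRNG substream keyed by
  `SeedSequence([master, experiment_tag, condition_key])`, where the
  condition key encodes the condition's parameters (e.g. round(1000·ρ));
  results are therefore independent of grid order, and doubling the
  iteration count leaves the first half of every condition unchanged
  (arrays are drawn in C order from a single stream; the loose-additivity
  study uses separate substreams for base draws and noise draws for the
  same reason). Identical seeds give bit-identical outputs on a platform.
* **Batch OLS.** Sweeps fit ~10⁴ regressions per condition through a
  vectorized slope/SE/CI computation, tested to agree with the scalar
  `fit_slope` path (scipy.stats.linregress + t CI, cross-checked against
  statsmodels) to 1e−12.
* **Degenerate fits.** Exact-linear data collapse the CI to a point;
  benchmark rejection is then strict inequality against that point. A
  constant predictor raises a domain error. A constant outcome yields
  slope 0 with SE 0 (computed from the residual sum of squares, since
  linregress reports NaN there).
* **Bootstrap vs fresh sampling.** The shared-error study resamples a
  *fixed* population of 1,000 with replacement (standard bootstrap), so its
  slope distributions center on that population's slopes, which differ from
  the analytic values by finite-population noise (slope SEs ≈ 0.015–0.022
  at N = 1,000 — reported values like −0.35 vs the analytic −0.325 are one
  such draw). The loose-additivity study instead draws *fresh* datasets of
  n = 25 per iteration, so its slope distributions center exactly on the
  closed-form attenuation prediction; the sampling scheme there is not
  pinned down externally, and this choice makes the prediction/simulation
  comparison clean.
* **Residual diagnostics.** ε = A − (I + E) is evaluated in that order so
  it is exactly zero whenever the total was constructed as the float sum of
  the components; correlations of ε with I, E, I·E and I+E are reported as
  0 when ε has zero variance. A multiplicative gating term leaves a
  negative ε–(I·E) correlation; a saturating combination, a negative
  ε–(I+E) correlation. Only these fingerprint statistics are computed; no
  specific gated/saturating generative model is implemented, since no
  concrete functional forms are established.
* **Monte Carlo tolerances.** Experiments emit per-condition MC standard
  errors (sd/√iterations for mean slopes, binomial SE for rejection rates);
  test tolerances are multiples of these, not fixed magic numbers
  (4 SEs for single comparisons, 5 for 19-point simultaneous bounds,
  1.2533·sd/√iters for medians).

## What the generators do and do not emulate

The generators reproduce the *population covariance structures* under which
slope benchmarks are evaluated: jointly normal individual differences,
exact within-individual additivity, homogeneous independent Gaussian
measurement noise. They do not emulate temporal instability of the
components, measurement reactivity of aim reporting, non-normal or
heteroscedastic individual differences, truncation of strategies at task
bounds, or within-subject trial noise. Passing tests therefore establish
the statistical argument — that slope deviations from −1/0/1 arise under
exact additivity — not that any particular empirical dataset satisfies
additivity; no empirical data are ingested or reanalysed.

## Known limitations

* OLS only; Deming/orthogonal regression would be the errors-in-variables
  alternative when both axes are noisy, but the benchmark tests under study
  are OLS-based, so that is deliberately out of scope.
* No asymptotic standard errors for the expected slopes: uncertainty is
  always simulation/bootstrap based.
* The β(I~A) shared-error prediction is sensitive to τ_I (the τ_I² term can
  flip its sign); conclusions about its sign at N = 1,000 are dominated by
  sampling noise.
* Problem sizes in the test and acceptance runs are the full published
  ones (10,000 iterations, populations of 10⁶ in oracle checks), chosen
  because the vectorized drivers complete them in seconds.
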