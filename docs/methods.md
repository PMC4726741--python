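# Methods

## The chemostat model family

A single microbial population of concentration *N* (units of 10⁶ cells/ml) is
cultured in a chemostat whose medium flows through at dilution rate *d*
(h⁻¹), removing cells at that per-capita rate, while the culture is
continuously irradiated at dose rate *R* (Gy/h).  Twenty candidate rate laws
M1–M20 describe the per-capita rate of change `(dN/dt)/N`.  They share a
common mechanistic vocabulary — proliferation split into a
radiation-independent component *g* (h⁻¹) and a radiation-responsive
component *q* (h⁻¹) suppressed exponentially at rate δ (h/Gy); direct
killing *k·R* (k in Gy⁻¹), with quadratic variants; logistic self-limitation
*m·N* (m in ml/(h·10⁶ cells)), optionally modulated by *R* and/or *d*
through auxiliary coefficients μ, σ — and differ in which mechanisms they
include and how stressors interact.  A twenty-first variant (`M1x`, separate
radiation sensitivities of the two proliferation components) is registered
but excluded from default selection: its extra sensitivity collapses to zero
at the optimum, making it mathematically indistinguishable from M1.

Every law is affine in *N*: `(dN/dt)/N = a(R, d) − b(R, d)·N` with *b* > 0.
That affinity is the backbone of the package and is enforced by a
three-point-collinearity property test.  It gives closed forms for

* the signed equilibrium *N*ₑ꘎ = *a*/*b* (negative values are reported as
  such and flagged extinct — they are the natural continuation of the
  prediction curve below zero);
* the critical dose rate *R*crit(*d*): the smallest *R* ≥ 0 with
  *a*(*R*, *d*) = 0.  Because some laws are non-monotone in *R* (M9's
  √R-stimulation term), the root is located by scanning a geometric grid
  (64 points per decade from 10⁻³ to a 10⁵ Gy/h ceiling, plus R = 0) for the
  first sign change and bisecting inside that bracket (default absolute
  tolerance 10⁻⁶ Gy/h).  If *a*(0, *d*) ≤ 0 the population is extinct even
  unirradiated and (0, extinct_without_radiation) is returned; if *a* never
  crosses zero below the ceiling (e.g. M17 with *g* > *d*, which has no
  unbounded loss term) an infinite no-extinction sentinel is returned rather
  than an error, so that model averaging can handle such laws gracefully;
* the full logistic trajectory, used only as an independent oracle for the
  equilibrium (the closed form and an LSODA integration agree to 10⁻⁸
  relative in tests).

Parameters are constrained nonnegative (denominators of the form `x·μ + 1`
are then automatically positive); √R evaluates to 0 at R = 0; exponents are
clipped at the double-precision range so pathological optimizer iterates
stay finite instead of overflowing.

## Fitting conventions

The original steady-state measurements behind this family are not shipped
with the package, and neither is the authors' exact objective; the fitting
conventions below are this package's own documented choices, all switchable
through `FitConfig`.

* **Objective.** Weighted Gaussian least squares on untransformed equilibrium
  concentrations: Σ[(value − *N*ₑ꘎)/sd]², i.e. −2 ln L up to a constant that
  cancels in all AICc differences.  Observation SDs come from the
  measurements' 95% CIs (half-width / 1.96), falling back to a relative CV
  (default 10%) when a CI is missing.  Critical-dose observations are *not*
  fitted by default; setting `fit_critical_dose=True` adds them as ordinary
  residuals.
* **The g convention.** The radiation-independent proliferation component is
  by default not freely adjusted: since *a* is affine in *g* for every law
  containing it, *g* is solved in closed form from the persistence boundary
  condition *a*(*R*crit_obs, *d*_obs) = 0 at the critical-dose observation
  with the lowest dilution rate — data that the objective itself never sees.
  Alternatives: `fixed` (an external value) and `free` (optimize *g* like
  any other parameter; required when no critical-dose observation exists).
* **Counting parameters.** `p_free` counts only freely optimized structural
  parameters (profiled/fixed *g* excluded; the residual variance is not
  counted because the SDs are fixed inputs, not estimates).  AICc =
  −2lnL + 2p + 2p(p+1)/(n−p−1) requires n > p+1; laws too rich for a given
  dataset are skipped and recorded, not silently dropped.
* **Optimization.** Bounded trust-region least squares
  (`scipy.optimize.least_squares`, TRF) from a deterministic
  characteristic-scale start plus 15 seeded Latin-hypercube starts drawn
  log-uniformly within the bounds m ∈ (10⁻⁵, 1), g, q ∈ (0, 5), k ∈ (0, 0.1),
  δ ∈ (0, 1), μ, σ ∈ (0, 10).  Log-uniform sampling matters: the parameters
  span four orders of magnitude, and uniform starts strand the competition
  exponents μ, σ in a flat overflow plateau.  Ties below 10⁻⁹ in the
  objective are broken by lexicographically smallest parameter vector, making
  fits bit-reproducible for a given (dataset, config, seed).
* **Model selection.** ΔAICc and Akaike weights exp(−Δᵢ/2)/Σexp(−Δⱼ/2);
  evidence for a mechanism is the summed weight of the laws embodying it; the
  confidence set is ΔAICc < 6 (always containing the best law).  Multimodel
  predictions average the confidence set with renormalized weights;
  no-extinction sentinels enter the average as the dose-rate ceiling with a
  warning.  `SelectionTable` can also be built from an externally reported
  (ΔAICc, weight) table, in which case the rounded published weights are
  renormalized to sum to one.
* **Bootstrap.** Parametric: every observation (including the critical-dose
  data consumed by the *g* profile) is redrawn from Normal(value, sd)
  truncated at zero, CIs shifted to keep their half-widths, and the model
  refitted warm-started from the base optimum; 2.5/97.5 percentiles give the
  intervals.  Parameter correlations (e.g. between *k* and δ) are Pearson
  correlations of the replicate draws.  More than 20% failed refits aborts
  with diagnostics.
* **Sensitivity.** One parameter at a time is multiplied by 1.10 with all
  others held at their fitted values, and the ratio of perturbed to baseline
  *R*crit is tabulated over a dilution-rate grid.  At near-zero dilution
  *R*crit ≈ *g*/*k*, so the *k* ratio approaches 1/1.1 ≈ 0.909; as *d* grows
  the proliferation parameters (*q*, *g*, δ) take over and the *k* ratio
  rises toward 1 — the package reproduces this crossover.
* **Collapse summary.** `rcrit_fold_drop` finds the dilution rate at which
  the unirradiated equilibrium halves (for M1, d = (g+q)/2) and reports
  *R*crit(baseline)/*R*crit(there).  Its value depends strongly on *g*, which
  the underlying study never printed; with the package's default g = 0.1 h⁻¹
  the fold is ≈ 8–10, demonstrating the super-proportional collapse of the
  extinction threshold under an added stressor.

## Community statistics

* **Chao2.** Bias-corrected incidence-based richness
  S_obs + ((m−1)/m)·q1(q1−1)/(2(q2+1)) with the matching variance and a
  log-normal 95% interval anchored at S_obs (zero-width when q1 ≤ 1, where
  the correction vanishes).  The classic variant q1²/(2q2) with its variance
  is available as `variant="classic"`; it is what common richness software
  (e.g. vegan's `specpool`) reports when duplicates are present, and the
  test suite cross-checks both variants against vegan through Rscript.
* **2×2 exact inference.** The odds-ratio point estimate is the cross-product
  ratio (a·d)/(b·c), with 0/∞/0-over-0 flagged rather than raised and an
  optional Haldane–Anscombe correction.  The two-sided p conditions on both
  margins and uses the minimum-likelihood convention (sum of noncentral-
  hypergeometric point probabilities not exceeding the observed one; at odds
  ratio 1 this equals the classic Fisher exact p).  The CI inverts the *same*
  test — the set of odds ratios whose two-sided p is ≥ α, located on a log
  grid that always contains ψ = 1 and refined by bisection — so the interval
  and the p-value are exactly dual by construction: the CI excludes 1 iff
  p < α.  This differs from the central (two one-sided tests) interval that
  R's `fisher.test` reports; published intervals computed that way will not
  match digit-for-digit.
* **Collinearity.** Pearson correlation (scipy) with explicit zero-variance
  guards; VIFⱼ = 1/(1−R²ⱼ) from the OLS regression (with intercept,
  statsmodels) of each predictor on the others, raising an error naming the
  dependent columns when the matrix is rank deficient.

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised and scored.

* **Chemostat** (`ChemostatDesign`): truth is law M1 with the reported
  best-fit coefficients k = 5.78×10⁻⁴ Gy⁻¹, δ = 4.78×10⁻² h/Gy,
  q = 0.599 h⁻¹, m = 2.11×10⁻³ ml/(h·10⁶ cells), completed with
  g = 0.1 h⁻¹ — a value consistent with all of the package's worked
  examples; the study itself never printed *g* (it was recovered from
  unpublished side data), so this is a package choice, made once.  The
  default grid crosses dose rates 0–80 Gy/h with dilution rates
  {0.05, 0.2} h⁻¹, keeping only persistent conditions (11 equilibrium
  points) plus critical-dose observations at both dilution rates; noise is
  multiplicative with CV 5% (truncated normal at zero by default, lognormal
  behind a flag), and the synthetic 95% CI fields are value ± 1.96·cv·truth
  so the CI-derived SD equals the generating SD exactly.  One observation
  per condition, matching a study design without reported replicates.
* **Incidence** (`IncidenceDesign`): detections are Bernoulli draws from
  logit⁻¹(α₀ + aᵢ + (β + bᵢ)x) with normal random intercepts/slopes per
  species — the data-generating form of a logistic GLMM.  Defaults mirror
  the reactor-building fungal survey scale: 37 species, 15 low- and 9
  high-exposure samples, a weak positive fixed effect β = 0.35 and unit
  random-effect SDs.  GLMM *estimation* is out of scope; only the simulator
  is provided.
* **Contaminants** (`ContaminantDesign`): multivariate normal on the log
  scale with a prescribed PSD correlation matrix, exponentiated to
  log-normal profiles; the default five-variable structure carries the
  reported Cr–NO₂ co-release correlation of 0.83.  Optional per-taxon
  presence outcomes follow a logistic model on the log concentrations.

What passing tests on these generators do *not* show: robustness to
non-Gaussian measurement error in the real chemostat data, to the unknown
replicate structure of the original experiments, to spatial correlation among
field samples, or to species interactions — none of which the generators
emulate.

## Problem sizes and numerical choices

The simulation studies in the test suite use deliberately modest sizes chosen
to characterize the estimators well: 50 replicates for noisy parameter
recovery, 12 replicates of the full 20-law ranking for selection recovery,
100 outer simulations × 100 bootstrap replicates for coverage, 1000 random
draws for the equilibrium/ODE oracle and 300 for the critical-dose/grid-scan
oracle, and exhaustive enumeration of all 2×2 tables with row margins ≤ 10
for the CI/p duality.  The acceptance script summarizes recovered
coefficients as the median over ten simulated experiments because
single-experiment estimates of *k* and δ are strongly collinear (bootstrap
correlation ≈ 0.96–0.97) and individually carry ~40–50% sampling error at 5%
measurement noise — an identifiability limit of the design itself, visible
equally in the wide reported intervals for these coefficients.

## Known limitations

* The profiling of *g* transmits the measurement error of a single
  critical-dose observation into all other coefficients, notably *k*; with
  noisy critical-dose data the `free` convention is statistically preferable.
* The exact-CI construction assumes the acceptance region in ψ is an
  interval; the minimum-likelihood test is not guaranteed unimodal, but the
  exhaustive small-table enumeration found no violations.
* Percentile bootstrap intervals undercover slightly at 100 replicates; the
  coverage test budget accounts for the binomial tolerance only.
* Equilibria are deterministic: no demographic noise, spatial structure,
  age/cell-cycle structure or multi-species competition.
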