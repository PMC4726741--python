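# radstress

Quantitative modeling of microbial population responses to chronic ionizing
radiation combined with other stressors.

Microbial communities in radionuclide-contaminated environments (nuclear waste
sites, reactor buildings, chronically irradiated cultures) are rarely limited
by radiation alone: chemical toxicants, oligotrophy and elevated cell removal
rates act at the same time. `radstress` packages the quantitative toolkit for
analysing such data:

* **Twenty mechanistic chemostat growth laws** (M1–M20) for a population of
  concentration *N* (10⁶ cells/ml) diluted at rate *d* (h⁻¹) under dose rate
  *R* (Gy/h).  Every law has the affine per-capita form

  ```
  (dN/dt)/N = a(R, d) − b(R, d)·N
  ```

  e.g. the best-supported law M1:
  `(dN/dt)/N = −d − m·N + g + q·exp(−δ·R) − k·R`, with proliferation
  components *g* (radiation-independent) and *q* (suppressed by radiation at
  rate δ), a linear kill term *k·R*, and logistic self-limitation *m*.
  The signed equilibrium is *N*ₑ꘎ = *a*/*b*; the critical dose rate
  *R*crit(*d*) is the smallest root of *a*(*R*, *d*) = 0 — above it the
  population goes extinct.
* **Inference**: weighted least-squares fits (SDs from the measurements' 95%
  CIs), analytic profiling of *g* from a critical-dose observation that is not
  itself fitted, AICc ranking with Akaike weights
  *wᵢ* = exp(−Δᵢ/2)/Σⱼexp(−Δⱼ/2), evidence sums over mechanism subsets,
  multimodel-averaged predictions over the ΔAICc < 6 confidence set,
  parametric-bootstrap confidence intervals, and one-at-a-time 10%
  perturbation sensitivity of *R*crit.
* **Community statistics** for field surveys: bias-corrected Chao2 incidence
  richness with log-normal CIs, exact 2×2 odds-ratio inference (minimum-
  likelihood two-sided p with the dual exact CI), Pearson correlation and
  variance inflation factors.
* **Synthetic-data generators** for all three input kinds (steady-state
  chemostat tables, logistic-GLMM presence/absence incidence, correlated
  log-normal contaminant profiles), each seeded and emitting a truth record.

## Worked example

```python
import radstress as rs

# simulate a chemostat experiment from the reported best-fit law M1
design = rs.ChemostatDesign(noise_cv=0.05, seed=8)
dataset, truth = rs.generate_chemostat_dataset(design)

fit = rs.ChemostatGrowthModel(dataset, "M1").fit(seed=2)
print(fit.summary())
```

```
Chemostat growth model fit: M1
  cell killing and suppression of proliferation by radiation
  (dN/dt)/N = -d - m*N + g + q*exp(-delta*R) - k*R
  n_obs = 11, p_free = 4, -2lnL = 8.0744, AICc = 22.7410
  parameters:
         m = 0.00195197  (free)
         g = 0.106789  (profiled)
         q = 0.549111  (free)
         k = 0.000675141  (free)
     delta = 0.047652  (free)
```

The generating truth was m = 0.00211, g = 0.1, q = 0.599, k = 0.000578,
δ = 0.0478 (the reported best-fit coefficients for chronically γ-irradiated
yeast).

Four parameters are freely optimized; *g* is recovered analytically from the
critical-dose observation at the lowest dilution rate (it makes the predicted
extinction threshold match that measurement exactly).  The fit recovers the
generating coefficients within their sampling error — *k* and δ in particular
are strongly collinear and individually uncertain, which the parametric
bootstrap quantifies:

```python
boot = fit.bootstrap(n_replicates=300, seed=3)
print(boot.param_ci.loc["k"])           # percentile CI for k
print(boot.param_correlations().loc["k", "delta"])
```

Ranking all twenty laws and averaging the extinction threshold over the
confidence set:

```python
selection = rs.fit_all_models(dataset, "all", seed=1)
print(selection.table.summary())        # dAICc and Akaike weight per law
rcrit = selection.mmi_predict("critical_dose", [0.05, 0.2, 0.35])
```

A published-table example — the detection contrast of *Penicillium hirsutum*
between high and low dose-rate locations:

```python
table = rs.ContingencyTable2x2(8, 1, 1, 14)
rs.sample_odds_ratio(table)             # 112.0
rs.fisher_exact(table).p_value          # 0.000104
```

The command-line interface mirrors the library
(`radstress simulate|fit|select|rcrit|bootstrap|sensitivity|richness|odds|corr|vif`);
run `radstress --help`.

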