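# interosat

Analysis pipeline for a satiety-interoception drink paradigm, plus a
precision-weighted Bayesian-observer simulator for validating it.

## The problem

Classic interoception measures (heartbeat counting, the satiety quotient)
confound two processes: **top-down expectations** about how a food will
make you feel, and **bottom-up sensations** arising from physiology.  In
a predictive-coding reading, a post-prandial feeling such as fullness is
a posterior belief — a precision-weighted blend of a prior expectation
and interoceptive evidence.  A single-visit paradigm can separate the two:
participants rate the *expected* satiety of a sweet drink (and their
confidence in that expectation) before and after tasting it, then drink
either glucose (flavour-nutrient congruent) or sucralose (sweet but
calorie-free), while hunger and blood glucose are tracked at 0, 15, 30
and 60 minutes.

`interosat` computes the per-participant indices this design affords and
runs the full statistical battery over them:

- **SD-BT / SD-AT** (satiety divergence): `1 − abs(E − A) / (E + A)` for
  expected satiety `E` (before/after tasting) vs actual satiety `A`
  (fullness at 15 min).  High = the post-prandial state matched the
  expectation (expectation-driven).
- **IC** (interoceptive coherence): `−corr(G(t), H(t))` over the 4-point
  glucose and hunger trajectories.  High = hunger falls as glucose rises
  (sensation-driven); an absolute variant `abs(corr)` is available.
- **ESC update**: confidence after − before tasting; how gustatory
  evidence changed prior precision.
- **AUCi**: baseline-anchored trapezoidal area of hunger over 0–60 min.
  Positive = rebound hunger, negative = sustained suppression.
- **glucose Δ60**: `G(60) − G(0)`, a coarse glucose-tolerance readout.

The battery: per-condition Pearson correlation matrices with
Benjamini–Hochberg FDR, partial correlations controlling BMI, pooled
t tests with a Levene gate, mixed-design (split-plot) ANCOVAs with a
continuous trait covariate (e.g. hunger: Time × Drink × DIF, with the
classic `F(3, 174)` df shape at N = 62), Cook's-distance outlier
replacement on the divergence scores, and median-split/correlation
probes of significant interactions.

Because no participant-level dataset is distributed with the paradigm,
the package ships a **synthetic-cohort generator**: each simulant is a
Bayesian observer whose reported hunger is
`H(t) = (π_prior·H_pred + π_sens·H_phys(t)) / (π_prior + π_sens)`,
with both precisions driven log-linearly by the trait score (difficulty
identifying feelings, DIF).  The generator reproduces the paradigm's
design (arms matched on DIF, a 75 g glucose load peaking ~30 min,
sucralose rebound drift) and exposes every generating parameter, so
parameter recovery and false-positive control are directly testable.

## Worked example

```python
from interosat import AnalysisConfig, SimulationConfig, run_pipeline, simulate_cohort

cohort, truths = simulate_cohort(SimulationConfig(seed=7))   # 31 per arm
report = run_pipeline(cohort, AnalysisConfig())
print(report.ancova.query("analysis == 'hunger'").to_string(index=False))
```

```
analysis             effect           F  df1  df2            p      pes
  hunger               time   96.225717    3  174 9.369588e-37 0.623928
  hunger       time_x_drink  180.999547    3  174 2.898664e-53 0.757322
  hunger         time_x_cov   43.151121    3  174 6.732164e-21 0.426601
  hunger time_x_drink_x_cov   74.384452    3  174 5.238798e-31 0.561882
  hunger              drink 1053.874349    1   58 6.813752e-39 0.947836
  hunger                cov   20.616892    1   58 2.884029e-05 0.262245
  hunger        drink_x_cov  447.904400    1   58 5.824918e-29 0.885354
```

The Time × Drink × DIF interaction (`time_x_drink_x_cov`) is the rebound-
hunger signature: only high-DIF simulants in the sucralose arm get
hungrier after 15 min.  The correlation table shows the expected trait
pattern in the glucose arm — confidence and divergence indices fall with
DIF while coherence rises:

```
condition      x   y         r  n            p        p_adj  significant
  GLUCOSE esc_bt dif -0.971227 31 1.281479e-19 2.691105e-18         True
  GLUCOSE  sd_at dif -0.647408 31 8.263837e-05 3.470811e-04         True
  GLUCOSE     ic dif  0.556480 31 1.149984e-03 1.857667e-03         True
```

And the two-group comparison table shows strong hunger
suppression after glucose versus rebound after sucralose
(`auci_hunger`: −790.4 vs +259.9 mm·min, t = −9.55).

The same pipeline runs from a shell:

```bash
interosat simulate --n 31 --seed 7 --out cohort_dir
interosat analyze cohort_dir/cohort.csv --out report_dir
interosat recover --n 500 --seed 1
```

`analyze` accepts `--ic-variant {signed,absolute}`,
`--sd-transform {none,arcsine}`, `--cooks-mode {4overN,0.2}` and
`--fdr-level`.

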