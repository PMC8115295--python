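# Methods

## Indices

**Satiety divergence.** `SD = 1 − |E − A| / (E + A)` with `E` the
expected-satiety VAS (mm) and `A` the actual-satiety (fullness) VAS
rated 10 minutes after consumption ends (15 minutes into the session).
"Actual satiety" is the fullness item, not any hunger item: it is the
only state rating collected at that timepoint.  SD is symmetric,
scale-invariant, equals 1 iff `E = A`, and is undefined at
`E = A = 0` (propagated as NaN with a warning — a silent 0 would bias
cohort correlations).  Because SD is bounded, the pipeline optionally
arcsine-transforms it before testing; the transform is `arcsin(x)`
(radians), which maps [0, 1] to [0, π/2].  The variance-stabilising
alternative `arcsin(√x)` would be equally defensible for proportions;
`arcsin(x)` is the minimal reading of "an arcsine transformation" and
the choice is confined to one function, selectable via
`AnalysisConfig.sd_transform`.

**Interoceptive coherence.** The within-person Pearson correlation
between the four blood-glucose and four hunger values on the
{0, 15, 30, 60} min grid, sign-reversed so +1 means hunger falls
exactly as glucose rises.  All four timepoints, including baseline,
enter the correlation.  With only 4 points the estimate is noisy;
degenerate (zero-variance) series yield NaN.  An `ABSOLUTE` variant
returns `|r|`, treating strong positive coupling (seen in some
non-caloric-arm participants) as coherence too.

**Rebound-hunger AUCi.** Trapezoidal area of `H(t) − H(0)` over
0–60 min (mm·min).  The baseline-anchored (incremental) definition is
used deliberately: a ground-anchored area of non-negative VAS values
could never be negative, whereas sustained post-drink suppression must
produce negative areas.  It is invariant to adding a constant to all
four values.

**Confidence and updating.** `ESC` ratings before/after tasting are
used raw; the updates `esc_at − esc_bt` and
`exp_satiety_at − exp_satiety_bt` quantify how gustatory evidence
shifted the precision and the content of the expectation.
`glucose_delta_60 = G(60) − G(0)` is the glucose-tolerance readout.

## Statistical battery

**Correlations and FDR.** Zero-order Pearson correlations are computed
per condition over the 21 pairs of {ESC-BT, ESC-AT, SD-BT, SD-AT, IC,
DIF, BMI}; each per-condition table is one Benjamini–Hochberg family at
δ = 0.05.  The family definition is per output table — the most
conservative defensible reading when no family is stated — and NaN
p-values from degenerate tests are excluded from the family with a
logged count.  Partial correlations (DIF vs each index controlling
BMI) residualise both series on [1, BMI] by least squares and test the
residual r with n − 3 df.

**Mixed-design ANCOVA.** For a within factor with t levels crossed
with a 2-level drink factor and one continuous covariate, the split-plot
decomposition is computed exactly: the N × t response matrix is
projected onto an orthonormal basis {mean contrast, t − 1 within
contrasts}; within-subject effects come from least squares of the
contrast scores on the between design [1, drink, cov, drink·cov]
(drink effect-coded ±1, covariate centred at the grand mean), pooled
over contrast columns; between-subject effects from the same design on
the orthonormal subject mean.  Sums of squares are Type III (full vs
drop-one-term comparison), sphericity is assumed (no correction), and
partial η² = SS_effect/(SS_effect + SS_error).  With N = 62 this gives
the (1, 58) and (3, 174) df shapes.  Strata whose total sum of squares
is at floating-point rounding level relative to the data are reported
as F = 0 rather than as ratios of rounding noise.  Covariates are
parameterised per analysis (ESC-BT for expected-satiety updating, DIF
elsewhere) since different probes pair naturally with different
covariates.

**Group comparisons.** Independent t tests are pooled-variance by
default (Levene's test, centre = mean, is reported as the homogeneity
gate, which is the convention that pairs with pooled t); Welch is
available by flag.  Zero-variance-with-unequal-means inputs raise
rather than return ±∞.

**Outlier policy.** Cook's distances from the simple regression of each
SD variable on DIF; points above threshold have their value replaced by
the mean of the unflagged values, and replacements are recorded in the
report manifest.  Two threshold modes exist because the source
descriptions conflict: the conventional 4/n rule (default) and a fixed
0.2 cutoff (replication mode).  For n = 62, "n/4" = 15.5 would flag
nothing, while cases with D > 0.2 were reportedly removed — so 4/n is
taken as the intended rule and 0.2 as the replicable behaviour.  The
policy applies to the SD variables only, before they enter any test.

**Median split.** Ties at the median go LOW; a constant series cannot
be split and raises.

## Synthetic cohorts

Each simulant is a Bayesian observer.  The trait score DIF ~
N(16.7, 5.6²) rounded and clipped to [7, 35] (arm-level means/SDs match
the paradigm's matched allocation), standardised to `z`, drives two
precisions log-linearly:

    log π_prior = a0 − a1·z      (a0 = 0, a1 = 0.5)
    log π_sens  = b0 + b1·z      (b0 = 0, b1 = 1.5)

so the sensory weight `w = π_sens/(π_prior + π_sens)` rises with DIF.
Log-linear maps keep precisions positive; only the directions are
externally specified, the magnitudes are calibration choices (below).

Glucose in the caloric arm follows `G(t) = G0 + amp·(t/tp)·e^(1−t/tp)`
(G0 = 5 mmol/L fasting, amp = 3 mmol/L, tp = 30 min — a typical 75 g
oral-load response), flat at G0 in the non-caloric arm; meter noise
SD 0.25 mmol/L.  Physiological hunger is
`H_phys(t) = H0 − k·(G_true(t) − G0)` (H0 = 65 mm fasting hunger,
k = 14 mm per mmol/L) plus a rebound drift `ρ·max(0, t − 15)`
(ρ = 0.6 mm/min) in the non-caloric arm only — the flavour-nutrient
mismatch signal.  The prior prediction is `H_pred = H0 − s`
(s = 14 mm of expected suppression).  Reported hunger is the
precision-weighted blend plus VAS noise (SD 3.5 mm), clipped to
[0, 100].  Expected satiety is the 100-complement of predicted hunger,
shifted by `u0·w` (u0 = 4 mm) after tasting; fullness at 15 min is the
100-complement of blended hunger at 15 min.  Confidence is a logistic
readout of log prior precision with a positive post-tasting boost only
above a precision threshold, so low-DIF simulants gain confidence after
tasting and high-DIF simulants do not.  BMI couples positively to DIF
(1.2 kg/m² per trait SD, residual SD 3).

Arms are matched on DIF by drawing all trait scores once, sorting, and
assigning the two conditions within each consecutive pair in
random order (random within-pair order avoids the systematic low/high
bias a strict alternation would create).

**Calibration.** The paradigm supplies directions, not effect sizes, so
the default magnitudes were calibrated once, under the package's own
recovery harness, to satisfy two competing constraints: (i) the
generating sensory weight must be recoverable from IC — which favours a
hunger-glucose gain large enough that mid-range `w` produces trajectory
signal above VAS noise, but not so large that IC saturates at 1 for most
of the weight range — and (ii) generating prior precision must be
recoverable from SD-AT, which requires the physiological state at 15 min
to diverge from the prior prediction in *both* arms (`k·ΔG(15) − s` away
from zero in the caloric arm, `s` itself in the non-caloric arm).  The
defaults above sit where both recovery correlations exceed 0.5 with
margin across seeds while every generated quantity stays physiologically
plausible.

**What the generator does not emulate.** Real cohorts have
non-Gaussian, possibly anchored VAS usage, hormonal mediators (ghrelin,
GLP-1, PYY), autocorrelated report noise, and unknown functional forms
for all couplings.  Passing recovery and pattern tests therefore shows
the *pipeline* is correct and sensitive under the stated generative
model — it does not validate the observer model against real
participants, and no fitting of the model to real data is provided.

## Experiments

**Recovery** (`recovery_experiment`): simulate, run the pipeline, and
report corr(w, IC) within the caloric arm (the only arm with a
physiological glucose signal for IC to track), corr(π_prior, SD-AT)
pooled, the DIF–ESC-AT correlation, the hunger Time × Drink × DIF
interaction (p and df), and the high-minus-low-DIF sucralose AUCi
contrast.

**Type-I control** (`type_one_error_experiment`): under a
trait-decoupled null (a1 = b1 = BMI coupling = 0) every *trait*
association is null by construction, but index–index pairs sharing a
raw measurement (SD-BT and SD-AT both use fullness) remain genuinely
correlated; the experiment therefore measures the BH family discovery
rate over the trait-association families (DIF and BMI against each
index, plus DIF–BMI, per condition), which should stay near δ.

**Problem sizes.** Defaults are 31 per arm (the study scale), 500 per
arm for recovery, 200 replicates for the null experiment and 100 seeds
for the pattern-consistency fractions — sizes at which the Monte-Carlo
error of every reported fraction is a few percent.

## Degenerate inputs, ties, tolerances

Undefined indices (0/0 divergence, zero-variance correlation) are NaN,
excluded pairwise per analysis; subjects with incomplete repeated
measures are dropped from that ANCOVA with a warning; `arcsin` accepts
1e-9 of rounding slack outside [0, 1] then clips; BH ranks ties stably;
ANCOVA agreement with the long-format design-matrix oracle is enforced
to 1e-8 in the tests.

## Known limitations

- IC from 4 timepoints is intrinsically noisy; its recovery ceiling is
  set by the saturating relationship between sensory weight and a
  4-point correlation.
- The 2-level/4-level ANCOVA assumes one 2-level between factor and one
  covariate (the paradigm's design); it is not a general mixed-model
  engine.
- Sphericity is assumed for the 4-level design (matching the reported
  uncorrected df); no Greenhouse-Geisser correction is offered.
- Pairwise deletion is used throughout; with substantial missingness
  the per-analysis n values will differ across tables.
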