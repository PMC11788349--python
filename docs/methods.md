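# Methods

## Generative model of the trial

The synthetic generator emulates a fully randomized single-season field
trial: `k` treatments × `r` replicate plots (defaults: CK/CS/CB × 3),
with every measured variable drawn independently per plot from

    value ~ Normal(baseline_mean × multiplier(treatment), cv × mean)

truncated at zero by redraw. Defaults: `cv = 0.05` for every variable,
chosen as a realistic within-treatment coefficient of variation for
composite soil samples from 30 m² plots; it is configurable per
property. Draws are made in a fixed order (treatment → replicate →
variable), so a run is a pure function of the seed.

Calibration constants are the published values of the trial the package
models. The baseline panel (pre-trial coastal saline soil: pH 8.46, salt
1.88 g kg⁻¹, soluble Na⁺ 1.52 g kg⁻¹, SOC 7.6 g kg⁻¹, TN 1.01 g kg⁻¹,
available N/P/K 50.41/34.98/393.71 mg kg⁻¹) doubles as the control's
end-of-season mean — a surrogate assumption, since control end-of-season
means were published only graphically. Treatment multipliers are
`1 + pct/100` of the reported significant percent changes (CS: salt
0.78, avN 1.91, avP 1.49, avK 1.25, BG 1.33, NAG 1.32, LAP 1.13, yield
1.22; CB: salt 0.82, CE 1.22, NAG 1.11). Non-significant changes are
modelled as no change (multiplier 1.0), except CB's BG and LAP, which
are pinned by the reported CS-vs-CB ratios (1.70 and 1.15, giving
1.33/1.70 ≈ 0.782 and 1.13/1.15 ≈ 0.983). Enzyme and yield baselines
(BG 50, CE 20, NAG 30, LAP 15 nmol g⁻¹ h⁻¹; yield 9 t ha⁻¹) are free
scale parameters: every downstream quantity is percent-change-,
min-max- or Z-score-based, and this scale invariance is itself tested
end-to-end.

What the generator does **not** emulate: spatial/block structure,
between-variable correlation beyond what the shared treatment means
induce, measurement error distinct from plot-to-plot variation,
non-normal or heteroscedastic-beyond-CV noise, and any soil-process
dynamics. Passing tests therefore show that the *analysis chain* is
correct and that the published contrasts are recoverable under the
stated noise model — not that the model captures real field
variability.

## Indices

**SQI.** Directional min-max scores use the pooled plot set as the
scoring reference (not per-treatment, not external reference ranges):
the equations define `v_max`/`v_min` with no external anchor, and
pooling is the only self-contained choice that keeps treatment
contrasts of the index well defined. The default property set is
{salt (less is better), TN, avN, avP, avK, SOC (more is better)},
n = 6; soluble ions can be added via configuration. The radar-area
formula is implemented exactly as printed in the source methodology
(`0.5 · sin(2π/n) · Σ Li²`); because radar-chart area is conventionally
the adjacent-product sum (`Σ Li·L_{i+1}`, never larger, by AM–GM), that
variant is available behind `variant="adjacent"` and a CLI flag, with
the printed form as the default for fidelity.

**EMF.** Z-scores use the sample standard deviation (N−1) — the norm
for n = 3 replicate designs — making the per-column mean-0/sd-1
invariants exact and tested at 1e−10. EMF is the row mean of Z-scores;
its grand mean over the scoring set is 0 by construction, which is why
percent changes of EMF are reported as undefined whenever the reference
mean is ≤ 0 rather than guessed.

## Inference

One-way fixed-effects ANOVA is computed from the classical sum-of-
squares decomposition (the pooled MSE and df are needed downstream by
the LSD test); it is cross-checked against `scipy.stats.f_oneway` and
against the `F = t²` identity at k = 2. Degenerate inputs: zero
within-group variance yields F = 0 (equal means) or F = ∞ with p = 0
(unequal means).

Fisher's LSD compares each pair with
`t(1−α/2, df_within) · sqrt(MSE · (1/nᵢ + 1/nⱼ))`; the default is the
*unprotected* form (pairwise tests regardless of the omnibus F), with a
`protected` option gating on the omnibus p < α — the source analysis
does not state which form it used. Letters come from an
insert-and-absorb compact letter display processed in descending-mean
order (ties broken by treatment order), with the absorb step applied
after every insertion so non-transitive significance patterns get no
superfluous letters; validity (share a letter ⟺ non-significant) is
enumerated exhaustively for all 3-treatment patterns.

Percent changes are contrasts of treatment means
(`100 · (mean_t − mean_ref)/mean_ref`), not means of per-plot ratios,
matching how such contrasts are conventionally reported. Correlation
panels use Pearson r with the two-sided t test; constant variables are
flagged NaN rather than raising.

## Yield drivers

Regressions are bivariate OLS (`scipy.stats.linregress`); slope
p-values are unadjusted — three planned contrasts, stated rather than
silently corrected.

`rf_importance` implements the `randomForest`-style %IncMSE measure:
regression trees (scikit-learn `DecisionTreeRegressor`) grown on
bootstrap samples of size n with `max_features = ⌈p/3⌉` (regression-
forest convention), unlimited depth, 500 trees by default; importance is
the mean over trees of `(OOB-MSE after permuting the feature − OOB-MSE)
/ OOB-MSE × 100`. Trees whose OOB MSE is exactly zero contribute zero
(no relative scale); bootstrap rounds with an empty OOB set are skipped.
Randomization scheme: features are canonicalized by sorted name before
fitting, the bootstrap/tree stream is seeded by the run seed, and each
feature's permutation stream is seeded by a hash of (seed, feature
name) — so results depend on seed and feature names but not on column
order. With 9 plots the importances are high-variance; the CLI offers
`--repeat-seeds k` to report means ± sd over k forests. Plot-level data
is the default input (treatment means would leave n = 3).

## Pipeline and reproducibility

`run_all` executes generate → score → analyze → relate under one
config. The master seed is split into named substreams via SHA-256
(`substream_seed(seed, "generate"|"forest")`, values < 2³¹), so forest
settings never perturb the simulated data. All stored values are full
precision; CSV output uses 12 significant digits; rounding happens only
at presentation. A config + seed reproduces every output byte-for-byte.

## Problem sizes used in validation

Self-checks run at deliberately modest sizes chosen to make the
statistics decisive: generator mean-convergence at 10⁴ replicates
(3·SE tolerance), ANOVA type-I error over 10⁴ null trials (nominal
0.05 ± 0.01), yield~SQI slope positivity over 200 simulated trials,
effect recovery over 200 trials, and forest rank behaviour over 15–100
seeds at 60–500 trees.

## Known limitations

* The control-equals-baseline surrogate makes the noise-free SQI
  contrast come out at +51.0% rather than the reported +52%; the CS-vs-
  CB SQI contrast (+35% reported) is not recoverable at all because
  CB's non-significant nutrient shifts were never published numerically.
* EMF percent contrasts reported for the original trial (+71%/+39%)
  cannot be reproduced: on the pooled Z scale the reference mean is
  non-positive by construction and the original denominator is unknown.
* Because CB's yield multiplier is pinned at 1.0 (its yield change was
  non-significant) while CB still lowers salt, salt is a weaker yield
  predictor in the generator than in the reported data; the forest
  importance tests therefore assert rank dominance of salt and
  available P over the no-effect properties, not the reported top-two
  finish.
* Independence of variables within a plot means multivariate structure
  (e.g. the salt–nutrient correlation the correlation panel displays)
  arises solely from treatment separation.
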