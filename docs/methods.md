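# Methods

## Signal-detection model

Each regional morphometry feature is modelled per diagnostic group as a
Gaussian: signal (diseased) N(t₁, σ₁²) and background N(t₂, σ₂²). Three
quantities follow in closed form:

- **Detectability index** d_A = (t₂ − t₁)/√(½σ₁² + ½σ₂²). The sign is
  retained (positive for atrophy, negative for ventricle dilation);
  downstream AUCs use |d_A|, so any informative feature scores ≥ 0.5.
- **Binormal AUC** = ½ + ½·erf(d_A/2), computed through `scipy.special`;
  `d_from_auc` is its exact inverse via `erfinv` (round-trip error below
  1e−10 over d ∈ [−6, 6]).
- **Ideal-observer cut-off**: the root of ln f_s(t) = ln f_b(t). With
  equal SDs this is the mean midpoint; otherwise the equation is quadratic
  and the root strictly between the means is returned — the other root
  lies in both far tails and never defines a usable single threshold.
  When no root falls between the means (a markedly wider signal
  distribution with closely spaced means, as in some NC→MCI contrasts)
  the function raises an error naming both roots, and tabular reports
  record the cut-off as NaN. Among single thresholds the returned
  criterion maximizes balanced accuracy under equal priors, which the
  test suite checks against a 1000-point criterion grid.

Percent change between group means is reported on the symmetric scale,
100·(c − r)/((c + r)/2), which is antisymmetric under swapping groups;
the plain convention 100·(c − r)/r is available behind a flag. The
symmetric convention is the one consistent with the published percentage
columns this package reproduces (the plain form disagrees by ~2 percentage
points on the largest effects).

The empirical ROC is built in-repo with midrank tie handling, so its
trapezoidal area equals the tie-corrected Mann–Whitney concordance
probability exactly; tests cross-check it against a brute-force pairwise
enumeration and against scikit-learn's implementation.

## Cohort reports

Group summaries use the sample SD (n−1). At cohort sizes of a few hundred
per group the choice of denominator is far below reporting precision.
Records missing a value are dropped from that feature's summary only, with
a logged count. Detectability tables evaluate every feature for every
ordered contrast (NC→AD, MCI→AD, NC→MCI by default).

Feature tables travel as delimited text (comma default, tab accepted),
one row per subject, columns `subject_id,group,region.measure,...`;
the writer keeps 12 significant digits. Group labels outside NC/MCI/AD
are rejected unless an explicit alias map (e.g. CN→NC) is supplied.

## Meta-ROI construction

Candidate regions per family are the standard "AD signature" sets: seven
cortical-thickness regions (entorhinal, middle temporal, inferior
temporal, fusiform, temporal pole, para-hippocampal, precuneus) and seven
regional volumes (hippocampus, inferior lateral ventricle, amygdala,
entorhinal, middle temporal, para-hippocampal, precuneus). The
total-ventricle volume is deliberately excluded from the volumetric
candidates: it is a global CSF composite, not a regional ROI, and its
diagnostic accuracy is the weakest of the volume set.

Features are ranked by NC→AD AUC (descending; ties break alphabetically
by region and are logged). The hybrid family takes the global top-n
(default 5) features across both families and interleaves them starting
with the best cortical feature, so each modality contributes its
strongest regions early; a `global` mode that ignores family and sorts
purely by AUC is also provided. With the published AUC ranking, the
alternating rule yields entorhinal thickness, hippocampal volume,
middle-temporal thickness, inferior-lateral-ventricle volume, amygdala
volume.

Every nested prefix of the inclusion order is scored by a one-hidden-layer
perceptron (scikit-learn `MLPClassifier`): tanh hidden units (default
⌈(k+2)/2⌉ clamped to [2, 8]), cross-entropy loss, adam with learning rate
0.01, and early stopping on a training-loss plateau (tolerance 1e−4 over
20 epochs; a held-out-score stopping criterion proved too noisy at a few
hundred subjects and could halt at initialization). Inputs are z-scored
with parameters fit on the training split only. Evaluation is a repeated
stratified 70/30 hold-out (default 25 repeats); repeat r derives its split
and its network initialization from `base_seed + r`, making the entire
evaluation bit-reproducible from one integer. The reported AUC is the
empirical ROC of the predicted signal-class probability on the held-out
split — an out-of-sample estimate by construction. The best set is the
smallest prefix attaining the maximal mean AUC (parsimony on ties: adding
regions beyond the informative core should not be rewarded). Feature
importances for the best set are permutation importances — mean held-out
AUC drop over 20 column shuffles — linearly rescaled so the maximum is
100.

## Synthetic cohorts

The generator emulates a three-group ADNI-style cohort of 789 subjects
(263 per group by default; only the total is published, so the even split
is a modelling choice) with per-feature group means and SDs set to the
bundled published statistics. Per group it draws a latent multivariate
standard normal with a configurable correlation matrix (identity by
default; an exchangeable ρ = 0.5 preset is provided), then maps each
margin to its target moments — linearly for Gaussian features, and
through the moment-matched lognormal transform
μ_ln = ln(m²/√(m² + s²)), σ_ln² = ln(1 + s²/m²) for the ventricle
volumes, whose published SD/mean ratios (up to ~0.73) would give a
Gaussian margin substantial negative mass. Gaussian rows containing
non-positive values are redrawn with a logged count. Identical configs and
seeds give bit-identical tables.

What the generator does *not* emulate: the spatial correlation structure
of real morphometry (no published inter-feature correlations exist to
calibrate it), age/sex/head-size covariates, scanner and site effects,
or label noise in clinical diagnoses. Consequently multivariate
classifier results on independent synthetic features are optimistic —
combining k independent informative features raises AUC faster than
correlated real features would (the default-cohort hybrid sets reach
AUC ≈ 0.97–0.99 where the corresponding subject-level result is ≈ 0.92)
— so the package treats subject-level classifier AUCs as
non-reproducible without the real cohort and verifies the qualitative
properties instead: single-feature classifier AUC tracks the feature's
own empirical AUC (within ±0.03 at 300/group over 25 repeats), greedy
curves do not drop when a pure-noise feature is appended (within 0.02),
and all stochastic runs are exactly seed-reproducible. The calibration
report quantifies, per feature, the gap between the empirical AUC of a
generated cohort and the binormal value implied by its parameters; the
lognormal ventricle margins show a genuine positive gap (empirical >
binormal), mirroring the same discrepancy in the published table, which
reports ventricle AUCs well above their Gaussian-formula values.

## FreeSurfer assembly

Parsers target the stable `# ColHeaders` layout of `aseg.stats` and
`?h.aparc.stats` and tolerate extra columns. Bilateral combination:
volumes and surface areas sum left + right; thickness is the
surface-area-weighted mean of the hemispheric averages (a simple mean is
available), since the published regional magnitudes (hippocampus
≈ 7.2 cm³ in NC) are on the bilateral scale. Total-ventricle volume sums
the lateral, inferior-lateral, 3rd and 4th ventricles (configurable).
Subjects missing a required file or structure are excluded with a logged
reason rather than failing the whole assembly.

## Numerical and reporting choices

- AUCs are reported to 3 decimals in tables but carried at full precision
  internally.
- Chance-level rows (identical group statistics) report AUC 0.5, percent
  change 0 and cut-off NaN rather than erroring out of a table.
- The published ventricle AUC cells are retained as reported data and
  flagged as binormal-inconsistent rather than "corrected"; ranking
  operations therefore accept any detectability table — computed or
  published — as input.
- Problem sizes in the test suite: closed-form checks are instantaneous;
  simulation-based checks use 10⁵ subjects/group for distributional
  properties, 2–5×10⁴ for AUC calibration (±0.01), and 300/group with
  25 hold-out repeats for classifier properties. These sizes put sampling
  noise comfortably below the asserted tolerances.

## Known limitations

- The binormal AUC understates the diagnostic accuracy of heavily skewed
  features; for those the empirical ROC on subject-level data is the
  meaningful figure.
- The ideal-observer criterion is a single threshold; for unequal
  variances the true likelihood-ratio acceptance region is two-sided, but
  the interior root is the only clinically usable criterion and the
  accuracy difference is negligible for the effect sizes here.
- Classifier AUCs on the default (independent-feature) synthetic cohort
  are upper bounds, not estimates of real-data performance; use the
  correlated preset for qualitatively realistic joint behaviour.
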