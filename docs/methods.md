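# Methods

## Problem setting

A comprehensive PPI predictor assigns a non-negative score to every protein
pair of a proteome (or every pair between two proteomes). True interactions
are rare — on the order of one per hundred candidate pairs — and predictors
carry strong per-protein biases: proteins with high-affinity or
high-frequency sequence features receive systematically inflated scores
against *all* partners, while highly specific proteins are suppressed. A
single global decision threshold therefore simultaneously over-calls some
proteins and silences others.

Reciprocal Perspective treats the complete score matrix as context. For a
protein *x*, the one-to-all curve (scores against all partners, sorted
descending) has a characteristic S or L shape: a short high-scoring head, a
long baseline plateau, and sometimes a low tail. Because true interactors
are rare, the baseline estimates the predictor's typical score for a
non-interactor of *x* — i.e. its bias. A candidate pair is then judged
relative to both partners' baselines and ranks rather than on its raw score
alone.

## Baseline estimation (knee detection)

Each curve is smoothed by locally weighted quadratic regression (LOESS) of
score on ordinal rank: at every rank, points within a symmetric window are
tricube-weighted and a degree-2 polynomial is fit; no robustness iterations
are applied. The knee is the interior maximum of the second derivative of
the fitted curve (central finite differences on the unit rank grid) — the
point of greatest upward concavity, where the steep head bends into the
baseline. The knee rank r_tau and fitted score s_tau define the protein's
local cutoff.

Parameters:

- **span α = 0.10** (window = fraction α of the curve length; default
  chosen once, exposed as config). Larger spans smooth more and can only
  merge curvature features, never split them (asserted as a property test).
- **degree = 2**, the minimum that tracks curvature.
- **Knee search excludes 2 grid points per end**, where finite-difference
  curvature is undefined or edge-dominated. Ties break toward the smallest
  rank, the most conservative baseline start.

### Boundary treatment

Classic nearest-neighbor LOESS keeps the window size fixed at the curve
ends by *shifting* the window inward. For knee detection this is
pathological: the shifted asymmetric windows impose a spurious curvature
maximum roughly 0.4 window-widths into the curve regardless of the data,
masking precisely the high-rank knees the model exists to find (knees live
in the head, i.e. at the curve start). We instead keep the window
*symmetric* with fixed halfwidth ⌈α·m⌉/2 and truncate it at the boundary,
as in fixed-bandwidth local polynomial regression; interior fits are
identical to the classic formulation. With this treatment, planted knees at
ranks 5–50 on 500-point curves are recovered to within a few ranks
(worst observed error: 7), where the shifted-window variant pins all
knees below rank ~25 to a constant position near rank 21.

### Degenerate curves

Curves shorter than 10 points, failed fits, and curves with no strictly
positive interior curvature (e.g. constant curves) fall back to
r_tau = ⌈m/2⌉ and s_tau = median raw score, flagged `degenerate`. The
median approximates the baseline of a flat curve; callers may filter
flagged proteins.

## Feature construction

For pair *x·y* with score s, reciprocal ranks r_xy, r_yx (ordinal, ties
broken lexicographically by partner id for reproducibility), proteome sizes
n, m (p = n = m intra-species):

- NaRRO = (r_xy · r_yx)^-1; ARRO = ((r_xy/n)(r_yx/m))^-1;
  NoRRO_A = (r_xy r_yx / n)^-1 and NoRRO_B = (r_xy r_yx / m)^-1
  (identical intra-species; two columns kept so the inter-species schema is
  stable).
- Fold differences FD_x = (s − s_tau_x)/max(s_tau_x, ε), ε = 1e-8 guarding
  flat zero-baseline curves; similarly FD_y.
- Local indicators use strict `>` (the knee point itself begins the
  baseline); the global indicator uses `≥` (a score exactly at the cutoff
  counts positive). The global threshold is the smallest score T such that
  at most (1 − specificity) of a supplied negative-score sample is ≥ T;
  target specificity defaults to 99.95%.

Features are typed Rank / Score / Fold for ablation; the raw score is the
"Original" feature. Pair orientation is fixed canonically (lexicographic)
by default. In symmetric mode each complementary X/Y pair of columns is
replaced by its mean and absolute difference, which makes rows exactly
invariant under orientation swap without destroying the spread information.

## Rescoring classifier

The cascade is a single second-stage random forest consuming the original
score plus RP features (the ablation conditions are feature subsets of this
one model). Hyperparameters are frozen — t = 100 trees, unbounded depth,
√F features per split, 5 stratified folds — and deliberately untuned so
conditions are comparable. Training data are all known positives plus an
equal-sized uniform negative sample (without replacement, self-pairs and
known positives excluded). Confidences are out-of-fold fractions of
positive tree votes, so they have granularity 1/t and no row is ever scored
by a model that saw it. Genome-wide rescoring uses a final forest trained
on the full balanced set.

## Evaluation

Balanced test sets misstate real-world precision, so precision is
recomputed from estimated sensitivity and specificity at an assumed
negative:positive ratio r: precision = Sn / (Sn + r(1 − Sp)), r = 100 by
default. PRC points sweep all distinct confidence thresholds descending
(predicted positive ⇔ confidence ≥ threshold); the precision at recall 0 is
carried from the highest threshold; AUC is trapezoidal over recall. The
empty-positive limit (Sn = 0, Sp = 1) is defined as precision 1. With
distinct-threshold grouping the ROC trapezoid equals the Mann–Whitney
statistic exactly (ties count ½), which the tests assert against a
pair-counting oracle.

Bootstrap comparison draws 80% of the positives without replacement plus a
fresh balanced negative sample each iteration, reruns the full
cross-validated training for both conditions, and compares the resulting
AUC samples with Welch's unequal-variances t-test
(Welch–Satterthwaite degrees of freedom); summaries are reported as
μ ± SE with SE = SD/√iterations. The orientation-symmetry permutation test
flips a random half of the rows' X/Y features per iteration, retrains with
identical folds, and reports percent differences in ROC-AUC, PRC-AUC, F1
and accuracy (the latter two at confidence 0.5, a fixed convention).

## Synthetic interactome generator

The generator encodes the study conditions; its defaults are fixed once:

| parameter | default | meaning |
|---|---|---|
| n_proteins | 300 | pipeline-scale proteome (44,850 pairs) |
| prevalence | 0.01 | marginal true-pair fraction, matching the 1:100 ratio used for r |
| baseline_bias_sd | 0.5 | SD of per-protein log-scale score bias (≈ ±65% typical spread) |
| head_effect | 2.0 | mean lift of a true pair above its own baseline (≈ 3× baseline) |
| noise_sd | 0.10 | multiplicative score noise SD |
| hub_fraction / multiplier | 0.05 / 4.0 | fraction of hub proteins and their degree scaling |

Per-protein baselines b_x are log-normal around a score scale of 50
(similarity-score magnitude); a pair's background score is √(b_x b_y), so a
pair couples both partners' biases through the geometric mean — the key
pathology RP exploits, where a pair looks high from a low-baseline
protein's perspective and unremarkable from a high-baseline one's. True
pairs add head_effect × background. Per-protein true-partner counts are
negative binomial (dispersion 2) with hub means scaled, realized by
Chung–Lu sampling so the marginal prevalence matches the configured value;
a protein's planted knee equals its true-partner count.

What the generator does **not** emulate: sequence-level structure,
predictor-specific score distributions (PIPE window counts, SPRINT seed
statistics), correlated errors between related proteins, and incomplete
matrices. Passing tests therefore demonstrate that the pipeline recovers
planted structure under per-protein bias and class imbalance — not that any
particular real interactome will show the same absolute AUCs.

`generate_curve` builds single one-to-all curves for knee-recovery studies:
a linear head descending to the baseline at the planted knee, an optional
S-shaped tail (final 5% of ranks dropped below baseline), additive Gaussian
noise, re-sorted descending.

## Problem sizes and numerical choices

- Knee recovery is measured on 200 curves of length 500 with knees in
  [5, 50] and noise at 1% of head height; recovery within max(3, 0.02·m)
  ranks.
- The end-to-end comparisons run on the default 300-protein interactome:
  out-of-fold AUCs for each ablation condition, 20 replicate interactomes
  for the win fraction, and a 50-iteration bootstrap for the Welch test.
  The symmetry permutation test uses 20 iterations on a 100-protein
  interactome.
- All randomness flows from explicit seeds; CLI stages derive per-stage
  seeds as (seed + 7919·offset) mod 2³¹−1. Fixed seeds reproduce every
  output file byte for byte.
- Scores must be non-negative and finite; duplicate pair orientations in
  intra-species input are averaged (the directed→undirected rule);
  conflicting duplicates in inter-species input are rejected.

## Known limitations

- Inter-species (rectangular) matrices are supported for I/O and ARRO, but
  the evaluation pipeline and NoRRO are intra-species; choosing a NoRRO
  normalization for unequal proteomes is deliberately out of scope.
- ARRO is implemented exactly as defined (r_xy normalized by n, r_yx by m)
  although r_xy ranges over m partners; intra-species the distinction
  vanishes. Both readings coincide with NoRRO up to scale there.
- The knee is a rank-resolution estimate limited by the LOESS window
  (⌈α·m⌉); knees much shorter than the half-window are located to within a
  few ranks, not exactly.
- `span` is a free parameter; no automatic span selection is attempted.
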