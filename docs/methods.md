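# Methods

## The model

`cpmkit` implements connectome-based predictive modeling (CPM) of a
behavioral score from functional connectomes, with permutation inference,
cross-cohort transfer, and network-level anatomy.

A subject's connectome is the matrix of Fisher z-transformed Pearson
correlations between regional BOLD time courses, z_ij = atanh(r_ij), with
the diagonal fixed at 0 and each off-diagonal entry treated as an *edge*.
Edges are vectorized in a fixed convention — strict upper triangle,
row-major, 0-based i < j — that every module shares; masks and serialized
models are only meaningful under this ordering, which is why it is pinned
in `datamodel` and checked against node counts whenever models cross
cohorts. Correlations are clamped to |r| <= 1 - 1e-7 before atanh so that
duplicated signals produce a large finite z rather than infinity; constant
time courses are a hard error, because silently imputing them would mask
upstream extraction problems.

CPM proper, for a training set of n subjects:

1. **Edge selection.** Correlate each edge with the score across subjects;
   keep edges with two-sided p < θ (t distribution, n − 2 df), split into a
   positively and a negatively correlated mask. The default statistic is
   the plain Pearson correlation on the Fisher-z edges; a
   partial-correlation variant (edges and score residualized on the
   nuisance covariates, df reduced accordingly) is available via
   `method="partial_pearson"`.
2. **Network strength.** For each subject, sum the selected edges per mask:
   s⁺ = Σ_{k∈M⁺} z_k and s⁻ likewise.
3. **Model.** Ordinary least squares of the score on s⁺ (intercept +
   slope), likewise on s⁻. The combined prediction defaults to the sum of
   the two single-model predictions; note that this sums both intercepts,
   so combined predictions are centered near twice the mean score. Because
   evaluation is rank-based this is immaterial, but a `two_predictor`
   rule (one OLS on both strengths) is provided when predictions on the
   score scale are wanted.
4. **LOOCV.** Steps 1–3 are repeated leaving each subject out in turn;
   the held-out subject is predicted from the fold's model. The procedure
   contains no randomness.

An empty mask (possible in small cohorts at strict thresholds) degrades to
the mean-score model with a logged warning instead of failing, so that a
full threshold sweep always completes.

### Implementation of the LOOCV folds

For the default Pearson statistic the per-fold edge-score correlations are
computed by downdating the full-sample sufficient statistics (subtracting
the held-out row from Σx, Σx², Σxy, ...), which is algebraically exact and
turns all n folds into a few dense array passes. Selection then thresholds
on |r| > r_crit, where r_crit = t_crit/√(t_crit² + df) is the exact
correlation equivalent of p < θ at the folds' common df — identical to
thresholding p, without forming a folds × edges p matrix. Tests verify
fold-for-fold mask equality and 1e-10 prediction agreement against a naive
per-fold re-implementation built on `scipy.stats.pearsonr`.

## Evaluation and inference

Agreement between predicted and observed scores is the Spearman *partial*
correlation controlling for age and in-scanner motion: predictions,
observations and covariates are all rank-transformed (average ranks on
ties), the ranked prediction and observation are residualized on the
ranked covariates plus intercept, and the Pearson correlation of the
residuals is reported. With no covariates this reduces exactly to
classical Spearman rho (tested to 1e-12 against `scipy.stats.spearmanr`).

Significance comes from a shuffled-score permutation null (default 1000
permutations): scores are permuted across subjects — covariates are *not*
permuted; they stay attached to their subjects' connectomes, so the null
breaks only the score-connectome link — and the full LOOCV including edge
re-selection is re-run per permutation. The one-sided add-one estimator
p = (1 + #{null ≥ observed}) / (1 + n_perm) is reported, so p is never 0
and never below 1/(n_perm + 1).

A point worth emphasizing: the cross-validated predicted-observed
correlation is *negatively biased* under the null (training folds overfit
noise whose sign anticorrelates with the held-out subject), with a mean
around −0.25 at n = 40 in our simulations. This is exactly why inference
is permutation-based — the null distribution carries the same bias — and
why no parametric p-value for the final rho is offered.

`evaluate_consistency` compares two models' prediction *deviations*
(pred − observed) on the same subjects by the same partial Spearman. Its
sign depends on how each model's dispersion relates to the observed
spread: two weakly predictive, shrunken models share a −observed component
in their deviations and look highly consistent; a shrunken model paired
with an over-dispersed one (as happens for our strongly planted synthetic
signal, where the transferred source model is nearly unshrunken on a wider
source score scale) can yield a negative consistency even when both
predict well. The statistic is therefore reported descriptively, not
tested against a benchmark value.

## Transfer

"Edges significant in X% of subjects" is interpreted as edges present in
at least ceil(X% × n_folds) of the leave-one-out fold masks (one fold per
subject). The ceiling is computed with a 1e-9 slack because floating
products like 0.9 × 10 land just above the integer boundary. Consensus
coefficients are re-fit by OLS on the full training cohort — the standard
externalization of a CPM, and deterministic — rather than averaged over
folds. Applied to an external cohort, the model requires matching node
counts (edge indexing must agree); predicted scores are reported raw, with
no recalibration to the target's score scale, since evaluation is
rank-based. Fractions nest: consensus(f₂) ⊆ consensus(f₁) for f₁ < f₂,
with the union of fold masks as f → 0 and their intersection at f = 1.

## Network anatomy

Nodes carry one of (canonically) 10 functional network labels; the 55
unordered network pairs (10 within + 45 between) partition the E node
pairs into blocks. For a mask of m edges of which k fall in a block
spanning K of the N = E possible edges, enrichment is the hypergeometric
upper tail p = P[X ≥ k] (population N, successes K, draws m), reported as
likelihood = 1 − p, computed by `scipy.stats.hypergeom` (log-space stable
at N = 35778) and validated against exact rational combinatorics both
exhaustively for N ≤ 25 and spot-wise at atlas scale. Only
over-representation is flagged (likelihood > 0.95, i.e. raw p < .05, no
multiple-testing correction across the 55 blocks — stated in the output
header); the population defaults to all node pairs. Output blocks are
sorted by likelihood, ties broken alphabetically for determinism.

## Synthetic cohorts

The generator plants the structure the analysis is designed to detect;
its defaults are the mirrored study's conditions:

| parameter | default | meaning |
| --- | --- | --- |
| n_subjects / n_target | 352 / 28 | source and target cohort sizes |
| n_nodes | 268 | parcellation size; 10 networks, contiguous near-equal blocks |
| n_signal_pos / n_signal_neg | 128 / 214 | planted edge counts (the reported p < .01 edge counts) |
| signal_scale | 0.5 | Fisher-z shift per unit latent trait; gives per-edge \|r\| ≈ 0.4 at the default beta and noise, mid-range for selected CPM edges |
| beta / noise_sd | 1.0 / 0.5 | score signal and noise in latent units |
| within_block_corr | 0.2 | correlation of edges sharing a network block |
| score mean/SD | 43.7/40.2 source, 55.1/32.0 target | SRS Total raw scale of the two cohorts |
| age | U(6, 15) source, U(4, 11) target | cohort age ranges in years |
| motion | Gamma, mean 0.147 mm, SD 0.044 mm | mean framewise displacement |

Direct-connectome mode draws each subject's edges as standard Gaussians
with a shared per-block factor, adds ±signal_scale·t (t ~ N(0,1) the
latent trait) on the planted edges, and sets
score = beta·t + covariate effects + N(0, noise_sd), affinely rescaled to
the cohort's score mean/SD (monotone, so rank-based results are
unchanged). Covariates are independent of the score by default; a
motion-confound switch exists to exercise the partial-correlation
evaluation. Time-series mode realizes a damped version of the same target
structure as actual node time courses (nearest-correlation-matrix
projection, Gaussian sampling) and routes them through the standard
connectome builder; finite scan length attenuates the planted signal,
which is what that mode is for.

What the generator does **not** emulate: hemodynamics and autocorrelated
BOLD noise, site/scanner effects, missing data, non-Gaussian score
distributions (synthetic scores are unbounded and can be negative,
unlike raw SRS), and realistic network topology beyond block-correlated
edges. Passing tests therefore demonstrate that the *procedure* is
correct and well calibrated under its assumed statistical structure —
not that the substantive findings of any real cohort are reproduced.
The planted effect also makes the synthetic source model stronger
(within-cohort rho ~0.5–0.8) than typical real-data CPMs (~0.3–0.5), with
the consistency-statistic consequence described above.

## Problem sizes and numerics

The validation experiments run at: oracle checks at 10–20 subjects and
E = 45; parameter recovery at 120 subjects × 60 nodes over 10 seeds with
99-permutation tests; null calibration over 200 no-signal cohorts of 60
subjects × 30 nodes, 99 permutations each; transfer at the full
352/28 × 268-node study scale over 10 seeds (plus 20 signal-free
targets); and 1000-permutation inference in the reproduction script.

Numerical choices: correlations clamped to [−1, 1] after the downdate;
constant edge columns get r = 0, p = 1 with a warning rather than an
error; zero-variance strengths and empty masks fall back to intercept-only
models; p-value thresholds are strict inequalities and edges with r = 0
are never selected; all randomness flows through `numpy` Generators with
explicit integer seeds, and repeated runs are bit-identical.

## Known limitations

- Only leave-one-out cross-validation is provided (no k-fold or
  split-half), and only univariate thresholded selection (no sparsity
  penalties).
- The consensus-mask false-selection rate is governed by the selection
  threshold and the number of null edges; at p < .01 a consensus-90% mask
  over ~1700 null edges retains roughly 5–15 spurious edges regardless of
  how strong the planted signal is, so mask *purity* cannot be pushed
  arbitrarily high by increasing effect size.
- Cohorts are taken as given; no harmonization (e.g. site correction) is
  applied before transfer.
- Tabular outputs only; no circle-plot or glass-brain rendering.
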