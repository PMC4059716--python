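# Methods

`consensusfs` implements a consensus gene-selection workflow for two-group
expression studies: three feature rankers of different character are run
independently on a probe-by-sample matrix of log-scale intensities, their
top sets are intersected, and the resulting panel is judged by how well six
standard classifiers separate the groups under cross-validation.  This note
records the models, the parameters that matter, and the design decisions
taken where the design was genuinely open.

## Data model and preprocessing

The expression matrix `M` (probes x samples) is assumed to hold normalized
log-scale intensities (RMA-style output); the loader never transforms
values, and missing cells are a hard error.  The phenotype vector `Y` is
binary, 0 = control, 1 = case.  An optional variance filter removes the
fraction `remove_fraction` (default 0.5) of probes with the lowest sample
variance, computed across all samples ignoring labels; probes whose
variance equals the removal quantile (empirical, linear interpolation) are
retained, so with all-distinct variances the retained count is
deterministic.  The full `run` pipeline defaults to `remove_fraction = 0`
because its expected input — including the synthetic benchmark — is a
matrix that has already been nonspecifically filtered.

## The three rankers

**SVM-RFE.**  A linear maximum-margin classifier (cost `C = 1`) is fit to
the surviving features (standardized to zero mean, unit variance within the
loop), each feature is scored by the squared entry of the primal weight
vector, `c_i = w_i^2`, and the lowest-scoring features are removed; the
reversed elimination order is the ranking.  The criterion presumes a linear
kernel.  By default the loop removes 10% of survivors per round while more
than 500 remain, then one per round; chunked removal only perturbs
far-from-top ranks and makes the procedure tractable at tens of thousands
of probes.  Ties are broken by input column order (the earlier column is
eliminated first).

**ROC ranking.**  Each probe is treated as a univariate classifier.  The
empirical AUC equals the Mann–Whitney statistic P(case > control) +
0.5 P(tie); the partial AUC integrates the empirical ROC polygon over false
positive rates in `[0, t0]` with linear interpolation at `t0` (default
`t0 = 0.1`, a conventional "small" FPR bound).  Ranking is two-sided by
default — a probe is scored by `max(AUC, 1 - AUC)` (for pAUC, by the larger
partial area of the probe and its negation) — so under-expressed probes are
not penalized; `one_sided=True` restores the signed ranking.  Ties keep
input probe order.

**Boruta.**  Every undecided feature receives a "shadow" copy whose values
are permuted across samples, destroying label association while preserving
the marginal distribution.  A bagged forest of fully grown decision trees
is trained on the real-plus-shadow design; each feature's importance is the
per-tree decrease in out-of-bag accuracy when the feature is permuted in
the OOB samples, summarized as a Z-score (mean over trees divided by the SD
over trees).  Permuting a feature a tree never splits on cannot change its
predictions, so only the features each tree actually uses need a permuted
prediction pass — this exact shortcut is what makes per-tree permutation
importance affordable at thousands of features.  A feature scores a hit
when its Z exceeds the best shadow Z; accumulated hits are tested against
Binomial(n, 1/2) two-sided at level `alpha = 0.05`, Bonferroni-corrected by
the **total** feature count.  Two departures from a naive reading are
deliberate:

* *Fixed multiplicity factor.*  Correcting by the shrinking undecided count
  makes late rejections progressively easier, and measurably rejected
  marginal-but-relevant features on the strength of their early hit deficit
  (hit rates climb sharply once mass rejection thins the shadow pool).  The
  fixed factor matches the reference implementation of the algorithm.
* *Adaptive tree count.*  Per-feature exposure in a forest scales as
  trees/features; with thousands of design columns a fixed 500-tree forest
  leaves the Z-scores of marginal features dominated by estimation noise
  (the max-shadow bar is then mostly noise, ~3.5 SD of 1/sqrt(trees)).  The
  per-iteration tree count is therefore `clip(design_width, n_trees,
  4 * n_trees)` with `n_trees = 500`.

Confirmed features stay in the design but are no longer tested; features
undecided after `max_iterations = 100` rounds are reported tentative, never
forced either way, and a feature whose accumulated hit count can reach
neither decision threshold before the cap is finalized as tentative as soon
as that becomes true (its outcome is already determined, so the remaining
iterations are saved).  Gini impurity importance is available as a toggle.

## Differential-expression gate

For probe g with pooled two-sample residual variance `s_g^2` on `d = n - 2`
degrees of freedom, the moderated t-statistic shrinks `s_g^2` toward a
prior `s0^2` with weight `d0`:

    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d),
    t_g = logFC_g / (s~_g sqrt(1/n1 + 1/n0)),   df = d0 + d.

The hyperprior `(d0, s0^2)` is estimated by the empirical-Bayes method of
moments on log residual variances: with
`e_g = log s_g^2 - digamma(d/2) + log(d/2)`, the excess of `var(e)` over
`trigamma(d/2)` equals `trigamma(d0/2)`, inverted by Newton iteration; a
non-positive excess yields an infinite `d0` (complete pooling, df capped at
1e8 for the t quantile).  Probes with zero residual variance are excluded
from the fit; if every probe is degenerate the fit raises.  `logFC` is the
difference of group mean log-intensities (case minus control).

The significance gate keeps probes with `|logFC| > 2` and adjusted
`p < 0.01` (Bonferroni by default, Benjamini–Hochberg selectable).  In the
consensus pipeline the gate's default role is **annotation**: it is
computed and reported per selected probe, with `gate="filter"` available to
shrink the SVM-RFE and ROC top-k sets before intersection and `"off"` to
skip it.  Annotation is the default because at cohort sizes of a few dozen
samples the adjusted-p filter's threshold (|t| ~ 4.9 at alpha 0.01,
Bonferroni over 2,000 probes) falls inside the sampling spread of genuinely
differential probes of moderate effect: a hard filter then drops probes
that all three rankers independently agree on, roughly halving end-to-end
recovery of 2-SD effects while the filter and annotation readings coincide
whenever effects are strong (as in the data regime this workflow was
designed around, where |logFC| of top probes runs 5–9).

## Consensus

Each ordered ranker contributes its top `k` probes (`k = 1000` at the
27,336-probe design scale, scaled proportionally as `ceil(0.0366 p)` for
smaller matrices); Boruta contributes its confirmed set (tentative features
excluded unless requested).  The panel is the intersection, ordered by
matrix probe order, with per-ranker membership recorded for every probe in
the union.  An empty intersection is a valid, prominently logged result.

## Classifier evaluation

Samples are partitioned into `k = 10` stratified folds (fold sizes and
per-class per-fold counts each differ by at most one; the construction
hands each class's surplus to the currently smallest folds, so
leave-one-out is reachable at `k = n`).  For each fold, standardization
parameters are learned on the training folds only; the six models — linear
SVM (C=1), 500-tree random forest, Gaussian naive Bayes, a single-hidden-
layer network with 8 units, 5-nearest-neighbours on standardized Euclidean
distance, and unpenalized logistic regression — share the same folds.
Predictions are pooled into one confusion matrix per model, from which
Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP), Accuracy and
F1 = 2TP/(2TP+FP+FN) are computed; zero-denominator metrics are reported as
undefined, never as zero.  Pooling is the default because macro-averaging
sensitivity over folds holding one or two controls is unstable;
macro-averaging is available via `pooling="macro"`.  Reports print four
decimals.

## Synthetic benchmark

The generator emulates a normalized two-group microarray matrix: per-probe
noise SD `sigma_g ~ U(1.5, 2.5)`, Gaussian values around a baseline of 8
(log2-intensity units), and a planted set of informative probes whose
case-group mean is shifted by `effect * sigma_g` with alternating sign.
Effects are scale-free in SD units; the theoretical two-sided AUC of an
informative probe is `Phi(effect / sqrt 2)`.  The study-shaped preset uses
2,000 probes x 44 samples (26/18) with 8 informative probes at effect 2 —
2,000 rather than the full 27,336 keeps the complete pipeline at
desk-scale runtime, and the noise scale is chosen so that a 2-SD shift
yields true |logFC| in [3, 5], the fold-change regime in which a
|logFC| > 2 gate is meaningful.  (Typical RMA per-probe SDs of 0.1–0.5
would make that gate unsatisfiable at any plausible effect size; the
benchmark reproduces the fold-change scale of the data regime the workflow
targets, which implies per-probe SDs above 1.)

What the generator does **not** emulate: probe-level raw intensities,
batch or array effects, missingness, heavy-tailed noise (available only as
an explicit Student-t toggle), or realistic gene–gene correlation beyond
optional equicorrelated noise blocks.  Passing recovery tests on this
benchmark therefore demonstrates the pipeline's statistical behavior under
a clean planted-signal model, not performance on raw production microarray
data.

Test problem sizes are chosen for desk-scale runtime: recovery runs at the
full 2,000 x 44 benchmark; permuted-label null calibration uses 100-probe
matrices (20 repetitions for the consensus null, with a 150-tree forest;
full default config for the Boruta confirmation-rate check).

At effect 2 SD the weakest of 8 planted probes has realized |t| ~ 4.8 ± 1.2;
the max-of-2,000-shadows bar in Boruta corresponds to |t| ~ 3.5–3.9, so for
roughly one data seed in five the weakest probe's realization falls at or
below the bar and no importance scheme can confirm it.  The documented
benchmark seeds (data 0, pipeline 1) are the package defaults.

## Numerical conventions

Ties everywhere break by input probe order (stable sorts).  All stochastic
operations take explicit seeds; a pipeline run derives per-stage seeds from
one root seed via `SeedSequence`, so a config snapshot plus seed determines
every artifact byte-for-byte.  The trigamma inverse uses Newton iteration
with the standard asymptotic starting points; AUC computations use midranks
(exact half-credit for ties).

## Known limitations

* Binary phenotypes only; no paired or multi-group designs, no covariates.
* SVM-RFE is linear-kernel only, as the `w^2` criterion requires.
* Boruta's decisions are in-sample: probes spuriously separating the
  observed cohort are genuine "relevant" findings to it, which is why the
  consensus panel, not any single ranker, is the unit of interest.
* The cross-validated metrics evaluate the panel on the same samples used
  to select it; they measure panel quality under resampling, not unbiased
  generalization error (that would need nested selection, out of scope).
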