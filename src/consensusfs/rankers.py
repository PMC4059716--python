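"""The three feature-ranking algorithms: SVM-RFE, ROC/pAUC, and Boruta.

Each ranker scores every probe of an aligned (matrix, labels) pair and is
used independently; the consensus step intersects their top sets.

* **SVM-RFE** trains a linear maximum-margin classifier, squares each weight
  (``c_i = w_i**2``) and iteratively discards the feature(s) with the
  smallest criterion; the elimination order, reversed, is the ranking.
* **ROC ranking** treats each probe as a univariate classifier and scores it
  by the (partial) area under its empirical ROC curve, two-sided so that
  under- and over-expressed probes rank equally high.
* **Boruta** pits every feature against "shadow" copies of itself (values
  permuted across samples) inside a random forest, accumulating binomial
  evidence that the feature's importance Z-score beats the best shadow.

All stochastic operations take explicit seeds; ties are broken everywhere
by input probe order (stable sorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_model import ExpressionMatrix, PhenotypeVector, RankedList

logger = logging.getLogger("consensusfs")


def _check_inputs(matrix: ExpressionMatrix, labels: PhenotypeVector) -> None:
    if matrix.sample_ids != labels.sample_ids:
        raise ValueError("matrix and labels are not aligned; call align() first")
    labels.require_both_classes()
    if not np.isfinite(matrix.values).all():
        raise ValueError("expression matrix contains non-finite values")


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RfeConfig:
    """Settings for recursive feature elimination.

    ``step`` is the number of features removed per iteration; ``None``
    selects the adaptive schedule (10% of survivors while more than 500
    remain, then one at a time), which changes only far-from-top ranks.
    ``regularization`` is the linear-SVM cost C.
    """

    step: int | None = None
    regularization: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.step is not None and self.step < 1:
            raise ValueError(f"step must be >= 1, got {self.step}")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")

    def step_for(self, n_surviving: int) -> int:
        if self.step is not None:
            return self.step
        if n_surviving > 500:
            return max(1, int(np.floor(0.1 * n_surviving)))
        return 1


def _standardized(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - mu) / sd


def svm_rfe_rank(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    config: RfeConfig = RfeConfig(),
) -> RankedList:
    """Rank probes by recursive elimination under a linear SVM.

    Each round fits ``SVC(kernel="linear")`` on the surviving features,
    computes the criterion ``c_i = w_i**2`` from the primal weight vector,
    and removes the ``step`` features with the smallest criterion (ties:
    lower column index eliminated first).  The returned list orders probes
    by elimination order, last eliminated first; scores are rank positions
    (1 = best).  Deterministic given the inputs and config.
    """
    _check_inputs(matrix, labels)
    y = labels.labels
    X_full = matrix.values.T  # samples x probes
    alive = list(range(matrix.n_probes))
    eliminated: list[int] = []

    while alive:
        if len(alive) == 1:
            eliminated.append(alive.pop())
            break
        X = X_full[:, alive]
        if config.standardize:
            X = _standardized(X)
        clf = SVC(kernel="linear", C=config.regularization)
        clf.fit(X, y)
        crit = np.asarray(clf.coef_).ravel() ** 2
        n_remove = min(config.step_for(len(alive)), len(alive))
        # stable ascending sort: among ties, lower column index goes first
        order = np.argsort(crit, kind="stable")
        victims = [alive[i] for i in order[:n_remove]]
        eliminated.extend(victims)
        victim_set = set(victims)
        alive = [i for i in alive if i not in victim_set]

    ranked_idx = eliminated[::-1]  # last eliminated = best
    return RankedList(
        ranker_name="svm-rfe",
        probe_ids=[matrix.probe_ids[i] for i in ranked_idx],
        scores=[float(r) for r in range(1, len(ranked_idx) + 1)],
        score_semantics="rank position",
    )


# ---------------------------------------------------------------------------
# ROC / AUC / pAUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocScore:
    """Per-probe ROC summary: full and partial area under the curve."""

    probe_id: str
    auc: float
    pauc: float
    t0: float

    def __post_init__(self) -> None:
        if not 0.0 < self.t0 <= 1.0:
            raise ValueError(f"t0 must be in (0, 1], got {self.t0}")
        if not -1e-12 <= self.pauc <= self.t0 + 1e-12:
            raise ValueError(f"pAUC {self.pauc} outside [0, t0={self.t0}]")
        if not -1e-12 <= self.auc <= 1.0 + 1e-12:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


def _roc_points(neg: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC polygon vertices, (fpr, tpr), from (0,0) to (1,1).

    One vertex per distinct observed value v, thresholding at "score >= v";
    tied values produce diagonal segments whose trapezoidal area awards the
    conventional half credit.
    """
    values = np.unique(np.concatenate([neg, pos]))[::-1]
    fpr = np.empty(len(values) + 1)
    tpr = np.empty(len(values) + 1)
    fpr[0] = tpr[0] = 0.0
    for i, v in enumerate(values, start=1):
        fpr[i] = np.mean(neg >= v)
        tpr[i] = np.mean(pos >= v)
    return fpr, tpr


def empirical_auc(neg: Sequence[float], pos: Sequence[float]) -> float:
    """Area under the empirical ROC curve of ``pos`` versus ``neg`` scores.

    Equals the Mann-Whitney statistic P(pos > neg) + 0.5 * P(pos = neg).
    """
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    rank_sum_pos = ranks[neg.size :].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def empirical_pauc(neg: Sequence[float], pos: Sequence[float], t0: float) -> float:
    """Area under the empirical ROC curve restricted to FPR in [0, t0].

    The ROC polygon is interpolated linearly at ``t0``; with ``t0 = 1`` the
    value equals :func:`empirical_auc`.
    """
    if not 0.0 < t0 <= 1.0:
        raise ValueError(f"t0 must be in (0, 1], got {t0}")
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    fpr, tpr = _roc_points(neg, pos)
    if t0 < 1.0:
        tpr_t0 = float(np.interp(t0, fpr, tpr))
        keep = fpr < t0
        fpr = np.append(fpr[keep], t0)
        tpr = np.append(tpr[keep], tpr_t0)
    return float(np.trapezoid(tpr, fpr))


def roc_scores(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    t0: float = 0.1,
) -> list[RocScore]:
    """Per-probe AUC and pAUC with pos = class-1, neg = class-0 samples."""
    _check_inputs(matrix, labels)
    pos_mask = labels.labels == 1
    out = []
    for i, probe in enumerate(matrix.probe_ids):
        row = matrix.values[i]
        pos, neg = row[pos_mask], row[~pos_mask]
        out.append(
            RocScore(probe, empirical_auc(neg, pos), empirical_pauc(neg, pos, t0), t0)
        )
    return out


def roc_rank(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    t0: float = 0.1,
    criterion: Literal["auc", "pauc"] = "auc",
    one_sided: bool = False,
) -> RankedList:
    """Rank probes by their (partial) AUC as univariate classifiers.

    By default the criterion is two-sided — ``max(AUC, 1 - AUC)`` (for pAUC,
    the larger partial area of the probe and its negation) — so that
    under-expressed probes rank as high as over-expressed ones.  Ties are
    broken by input probe order.
    """
    _check_inputs(matrix, labels)
    if criterion not in ("auc", "pauc"):
        raise ValueError(f"criterion must be 'auc' or 'pauc', got {criterion!r}")
    pos_mask = labels.labels == 1
    scores = np.empty(matrix.n_probes)
    for i in range(matrix.n_probes):
        row = matrix.values[i]
        pos, neg = row[pos_mask], row[~pos_mask]
        if criterion == "auc":
            s = empirical_auc(neg, pos)
            scores[i] = s if one_sided else max(s, 1.0 - s)
        else:
            s = empirical_pauc(neg, pos, t0)
            if one_sided:
                scores[i] = s
            else:
                scores[i] = max(s, empirical_pauc(-neg, -pos, t0))
    order = np.argsort(-scores, kind="stable")
    return RankedList(
        ranker_name="roc",
        probe_ids=[matrix.probe_ids[i] for i in order],
        scores=[float(scores[i]) for i in order],
        score_semantics="higher is better",
    )


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BorutaConfig:
    """Settings for the shadow-feature relevance test.

    ``alpha`` is the level of the two-sided binomial hit test, Bonferroni
    corrected across all input features.  ``importance`` selects
    the per-tree measure: ``"mda"`` (mean decrease in out-of-bag accuracy,
    default) or ``"gini"`` (impurity decrease).
    """

    n_trees: int = 500
    max_iterations: int = 100
    alpha: float = 0.05
    seed: int = 0
    importance: Literal["mda", "gini"] = "mda"
    max_features: str | int | float = "sqrt"

    def trees_for(self, n_design_features: int) -> int:
        """Per-iteration tree count, scaled with the design width.

        Per-feature exposure in the forest goes as trees/features, so with
        thousands of real+shadow columns a fixed small forest leaves the
        importance Z-scores of marginal-but-relevant features dominated by
        estimation noise; the tree count follows the design width, floored
        at ``n_trees`` and capped at ``4 * n_trees``.
        """
        return int(np.clip(n_design_features, self.n_trees, 4 * self.n_trees))

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BorutaResult:
    """Per-probe decisions and the per-iteration importance Z-scores."""

    decisions: dict[str, str]  # probe_id -> confirmed | tentative | rejected
    zscores: dict[str, list[float]]
    n_iterations: int

    def by_decision(self, decision: str) -> set[str]:
        return {p for p, d in self.decisions.items() if d == decision}

    @property
    def confirmed(self) -> set[str]:
        return self.by_decision("confirmed")

    @property
    def rejected(self) -> set[str]:
        return self.by_decision("rejected")

    @property
    def tentative(self) -> set[str]:
        return self.by_decision("tentative")


def _forest_importance_z(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
    importance: str,
    max_features,
) -> np.ndarray:
    """Importance Z-score (mean over trees / sd over trees) per column of X.

    A bagged ensemble of decision trees is grown by hand so that per-tree
    out-of-bag permutation importance can be computed exactly: permuting a
    feature a tree never splits on leaves that tree's predictions unchanged,
    so only features actually used by the tree need a permuted prediction
    pass.
    """
    n_samples, n_feat = X.shape
    # single upfront conversion lets every tree fit/predict skip sklearn's
    # per-call validation (check_input=False requires C-contiguous float32)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    imp = np.zeros((n_trees, n_feat))
    n_oob_trees = 0
    for t in range(n_trees):
        boot = rng.integers(0, n_samples, n_samples)
        oob_mask = np.ones(n_samples, dtype=bool)
        oob_mask[boot] = False
        oob = np.flatnonzero(oob_mask)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X32[boot], y[boot], check_input=False)
        if importance == "gini":
            imp[t] = tree.feature_importances_
            n_oob_trees += 1
            continue
        if oob.size == 0:
            imp[t] = np.nan
            continue
        n_oob_trees += 1
        X_oob = X32[oob]
        y_oob = y[oob]
        acc0 = float(
            np.mean(tree.predict(X_oob, check_input=False) == y_oob)
        )
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size:
            # one batched prediction pass over all per-feature permutations
            batch = np.repeat(X_oob[None, :, :], used.size, axis=0)
            for j, f in enumerate(used):
                batch[j, :, f] = X_oob[rng.permutation(oob.size), f]
            preds = tree.predict(
                np.ascontiguousarray(batch.reshape(-1, n_feat)), check_input=False
            )
            acc_perm = (preds.reshape(used.size, -1) == y_oob).mean(axis=1)
            imp[t, used] = acc0 - acc_perm
    if n_oob_trees == 0:
        return np.zeros(n_feat)
    mean = np.nanmean(imp, axis=0)
    sd = np.nanstd(imp, axis=0, ddof=1) if n_oob_trees > 1 else np.zeros(n_feat)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = mean / sd
    z[(sd == 0) & (mean == 0)] = 0.0
    z[(sd == 0) & (mean > 0)] = np.inf
    z[(sd == 0) & (mean < 0)] = -np.inf
    return z


def boruta_select(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    config: BorutaConfig = BorutaConfig(),
) -> BorutaResult:
    """All-relevant feature selection against permuted shadow features.

    Each iteration builds a shadow copy of every undecided feature by
    independently permuting its values across samples, grows a bagged
    random forest on the real plus shadow design, and scores a "hit" for
    every undecided feature whose importance Z-score exceeds the best shadow
    Z.  Accumulated hits are tested against Binomial(i, 1/2) two-sided at
    level ``alpha`` with Bonferroni correction across all features;
    significant excesses are confirmed, deficits rejected.  Confirmed
    features stay in the design but are no longer tested; features still
    undecided at ``max_iterations`` are reported tentative, and a feature
    whose accumulated hits can no longer reach either decision before the
    cap is finalized as tentative immediately (saving the remaining
    iterations without changing its outcome).
    """
    _check_inputs(matrix, labels)
    rng = np.random.default_rng(config.seed)
    y = labels.labels
    X_all = matrix.values.T
    n_probes = matrix.n_probes
    # 0 undecided, 1 confirmed, -1 rejected, 2 tentative-finalized (no
    # decision reachable before the iteration cap)
    status = np.zeros(n_probes, dtype=int)
    hits = np.zeros(n_probes, dtype=int)
    tested = np.zeros(n_probes, dtype=int)
    zscores: dict[str, list[float]] = {p: [] for p in matrix.probe_ids}
    n_iter = 0

    for n_iter in range(1, config.max_iterations + 1):
        undecided = np.flatnonzero(status == 0)
        if undecided.size == 0:
            n_iter -= 1
            break
        # undecided, confirmed and tentative-finalized features stay in the
        # design; only rejected ones leave
        keep = np.flatnonzero(status >= 0)
        shadows = X_all[:, undecided].copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = shadows[rng.permutation(len(y)), j]
        X = np.hstack([X_all[:, keep], shadows])
        z = _forest_importance_z(
            X, y, config.trees_for(X.shape[1]), rng,
            config.importance, config.max_features,
        )
        z_real = dict(zip(keep, z[: keep.size]))
        z_shadow_max = float(np.max(z[keep.size :]))
        for f in undecided:
            zscores[matrix.probe_ids[f]].append(float(z_real[f]))
            tested[f] += 1
            if z_real[f] > z_shadow_max:
                hits[f] += 1
        # Two-sided binomial hit test. The Bonferroni factor is the TOTAL
        # feature count, not the currently undecided count: a shrinking
        # factor would let early hit deficits of marginal features (whose
        # hit rate climbs once mass rejection thins the shadow pool) turn
        # into spurious late rejections.
        m = n_probes
        horizon = config.max_iterations - n_iter
        for f in undecided:
            k, n = int(hits[f]), int(tested[f])
            p_hi = stats.binom.sf(k - 1, n, 0.5)  # P(X >= k)
            p_lo = stats.binom.cdf(k, n, 0.5)
            p_two = min(1.0, 2.0 * min(p_hi, p_lo))
            if p_two * m < config.alpha:
                status[f] = 1 if k > n / 2 else -1
            elif horizon > 0:
                # finalize as tentative once no run of future hits (or
                # misses) can reach either decision before the cap
                best_hi = 2.0 * stats.binom.sf(k + horizon - 1, n + horizon, 0.5)
                best_lo = 2.0 * stats.binom.cdf(k, n + horizon, 0.5)
                if best_hi * m >= config.alpha and best_lo * m >= config.alpha:
                    status[f] = 2
        if (status == 0).sum() == 0:
            break

    decision_name = {1: "confirmed", -1: "rejected", 0: "tentative", 2: "tentative"}
    decisions = {
        matrix.probe_ids[f]: decision_name[int(status[f])] for f in range(n_probes)
    }
    logger.info(
        "boruta: %d confirmed / %d rejected / %d tentative after %d iteration(s)",
        (status == 1).sum(),
        (status == -1).sum(),
        ((status == 0) | (status == 2)).sum(),
        n_iter,
    )
    return BorutaResult(decisions=decisions, zscores=zscores, n_iterations=n_iter)
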