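"""Moderated two-sample t-statistics and the fold-change/significance gate.

With tens of thousands of probes and a few dozen samples, per-probe variance
estimates are noisy; the moderated t shrinks each probe's pooled residual
variance s_g^2 (d = n - 2 df) toward a prior s0^2 with weight d0, where
(d0, s0^2) are estimated across probes by the empirical-Bayes method of
moments on log residual variances.  Under the hierarchical model
s_g^2 ~ s0^2 * F(d, d0)/..., the statistic

    t_mod = logFC_g / (s~_g * sqrt(1/n1 + 1/n0)),
    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

follows a t distribution with d0 + d degrees of freedom.  Setting d0 = 0
recovers the classical pooled t; d0 -> infinity pools all probes to a single
variance.

The significance gate keeps probes with |logFC| above a threshold and an
adjusted p-value below alpha, the filter applied to each ranker's top set
before intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_model import ExpressionMatrix, PhenotypeVector

_DF_CAP = 1e8  # stands in for an infinite prior df in t-distribution calls


@dataclass(frozen=True)
class ModeratedTestResult:
    probe_id: str
    logfc: float
    t_mod: float
    p: float
    p_adj: float
    d0: float
    s0_sq: float


def _group_arrays(
    matrix: ExpressionMatrix, labels: PhenotypeVector
) -> tuple[np.ndarray, np.ndarray]:
    if matrix.sample_ids != labels.sample_ids:
        raise ValueError("matrix and labels are not aligned; call align() first")
    mask1 = labels.labels == 1
    return matrix.values[:, mask1], matrix.values[:, ~mask1]


def log_fold_change(
    matrix: ExpressionMatrix, labels: PhenotypeVector
) -> dict[str, float]:
    """Per-probe class-1 mean minus class-0 mean (log-scale units)."""
    x1, x0 = _group_arrays(matrix, labels)
    if x1.shape[1] == 0 or x0.shape[1] == 0:
        raise ValueError("both classes must have at least one sample")
    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    return dict(zip(matrix.probe_ids, lfc.astype(float)))


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive; y must be > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Fit the shared prior (d0, s0^2) by moments of log residual variances.

    For s_g^2 ~ s0^2 * (d0/d) * F(d, d0), the variable
    e_g = log(s_g^2) - digamma(d/2) + log(d/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2); matching the sample mean and variance of
    e_g gives the estimates.  An excess variance <= 0 yields an infinite d0
    (complete pooling).  Probes with zero residual variance are excluded
    from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("degenerate moment fit: every probe has zero residual variance")
    z = np.log(positive)
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    if positive.size < 2:
        return math.inf, float(math.exp(e_mean))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return float(d0), float(s0_sq)


def moderated_t(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    prior_df: float | None = None,
    prior_var: float | None = None,
    adjust: Literal["bonferroni", "bh"] = "bonferroni",
) -> list[ModeratedTestResult]:
    """Moderated two-sample t-test for every probe.

    ``prior_df``/``prior_var`` override the empirical-Bayes estimates
    (``prior_df=0`` gives the classical pooled t).  ``adjust`` selects the
    multiple-testing correction applied to fill ``p_adj``.
    """
    x1, x0 = _group_arrays(matrix, labels)
    n1, n0 = x1.shape[1], x0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each class needs >= 2 samples, got {n1}/{n0}")
    d = n1 + n0 - 2
    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    s2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)) / d

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")
        if prior_var is not None:
            s0_sq = float(prior_var)
        elif d0 == 0:
            s0_sq = float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 1.0
        else:
            _, s0_sq = estimate_variance_prior(s2, d)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = min(_DF_CAP, d + _DF_CAP)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no change, no evidence
    p = 2.0 * stats.t.sf(np.abs(t), df=min(df_total, _DF_CAP))
    p = np.clip(p, 0.0, 1.0)
    p_adj = adjust_p(p, method=adjust)
    return [
        ModeratedTestResult(
            probe_id=probe,
            logfc=float(lfc[g]),
            t_mod=float(t[g]),
            p=float(p[g]),
            p_adj=float(p_adj[g]),
            d0=float(d0),
            s0_sq=float(s0_sq),
        )
        for g, probe in enumerate(matrix.probe_ids)
    ]


def adjust_p(
    p_values: Iterable[float], method: Literal["bonferroni", "bh"] = "bonferroni"
) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni (min(1, m*p)) or BH step-up."""
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values,
                   dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method: {method!r}")


def significance_gate(
    results: Iterable[ModeratedTestResult],
    lfc_threshold: float = 2.0,
    alpha: float = 0.01,
    two_sided: bool = True,
) -> set[str]:
    """Probes passing both the fold-change and adjusted-p thresholds.

    Two-sided by default: |logFC| > threshold.  ``two_sided=False`` gates on
    the signed logFC (over-expression only).
    """
    results = list(results)
    if not results:
        raise ValueError("significance_gate requires at least one test result")
    out = set()
    for r in results:
        fc = abs(r.logfc) if two_sided else r.logfc
        if fc > lfc_threshold and r.p_adj < alpha:
            out.add(r.probe_id)
    return out


def results_table(results: Iterable[ModeratedTestResult]):
    """Table mirroring the standard report: probe_id, logFC, t, P, adjusted P."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "probe_id": r.probe_id,
                "logFC": r.logfc,
                "t": r.t_mod,
                "P-value": r.p,
                "adjusted P-value": r.p_adj,
            }
            for r in results
        ]
    )
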