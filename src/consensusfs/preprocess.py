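"""Variance-based probe filtering.

Before ranking, probes with little overall variability across samples are
removed: they carry almost no discriminative signal and inflate the
multiple-testing burden.  The filter is label-blind — the per-probe sample
variance is computed across all samples regardless of group — mirroring the
nonspecific filtering step commonly applied to normalized microarray data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_model import ExpressionMatrix

logger = logging.getLogger("consensusfs")


@dataclass(frozen=True)
class FilterConfig:
    """Fraction of lowest-variance probes to remove (default: half)."""

    remove_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.remove_fraction < 1.0:
            raise ValueError(
                f"remove_fraction must be in [0, 1), got {self.remove_fraction}"
            )


def probe_variances(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-probe sample variance (ddof=1) across all samples."""
    if matrix.n_samples < 2:
        raise ValueError("variance filtering needs at least 2 samples")
    return matrix.values.var(axis=1, ddof=1)


def variance_filter(matrix: ExpressionMatrix, config: FilterConfig) -> ExpressionMatrix:
    """Drop probes whose variance falls strictly below the removal quantile.

    The threshold is the empirical ``remove_fraction`` quantile (linear
    interpolation) of all probe variances; probes whose variance equals the
    threshold exactly are retained.  Input probe order is preserved.
    """
    if config.remove_fraction == 0.0:
        return matrix
    v = probe_variances(matrix)
    threshold = float(np.quantile(v, config.remove_fraction))
    keep = v >= threshold
    out = ExpressionMatrix(
        [p for p, k in zip(matrix.probe_ids, keep) if k],
        list(matrix.sample_ids),
        matrix.values[keep],
    )
    logger.info(
        "variance_filter: %d -> %d probes (remove_fraction=%.3g, threshold=%.4g)",
        matrix.n_probes,
        out.n_probes,
        config.remove_fraction,
        threshold,
    )
    return out
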