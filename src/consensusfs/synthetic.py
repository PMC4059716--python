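"""Synthetic two-group expression matrices with planted differential signal.

The generator emulates a normalized (log-scale, e.g. RMA-style) probe-by-
sample intensity matrix for a case/control cohort: every probe draws a
per-probe noise SD sigma_g uniformly from ``baseline_sd_range`` and Gaussian
values around ``baseline_mean``; a small planted set of informative probes
additionally shifts the case-group mean by ``effect * sigma_g``, with the
shift sign alternating so both over- and under-expression occur.  Effect
sizes are therefore scale-free (in per-probe SD units); the theoretical
two-sided AUC of an informative probe is Phi(effect / sqrt(2)).

Defaults mirror the study design this package is benchmarked on: 44 samples
(26 cases / 18 controls) and, at the "study-shaped" preset, 2,000 probes
with 8 informative ones.  The noise scale (SD 1.5-2.5) is chosen so that a
2-SD shift yields |logFC| in roughly [3, 5], the fold-change regime in which
the |logFC| > 2 significance gate is meaningful.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io_model import (
    ExpressionMatrix,
    PhenotypeVector,
    write_expression_table,
    write_labels,
)


@dataclass(frozen=True)
class SimConfig:
    n_probes: int = 2000
    n_informative: int = 8
    n_case: int = 26
    n_control: int = 18
    effect: float = 2.0
    baseline_mean: float = 8.0
    baseline_sd_range: tuple[float, float] = (1.5, 2.5)
    correlation_block: tuple[int, float] | None = None  # (block size, rho)
    heavy_tail_df: float | None = None  # Student-t noise toggle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_probes:
            raise ValueError("n_informative cannot exceed n_probes")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        lo, hi = self.baseline_sd_range
        if not 0 < lo <= hi:
            raise ValueError("baseline_sd_range must be positive with low <= high")
        if self.correlation_block is not None:
            size, rho = self.correlation_block
            if size < 2 or not 0.0 <= rho < 1.0:
                raise ValueError("correlation_block needs size >= 2 and 0 <= rho < 1")


def theoretical_auc(effect: float) -> float:
    """Two-sided AUC of a probe with a Gaussian group-mean shift of
    ``effect`` SD: Phi(effect / sqrt(2))."""
    from scipy.stats import norm

    return float(norm.cdf(effect / math.sqrt(2.0)))


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, PhenotypeVector, set[str]]:
    """Draw one matrix + labels + ground-truth set, reproducibly by seed."""
    rng = np.random.default_rng(config.seed)
    p, n1, n0 = config.n_probes, config.n_case, config.n_control
    n = n1 + n0
    width = max(2, len(str(p)))
    probe_ids = [f"probe_{i + 1:0{width}d}" for i in range(p)]
    sample_ids = [f"case_{i + 1:02d}" for i in range(n1)] + [
        f"ctrl_{i + 1:02d}" for i in range(n0)
    ]
    labels = PhenotypeVector(sample_ids, np.array([1] * n1 + [0] * n0))

    lo, hi = config.baseline_sd_range
    sigma = rng.uniform(lo, hi, size=p)
    if config.heavy_tail_df is not None:
        df = config.heavy_tail_df
        noise = rng.standard_t(df, size=(p, n)) / math.sqrt(df / (df - 2.0))
    else:
        noise = rng.standard_normal((p, n))

    informative = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    if config.correlation_block is not None:
        size, rho = config.correlation_block
        noise_idx = np.setdiff1d(np.arange(p), informative)
        for start in range(0, len(noise_idx) - size + 1, size):
            block = noise_idx[start : start + size]
            shared = rng.standard_normal(n)
            noise[block] = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise[block]

    values = config.baseline_mean + sigma[:, None] * noise
    for j, g in enumerate(informative):
        sign = 1.0 if j % 2 == 0 else -1.0
        values[g, :n1] += sign * config.effect * sigma[g]

    matrix = ExpressionMatrix(probe_ids, sample_ids, values)
    truth = {probe_ids[g] for g in informative}
    return matrix, labels, truth


PRESETS: dict[str, SimConfig] = {
    # small smoke-test design
    "tiny": SimConfig(
        n_probes=50, n_informative=3, n_case=6, n_control=6, effect=3.0
    ),
    # no signal at all: for null calibration
    "null": SimConfig(n_probes=200, n_informative=0, effect=0.0),
    # the study-scale benchmark: 2,000 x 44 with an 8-probe planted panel
    "study-shaped": SimConfig(),
}


def make_fixture(
    name: str, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write a preset dataset (matrix TSV, labels CSV, truth JSON) to disk."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    config = PRESETS[name]
    if seed is not None:
        config = SimConfig(**{**asdict(config), "seed": seed})
    matrix, labels, truth = simulate_dataset(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{name}_matrix.tsv",
        "labels": out_dir / f"{name}_labels.csv",
        "truth": out_dir / f"{name}_truth.json",
    }
    write_expression_table(matrix, paths["matrix"])
    write_labels(labels, paths["labels"])
    cfg = asdict(config)
    cfg["baseline_sd_range"] = list(cfg["baseline_sd_range"])
    paths["truth"].write_text(
        json.dumps({"informative": sorted(truth), "config": cfg}, indent=2)
    )
    return paths
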