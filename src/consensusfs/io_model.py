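"""Core data types and file I/O for expression matrices, labels and ranked lists.

The central objects are a probe-by-sample matrix of log-scale expression
intensities (``ExpressionMatrix``) and a binary phenotype vector aligned to
its samples (``PhenotypeVector``, 0 = control, 1 = case).  Rankers emit
``RankedList`` objects; downstream code consumes aligned (matrix, labels)
pairs produced by :func:`align`.

On-disk formats are deliberately plain: tab-separated matrices with a sample
header row and probe ids in the first column, two-column label tables, and
TSV ranked lists.  Values are assumed to be already log-scale (e.g. RMA
output); nothing here transforms intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("consensusfs")


class FormatError(ValueError):
    """Malformed input file (duplicates, missing cells, empty table)."""


class AlignmentError(ValueError):
    """Matrix and labels share no samples."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of log-scale intensities.

    Rows are probes, columns are samples.  Probe and sample identifiers are
    unique and ordered; values contain no missing entries.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            raise FormatError("expression matrix contains missing values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given probes, keeping this matrix's probe order."""
        wanted = set(probe_ids)
        idx = [i for i, p in enumerate(self.probe_ids) if p in wanted]
        missing = wanted - {self.probe_ids[i] for i in idx}
        if missing:
            raise KeyError(f"unknown probe ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            [self.probe_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class PhenotypeVector:
    """Binary group labels (0 = control, 1 = case) aligned to samples."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise FormatError("labels must be one integer per sample")
        _check_unique(self.sample_ids, "sample")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0 or 1, got {sorted(bad)}")

    def class_counts(self) -> dict[int, int]:
        return {1: int((self.labels == 1).sum()), 0: int((self.labels == 0).sum())}

    def require_both_classes(self) -> None:
        counts = self.class_counts()
        if counts[0] == 0 or counts[1] == 0:
            raise ValueError(
                f"both classes required; class counts are {counts}"
            )

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeVector":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return PhenotypeVector(list(sample_ids), self.labels[idx])


@dataclass
class RankedList:
    """A ranker's ordered probe identifiers (best first) with aligned scores.

    ``score_semantics`` is either ``"higher is better"`` (e.g. a two-sided
    AUC) or ``"rank position"`` (1 = best, as produced by elimination-order
    rankers).
    """

    ranker_name: str
    probe_ids: list[str]
    scores: list[float]
    score_semantics: str = "higher is better"

    def __post_init__(self) -> None:
        if len(self.probe_ids) != len(self.scores):
            raise ValueError("probe_ids and scores must have equal length")
        _check_unique(self.probe_ids, "probe")
        if self.score_semantics not in ("higher is better", "rank position"):
            raise ValueError(f"unknown score semantics: {self.score_semantics!r}")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "probe_id": self.probe_ids,
                "score": self.scores,
                "ranker": self.ranker_name,
            }
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table: header = sample ids, column 1 = probe ids.

    Raises :class:`FormatError` for empty files or duplicate identifiers and
    a parse error naming the offending cell for non-numeric values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty expression table: {path}")
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"expression table has no data cells: {path}")
    probe_ids = [str(p) for p in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _check_unique(probe_ids, "probe")
    _check_unique(sample_ids, "sample")
    try:
        values = raw.to_numpy(dtype=str).astype(float)
    except ValueError:
        for i, row in enumerate(raw.to_numpy(dtype=str)):
            for j, cell in enumerate(row):
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"non-numeric cell at probe {probe_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}: {cell!r}"
                    ) from None
                if np.isnan(v):
                    raise FormatError(
                        f"missing value at probe {probe_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}"
                    )
        raise
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise FormatError(
            f"missing value at probe {probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(probe_ids, sample_ids, values)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def read_labels(path: str | Path) -> PhenotypeVector:
    """Read a two-column sample_id,label table (CSV or TSV; 0/1 labels)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file needs columns sample_id,label: {path}")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    _check_unique(sample_ids, "sample")
    labels = []
    for s, raw in zip(sample_ids, df.iloc[:, 1]):
        try:
            v = int(str(raw).strip())
        except ValueError:
            raise ValueError(f"label for sample {s!r} is not an integer: {raw!r}") from None
        if v not in (0, 1):
            raise ValueError(f"label for sample {s!r} must be 0 or 1, got {v}")
        labels.append(v)
    return PhenotypeVector(sample_ids, np.asarray(labels))


def write_labels(labels: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, index=False
    )


def read_ranked_list(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"probe_id": str})
    name = str(df["ranker"].iloc[0]) if len(df) else "unknown"
    semantics = "rank position"
    scores = df["score"].astype(float).tolist()
    if scores and not np.allclose(scores, np.arange(1, len(scores) + 1)):
        semantics = "higher is better"
    return RankedList(name, [str(p) for p in df["probe_id"]], scores, semantics)


def write_ranked_list(ranked: RankedList, path: str | Path) -> None:
    ranked.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align(
    matrix: ExpressionMatrix, labels: PhenotypeVector
) -> tuple[ExpressionMatrix, PhenotypeVector]:
    """Restrict matrix and labels to their shared samples, in matrix order.

    Idempotent; dropping samples present on only one side is logged.  Raises
    :class:`AlignmentError` when the sample sets are disjoint.
    """
    label_set = set(labels.sample_ids)
    shared = [s for s in matrix.sample_ids if s in label_set]
    if not shared:
        raise AlignmentError("matrix and labels have no samples in common")
    dropped = (len(matrix.sample_ids) - len(shared)) + (len(labels.sample_ids) - len(shared))
    if dropped:
        logger.warning(
            "align: dropping %d sample(s) absent from one input; %d shared remain",
            dropped,
            len(shared),
        )
    if shared == matrix.sample_ids and shared == labels.sample_ids:
        return matrix, labels
    return matrix.subset_samples(shared), labels.subset(shared)
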