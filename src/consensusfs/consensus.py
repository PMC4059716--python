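"""Consensus feature selection: top-k sets, significance gating, intersection.

The combined procedure runs three independent rankers, truncates the two
ordered rankers (SVM-RFE, ROC) to their top-k probes, gates those sets by a
moderated-t significance filter (|logFC| and adjusted p), takes Boruta's
confirmed set as-is, and intersects the three.  Probes every ranker agrees
on form the consensus panel used for classifier evaluation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_model import (
    ExpressionMatrix,
    PhenotypeVector,
    RankedList,
    write_ranked_list,
)
from .modstats import moderated_t, results_table, significance_gate
from .rankers import (
    BorutaConfig,
    BorutaResult,
    RfeConfig,
    boruta_select,
    roc_rank,
    svm_rfe_rank,
)

logger = logging.getLogger("consensusfs")

# top-k fraction mirroring 1,000 of 27,336 probes at full scale
DEFAULT_K_FRACTION = 1000.0 / 27336.0


@dataclass
class ConsensusPanel:
    """The intersected feature set with per-ranker membership flags."""

    selected: list[str]
    membership: dict[str, set[str]]  # probe_id -> ranker names containing it
    k: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected)

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": self.selected,
                "membership": {p: sorted(m) for p, m in self.membership.items()},
                "k": self.k,
                "provenance": self.provenance,
            },
            indent=2,
        )


def top_k(ranked: RankedList, k: int) -> set[str]:
    """The first k probe ids of a ranked list."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must be in [1, {len(ranked)}], got {k}")
    return set(ranked.probe_ids[:k])


def consensus_panel(
    sets: Sequence[tuple[str, set[str]]],
    probe_order: Sequence[str] | None = None,
    k: int = 0,
) -> ConsensusPanel:
    """Intersect named probe sets; membership records every containing set.

    ``probe_order`` fixes the output ordering (e.g. matrix probe order);
    without it the selection is sorted lexicographically.  The result is
    invariant to the order in which the sets are supplied.
    """
    if len(sets) < 2:
        raise ValueError("consensus requires at least 2 sets")
    names = [name for name, _ in sets]
    if len(set(names)) != len(names):
        raise ValueError("ranker names must be unique")
    inter = set.intersection(*(set(s) for _, s in sets))
    union = set.union(*(set(s) for _, s in sets))
    if probe_order is not None:
        pos = {p: i for i, p in enumerate(probe_order)}
        selected = sorted(inter, key=lambda p: pos.get(p, math.inf))
    else:
        selected = sorted(inter)
    membership = {p: {name for name, s in sets if p in s} for p in sorted(union)}
    return ConsensusPanel(selected=selected, membership=membership, k=k)


@dataclass(frozen=True)
class SelectConfig:
    """End-to-end selection settings.

    ``k`` is the per-ranker top-set size; ``None`` scales the full-design
    value of 1,000 (out of 27,336 probes) proportionally to the matrix,
    ``ceil(0.0366 * n_probes)``.  The gate thresholds default to
    |logFC| > 2 and adjusted p < 0.01 (Bonferroni).

    ``gate`` selects what the moderated-t significance check does:
    ``"annotate"`` (default) computes it and reports, per selected probe,
    whether it passes; ``"filter"`` additionally shrinks the SVM-RFE and ROC
    top-k sets to gate-passing probes before intersection; ``"off"`` skips
    it.  Annotation is the default because a hard adjusted-p filter at small
    n rejects moderate, genuinely differential probes that all three rankers
    agree on — the gate is most useful as a per-probe credential on the
    final panel.
    """

    k: int | None = None
    lfc_threshold: float = 2.0
    alpha: float = 0.01
    adjust: str = "bonferroni"
    gate: str = "annotate"
    include_tentative: bool = False
    t0: float = 0.1
    roc_criterion: str = "auc"
    rfe: RfeConfig = field(default_factory=RfeConfig)
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gate not in ("filter", "annotate", "off"):
            raise ValueError(
                f"gate must be 'filter', 'annotate' or 'off', got {self.gate!r}"
            )

    def resolve_k(self, n_probes: int) -> int:
        if self.k is not None:
            return self.k
        return max(1, math.ceil(DEFAULT_K_FRACTION * n_probes))

    def snapshot(self) -> dict:
        d = asdict(self)
        d["rfe"] = asdict(self.rfe)
        d["boruta"] = asdict(self.boruta)
        return d


def select_features(
    matrix: ExpressionMatrix,
    labels: PhenotypeVector,
    config: SelectConfig = SelectConfig(),
    out_dir: str | Path | None = None,
) -> ConsensusPanel:
    """Run the full consensus pipeline and intersect the three feature sets.

    Stages: (1) SVM-RFE ranking, truncated to top k; (2) ROC ranking,
    truncated to top k; (3) Boruta, keeping confirmed probes (optionally
    tentative too); (4) the moderated-t significance gate — filtering sets
    (1) and (2) when ``config.gate == "filter"``, otherwise annotating the
    selection; (5) intersection.  An empty intersection is a valid result.
    Intermediates are written to ``out_dir`` when given and are stashed in
    ``panel.provenance["stages"]`` regardless.
    """
    labels.require_both_classes()
    k = config.resolve_k(matrix.n_probes)
    boruta_cfg = config.boruta
    if boruta_cfg.seed == 0 and config.seed != 0:
        # split the root seed so stages draw independent streams
        child = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31 - 1))
        boruta_cfg = BorutaConfig(
            n_trees=boruta_cfg.n_trees,
            max_iterations=boruta_cfg.max_iterations,
            alpha=boruta_cfg.alpha,
            seed=child,
            importance=boruta_cfg.importance,
            max_features=boruta_cfg.max_features,
        )

    rfe_list = svm_rfe_rank(matrix, labels, config.rfe)
    roc_list = roc_rank(matrix, labels, t0=config.t0, criterion=config.roc_criterion)
    boruta_res = boruta_select(matrix, labels, boruta_cfg)

    set_rfe = top_k(rfe_list, min(k, len(rfe_list)))
    set_roc = top_k(roc_list, min(k, len(roc_list)))
    set_boruta = boruta_res.confirmed
    if config.include_tentative:
        set_boruta = set_boruta | boruta_res.tentative

    tests = None
    passing: set[str] | None = None
    if config.gate != "off":
        tests = moderated_t(matrix, labels, adjust=config.adjust)
        passing = significance_gate(
            tests, lfc_threshold=config.lfc_threshold, alpha=config.alpha
        )
        if config.gate == "filter":
            set_rfe &= passing
            set_roc &= passing

    panel = consensus_panel(
        [("svm-rfe", set_rfe), ("roc", set_roc), ("boruta", set_boruta)],
        probe_order=matrix.probe_ids,
        k=k,
    )
    panel.provenance = {"config": config.snapshot(), "k_resolved": k}
    if passing is not None:
        panel.provenance["gate"] = {p: (p in passing) for p in panel.selected}
        failed = [p for p in panel.selected if p not in passing]
        if failed and config.gate == "annotate":
            logger.warning(
                "%d selected probe(s) fail the significance gate "
                "(|logFC| > %g and adjusted p < %g): %s",
                len(failed), config.lfc_threshold, config.alpha, failed,
            )
    panel.provenance["stages"] = {
        "svm_rfe": rfe_list,
        "roc": roc_list,
        "boruta": boruta_res,
        "moderated_t": tests,
        "set_sizes": {
            "svm-rfe": len(set_rfe),
            "roc": len(set_roc),
            "boruta": len(set_boruta),
        },
    }
    if len(panel) == 0:
        logger.warning("consensus panel is EMPTY (no probe survives all rankers)")
    logger.info(
        "consensus: k=%d, set sizes %s, panel size %d",
        k,
        panel.provenance["stages"]["set_sizes"],
        len(panel),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ranked_list(rfe_list, out_dir / "ranked_svm_rfe.tsv")
        write_ranked_list(roc_list, out_dir / "ranked_roc.tsv")
        _write_boruta(boruta_res, out_dir / "boruta_decisions.tsv")
        if tests is not None:
            results_table(tests).to_csv(out_dir / "moderated_t.tsv", sep="\t", index=False)
        prov = dict(panel.provenance)
        prov.pop("stages")
        (out_dir / "panel.json").write_text(
            json.dumps(
                {
                    "selected": panel.selected,
                    "membership": {p: sorted(m) for p, m in panel.membership.items()},
                    "k": panel.k,
                    "provenance": prov,
                },
                indent=2,
            )
        )
    return panel


def _write_boruta(result: BorutaResult, path: Path) -> None:
    import pandas as pd

    rows = []
    for probe, decision in result.decisions.items():
        zs = result.zscores.get(probe, [])
        finite = [z for z in zs if math.isfinite(z)]
        rows.append(
            {
                "probe_id": probe,
                "decision": decision,
                "median_z": float(np.median(finite)) if finite else float("nan"),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
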