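"""Intersection of predicted miRNA target-gene lists and the DEG filter.

Target predictions come from external databases (e.g. miRDB and TargetScan
exports) as flat gene-symbol lists; symbols are uppercased and
whitespace-stripped before any set operation.  Genes predicted as miRNA
targets by every source, shared across the three site-type groups, and not
demonstrably down-regulated in the tumour transcriptome are nominated as
genes released from miRNA control by sponge REs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "TargetGeneSet",
    "read_gene_list",
    "intersect_targets",
    "common_across_types",
    "classify_degs",
    "remove_downregulated",
]


def _normalize(genes) -> frozenset[str]:
    return frozenset(g.strip().upper() for g in genes if g and g.strip())


@dataclass(frozen=True)
class TargetGeneSet:
    """A named set of normalized gene symbols."""

    source_label: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _normalize(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def read_gene_list(path: str | Path, source_label: str | None = None, column: str | None = None) -> TargetGeneSet:
    """Read a one-symbol-per-line file (or one TSV column) into a TargetGeneSet."""
    path = Path(path)
    if column is not None:
        genes = pd.read_csv(path, sep="\t")[column].astype(str).tolist()
    else:
        genes = [line.strip() for line in path.read_text().splitlines()]
    return TargetGeneSet(source_label or path.stem, genes)


def intersect_targets(sets: Sequence[TargetGeneSet]) -> TargetGeneSet:
    """Genes shared by every input source (>= 2 sets required)."""
    if len(sets) < 2:
        raise ValueError(f"need >= 2 target sets to intersect, got {len(sets)}")
    common = frozenset.intersection(*(s.genes for s in sets))
    return TargetGeneSet("&".join(s.source_label for s in sets), common)


def common_across_types(
    targets_by_type: Mapping[str, TargetGeneSet]
) -> tuple[TargetGeneSet, dict[str, int]]:
    """Three-way intersection across the 8M/7A1/7M8 site-type groups.

    Returns the common set and the per-region Venn counts (exclusive regions,
    keys like ``8M``, ``8M&7A1``, ``8M&7A1&7M8``).
    """
    keys = ("8M", "7A1", "7M8")
    missing = [k for k in keys if k not in targets_by_type]
    if missing:
        raise KeyError(f"targets_by_type missing site-type groups: {missing}")
    sets = {k: targets_by_type[k].genes for k in keys}
    venn: dict[str, int] = {}
    for r in (1, 2, 3):
        for combo in combinations(keys, r):
            inside = frozenset.intersection(*(sets[k] for k in combo))
            outside = frozenset().union(*(sets[k] for k in keys if k not in combo))
            venn["&".join(combo)] = len(inside - outside)
    common = frozenset.intersection(*sets.values())
    return TargetGeneSet("&".join(keys), common), venn


def classify_degs(
    degs: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 1.0
) -> pd.DataFrame:
    """Add an up/down/ns direction call to a (gene, log2fc, p_value) table."""
    out = degs.copy()
    sig = out["p_value"] < alpha
    out["direction"] = "ns"
    out.loc[sig & (out["log2fc"] > fc_threshold), "direction"] = "up"
    out.loc[sig & (out["log2fc"] < -fc_threshold), "direction"] = "down"
    return out


def remove_downregulated(common: TargetGeneSet, degs: pd.DataFrame) -> TargetGeneSet:
    """Drop genes called down-regulated; genes absent from the DEG table are kept.

    ``degs`` must carry ``gene`` and ``direction`` columns (see
    :func:`classify_degs`); only demonstrably down-regulated genes are removed.
    """
    if "direction" not in degs.columns:
        raise KeyError("DEG table lacks a 'direction' column; run classify_degs first")
    down = _normalize(degs.loc[degs["direction"] == "down", "gene"].astype(str))
    return TargetGeneSet(common.source_label, common.genes - down)
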