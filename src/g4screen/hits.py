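"""Hit thresholding and multi-condition consolidation.

Implements the screen's hit logic: per-condition thresholding of gene
p-values (strict p < 0.045 by default), union consolidation across drug
conditions, exclusion of genes shared with a counter-screen (here the
BMH-21 arm, which inhibits RNA polymerase I without stabilizing G4
structures), and exclusive intersection sets in UpSet-plot semantics.

The package ships the study's published per-condition top-depleted gene
lists (five drug/dose conditions) as a CSV fixture so the consolidation
arithmetic is checkable end to end: 81 genes in the overall union, 58
G4-specific genes after counter-screen exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ConditionHitList",
    "threshold_hits",
    "consolidate",
    "counter_screen_exclude",
    "intersection_sets",
    "load_table2",
    "G4_CONDITIONS",
    "COUNTER_CONDITION",
]

#: Condition labels of the packaged top-depleted-genes fixture.
G4_CONDITIONS = (
    "CX-5461 (IC50)",
    "CX-5461 (IC30)",
    "PDS (IC50)",
    "PDS (IC30)",
)
COUNTER_CONDITION = "BMH-21 (IC30)"


def _normalize_symbols(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(str(g).strip().upper() for g in genes if str(g).strip())


@dataclass(frozen=True)
class ConditionHitList:
    """Set of hit genes for one drug/dose condition."""

    condition: str
    genes: frozenset[str]
    p_values: Mapping[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _normalize_symbols(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def threshold_hits(
    gene_scores: pd.DataFrame, condition: str, p_cut: float = 0.045
) -> ConditionHitList:
    """Genes with p-value strictly below ``p_cut`` in a gene-score table.

    Expects ``gene`` and ``p_value`` columns (the :mod:`g4screen.rra`
    output); non-targeting pseudo-genes (``is_nt`` truthy) are ignored.
    """
    if "p_value" not in gene_scores.columns or "gene" not in gene_scores.columns:
        raise ValueError("gene score table needs 'gene' and 'p_value' columns")
    df = gene_scores
    if "is_nt" in df.columns:
        df = df[~df["is_nt"].astype(bool)]
    hit = df[df["p_value"] < p_cut]
    return ConditionHitList(
        condition=condition,
        genes=frozenset(hit["gene"]),
        p_values=dict(zip(hit["gene"].astype(str).str.upper(), hit["p_value"])),
    )


def consolidate(*lists: ConditionHitList) -> frozenset[str]:
    """Union of hit genes across conditions."""
    if not lists:
        raise ValueError("need at least one hit list")
    out: frozenset[str] = frozenset()
    for lst in lists:
        out |= lst.genes
    return out


def counter_screen_exclude(
    g4_lists: Iterable[ConditionHitList], counter: ConditionHitList
) -> frozenset[str]:
    """Union of the G4-drug hit lists minus any counter-screen hit."""
    g4_lists = list(g4_lists)
    if not g4_lists:
        raise ValueError("need at least one G4 hit list")
    return consolidate(*g4_lists) - counter.genes


def intersection_sets(
    *lists: ConditionHitList,
) -> dict[frozenset[str], frozenset[str]]:
    """Exclusive intersection sets (UpSet semantics).

    Every gene in the union is assigned to exactly one signature: the
    full set of condition labels whose lists contain it.  The returned
    sets are pairwise disjoint and cover the union.
    """
    if len(lists) < 2:
        raise ValueError("need at least two hit lists")
    union = consolidate(*lists)
    out: dict[frozenset[str], set[str]] = {}
    for gene in union:
        sig = frozenset(lst.condition for lst in lists if gene in lst.genes)
        out.setdefault(sig, set()).add(gene)
    return {sig: frozenset(genes) for sig, genes in out.items()}


def load_table2() -> dict[str, ConditionHitList]:
    """The packaged per-condition top-depleted gene lists.

    Returns a mapping of condition label (see :data:`G4_CONDITIONS` and
    :data:`COUNTER_CONDITION`) to its :class:`ConditionHitList`.
    """
    with resources.files("g4screen.data").joinpath(
        "table2_top_depleted.csv"
    ).open() as handle:
        df = pd.read_csv(handle)
    return {
        cond: ConditionHitList(condition=cond, genes=frozenset(sub["gene"]))
        for cond, sub in df.groupby("condition")
    }
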