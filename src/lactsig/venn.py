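"""Set algebra over differential-expression gene lists.

Bulk RNA-seq contrasts (lactation day vs non-lactating baseline, per
genotype) yield per-day DE tables. This module filters them into
significant up/down gene sets (BH-adjusted p below alpha, sign of the
log2 fold change) and partitions 2-3 named sets into the disjoint Venn
regions used to count day-exclusive and common genes, plus the
cross-genotype shared/unique split.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import pandas as pd

from .errors import LactsigError

__all__ = ["VennPartition", "de_filter", "venn_partition", "cross_genotype_unique"]


@dataclass
class VennPartition:
    """Disjoint region -> gene-set map over 2-3 named input sets.

    Region labels are tuples of input-set names (in input order); the
    region labelled ``(a,)`` holds genes exclusive to set ``a``, the
    region labelled with all names holds genes common to every input.
    Only non-empty is guaranteed about nothing: all 2^k - 1 regions are
    present, possibly empty.
    """

    names: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset[str]]

    def counts(self) -> dict[tuple[str, ...], int]:
        return {label: len(genes) for label, genes in self.regions.items()}

    def exclusive(self, name: str) -> frozenset[str]:
        return self.regions[(name,)]

    def common_all(self) -> frozenset[str]:
        return self.regions[self.names]

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return frozenset(out)

    def reconstruct_input(self, name: str) -> frozenset[str]:
        """The original input set, rebuilt from the disjoint regions."""
        out: set[str] = set()
        for label, genes in self.regions.items():
            if name in label:
                out |= genes
        return frozenset(out)


def de_filter(
    table: pd.DataFrame,
    alpha: float = 0.05,
    direction: Literal["up", "down"] = "up",
) -> frozenset[str]:
    """Significant genes in one direction: padj strictly below alpha and a
    strictly signed log2 fold change (genes at log2fc == 0 are in neither
    direction; genes at padj == alpha are excluded).
    """
    if direction not in ("up", "down"):
        raise LactsigError(f"direction must be 'up' or 'down', got {direction!r}")
    sig = table["padj"].astype(float) < alpha
    lfc = table["log2fc"].astype(float)
    keep = sig & (lfc > 0 if direction == "up" else lfc < 0)
    return frozenset(table.loc[keep, "gene"].astype(str))


def venn_partition(named_sets: Mapping[str, Sequence[str] | frozenset[str]]) -> VennPartition:
    """Exact Venn partition of 2 or 3 named gene sets by inclusion/exclusion."""
    names = tuple(named_sets.keys())
    if len(names) != len(set(names)):
        raise LactsigError("duplicate set names")
    if not 2 <= len(names) <= 3:
        raise LactsigError(f"need 2 or 3 input sets, got {len(names)}")
    sets = {name: frozenset(map(str, s)) for name, s in named_sets.items()}
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for k in range(1, len(names) + 1):
        for label in combinations(names, k):
            inside = set.intersection(*(set(sets[n]) for n in label))
            for other in names:
                if other not in label:
                    inside -= sets[other]
            regions[label] = frozenset(inside)
    return VennPartition(names=names, regions=regions)


def cross_genotype_unique(
    set_a: Sequence[str] | frozenset[str],
    set_b: Sequence[str] | frozenset[str],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Split two gene sets into (shared, unique to A, unique to B)."""
    a, b = frozenset(map(str, set_a)), frozenset(map(str, set_b))
    return a & b, a - b, b - a
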