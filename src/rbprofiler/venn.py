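"""Disjoint Venn partitioning of 2-3 named gene sets."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .model import ValidationError


@dataclass
class VennPartition:
    """All 2^k - 1 disjoint regions over k named sets (k = 2 or 3).

    Regions are keyed by the frozenset of set names whose exclusive
    intersection they represent; e.g. for sets A, B, C the key
    ``frozenset({"A", "B"})`` holds genes in A and B but not C.
    """

    set_names: list[str]
    regions: dict[frozenset[str], set[str]]

    def region(self, *names: str) -> set[str]:
        return self.regions[frozenset(names)]

    @property
    def counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def venn_partition(named_sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition the union of 2-3 named gene sets into disjoint regions.

    Every gene lands in exactly one region: the one labeled by the exact
    collection of input sets containing it.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 3:
        raise ValidationError(f"venn_partition needs 2 or 3 sets, got {len(names)}")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate set names")
    sets = {name: set(named_sets[name]) for name in names}
    regions: dict[frozenset[str], set[str]] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[frozenset(combo)] = set()
    for gene in set().union(*sets.values()):
        members = frozenset(n for n in names if gene in sets[n])
        regions[members].add(gene)
    return VennPartition(set_names=names, regions=regions)
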