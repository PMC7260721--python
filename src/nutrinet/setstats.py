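"""Gene-set algebra: overlapping coefficient, hypergeometric enrichment, Venn.

The overlapping coefficient |A∩B| / min(|A|, |B|) ranges from 0 (no
overlap) to 1 (one set nested in the other).  Enrichment of an observed
intersection is scored with the upper-tail hypergeometric probability
P(X >= |A∩B|) in an explicit finite universe N — the universe is always a
required, reported quantity because the tail is meaningless without it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "GeneSet",
    "OverlapResult",
    "overlap_coefficient",
    "hypergeometric_overlap",
    "venn_partition",
    "mutant_nutrient_intersections",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, members) -> "GeneSet":
        return cls(name, frozenset(members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapResult:
    set_a: str
    set_b: str
    size_a: int
    size_b: int
    intersection: int
    universe_size: int
    overlap_coefficient: float
    hypergeometric_p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _members(s) -> frozenset:
    return s.members if isinstance(s, GeneSet) else frozenset(s)


def _name(s, default: str) -> str:
    return s.name if isinstance(s, GeneSet) else default


def overlap_coefficient(a, b) -> float:
    """|A∩B| / min(|A|, |B|); errors on an empty set (undefined)."""
    sa, sb = _members(a), _members(b)
    if not sa or not sb:
        raise ValueError("overlap coefficient undefined for an empty set")
    return len(sa & sb) / min(len(sa), len(sb))


def hypergeometric_overlap(a, b, universe) -> float:
    """Upper-tail P(X >= |A∩B|), X ~ Hypergeom(N=|U|, K=|A|, n=|B|).

    Both sets must be subsets of the universe; the observed count is
    included in the tail (standard enrichment convention).
    """
    sa, sb, su = _members(a), _members(b), _members(universe)
    offenders = sorted((sa | sb) - su)
    if offenders:
        raise ValueError(f"genes outside the declared universe: {offenders[:10]}")
    k = len(sa & sb)
    return float(stats.hypergeom.sf(k - 1, len(su), len(sa), len(sb)))


def venn_partition(sets: list) -> dict[tuple[bool, ...], int]:
    """Counts of the 2^k - 1 nonempty membership regions of 2 or 3 sets.

    Keys are membership tuples aligned with the input order, e.g. for
    (A, B, C) the key (True, True, False) is the "A∩B only" region.
    Counts sum to |union|.
    """
    if len(sets) < 2:
        raise ValueError("venn partition needs >=2 sets")
    members = [_members(s) for s in sets]
    regions: dict[tuple[bool, ...], int] = {}
    for pattern in itertools.product([True, False], repeat=len(members)):
        if not any(pattern):
            continue
        region = frozenset.intersection(*(m for m, keep in zip(members, pattern) if keep))
        for m, keep in zip(members, pattern):
            if not keep:
                region = region - m
        regions[pattern] = len(region)
    return regions


def mutant_nutrient_intersections(common, mutant_sets: list, universe) -> list[OverlapResult]:
    """One OverlapResult per mutant-specific set against the common set."""
    results = []
    sc = _members(common)
    su = _members(universe)
    for i, mutant in enumerate(mutant_sets):
        sm = _members(mutant)
        results.append(
            OverlapResult(
                set_a=_name(common, "common_responsive"),
                set_b=_name(mutant, f"mutant_{i}"),
                size_a=len(sc),
                size_b=len(sm),
                intersection=len(sc & sm),
                universe_size=len(su),
                overlap_coefficient=overlap_coefficient(sc, sm),
                hypergeometric_p=hypergeometric_overlap(sc, sm, su),
            )
        )
    return results
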