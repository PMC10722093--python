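"""Partition VCF samples into two groups fixed for distinct alleles.

A marker is only useful when every assayed sample carries a known, fixed
allele, so both grouping modes demand homozygosity: a sample enters a
group only if both of its allele calls equal the group's allele.
Heterozygous or missing samples are left out of auto-mode groups and veto
a user-specified group outright (the user explicitly claimed them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Set

from markerforge.io_layer import MISSING, VariantSite


@dataclass(frozen=True)
class GroupPair:
    """Two disjoint sample sets, each fixed (homozygous) for one allele."""

    group_a: FrozenSet[str]
    group_b: FrozenSet[str]
    allele_a: int
    allele_b: int

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError("groups must be disjoint")
        if self.allele_a == self.allele_b:
            raise ValueError("group alleles must differ")


def _homozygous_allele(site: VariantSite, sample: str) -> Optional[int]:
    """The allele index a sample is homozygous for, else None."""
    gt = site.genotypes.get(sample)
    if gt is None:
        return None
    a, b = gt
    if a == MISSING or b == MISSING or a != b:
        return None
    return a


def group_user(site: VariantSite, group_a: Set[str],
               group_b: Set[str]) -> Optional[GroupPair]:
    """Validate a user-specified grouping at one site.

    Returns a :class:`GroupPair` iff every member of ``group_a`` is
    homozygous for one allele, every member of ``group_b`` homozygous for a
    different allele, and nobody is heterozygous or missing; else None.
    Overlapping groups are a hard error (a config mistake, not a bad site).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    alleles_a = {_homozygous_allele(site, s) for s in group_a}
    alleles_b = {_homozygous_allele(site, s) for s in group_b}
    if len(alleles_a) != 1 or len(alleles_b) != 1:
        return None
    (aa,) = alleles_a
    (ab,) = alleles_b
    if aa is None or ab is None or aa == ab:
        return None
    return GroupPair(frozenset(group_a), frozenset(group_b), aa, ab)


def group_auto(site: VariantSite) -> List[GroupPair]:
    """Exhaustively group samples by the allele each is homozygous for.

    One :class:`GroupPair` per unordered allele pair (i, j), i < j, with at
    least one homozygote each.  Heterozygous/missing samples belong to no
    group.  Output order is ascending (i, j), so it is deterministic and
    invariant under sample reordering.
    """
    by_allele: dict[int, set[str]] = {}
    for sample in site.genotypes:
        allele = _homozygous_allele(site, sample)
        if allele is not None:
            by_allele.setdefault(allele, set()).add(sample)
    alleles = sorted(by_allele)
    pairs: List[GroupPair] = []
    for i, ai in enumerate(alleles):
        for aj in alleles[i + 1:]:
            pairs.append(GroupPair(frozenset(by_allele[ai]),
                                   frozenset(by_allele[aj]), ai, aj))
    return pairs
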