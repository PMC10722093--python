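"""Design-template construction: 500-bp extension, exclusion masks, CAPS trim.

The template is the masked genomic window handed to the primer-design
engine.  It is the target sequence (variant ±20 bp) extended by 500 bp on
each side, annotated with regions primers must not touch: other variants
segregating among the grouped samples, low-read-depth runs, footprints of
previously rejected primers, and — for CAPS — everything beyond a second
recognition site of the marker's own enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

from markerforge.grouping import GroupPair
from markerforge.io_layer import MISSING, DepthTrack, Reference, VariantSite
from markerforge.marker_screen import (EnzymeDefinition, TargetSequence,
                                       scan_sites)

TEMPLATE_FLANK = 500  # bp added on each side of the target sequence

EXCLUSION_REASONS = ("variant", "low_depth", "rejected_primer",
                     "same_enzyme_site_trim")

Region = Tuple[int, int, str]  # (start, end, reason) in template coordinates


class TrimError(ValueError):
    """A CAPS template could not be reduced to a single cut site."""


@dataclass
class TemplateSequence:
    """Masked design template in 0-based half-open template coordinates.

    ``seq`` is the reference-realized window; the marker allele is
    substituted only when a per-allele realization is requested
    (:func:`realize_allele`).  ``target_start``/``target_end`` delimit the
    sub-interval the amplicon must contain.
    """

    contig: str
    start: int                       # genomic
    end: int                         # genomic
    seq: str
    target_start: int                # template coords
    target_end: int
    var_offset: int                  # marker variant start, template coords
    ref_len: int                     # marker reference-allele length
    allele_a: str
    allele_b: str
    excluded_regions: List[Region] = field(default_factory=list)
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def realize_allele(self, allele: str) -> str:
        """Template sequence with ``allele`` substituted at the marker span."""
        return (self.seq[:self.var_offset] + allele
                + self.seq[self.var_offset + self.ref_len:])


def _normalize(regions: Sequence[Region], bound: int) -> List[Region]:
    """Clip to [0, bound), sort, and merge overlaps into disjoint regions."""
    clipped = [(max(0, s), min(bound, e), r) for s, e, r in regions
               if min(bound, e) > max(0, s)]
    clipped.sort()
    merged: List[Region] = []
    for s, e, r in clipped:
        if merged and s <= merged[-1][1]:
            ps, pe, pr = merged[-1]
            reasons = sorted(set(pr.split("+")) | set(r.split("+")))
            merged[-1] = (ps, max(pe, e), "+".join(reasons))
        else:
            merged.append((s, e, r))
    return merged


def add_exclusions(tmpl: TemplateSequence,
                   regions: Sequence[Region]) -> TemplateSequence:
    """Return a copy of the template with extra excluded regions merged in."""
    return replace(tmpl, excluded_regions=_normalize(
        list(tmpl.excluded_regions) + list(regions), len(tmpl.seq)))


def build_template(ref: Reference, target: TargetSequence,
                   flank: int = TEMPLATE_FLANK) -> TemplateSequence:
    """Extend the target interval by ``flank`` bp each side, clipped to contig."""
    contig_len = ref.length(target.contig)
    start = max(0, target.start - flank)
    end = min(contig_len, target.end + flank)
    clipped = target.clipped or start != target.start - flank \
        or end != target.end + flank
    return TemplateSequence(
        contig=target.contig, start=start, end=end,
        seq=ref.slice(target.contig, start, end),
        target_start=target.start - start,
        target_end=target.end - start,
        var_offset=target.start - start + target.var_offset,
        ref_len=target.ref_len,
        allele_a=target.allele_a, allele_b=target.allele_b,
        clipped=clipped,
    )


def _is_polymorphic(site: VariantSite, samples: Sequence[str]) -> bool:
    """True unless every grouped sample is homozygous for the same allele.

    Heterozygous or missing genotypes count as polymorphic (conservative:
    a primer must bind identically in all assayed material).
    """
    seen = set()
    for s in samples:
        gt = site.genotypes.get(s)
        if gt is None:
            continue
        a, b = gt
        if a == MISSING or b == MISSING or a != b:
            return True
        seen.add(a)
        if len(seen) > 1:
            return True
    return len(seen) > 1


def mask_variants(tmpl: TemplateSequence, nearby: Sequence[VariantSite],
                  pair: GroupPair) -> TemplateSequence:
    """Exclude the span (±1 bp guard) of every nearby segregating variant.

    ``nearby`` should hold the VCF sites overlapping the template interval,
    excluding the marker site itself.  A site masks only when it is
    non-monomorphic across the union of the two grouped sample sets; sites
    segregating only in unselected samples do not mask.
    """
    grouped = sorted(pair.group_a | pair.group_b)
    regions: List[Region] = []
    for site in nearby:
        if site.contig != tmpl.contig:
            continue
        if site.end <= tmpl.start or site.pos >= tmpl.end:
            continue
        if _is_polymorphic(site, grouped):
            regions.append((site.pos - tmpl.start - 1,
                            site.end - tmpl.start + 1, "variant"))
    return add_exclusions(tmpl, regions)


def mask_low_depth(tmpl: TemplateSequence, depth: DepthTrack,
                   min_depth: int) -> TemplateSequence:
    """Exclude every maximal run of positions with pooled depth < min_depth."""
    if min_depth <= 0:
        return tmpl
    depths = depth.depths(tmpl.contig, tmpl.start, tmpl.end)
    regions: List[Region] = []
    run_start = None
    for i, d in enumerate(depths):
        low = d < min_depth
        if low and run_start is None:
            run_start = i
        elif not low and run_start is not None:
            regions.append((run_start, i, "low_depth"))
            run_start = None
    if run_start is not None:
        regions.append((run_start, len(depths), "low_depth"))
    return add_exclusions(tmpl, regions)


def trim_caps_template(tmpl: TemplateSequence, enzyme: EnzymeDefinition,
                       digested_allele: str) -> TemplateSequence:
    """Shorten the template until the digested allele has exactly one cut site.

    The digested-allele-realized template is scanned; if recognition sites
    exist outside the target sub-interval, the template edge is moved past
    the nearest flanking extra site (the extra site itself is removed —
    the only reading that guarantees uniqueness).  Raises :class:`TrimError`
    when more than one site falls inside the untrimmable target window.
    """
    for _ in range(8):  # trimming converges in one pass; loop is a guard
        shift = len(digested_allele) - tmpl.ref_len
        realized = tmpl.realize_allele(digested_allele)
        hits = scan_sites(realized, enzyme)
        site_len = len(enzyme.site)
        # realized coordinates of the target sub-interval
        t_start = tmpl.target_start
        t_end = tmpl.target_end + shift
        in_target = [h for h in hits if h + site_len > t_start and h < t_end]
        if not in_target:
            raise TrimError(f"{enzyme.name}: no cut site left in target window")
        if len(in_target) > 1:
            raise TrimError(
                f"{enzyme.name}: {len(in_target)} cut sites inside the "
                f"target window; cannot isolate one by trimming")
        left_extras = [h for h in hits if h + site_len <= t_start]
        right_extras = [h for h in hits if h >= t_end]
        if not left_extras and not right_extras:
            return tmpl
        new_lo = max(h + site_len for h in left_extras) if left_extras else 0
        # right extras sit beyond the allele span: map back to template coords
        new_hi = (min(right_extras) - shift) if right_extras else len(tmpl.seq)
        tmpl = _slice_template(tmpl, new_lo, new_hi)
    raise TrimError(f"{enzyme.name}: trimming did not converge")


def _slice_template(tmpl: TemplateSequence, lo: int,
                    hi: int) -> TemplateSequence:
    """Restrict the template to template-coordinate window [lo, hi)."""
    if lo > tmpl.target_start or hi < tmpl.target_end:
        raise TrimError("trim would cut into the target sub-interval")
    shifted = [(s - lo, e - lo, r) for s, e, r in tmpl.excluded_regions]
    return replace(
        tmpl,
        start=tmpl.start + lo, end=tmpl.start + hi,
        seq=tmpl.seq[lo:hi],
        target_start=tmpl.target_start - lo, target_end=tmpl.target_end - lo,
        var_offset=tmpl.var_offset - lo,
        excluded_regions=_normalize(shifted, hi - lo),
    )
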