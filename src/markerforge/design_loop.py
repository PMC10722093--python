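"""Primer-pair design over a masked template, with specificity and
secondary-structure validation and iterative redesign.

The engine enumerates candidate left/right primers that flank the target
sub-interval, avoid every excluded region, and satisfy length, GC and
melting-temperature constraints (Tm from the nearest-neighbor
thermodynamic model, SantaLucia parameters, via Biopython).  Pairs are
ranked by a penalty that prefers optimal Tm, optimal length and balanced
Tm between mates.

Specificity is checked genome-wide with a 3'-anchored rule that mirrors
PCR extension chemistry: a binding site requires an exact match of the
primer's 3'-terminal 15-mer and at most 2 mismatches over the remainder.
Any two facing binding sites of the pair within 10 kb — other than the
intended locus — predict an off-target amplicon and reject the pair.
Rejected primers' footprints become excluded regions and design repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from Bio.SeqUtils import MeltingTemp as mt

from markerforge.io_layer import Reference
from markerforge.marker_screen import reverse_complement
from markerforge.template_builder import TemplateSequence, add_exclusions

# Universal 22-nt adapter tags for two-step multiplex amplicon sequencing
CS1_TAG = "ACACTGACGACATGGTTCTACA"
CS2_TAG = "TACGGTAGCAGAGACTTGGTCT"

SEED_LENGTH = 15        # exact-match 3'-terminal seed for binding-site search
MAX_MISMATCHES = 2      # allowed outside the 3'-terminal 5 bases
THREE_PRIME_EXACT = 5
MAX_OFFTARGET_PRODUCT = 10_000  # facing sites within 10 kb predict a product


@dataclass
class DesignParams:
    """Tunable constraints for the design engine.

    Defaults follow common practice for gel- and sequencing-scored
    markers: 150-200 bp products, 18-25 nt primers around a 60 C optimum.
    ``engine_options`` passes opaque overrides (keys matching field names).
    """

    product_min: int = 150
    product_max: int = 200
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    len_min: int = 18
    len_opt: int = 20
    len_max: int = 25
    gc_min: float = 20.0
    gc_max: float = 80.0
    max_poly_x: int = 5
    max_candidates_per_side: int = 250
    max_pairs: int = 100
    min_three_prime_distance: int = 2
    max_iterations: int = 10
    engine_options: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.engine_options.items():
            if hasattr(self, key) and key != "engine_options":
                setattr(self, key, val)
        if self.product_min > self.product_max:
            raise ValueError("product_min > product_max")
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("need tm_min <= tm_opt <= tm_max")


@dataclass
class StructureThresholds:
    """Secondary-structure limits in contiguous complementary-run units."""

    dimer_any_max_run: int = 7    # fail when a duplex run reaches 8 bp
    dimer_end_max_run: int = 4    # fail when a 3'-anchored run reaches 5 bp
    hairpin_max_stem: int = 5     # fail when a stem reaches 6 bp
    hairpin_min_loop: int = 3


@dataclass
class PrimerPairResult:
    """A designed primer pair with its provenance and validation status."""

    left_seq: str                 # 5'->3', including any tag
    right_seq: str
    left_start: int               # template coords, leftmost footprint base
    right_start: int
    left_len: int                 # genomic footprint length (tag excluded)
    right_len: int
    tm_left: float
    tm_right: float
    product_size: int             # right 3' end - left 5' end + 1 on template
    penalty: float
    specificity_status: str = "untested"   # untested | pass | off_target
    structure_status: str = "untested"     # untested | pass | hairpin | dimer
    iteration: int = 0
    tagged: bool = False

    @property
    def left_core(self) -> str:
        """Genomic (untagged) left primer."""
        return self.left_seq[-self.left_len:]

    @property
    def right_core(self) -> str:
        return self.right_seq[-self.right_len:]

    @property
    def left_end(self) -> int:
        return self.left_start + self.left_len

    @property
    def right_end(self) -> int:
        return self.right_start + self.right_len


@dataclass(frozen=True)
class OffTargetHit:
    """A facing pair of binding sites predicting an unintended amplicon."""

    contig: str
    left_pos: int       # leftmost genomic base of the left primer's site
    left_strand: str    # "+" | "-"
    right_pos: int
    right_strand: str
    product: int


@dataclass
class DesignOutcome:
    """Result of the redesign loop: the pair (or None) and the final template."""

    pair: Optional[PrimerPairResult]
    template: TemplateSequence
    reason: str = ""
    iterations: int = 0


def primer_tm(seq: str) -> float:
    """Nearest-neighbor melting temperature (SantaLucia 1998, 50 mM Na+)."""
    return float(mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=50, dnac2=0))


def _gc_percent(seq: str) -> float:
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _exclusion_mask(tmpl: TemplateSequence) -> List[bool]:
    mask = [False] * len(tmpl.seq)
    for s, e, _ in tmpl.excluded_regions:
        for i in range(max(0, s), min(len(mask), e)):
            mask[i] = True
    return mask


def _free(mask: List[bool], start: int, end: int) -> bool:
    return not any(mask[start:end])


def _primer_ok(seq: str, params: DesignParams) -> bool:
    if "N" in seq:
        return False
    if not params.gc_min <= _gc_percent(seq) <= params.gc_max:
        return False
    if _max_homopolymer(seq) > params.max_poly_x:
        return False
    return True


def design_candidates(tmpl: TemplateSequence,
                      params: DesignParams) -> List[PrimerPairResult]:
    """Enumerate primer pairs flanking the target, best penalty first.

    Both primers lie outside every excluded region and outside the target
    sub-interval; the product contains the full target and its size lies
    in [product_min, product_max].  Candidates per side are collected
    scanning outward from the target, capped for tractability.
    """
    mask = _exclusion_mask(tmpl)
    n = len(tmpl.seq)
    ts, te = tmpl.target_start, tmpl.target_end

    # Left primers: footprint [e-L, e), e <= target_start.
    # Product floor: left_start >= te - product_max.
    lefts: List[Tuple[int, int, float, float]] = []  # (start, len, tm, pen)
    for e in range(ts, -1, -1):
        if len(lefts) >= params.max_candidates_per_side:
            break
        if e - params.len_min < max(0, te - params.product_max):
            break
        for L in range(params.len_min, params.len_max + 1):
            s = e - L
            if s < 0 or s < te - params.product_max:
                continue
            if not _free(mask, s, e):
                continue
            seq = tmpl.seq[s:e]
            if not _primer_ok(seq, params):
                continue
            tm = primer_tm(seq)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            pen = abs(tm - params.tm_opt) + abs(L - params.len_opt)
            lefts.append((s, L, tm, pen))

    rights: List[Tuple[int, int, float, float]] = []
    for s in range(te, n):
        if len(rights) >= params.max_candidates_per_side:
            break
        if s + params.len_min > min(n, ts + params.product_max):
            break
        for L in range(params.len_min, params.len_max + 1):
            e = s + L
            if e > n or e > ts + params.product_max:
                continue
            if not _free(mask, s, e):
                continue
            genomic = tmpl.seq[s:e]
            if "N" in genomic:
                continue
            seq = reverse_complement(genomic)
            if not _primer_ok(seq, params):
                continue
            tm = primer_tm(seq)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            pen = abs(tm - params.tm_opt) + abs(L - params.len_opt)
            rights.append((s, L, tm, pen))

    scored: List[Tuple[float, int, int, int, float, int, int, float]] = []
    for ls, ll, ltm, lpen in lefts:
        for rs, rl, rtm, rpen in rights:
            product = rs + rl - ls
            if not params.product_min <= product <= params.product_max:
                continue
            pen = lpen + rpen + 0.5 * abs(ltm - rtm)
            scored.append((pen, ls, rs, ll, ltm, rl, product, rtm))
    scored.sort()
    # diversity: a returned pair must place at least one primer 3' end
    # at min_three_prime_distance from every already-returned 3' end on
    # that side, so one bad neighborhood cannot monopolize the list
    d = params.min_three_prime_distance
    best: List[Tuple[float, int, int, int, float, int, int, float]] = []
    l3s: List[int] = []
    r3s: List[int] = []
    for tup in scored:
        _, ls, rs, ll, _, _, _, _ = tup
        l3, r3 = ls + ll - 1, rs
        if (all(abs(l3 - x) >= d for x in l3s)
                or all(abs(r3 - x) >= d for x in r3s)):
            best.append(tup)
            l3s.append(l3)
            r3s.append(r3)
            if len(best) >= params.max_pairs:
                break
    return [PrimerPairResult(
        left_seq=tmpl.seq[ls:ls + ll],
        right_seq=reverse_complement(tmpl.seq[rs:rs + rl]),
        left_start=ls, right_start=rs,
        left_len=ll, right_len=rl,
        tm_left=round(ltm, 2), tm_right=round(rtm, 2),
        product_size=product, penalty=round(pen, 4),
    ) for pen, ls, rs, ll, ltm, rl, product, rtm in best]


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def _find_all(hay: str, needle: str) -> List[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _binding_sites(primer: str, contig_seq: str) -> List[Tuple[int, str]]:
    """(leftmost genomic pos, strand) of every annealing site of ``primer``.

    Plus-strand site: the genome top strand contains the primer sequence,
    extension runs rightward.  Minus-strand site: the top strand contains
    the primer's reverse complement, extension runs leftward.  Matching
    requires the 3'-terminal 15-mer exact and <= 2 mismatches elsewhere.
    """
    L = len(primer)
    sites: List[Tuple[int, str]] = []
    seed = primer[-SEED_LENGTH:]
    head = primer[:-SEED_LENGTH]
    for j in _find_all(contig_seq, seed):
        s = j - len(head)
        if s < 0:
            continue
        mism = sum(a != b for a, b in zip(head, contig_seq[s:j]))
        if mism <= MAX_MISMATCHES:
            sites.append((s, "+"))
    rc = reverse_complement(primer)
    rseed = rc[:SEED_LENGTH]     # the primer 3' end maps to the site's left
    tail = rc[SEED_LENGTH:]
    for j in _find_all(contig_seq, rseed):
        e = j + L
        if e > len(contig_seq):
            continue
        mism = sum(a != b
                   for a, b in zip(tail, contig_seq[j + SEED_LENGTH:e]))
        if mism <= MAX_MISMATCHES:
            sites.append((j, "-"))
    return sites


def find_off_targets(pair: PrimerPairResult, ref: Reference,
                     target_interval: Tuple[str, int, int],
                     max_product: int = MAX_OFFTARGET_PRODUCT,
                     ) -> List[OffTargetHit]:
    """Facing binding-site combinations of the pair within ``max_product`` bp.

    Only the genomic cores anneal (tags are non-genomic).  The facing rule:
    a plus-strand site lies upstream of a minus-strand site and the implied
    product (minus-site 3' coordinate - plus-site 5' coordinate + 1) is
    positive and at most ``max_product``.  The combination whose implied
    product overlaps the intended target interval is the marker itself and
    is excluded.
    """
    if min(pair.left_len, pair.right_len) < SEED_LENGTH:
        raise ValueError("primers shorter than the seed cannot be screened")
    t_contig, t_start, t_end = target_interval
    hits: List[OffTargetHit] = []
    for contig, seq in ref.contigs.items():
        lsites = _binding_sites(pair.left_core, seq)
        rsites = _binding_sites(pair.right_core, seq)
        for (lp, lstrand) in lsites:
            for (rp, rstrand) in rsites:
                if lstrand == rstrand:
                    continue
                if lstrand == "+":
                    plus5, minus3 = lp, rp
                else:
                    plus5, minus3 = rp, lp
                product = minus3 - plus5 + 1
                if not 0 < product <= max_product:
                    continue
                if (contig == t_contig and minus3 >= t_start
                        and plus5 < t_end):
                    continue  # the intended locus itself
                hits.append(OffTargetHit(contig, lp, lstrand, rp, rstrand,
                                         product))
    return hits


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b):
            if ca == cb:
                cur[j + 1] = prev[j] + 1
                if cur[j + 1] > best:
                    best = cur[j + 1]
        prev = cur
    return best


def _dimer_any_run(a: str, b: str) -> int:
    """Longest contiguous complementary duplex between two oligos."""
    return _longest_common_substring(a, reverse_complement(b))


def _dimer_end_run(a: str, b: str) -> int:
    """Longest 3'-terminal suffix of ``a`` complementary to a window of ``b``."""
    rc = reverse_complement(b)
    k = 0
    while k < len(a) and a[len(a) - k - 1:] in rc:
        k += 1
    return k


def _hairpin_stem(seq: str, min_loop: int) -> int:
    """Longest self-complementary stem closable with a loop >= min_loop."""
    n = len(seq)
    rc = reverse_complement(seq)
    best = 0
    # match[i][j]: duplex run ending at seq[i] paired with rc[j]
    prev = [0] * n
    for i in range(n):
        cur = [0] * n
        for j in range(n):
            if seq[i] == rc[j]:
                cur[j] = (prev[j - 1] if j else 0) + 1
                k = cur[j]
                # rc index j maps back to seq position n-1-j, the leftmost
                # base of the partner arm; the loop sits between the arms
                loop = (n - 1 - j) - i - 1
                if loop >= min_loop and k > best:
                    best = k
        prev = cur
    return best


def has_secondary_structure(pair: PrimerPairResult,
                            thresholds: Optional[StructureThresholds] = None,
                            ) -> bool:
    """True when the pair forms a hairpin, self-dimer or cross-dimer.

    Checked on the full synthesized oligos (tags included when present),
    since adapter tags can base-pair just as genomic sequence does.
    """
    th = thresholds or StructureThresholds()
    a, b = pair.left_seq, pair.right_seq
    for oligo in (a, b):
        if _hairpin_stem(oligo, th.hairpin_min_loop) > th.hairpin_max_stem:
            return True
    for x, y in ((a, a), (b, b), (a, b)):
        if _dimer_any_run(x, y) > th.dimer_any_max_run:
            return True
    for x, y in ((a, a), (b, b), (a, b), (b, a)):
        if _dimer_end_run(x, y) > th.dimer_end_max_run:
            return True
    return False


# ---------------------------------------------------------------------------
# Tags & redesign loop
# ---------------------------------------------------------------------------

def add_tags(pair: PrimerPairResult, tag_fwd: str,
             tag_rev: str) -> PrimerPairResult:
    """Prepend adapter tags to the 5' ends; genomic footprints unchanged."""
    if not tag_fwd and not tag_rev:
        return pair
    return replace(pair,
                   left_seq=tag_fwd + pair.left_seq,
                   right_seq=tag_rev + pair.right_seq,
                   tagged=True)


def design_with_redesign(tmpl: TemplateSequence, params: DesignParams,
                         ref: Reference, mode: str,
                         tag_fwd: str = CS1_TAG, tag_rev: str = CS2_TAG,
                         thresholds: Optional[StructureThresholds] = None,
                         ) -> DesignOutcome:
    """Design, validate, and redesign until a specific clean pair is found.

    Each round evaluates the engine's ranked candidates in order — the
    list is what successive engine invocations would return — and the
    first pair with no facing off-target sites within 10 kb and no
    hairpin/dimer wins.  When a whole round fails, every rejected pair's
    template footprints join the excluded regions
    (reason=rejected_primer) and the engine re-runs, up to
    ``params.max_iterations`` rounds.  In SNP mode the adapter tags are
    prepended before the structure check, since the full synthesized
    oligo is what can dimerize.
    """
    reason = ""
    for iteration in range(params.max_iterations):
        candidates = design_candidates(tmpl, params)
        if not candidates:
            return DesignOutcome(None, tmpl,
                                 reason or "no_candidates", iteration)
        rejected: List[Tuple[int, int]] = []
        for raw in candidates:
            cand = replace(raw, iteration=iteration)
            if mode.upper() == "SNP":
                cand = add_tags(cand, tag_fwd, tag_rev)
            if has_secondary_structure(cand, thresholds):
                cand = replace(cand, structure_status="dimer_or_hairpin")
                reason = "secondary_structure"
            else:
                cand = replace(cand, structure_status="pass")
                off = find_off_targets(cand, ref, (tmpl.contig, tmpl.start,
                                                   tmpl.end))
                if off:
                    cand = replace(cand, specificity_status="off_target")
                    reason = "off_target"
                else:
                    cand = replace(cand, specificity_status="pass")
                    return DesignOutcome(cand, tmpl, "ok", iteration)
            rejected.extend([(cand.left_start, cand.left_end),
                             (cand.right_start, cand.right_end)])
        tmpl = add_exclusions(tmpl, [(s, e, "rejected_primer")
                                     for s, e in rejected])
    return DesignOutcome(None, tmpl, reason or "iteration_cap",
                         params.max_iterations)
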