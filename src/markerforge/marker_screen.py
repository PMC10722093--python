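"""Marker-type screening: InDel size, CAPS restriction polymorphism, SNP.

Includes the restriction-site engine: IUPAC-degenerate motif scanning on
both strands, and the curated default enzyme table.  The target sequence
for screening is the variant plus 20 bp of flank on each side, realized
separately for each group allele; because the flanks are identical by
construction, any differential enzyme site is attributable to the variant.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from markerforge.grouping import GroupPair
from markerforge.io_layer import Reference, VariantSite

TARGET_FLANK = 20  # bp of reference flank kept on each side of the variant

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeDefinition:
    """A restriction enzyme: recognition motif (IUPAC) and top-strand cut."""

    name: str
    site: str
    cut_offset: int  # bp from motif start, top strand

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise ValueError(f"{self.name}: site shorter than 4 bp")
        bad = set(self.site) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut offset out of range")


# Common commercially available 6- and 4-cutters.  Users can supply their
# own table (name<TAB>site<TAB>cut_offset) via load_enzyme_table.
DEFAULT_ENZYMES: Tuple[EnzymeDefinition, ...] = (
    EnzymeDefinition("EcoRI", "GAATTC", 1),
    EnzymeDefinition("BamHI", "GGATCC", 1),
    EnzymeDefinition("HindIII", "AAGCTT", 1),
    EnzymeDefinition("EcoRV", "GATATC", 3),
    EnzymeDefinition("XbaI", "TCTAGA", 1),
    EnzymeDefinition("PstI", "CTGCAG", 5),
    EnzymeDefinition("SalI", "GTCGAC", 1),
    EnzymeDefinition("SmaI", "CCCGGG", 3),
    EnzymeDefinition("KpnI", "GGTACC", 5),
    EnzymeDefinition("SacI", "GAGCTC", 5),
    EnzymeDefinition("SphI", "GCATGC", 5),
    EnzymeDefinition("NdeI", "CATATG", 2),
    EnzymeDefinition("DraI", "TTTAAA", 3),
    EnzymeDefinition("ApoI", "RAATTY", 1),
    EnzymeDefinition("HinfI", "GANTC", 1),
    EnzymeDefinition("AluI", "AGCT", 2),
    EnzymeDefinition("HaeIII", "GGCC", 2),
    EnzymeDefinition("MspI", "CCGG", 1),
    EnzymeDefinition("TaqI", "TCGA", 1),
    EnzymeDefinition("RsaI", "GTAC", 2),
    EnzymeDefinition("MseI", "TTAA", 1),
)


def load_enzyme_table(path: os.PathLike | str) -> List[EnzymeDefinition]:
    """Load a user enzyme table: name<TAB>site<TAB>cut_offset per line."""
    enzymes: List[EnzymeDefinition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            enzymes.append(EnzymeDefinition(parts[0], parts[1].upper(),
                                            int(parts[2])))
    return enzymes


def _matches_at(seq: str, pattern: str, offset: int) -> bool:
    # N in the *sequence* never matches (unknown base cannot confirm a site)
    for pc, sc in zip(pattern, seq[offset:offset + len(pattern)]):
        if sc not in IUPAC[pc] or sc == "N":
            return False
    return True


def scan_sites(seq: str, enzyme: EnzymeDefinition) -> List[int]:
    """All start offsets where the recognition motif occurs on either strand.

    The motif is matched forward, and its reverse complement is matched
    forward as well (equivalent to matching the motif on the bottom
    strand).  Palindromic motifs are reported once per position.  Offsets
    ascend.
    """
    fwd = enzyme.site
    rev = reverse_complement(enzyme.site)
    patterns = [fwd] if rev == fwd else [fwd, rev]
    n, m = len(seq), len(fwd)
    hits: List[int] = []
    for off in range(n - m + 1):
        if any(_matches_at(seq, p, off) for p in patterns):
            hits.append(off)
    return hits


@dataclass
class TargetSequence:
    """The variant ±20 bp, realized for each of the two group alleles.

    ``start``/``end`` are genomic (0-based half-open) over the reference
    span; ``var_offset`` locates the variant within the interval.  The two
    realized sequences share both flanks and differ only in the allele.
    """

    contig: str
    start: int
    end: int
    var_offset: int      # variant start within the interval
    ref_len: int         # length of the reference allele
    allele_a: str
    allele_b: str
    seq_a: str           # flank + allele_a + flank
    seq_b: str
    clipped: bool = False


@dataclass
class MarkerCandidate:
    """A grouped variant that passed screening for one marker type."""

    site: VariantSite
    group_pair: GroupPair
    marker_type: str                     # INDEL | CAPS | SNP
    target: TargetSequence
    enzyme: Optional[EnzymeDefinition] = None
    digested_allele: Optional[str] = None  # "A" | "B"

    def __post_init__(self) -> None:
        is_caps = self.marker_type == "CAPS"
        if is_caps != (self.enzyme is not None and
                       self.digested_allele is not None):
            raise ValueError("enzyme/digested_allele set iff marker is CAPS")


def extract_target(ref: Reference, site: VariantSite,
                   pair: GroupPair, flank: int = TARGET_FLANK) -> TargetSequence:
    """Extract the variant ±``flank`` bp and realize both group alleles.

    The interval is clipped at contig edges (flagged, not fatal).
    """
    contig_len = ref.length(site.contig)
    start = max(0, site.pos - flank)
    end = min(contig_len, site.pos + len(site.ref) + flank)
    clipped = (start != site.pos - flank) or (end != site.pos + len(site.ref) + flank)
    left = ref.slice(site.contig, start, site.pos)
    right = ref.slice(site.contig, site.pos + len(site.ref), end)
    allele_a = site.allele(pair.allele_a)
    allele_b = site.allele(pair.allele_b)
    return TargetSequence(
        contig=site.contig, start=start, end=end,
        var_offset=site.pos - start, ref_len=len(site.ref),
        allele_a=allele_a, allele_b=allele_b,
        seq_a=left + allele_a + right,
        seq_b=left + allele_b + right,
        clipped=clipped,
    )


def screen_indel(alleles: Tuple[str, str], size_min: int,
                 size_max: int) -> bool:
    """Pass iff the allele length difference lies in [size_min, size_max]."""
    if size_min < 1 or size_max < size_min:
        raise ValueError("need 1 <= size_min <= size_max")
    diff = abs(len(alleles[0]) - len(alleles[1]))
    return size_min <= diff <= size_max


def screen_caps(target: TargetSequence,
                enzymes: List[EnzymeDefinition],
                ) -> List[Tuple[EnzymeDefinition, str]]:
    """Enzymes that cut exactly one group allele's realized target.

    Returns (enzyme, digested_allele) for every enzyme with >=1 recognition
    site in one realized sequence and 0 in the other.  Symmetric: swapping
    allele labels swaps the digested-allele label and nothing else.
    """
    out: List[Tuple[EnzymeDefinition, str]] = []
    for enz in enzymes:
        hits_a = scan_sites(target.seq_a, enz)
        hits_b = scan_sites(target.seq_b, enz)
        if hits_a and not hits_b:
            out.append((enz, "A"))
        elif hits_b and not hits_a:
            out.append((enz, "B"))
    return out


def screen_snp(site: VariantSite, pair: GroupPair) -> bool:
    """Pass iff both grouped alleles are single bases and differ."""
    a = site.allele(pair.allele_a)
    b = site.allele(pair.allele_b)
    return len(a) == 1 and len(b) == 1 and a != b
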