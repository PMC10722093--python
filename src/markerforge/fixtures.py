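"""Synthetic fixtures: seeded genomes, VCFs with planted marker loci, depth.

Every stage of the pipeline is testable without external data.  The
generator plants loci whose expected outcome is known by construction —
e.g. a restriction site stamped into the reference and destroyed by the
alternate allele is CAPS-recoverable; a 1-bp indel under a 3-50 bp size
window is not.  The truth table records, per locus, which marker modes
should recover it under the fixture's stated settings.

Construction is self-validating: each locus window is scrubbed of
incidental recognition sites and repaired until the realized allele
windows carry exactly the site counts the locus type promises, so truth
flags follow from construction for every seed.  All randomness flows
from one integer seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from markerforge.io_layer import Reference
from markerforge.marker_screen import (DEFAULT_ENZYMES, EnzymeDefinition,
                                       scan_sites)

ECORI = next(e for e in DEFAULT_ENZYMES if e.name == "EcoRI")

GROUP_A_SAMPLES = ("A1", "A2")
GROUP_B_SAMPLES = ("B1", "B2")
ALL_SAMPLES = GROUP_A_SAMPLES + GROUP_B_SAMPLES

# genotype patterns over (A1, A2, B1, B2)
PATTERNS = {
    "split": ("0/0", "0/0", "1/1", "1/1"),
    "monomorphic": ("0/0", "0/0", "0/0", "0/0"),
    "het": ("0/1", "0/1", "0/1", "0/1"),
}

# expected recognition-site counts in the (ref, alt) realized windows
_CAPS_EXPECT = {"destroyed": (1, 0), "retained": (1, 1), "absent": (0, 0)}


@dataclass
class PlantInstruction:
    """One locus to plant: what it is and what it should yield."""

    locus_id: str
    contig: str
    pos: int                  # 0-based anchor position
    kind: str                 # snp | ins | del
    indel_len: int = 0        # inserted/deleted bases (kind != snp)
    caps_mode: str = "absent"  # destroyed | retained | absent
    pattern: str = "split"
    indel_ok: bool = False
    caps_ok: bool = False
    snp_ok: bool = False
    note: str = ""


@dataclass
class PlantedLocus:
    """Truth-table row for a planted locus."""

    locus_id: str
    contig: str
    pos: int                  # 0-based variant position
    kind: str
    ref_allele: str
    alt_allele: str
    enzyme: str
    pattern: str
    indel_ok: bool
    caps_ok: bool
    snp_ok: bool
    note: str = ""


@dataclass
class Fixture:
    """Paths and truth for one generated fixture set."""

    ref_path: Path
    vcf_path: Path
    depth_path: Optional[Path]
    truth: List[PlantedLocus]
    settings: Dict[str, object] = field(default_factory=dict)
    duplications: List[Tuple[str, int, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(n_contigs: int = 1, length: int = 200_000, gc: float = 0.5,
                seed: int = 0,
                duplications: Sequence[Tuple[str, int, int, int]] = (),
                ) -> Reference:
    """A seeded random genome; ``duplications`` plants exact copies.

    Each duplication is (contig, src_start, dst_start, block_length): the
    block at ``src_start`` is copied over ``dst_start``, producing two
    identical substrings for off-target testing.
    """
    if length < 2000:
        raise ValueError("contig length must be >= 2 kb")
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    bases = np.array(list("ACGT"))
    arrays: Dict[str, np.ndarray] = {}
    for i in range(n_contigs):
        arrays[f"chr{i + 1}"] = rng.choice(bases, size=length, p=probs)
    for contig, src, dst, blen in duplications:
        arr = arrays[contig]
        arr[dst:dst + blen] = arr[src:src + blen].copy()
    return Reference({name: "".join(arr) for name, arr in arrays.items()})


def write_fasta(ref: Reference, path: os.PathLike | str,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

def _snp_alt(ref_base: str, rng: np.random.Generator) -> str:
    return [b for b in "ACGT" if b != ref_base][int(rng.integers(3))]


def _caps_counts(seq: List[str] | str, pos: int, ref_allele: str,
                 alt_allele: str, enzyme: EnzymeDefinition,
                 flank: int = 20) -> Tuple[int, int]:
    """Recognition-site counts in the ±flank realized windows of each allele."""
    if not isinstance(seq, str):
        seq = "".join(seq[max(0, pos - flank):pos + len(ref_allele) + flank])
        pos_local = min(pos, flank)
        left = seq[:pos_local]
        right = seq[pos_local + len(ref_allele):]
    else:
        lo = max(0, pos - flank)
        left = seq[lo:pos]
        right = seq[pos + len(ref_allele):pos + len(ref_allele) + flank]
    return (len(scan_sites(left + ref_allele + right, enzyme)),
            len(scan_sites(left + alt_allele + right, enzyme)))


def _scrub(seq: List[str], lo: int, hi: int, enzyme: EnzymeDefinition,
           protect: Tuple[int, int], rng: np.random.Generator) -> None:
    """Mutate bases until [lo, hi) holds no recognition site outside protect."""
    for _ in range(300):
        window = "".join(seq[lo:hi])
        hits = [h for h in scan_sites(window, enzyme)
                if not (protect[0] <= lo + h < protect[1])]
        if not hits:
            return
        i = lo + hits[0] + int(rng.integers(len(enzyme.site)))
        if protect[0] <= i < protect[1]:
            continue
        seq[i] = _snp_alt(seq[i], rng)
    raise RuntimeError("could not scrub enzyme sites from window")


def _plant_one(seq: List[str], ins: PlantInstruction,
               enzyme: EnzymeDefinition, rng: np.random.Generator,
               ) -> Tuple[int, str, str]:
    """Engineer one locus in place; return (pos, ref_allele, alt_allele).

    Repairs the local sequence until the realized ±20 bp windows of both
    alleles carry exactly the site counts the locus type promises.
    """
    site_len = len(enzyme.site)
    span = max(ins.indel_len + 1, site_len)
    # A CAPS-recoverable locus promises a *unique* cut site over the whole
    # design template (target ±500 bp), not just the ±20 bp target window:
    # incidental motif copies would trigger template trimming and shrink
    # the design space below the product size.  Scrub accordingly.
    margin = 580 if ins.caps_mode == "destroyed" else 30
    lo = max(0, ins.pos - margin)
    hi = min(len(seq), ins.pos + span + margin)

    if ins.caps_mode == "destroyed":
        stamp_at = ins.pos
        seq[stamp_at:stamp_at + site_len] = list(enzyme.site)
        protect = (stamp_at, stamp_at + site_len)
        pos = ins.pos + site_len // 2      # break a core base of the motif
    elif ins.caps_mode == "retained":
        stamp_at = ins.pos - site_len - 4  # motif upstream, allele-free
        seq[stamp_at:stamp_at + site_len] = list(enzyme.site)
        protect = (stamp_at, stamp_at + site_len)
        pos = ins.pos
    else:
        protect = (-1, -1)
        pos = ins.pos
    _scrub(seq, lo, hi, enzyme, protect, rng)

    expected = _CAPS_EXPECT[ins.caps_mode]
    for _ in range(200):
        if ins.kind == "snp":
            ref_allele = seq[pos]
            alt_allele = _snp_alt(ref_allele, rng)
        elif ins.kind == "del":
            ref_allele = "".join(seq[pos:pos + ins.indel_len + 1])
            alt_allele = seq[pos]
        elif ins.kind == "ins":
            ref_allele = seq[pos]
            alt_allele = ref_allele + "".join(
                "ACGT"[int(rng.integers(4))] for _ in range(ins.indel_len))
        else:
            raise ValueError(f"unknown kind {ins.kind!r}")
        if _caps_counts(seq, pos, ref_allele, alt_allele, enzyme) == expected:
            return pos, ref_allele, alt_allele
        # repair: an allele junction re-created a site; nudge a nearby
        # base outside the protected motif and re-scrub
        j = lo + int(rng.integers(hi - lo))
        if not protect[0] <= j < protect[1] and j != pos:
            seq[j] = _snp_alt(seq[j], rng)
            _scrub(seq, lo, hi, enzyme, protect, rng)
    raise RuntimeError(f"{ins.locus_id}: could not satisfy site-count "
                       f"expectation {expected}")


def plant_variants(ref: Reference,
                   instructions: Sequence[PlantInstruction],
                   samples: Sequence[str], seed: int,
                   vcf_path: os.PathLike | str,
                   enzyme: EnzymeDefinition = ECORI,
                   ) -> Tuple[Reference, List[PlantedLocus]]:
    """Engineer loci into the reference, write the VCF, return the truth.

    Returns the engineered reference (write it with :func:`write_fasta`)
    and one :class:`PlantedLocus` per instruction.  Overlapping plantings
    (closer than 100 bp) are a hard error.
    """
    rng = np.random.default_rng(seed + 13)
    by_pos = sorted(instructions, key=lambda i: (i.contig, i.pos))
    for a, b in zip(by_pos, by_pos[1:]):
        if a.contig == b.contig and b.pos - a.pos < 100:
            raise ValueError(f"overlapping plantings {a.locus_id}/{b.locus_id}")

    arrays = {name: list(s) for name, s in ref.contigs.items()}
    truth: List[PlantedLocus] = []
    records: List[Tuple[str, int, str, str, Tuple[str, ...]]] = []
    for ins in by_pos:
        pos, ref_allele, alt_allele = _plant_one(arrays[ins.contig], ins,
                                                 enzyme, rng)
        records.append((ins.contig, pos, ref_allele, alt_allele,
                        PATTERNS[ins.pattern]))
        truth.append(PlantedLocus(
            locus_id=ins.locus_id, contig=ins.contig, pos=pos,
            kind=ins.kind, ref_allele=ref_allele, alt_allele=alt_allele,
            enzyme=enzyme.name if ins.caps_mode == "destroyed" else "",
            pattern=ins.pattern,
            indel_ok=ins.indel_ok, caps_ok=ins.caps_ok, snp_ok=ins.snp_ok,
            note=ins.note))

    planted = Reference({name: "".join(s) for name, s in arrays.items()})
    _write_vcf(vcf_path, planted, samples, records)
    return planted, truth


def _write_vcf(path: os.PathLike | str, ref: Reference,
               samples: Sequence[str],
               records: Sequence[Tuple[str, int, str, str, Tuple[str, ...]]],
               ) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for name, seq in ref.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for contig, pos, ra, aa, gts in sorted(records):
            fh.write(f"{contig}\t{pos + 1}\t.\t{ra}\t{aa}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

def make_depth(ref: Reference, base_depth: int,
               holes: Sequence[Tuple[str, int, int]],
               path: os.PathLike | str) -> None:
    """Uniform depth TSV with zero-depth holes (0-based half-open input)."""
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for contig, s, e in holes:
        by_contig.setdefault(contig, []).append((s, e))
    with open(path, "w") as fh:
        for name, seq in ref.contigs.items():
            cursor = 0
            for s, e in sorted(by_contig.get(name, [])):
                if s > cursor:
                    fh.write(f"{name}\t{cursor + 1}\t{s}\t{base_depth}\n")
                fh.write(f"{name}\t{s + 1}\t{e}\t0\n")
                cursor = e
            if cursor < len(seq):
                fh.write(f"{name}\t{cursor + 1}\t{len(seq)}\t{base_depth}\n")


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _mixed_instructions(contig: str, start: int, step: int,
                        ) -> List[PlantInstruction]:
    """30 loci: 10 InDel, 10 CAPS, 10 SNP, each decade with planted failures."""
    out: List[PlantInstruction] = []
    pos = start
    for i in range(7):
        kind = "del" if i % 2 == 0 else "ins"
        out.append(PlantInstruction(f"indel{i + 1}", contig, pos, kind,
                                    indel_len=3 + i, indel_ok=True,
                                    note="length inside window"))
        pos += step
    out.append(PlantInstruction("indel8", contig, pos, "del", indel_len=1,
                                note="below size window"))
    pos += step
    out.append(PlantInstruction("indel9", contig, pos, "ins", indel_len=60,
                                note="above size window"))
    pos += step
    out.append(PlantInstruction("indel10", contig, pos, "del", indel_len=5,
                                pattern="monomorphic", note="monomorphic"))
    pos += step
    for i in range(7):
        out.append(PlantInstruction(f"caps{i + 1}", contig, pos, "snp",
                                    caps_mode="destroyed", caps_ok=True,
                                    snp_ok=True,
                                    note="alt destroys stamped site"))
        pos += step
    for i in (8, 9):
        out.append(PlantInstruction(f"caps{i}", contig, pos, "snp",
                                    caps_mode="retained", snp_ok=True,
                                    note="site cut in both alleles"))
        pos += step
    out.append(PlantInstruction("caps10", contig, pos, "snp",
                                caps_mode="absent", snp_ok=True,
                                note="no site near the variant"))
    pos += step
    for i in range(7):
        out.append(PlantInstruction(f"snp{i + 1}", contig, pos, "snp",
                                    snp_ok=True, note="clean grouped SNP"))
        pos += step
    out.append(PlantInstruction("snp8", contig, pos, "snp",
                                note="low-depth hole over the locus"))
    pos += step
    out.append(PlantInstruction("snp9", contig, pos, "snp",
                                pattern="monomorphic", note="monomorphic"))
    pos += step
    out.append(PlantInstruction("snp10", contig, pos, "snp", pattern="het",
                                note="all samples heterozygous"))
    return out


def make_fixture(profile: str, out_dir: os.PathLike | str,
                 seed: int = 0) -> Fixture:
    """Generate a complete fixture set under ``out_dir``.

    Profiles: ``mixed`` (30 loci on 200 kb, all three marker types with
    planted failures, a low-depth hole and a depth track), ``indel`` /
    ``caps`` / ``snp`` (the corresponding 10-locus subset), ``offtarget``
    (a duplicated block carrying a SNP locus, copies 5 kb apart).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profile == "offtarget":
        return make_offtarget_fixture(out_dir, seed=seed)
    if profile not in ("mixed", "indel", "caps", "snp"):
        raise ValueError(f"unknown profile {profile!r}")

    length, start, step = 200_000, 3000, 6500
    instructions = _mixed_instructions("chr1", start, step)
    if profile != "mixed":
        instructions = [i for i in instructions
                        if i.locus_id.startswith(profile)]
    base = make_genome(n_contigs=1, length=length, gc=0.5, seed=seed)
    vcf_path = out_dir / "variants.vcf"
    ref, truth = plant_variants(base, instructions, ALL_SAMPLES, seed,
                                vcf_path)
    ref_path = out_dir / "reference.fasta"
    write_fasta(ref, ref_path)

    holes = [(loc.contig, loc.pos - 650, loc.pos + 650)
             for loc in truth if "low-depth" in loc.note]
    depth_path = out_dir / "depth.tsv"
    make_depth(ref, base_depth=30, holes=holes, path=depth_path)
    write_truth_table(truth, out_dir / "truth.tsv")

    return Fixture(
        ref_path=ref_path, vcf_path=vcf_path, depth_path=depth_path,
        truth=truth,
        settings={
            "indel_min": 3, "indel_max": 50,
            "enzymes": [ECORI], "min_depth": 5,
            "product_min": 150, "product_max": 200,
            "group_a": list(GROUP_A_SAMPLES), "group_b": list(GROUP_B_SAMPLES),
        })


def make_offtarget_fixture(out_dir: os.PathLike | str, seed: int = 0,
                           separation: int = 5000) -> Fixture:
    """A genome where both primer neighborhoods of a SNP locus recur.

    The region left of the locus (where every left primer must sit) and
    the region right of it are copied elsewhere, ``separation`` bp apart
    and facing the same way.  Any primer pair for the locus therefore has
    a second facing site combination with an implied product close to
    ``separation``: within 10 kb it must be rejected as an off-target,
    beyond 10 kb it is acceptable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    locus = 3000
    width = 290
    a_src, b_src = locus - 300, locus + 10   # flank blocks around the locus
    a_dst = 16_000
    b_dst = a_dst + separation
    length = max(40_000, b_dst + width + 3000)
    instructions = [PlantInstruction("dup_snp", "chr1", locus, "snp",
                                     snp_ok=True,
                                     note="flanks duplicated elsewhere")]
    base = make_genome(n_contigs=1, length=length, gc=0.5, seed=seed)
    vcf_path = out_dir / "variants.vcf"
    ref, truth = plant_variants(base, instructions, ALL_SAMPLES, seed,
                                vcf_path)
    # copy the planted flanks so the duplicates are exact; the variant
    # itself lives only in the VCF, not in the reference string
    arr = list(ref.contigs["chr1"])
    arr[a_dst:a_dst + width] = arr[a_src:a_src + width]
    arr[b_dst:b_dst + width] = arr[b_src:b_src + width]
    ref = Reference({"chr1": "".join(arr)})
    ref_path = out_dir / "reference.fasta"
    write_fasta(ref, ref_path)
    write_truth_table(truth, out_dir / "truth.tsv")
    return Fixture(ref_path=ref_path, vcf_path=vcf_path, depth_path=None,
                   truth=truth,
                   settings={"product_min": 150, "product_max": 200},
                   duplications=[("chr1", a_src, a_dst, width),
                                 ("chr1", b_src, b_dst, width)])


def write_truth_table(truth: Sequence[PlantedLocus],
                      path: os.PathLike | str) -> None:
    cols = ["locus_id", "contig", "pos", "kind", "ref_allele", "alt_allele",
            "enzyme", "pattern", "indel_ok", "caps_ok", "snp_ok", "note"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for loc in truth:
            fh.write("\t".join(str(getattr(loc, c)) for c in cols) + "\n")
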