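"""Input/output layer: reference FASTA, multi-sample VCF, depth tracks, reports.

All coordinates are 0-based half-open internally.  Conversion to and from the
1-based conventions of VCF and the depth-TSV dialect happens only at this
module's boundary.
"""

from __future__ import annotations

import bisect
import logging
import os
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO

log = logging.getLogger("markerforge")

MISSING = -1  # sentinel for a missing allele index in a genotype

_VALID_REF_CHARS = set("ACGTNRYSWKMBDHV")  # IUPAC; non-ACGTN folds to N


@dataclass
class Reference:
    """An in-memory reference genome: ordered map contig name -> sequence.

    Sequences are uppercase over {A,C,G,T,N}; ambiguity codes in the input
    are folded to N (primer design cannot place a primer over them anyway).
    """

    contigs: Dict[str, str]

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def slice(self, name: str, start: int, end: int) -> str:
        """Return contig[start:end], clipped to contig bounds."""
        seq = self.contigs[name]
        return seq[max(0, start):min(len(seq), end)]


@dataclass
class VariantSite:
    """One VCF record restricted to the selected samples.

    ``pos`` is 0-based (the VCF POS minus one).  ``genotypes`` maps sample
    name to an allele-index pair; missing allele calls use the sentinel
    :data:`MISSING`.  Multi-allelic records are kept un-split.
    """

    contig: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    genotypes: Dict[str, Tuple[int, int]]

    @property
    def pos1(self) -> int:
        """1-based position, for report output."""
        return self.pos + 1

    def allele(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]

    @property
    def end(self) -> int:
        """0-based exclusive end of the reference-allele span."""
        return self.pos + len(self.ref)


class DepthTrack:
    """Pooled per-position read depth, queryable at any reference position.

    Backed either by sorted depth intervals (TSV input) or by per-contig
    numpy arrays (SAM/BAM input).  Positions absent from the track report
    depth 0.
    """

    def __init__(self) -> None:
        self._intervals: Dict[str, Tuple[List[int], List[int], List[int]]] = {}
        self._arrays: Dict[str, np.ndarray] = {}

    # -- construction -----------------------------------------------------
    def add_interval(self, contig: str, start: int, end: int, depth: int) -> None:
        """Record depth over [start, end) (0-based half-open)."""
        if depth < 0:
            raise ValueError(f"negative depth {depth} on {contig}")
        starts, ends, depths = self._intervals.setdefault(contig, ([], [], []))
        starts.append(start)
        ends.append(end)
        depths.append(depth)

    def _finalize(self) -> None:
        for contig, (starts, ends, depths) in self._intervals.items():
            order = sorted(range(len(starts)), key=lambda i: starts[i])
            self._intervals[contig] = (
                [starts[i] for i in order],
                [ends[i] for i in order],
                [depths[i] for i in order],
            )

    def set_array(self, contig: str, depths: np.ndarray) -> None:
        self._arrays[contig] = depths

    # -- queries -----------------------------------------------------------
    def depth(self, contig: str, pos: int) -> int:
        if contig in self._arrays:
            arr = self._arrays[contig]
            if 0 <= pos < len(arr):
                return int(arr[pos])
            return 0
        if contig in self._intervals:
            starts, ends, depths = self._intervals[contig]
            i = bisect.bisect_right(starts, pos) - 1
            # intervals may abut but are assumed non-overlapping; scan back
            while i >= 0:
                if starts[i] <= pos < ends[i]:
                    return depths[i]
                if ends[i] <= pos and starts[i] <= pos:
                    break
                i -= 1
            return 0
        return 0

    def depths(self, contig: str, start: int, end: int) -> np.ndarray:
        """Vector of pooled depths over [start, end)."""
        if contig in self._arrays:
            arr = self._arrays[contig]
            out = np.zeros(end - start, dtype=np.int64)
            lo, hi = max(start, 0), min(end, len(arr))
            if hi > lo:
                out[lo - start:hi - start] = arr[lo:hi]
            return out
        return np.array([self.depth(contig, p) for p in range(start, end)],
                        dtype=np.int64)


@dataclass
class MarkerReportRow:
    """One line of the tab-delimited marker report.

    ``pos`` is 1-based, matching the input VCF convention.  Fragment lists
    are comma-joined in the TSV; empty string marks a non-applicable field.
    """

    marker_id: str
    contig: str
    pos: int
    marker_type: str                      # INDEL | CAPS | SNP
    allele_a: str
    allele_b: str
    left_primer: str
    right_primer: str
    tm_left: float
    tm_right: float
    product_size: int
    enzyme: str = ""                      # CAPS only
    digested_allele: str = ""             # CAPS only: "A" or "B"
    fragments_a: Tuple[int, ...] = ()     # CAPS only
    fragments_b: Tuple[int, ...] = ()     # CAPS only
    tag_status: str = ""                  # SNP only: "CS1/CS2" or ""
    product_seq: str = ""                 # allele-A realized amplicon

    def validate(self) -> None:
        if self.marker_type not in ("INDEL", "CAPS", "SNP"):
            raise ValueError(f"bad marker type {self.marker_type!r}")
        if self.marker_type == "CAPS":
            if not self.enzyme:
                raise ValueError("CAPS row without enzyme name")
            dig, other = ((self.fragments_a, self.fragments_b)
                          if self.digested_allele == "A"
                          else (self.fragments_b, self.fragments_a))
            if len(dig) < 2 or len(other) != 1:
                raise ValueError(
                    f"CAPS row {self.marker_id}: digested allele needs >=2 "
                    f"fragments and the other exactly 1 "
                    f"(got {self.fragments_a} / {self.fragments_b})")


REPORT_COLUMNS = [f.name for f in dc_fields(MarkerReportRow)]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_reference(path: os.PathLike | str) -> Reference:
    """Load a FASTA file into memory, case-folded to uppercase.

    Raises ``ValueError`` on duplicate contig names or characters outside
    the IUPAC nucleotide alphabet.
    """
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_REF_CHARS
        if bad:
            raise ValueError(
                f"non-nucleotide characters {sorted(bad)} in record {rec.id!r}")
        if not seq:
            raise ValueError(f"empty sequence for contig {rec.id!r}")
        # fold ambiguity codes (other than N) to N for design purposes
        folded = "".join(c if c in "ACGTN" else "N" for c in seq)
        contigs[rec.id] = folded
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return Reference(contigs=contigs)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def stream_variants(path: os.PathLike | str,
                    samples: Optional[Sequence[str]] = None,
                    counters: Optional[Dict[str, int]] = None,
                    ) -> Iterator[VariantSite]:
    """Yield :class:`VariantSite` records for the requested samples.

    ``samples=None`` selects all header samples.  Records without GT are
    skipped (counted under ``no_gt``); records with symbolic alleles
    (``<DEL>``, breakends, ``*``) are skipped under ``symbolic`` — marker
    design needs literal allele sequences.
    """
    vcf = pysam.VariantFile(str(path))
    header_samples = list(vcf.header.samples)
    if samples is None:
        samples = header_samples
    missing = [s for s in samples if s not in header_samples]
    if missing:
        raise ValueError(f"samples not in VCF header: {missing}")
    if counters is None:
        counters = {}
    counters.setdefault("no_gt", 0)
    counters.setdefault("symbolic", 0)

    for rec in vcf:
        alts = rec.alts or ()
        if any(a is None or not _is_literal_allele(a) for a in alts) or not alts:
            counters["symbolic"] += 1
            continue
        if "GT" not in rec.format:
            counters["no_gt"] += 1
            log.warning("record %s:%d has no GT; skipped", rec.contig, rec.pos)
            continue
        genotypes: Dict[str, Tuple[int, int]] = {}
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or len(gt) == 0:
                genotypes[s] = (MISSING, MISSING)
                continue
            pair = tuple(MISSING if a is None else int(a) for a in gt)
            if len(pair) == 1:  # haploid call: treat as homozygous
                pair = (pair[0], pair[0])
            genotypes[s] = pair[:2]
        yield VariantSite(
            contig=rec.contig,
            pos=rec.pos - 1,
            ref=rec.ref.upper(),
            alts=tuple(a.upper() for a in alts),
            genotypes=genotypes,
        )


def _is_literal_allele(a: str) -> bool:
    return bool(a) and all(c in "ACGTNacgtn" for c in a)


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

def load_depth(path: os.PathLike | str) -> DepthTrack:
    """Load a depth source: SAM/BAM alignments or a depth-interval TSV.

    The TSV dialect is ``contig<TAB>start(1-based)<TAB>end(inclusive)<TAB>
    depth``.  Alignment files are streamed once and coverage accumulated
    per position, so no index is needed.
    """
    path = str(path)
    if path.endswith((".bam", ".sam", ".cram")):
        return _depth_from_alignments(path)
    return _depth_from_tsv(path)


def _depth_from_alignments(path: str) -> DepthTrack:
    mode = "rb" if path.endswith((".bam", ".cram")) else "r"
    track = DepthTrack()
    with pysam.AlignmentFile(path, mode) as af:
        arrays = {name: np.zeros(length, dtype=np.int64)
                  for name, length in zip(af.references, af.lengths)}
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name is None:
                continue
            arr = arrays[aln.reference_name]
            for start, end in aln.get_blocks():
                arr[start:end] += 1
    for name, arr in arrays.items():
        track.set_array(name, arr)
    return track


def _depth_from_tsv(path: str) -> DepthTrack:
    track = DepthTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            try:
                contig = parts[0]
                start1, end1, depth = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if depth < 0 or start1 < 1 or end1 < start1:
                raise ValueError(f"{path}:{lineno}: bad interval/depth")
            track.add_interval(contig, start1 - 1, end1, depth)
    track._finalize()
    return track


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _format_field(value) -> str:
    if isinstance(value, tuple):
        return ",".join(str(v) for v in value)
    if isinstance(value, float):
        return f"{value:.2f}"
    return str(value)


def write_report(rows: Sequence[MarkerReportRow], path: os.PathLike | str) -> None:
    """Write the tab-delimited marker report (header + one line per row)."""
    for row in rows:
        row.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_format_field(getattr(row, c))
                               for c in REPORT_COLUMNS) + "\n")


def read_report(path: os.PathLike | str) -> List[MarkerReportRow]:
    """Parse a report written by :func:`write_report` (lossless round-trip)."""
    rows: List[MarkerReportRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != REPORT_COLUMNS:
            raise ValueError(f"unexpected report header in {path}")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            kw = dict(zip(REPORT_COLUMNS, vals))
            kw["pos"] = int(kw["pos"])
            kw["tm_left"] = float(kw["tm_left"])
            kw["tm_right"] = float(kw["tm_right"])
            kw["product_size"] = int(kw["product_size"])
            for frag in ("fragments_a", "fragments_b"):
                kw[frag] = (tuple(int(x) for x in kw[frag].split(","))
                            if kw[frag] else ())
            rows.append(MarkerReportRow(**kw))
    return rows
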