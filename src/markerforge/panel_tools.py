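"""Post-design selection for multiplex amplicon panels, and CAPS fragments.

Panel selection mirrors how amplicon-sequencing panels are assembled in
practice: keep products in a GC and size window (balanced amplification
in a single multiplex reaction), then thin markers to an approximately
even genomic spacing so the panel tiles the genome.
"""

from __future__ import annotations

from typing import List, Sequence

from markerforge.io_layer import MarkerReportRow
from markerforge.marker_screen import EnzymeDefinition, scan_sites


def gc_content(seq: str) -> float:
    """GC percentage of a sequence (0-100)."""
    if not seq:
        raise ValueError("empty sequence has no GC content")
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def filter_panel(rows: Sequence[MarkerReportRow],
                 gc_min: float = 40.0, gc_max: float = 60.0,
                 size_min: int = 150, size_max: int = 175,
                 require_parent_homozygosity: bool = True,
                 ) -> List[MarkerReportRow]:
    """Keep rows whose amplicon GC and size fall in the stated windows.

    GC is computed over the genomic amplicon (primers included, adapter
    tags excluded).  ``require_parent_homozygosity`` is satisfied by
    construction for rows from this pipeline — grouping only ever emits
    homozygous groups — so it filters only rows lacking both alleles.
    Order is preserved; the operation is idempotent.
    """
    kept: List[MarkerReportRow] = []
    for row in rows:
        if not row.product_seq:
            continue
        if not gc_min <= gc_content(row.product_seq) <= gc_max:
            continue
        if not size_min <= row.product_size <= size_max:
            continue
        if require_parent_homozygosity and not (row.allele_a and row.allele_b):
            continue
        kept.append(row)
    return kept


def space_markers(rows: Sequence[MarkerReportRow],
                  interval: int = 2_000_000) -> List[MarkerReportRow]:
    """Greedy per-contig thinning to >= ``interval`` bp between kept markers.

    Rows must be sorted by (contig, pos).  The first marker on each contig
    is kept; each next kept marker is the first one at least ``interval``
    bp downstream of the previous kept one.
    """
    kept: List[MarkerReportRow] = []
    last_by_contig: dict[str, int] = {}
    for row in rows:
        last = last_by_contig.get(row.contig)
        if last is not None and row.pos < last:
            raise ValueError("rows must be sorted by contig then position")
        if last is None or row.pos - last >= interval:
            kept.append(row)
            last_by_contig[row.contig] = row.pos
    return kept


def predict_fragments(product_seq: str,
                      enzyme: EnzymeDefinition) -> List[int]:
    """Fragment lengths after digesting the amplicon, 5'->3'.

    Cuts at every recognition site's top-strand cut offset; fragment
    lengths always sum to the product length.
    """
    cuts = sorted({h + enzyme.cut_offset for h in scan_sites(product_seq,
                                                             enzyme)})
    cuts = [c for c in cuts if 0 < c < len(product_seq)]
    bounds = [0] + cuts + [len(product_seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]
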