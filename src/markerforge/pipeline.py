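"""End-to-end marker pipeline: VCF stream -> grouping -> screening ->
template construction/masking -> design loop -> report rows.

This is the library behind the ``markerforge run`` command; tests and the
reproduction script drive it directly.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from markerforge import design_loop, grouping, marker_screen, template_builder
from markerforge.design_loop import (CS1_TAG, CS2_TAG, DesignOutcome,
                                     DesignParams)
from markerforge.io_layer import (DepthTrack, MarkerReportRow, Reference,
                                  VariantSite, load_depth, load_reference,
                                  stream_variants, write_report)
from markerforge.marker_screen import (DEFAULT_ENZYMES, EnzymeDefinition,
                                       MarkerCandidate)
from markerforge.panel_tools import predict_fragments
from markerforge.template_builder import TemplateSequence, TrimError

log = logging.getLogger("markerforge")


@dataclass
class PipelineConfig:
    """Validated run configuration (CLI flags map onto these fields)."""

    ref_path: str
    vcf_path: str
    marker_type: str                      # indel | caps | snp
    depth_path: Optional[str] = None
    samples: Optional[List[str]] = None
    group_a: Optional[List[str]] = None   # None + None -> auto-group mode
    group_b: Optional[List[str]] = None
    indel_min: int = 3
    indel_max: int = 50
    enzymes: Sequence[EnzymeDefinition] = DEFAULT_ENZYMES
    min_depth: int = 0
    target_flank: int = marker_screen.TARGET_FLANK
    template_flank: int = template_builder.TEMPLATE_FLANK
    design: DesignParams = field(default_factory=DesignParams)
    tag_fwd: str = CS1_TAG
    tag_rev: str = CS2_TAG

    def __post_init__(self) -> None:
        if self.marker_type not in ("indel", "caps", "snp"):
            raise ValueError(f"bad marker type {self.marker_type!r}")
        if (self.group_a is None) != (self.group_b is None):
            raise ValueError("give both --group-a and --group-b or neither")


@dataclass
class MarkerDetail:
    """Per-marker provenance: the report row plus its design outcome."""

    row: MarkerReportRow
    candidate: MarkerCandidate
    outcome: DesignOutcome


@dataclass
class PipelineResult:
    rows: List[MarkerReportRow]
    details: List[MarkerDetail]
    counters: Dict[str, int]


def _nearby_sites(sites_by_contig: Dict[str, Tuple[List[int], List[VariantSite]]],
                  tmpl: TemplateSequence,
                  exclude: VariantSite) -> List[VariantSite]:
    if tmpl.contig not in sites_by_contig:
        return []
    positions, sites = sites_by_contig[tmpl.contig]
    lo = bisect.bisect_left(positions, tmpl.start - 500)
    hi = bisect.bisect_right(positions, tmpl.end)
    return [s for s in sites[lo:hi]
            if s is not exclude and s.end > tmpl.start and s.pos < tmpl.end]


def _screen(site: VariantSite, pair: grouping.GroupPair,
            ref: Reference, cfg: PipelineConfig,
            counters: Dict[str, int]) -> Optional[MarkerCandidate]:
    target = marker_screen.extract_target(ref, site, pair, cfg.target_flank)
    if cfg.marker_type == "indel":
        if marker_screen.screen_indel((target.allele_a, target.allele_b),
                                      cfg.indel_min, cfg.indel_max):
            return MarkerCandidate(site, pair, "INDEL", target)
        counters["screened_out"] += 1
        return None
    if cfg.marker_type == "snp":
        if marker_screen.screen_snp(site, pair):
            return MarkerCandidate(site, pair, "SNP", target)
        counters["screened_out"] += 1
        return None
    hits = marker_screen.screen_caps(target, list(cfg.enzymes))
    if not hits:
        counters["screened_out"] += 1
        return None
    enzyme, digested = hits[0]   # deterministic: enzyme-table order
    return MarkerCandidate(site, pair, "CAPS", target, enzyme=enzyme,
                           digested_allele=digested)


def _product_seq(tmpl: TemplateSequence, allele: str, left_start: int,
                 right_end: int) -> str:
    shift = len(allele) - tmpl.ref_len
    return tmpl.realize_allele(allele)[left_start:right_end + shift]


def _build_row(cand: MarkerCandidate, outcome: DesignOutcome,
               cfg: PipelineConfig) -> MarkerReportRow:
    pair, tmpl = outcome.pair, outcome.template
    assert pair is not None
    site = cand.site
    product_a = _product_seq(tmpl, cand.target.allele_a, pair.left_start,
                             pair.right_end)
    marker_id = f"{site.contig}_{site.pos1}_{cand.marker_type}"
    row = MarkerReportRow(
        marker_id=marker_id, contig=site.contig, pos=site.pos1,
        marker_type=cand.marker_type,
        allele_a=cand.target.allele_a, allele_b=cand.target.allele_b,
        left_primer=pair.left_seq, right_primer=pair.right_seq,
        tm_left=pair.tm_left, tm_right=pair.tm_right,
        product_size=pair.product_size,
        tag_status=("CS1/CS2" if pair.tagged else ""),
        product_seq=product_a,
    )
    if cand.marker_type == "CAPS":
        product_b = _product_seq(tmpl, cand.target.allele_b, pair.left_start,
                                 pair.right_end)
        row.enzyme = cand.enzyme.name
        row.digested_allele = cand.digested_allele
        row.fragments_a = tuple(predict_fragments(product_a, cand.enzyme))
        row.fragments_b = tuple(predict_fragments(product_b, cand.enzyme))
        row.marker_id += f"_{cand.enzyme.name}"
    return row


def run_pipeline(cfg: PipelineConfig,
                 out_path: Optional[str] = None) -> PipelineResult:
    """Run the full marker-design pipeline; optionally write the TSV report.

    Stage counters: ``sites_seen``, ``grouped``, ``screened_in``,
    ``screened_out``, ``designed``, ``design_failed``, ``trim_failed``.
    """
    ref = load_reference(cfg.ref_path)
    depth: Optional[DepthTrack] = (load_depth(cfg.depth_path)
                                   if cfg.depth_path else None)
    counters: Dict[str, int] = {k: 0 for k in
                                ("sites_seen", "grouped", "screened_in",
                                 "screened_out", "designed", "design_failed",
                                 "trim_failed", "skipped")}
    sites = list(stream_variants(cfg.vcf_path, cfg.samples, counters))
    counters["sites_seen"] = len(sites)
    by_contig: Dict[str, Tuple[List[int], List[VariantSite]]] = {}
    for s in sorted(sites, key=lambda s: (s.contig, s.pos)):
        by_contig.setdefault(s.contig, ([], []))
        by_contig[s.contig][0].append(s.pos)
        by_contig[s.contig][1].append(s)

    rows: List[MarkerReportRow] = []
    details: List[MarkerDetail] = []
    for site in sites:
        if cfg.group_a is not None:
            pair = grouping.group_user(site, set(cfg.group_a),
                                       set(cfg.group_b))
            pairs = [pair] if pair else []
        else:
            pairs = grouping.group_auto(site)
        if pairs:
            counters["grouped"] += 1
        for pair in pairs:
            cand = _screen(site, pair, ref, cfg, counters)
            if cand is None:
                continue
            counters["screened_in"] += 1
            tmpl = template_builder.build_template(ref, cand.target,
                                                   cfg.template_flank)
            nearby = _nearby_sites(by_contig, tmpl, site)
            tmpl = template_builder.mask_variants(tmpl, nearby, pair)
            if depth is not None and cfg.min_depth > 0:
                tmpl = template_builder.mask_low_depth(tmpl, depth,
                                                       cfg.min_depth)
            if cand.marker_type == "CAPS":
                digested_seq = (cand.target.allele_a
                                if cand.digested_allele == "A"
                                else cand.target.allele_b)
                try:
                    tmpl = template_builder.trim_caps_template(
                        tmpl, cand.enzyme, digested_seq)
                except TrimError as exc:
                    log.info("trim failed at %s:%d: %s", site.contig,
                             site.pos1, exc)
                    counters["trim_failed"] += 1
                    continue
            outcome = design_loop.design_with_redesign(
                tmpl, cfg.design, ref, cand.marker_type,
                tag_fwd=cfg.tag_fwd, tag_rev=cfg.tag_rev)
            if outcome.pair is None:
                counters["design_failed"] += 1
                log.info("design failed at %s:%d (%s)", site.contig,
                         site.pos1, outcome.reason)
                continue
            counters["designed"] += 1
            row = _build_row(cand, outcome, cfg)
            rows.append(row)
            details.append(MarkerDetail(row, cand, outcome))

    order = sorted(range(len(rows)),
                   key=lambda i: (rows[i].contig, rows[i].pos,
                                  rows[i].marker_id))
    rows = [rows[i] for i in order]
    details = [details[i] for i in order]
    if out_path is not None:
        write_report(rows, out_path)
    return PipelineResult(rows=rows, details=details, counters=counters)
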