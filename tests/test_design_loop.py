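"""Design engine, specificity search, structure filters, redesign loop."""

import random

import pytest

from markerforge.design_loop import (CS1_TAG, CS2_TAG, DesignParams,
                                     PrimerPairResult, add_tags,
                                     design_candidates, design_with_redesign,
                                     find_off_targets, has_secondary_structure,
                                     primer_tm)
from markerforge.grouping import GroupPair
from markerforge.io_layer import Reference, VariantSite
from markerforge.marker_screen import extract_target, reverse_complement
from markerforge.template_builder import add_exclusions, build_template


def _rand_seq(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _pair():
    return GroupPair(frozenset({"a"}), frozenset({"b"}), 0, 1)


def _template(seed=0, pos=2020, length=10_000):
    seq = _rand_seq(length, seed)
    ref = Reference({"c1": seq})
    alt = "T" if seq[pos] != "T" else "C"
    site = VariantSite("c1", pos, seq[pos], (alt,),
                       {"a": (0, 0), "b": (1, 1)})
    tmpl = build_template(ref, extract_target(ref, site, _pair()))
    return ref, tmpl


def _overlaps(a_start, a_end, regions):
    return any(a_start < e and a_end > s for s, e, _ in regions)


def test_design_candidates_respect_all_constraints():
    _, tmpl = _template(seed=3)
    tmpl = add_exclusions(tmpl, [(300, 360, "variant"),
                                 (700, 760, "low_depth")])
    params = DesignParams(product_min=150, product_max=200)
    cands = design_candidates(tmpl, params)
    assert cands
    assert [c.penalty for c in cands] == sorted(c.penalty for c in cands)
    for c in cands:
        assert 150 <= c.product_size <= 200
        assert c.product_size == c.right_end - c.left_start
        # amplicon contains the whole target; primers flank it
        assert c.left_start <= tmpl.target_start
        assert c.left_end <= tmpl.target_start
        assert c.right_start >= tmpl.target_end
        # no primer overlaps any excluded base (interval oracle)
        assert not _overlaps(c.left_start, c.left_end, tmpl.excluded_regions)
        assert not _overlaps(c.right_start, c.right_end,
                             tmpl.excluded_regions)
        assert params.tm_min <= c.tm_left <= params.tm_max
        assert params.tm_min <= c.tm_right <= params.tm_max
        # orientation: left maps forward, right maps reverse-complement
        assert c.left_seq == tmpl.seq[c.left_start:c.left_end]
        assert c.right_seq == reverse_complement(
            tmpl.seq[c.right_start:c.right_end])


def test_design_candidates_empty_when_fully_masked():
    _, tmpl = _template(seed=4)
    tmpl = add_exclusions(tmpl, [(0, tmpl.target_start, "low_depth")])
    assert design_candidates(tmpl, DesignParams()) == []


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def _mk_pair(left, right, left_start=0, right_start=100):
    return PrimerPairResult(
        left_seq=left, right_seq=right, left_start=left_start,
        right_start=right_start, left_len=len(left), right_len=len(right),
        tm_left=60.0, tm_right=60.0,
        product_size=right_start + len(right) - left_start, penalty=0.0)


def oracle_off_targets(pair, ref, target_interval, max_product=10_000):
    """Exhaustive scan: every near-exact site pair facing within range."""
    out = []
    for contig, seq in ref.contigs.items():
        def sites(primer):
            hits = []
            L = len(primer)
            for i in range(len(seq) - L + 1):
                window = seq[i:i + L]
                if window[-15:] == primer[-15:] and sum(
                        a != b for a, b in zip(window, primer)) <= 2:
                    hits.append((i, "+"))
                rc = reverse_complement(primer)
                if seq[i:i + 15] == rc[:15] and sum(
                        a != b for a, b in zip(seq[i:i + L], rc)) <= 2:
                    hits.append((i, "-"))
            return hits
        for lp, ls in sites(pair.left_core):
            for rp, rs in sites(pair.right_core):
                if ls == rs:
                    continue
                plus5, minus3 = (lp, rp) if ls == "+" else (rp, lp)
                product = minus3 - plus5 + 1
                if not 0 < product <= max_product:
                    continue
                tc, ts, te = target_interval
                if contig == tc and minus3 >= ts and plus5 < te:
                    continue
                out.append((contig, lp, ls, rp, rs, product))
    return sorted(out)


def test_find_off_targets_specific_pair_is_clean():
    seq = _rand_seq(30_000, seed=5)
    ref = Reference({"c1": seq})
    left = seq[1000:1020]
    right = reverse_complement(seq[1150:1170])
    pair = _mk_pair(left, right)
    assert find_off_targets(pair, ref, ("c1", 990, 1180)) == []


def test_find_off_targets_matches_oracle_with_duplication():
    rng = random.Random(6)
    base = _rand_seq(30_000, seed=6)
    # duplicate the primer-site block 5 kb downstream
    seq = base[:8000] + base[1000:1200] + base[8200:]
    ref = Reference({"c1": seq})
    left = seq[1000:1020]
    right = reverse_complement(seq[1150:1170])
    pair = _mk_pair(left, right)
    hits = find_off_targets(pair, ref, ("c1", 990, 1180))
    got = sorted((h.contig, h.left_pos, h.left_strand, h.right_pos,
                  h.right_strand, h.product) for h in hits)
    assert got == oracle_off_targets(pair, ref, ("c1", 990, 1180))
    assert len(hits) >= 1
    assert all(h.product <= 10_000 for h in hits)


def test_find_off_targets_beyond_10kb_not_reported():
    base = _rand_seq(60_000, seed=7)
    # duplicate the two primer-site blocks separately, 15 kb apart, so the
    # second facing combination implies a ~15 kb product
    seq = (base[:20_000] + base[995:1025] + base[20_030:35_000]
           + base[1145:1175] + base[35_030:])
    ref = Reference({"c1": seq})
    left = seq[1000:1020]
    right = reverse_complement(seq[1150:1170])
    pair = _mk_pair(left, right)
    assert find_off_targets(pair, ref, ("c1", 990, 1180)) == []
    # but a raised ceiling sees the duplicate
    assert find_off_targets(pair, ref, ("c1", 990, 1180),
                            max_product=25_000)


def test_find_off_targets_short_primer_rejected():
    pair = _mk_pair("ACGTACGTACGT", "ACGTACGTACGT")
    with pytest.raises(ValueError):
        find_off_targets(pair, Reference({"c1": "A" * 100}), ("c1", 0, 10))


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def test_structure_perfect_cross_dimer_fails():
    pair = _mk_pair("A" * 20, "T" * 20)
    assert has_secondary_structure(pair)


def test_structure_random_noncomplementary_pair_passes():
    pair = _mk_pair("ACTGGATCTACGATGCAAGT", "TGACCTAGATGCTACGTTCA"[::-1])
    # hand-picked non-complementary 20-mers
    pair = _mk_pair("ACTGGATCTACGATGCAAGT", "AGGTCCATTCACGAGATGAC")
    assert not has_secondary_structure(pair)


def test_structure_hairpin_inverted_repeat_fails():
    stem = "ACGTACGTAG"
    hairpin = stem + "TTTT" + reverse_complement(stem)
    pair = _mk_pair(hairpin, "AGGTCCATTCACGAGATGAC")
    assert has_secondary_structure(pair)


def test_add_tags_prepends_and_empty_is_identity():
    pair = _mk_pair("ACTGGATCTACGATGCAAGT", "AGGTCCATTCACGAGATGAC")
    tagged = add_tags(pair, CS1_TAG, CS2_TAG)
    assert tagged.left_seq == CS1_TAG + pair.left_seq
    assert tagged.right_seq == CS2_TAG + pair.right_seq
    assert tagged.left_core == pair.left_seq      # genomic footprint intact
    assert (tagged.left_start, tagged.right_start) == (pair.left_start,
                                                       pair.right_start)
    assert add_tags(pair, "", "") is pair


# ---------------------------------------------------------------------------
# Redesign loop
# ---------------------------------------------------------------------------

def test_redesign_returns_validated_pair_on_clean_template():
    ref, tmpl = _template(seed=8)
    out = design_with_redesign(tmpl, DesignParams(), ref, "indel")
    assert out.pair is not None
    assert out.pair.specificity_status == "pass"
    assert out.pair.structure_status == "pass"
    # post-hoc oracle: the returned pair really has no off-targets
    assert find_off_targets(out.pair, ref,
                            (tmpl.contig, tmpl.start, tmpl.end)) == []


def test_redesign_snp_mode_tags_before_structure_check():
    ref, tmpl = _template(seed=9)
    out = design_with_redesign(tmpl, DesignParams(), ref, "snp")
    assert out.pair is not None and out.pair.tagged
    assert out.pair.left_seq.startswith(CS1_TAG)
    assert not has_secondary_structure(out.pair)


def test_redesign_terminates_on_repetitive_template():
    """An adversarial all-repeat genome exhausts without looping forever."""
    unit = "ACGTTGCAAC"
    seq = unit * 2000
    ref = Reference({"c1": seq})
    site = VariantSite("c1", 5005, seq[5005], ("T",),
                       {"a": (0, 0), "b": (1, 1)})
    tmpl = build_template(ref, extract_target(ref, site, _pair()))
    params = DesignParams(max_iterations=4)
    out = design_with_redesign(tmpl, params, ref, "indel")
    assert out.pair is None
    assert out.iterations <= 4
    assert out.reason != ""


def test_redesign_exclusions_never_shrink():
    ref, tmpl = _template(seed=10)
    tmpl = add_exclusions(tmpl, [(100, 140, "variant")])
    before = sum(e - s for s, e, _ in tmpl.excluded_regions)
    out = design_with_redesign(tmpl, DesignParams(), ref, "snp")
    after = sum(e - s for s, e, _ in out.template.excluded_regions)
    assert after >= before
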