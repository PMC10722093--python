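"""Template construction, exclusion masking, and CAPS trimming."""

import random

import pytest

from markerforge.grouping import GroupPair
from markerforge.io_layer import DepthTrack, MISSING, Reference, VariantSite
from markerforge.marker_screen import DEFAULT_ENZYMES, extract_target, scan_sites
from markerforge.template_builder import (TrimError, add_exclusions,
                                          build_template, mask_low_depth,
                                          mask_variants, trim_caps_template)

ECORI = next(e for e in DEFAULT_ENZYMES if e.name == "EcoRI")


def _rand_seq(n, seed=0, forbid="GAATTC"):
    rng = random.Random(seed)
    while True:
        s = "".join(rng.choice("ACGT") for _ in range(n))
        if forbid not in s and forbid not in s[::-1]:
            return s


def _pair(samples_a=("a",), samples_b=("b",)):
    return GroupPair(frozenset(samples_a), frozenset(samples_b), 0, 1)


def _snp_site(pos, seq):
    alt = "T" if seq[pos] != "T" else "C"
    return VariantSite("c1", pos, seq[pos], (alt,),
                       {"a": (0, 0), "b": (1, 1)})


def _template(seq, pos):
    ref = Reference({"c1": seq})
    site = _snp_site(pos, seq)
    return ref, site, build_template(ref, extract_target(ref, site, _pair()))


def test_build_template_geometry_and_identity():
    seq = _rand_seq(10_000, seed=1)
    ref, site, tmpl = _template(seq, 2020)
    assert (tmpl.start, tmpl.end) == (1500, 2541)
    assert len(tmpl.seq) == 1041
    assert tmpl.seq == seq[1500:2541]
    assert (tmpl.target_start, tmpl.target_end) == (500, 541)
    assert not tmpl.clipped


def test_build_template_clips_at_contig_edge():
    seq = _rand_seq(10_000, seed=2)
    ref, site, tmpl = _template(seq, 80)
    assert tmpl.start == 0 and tmpl.clipped


def test_mask_variants_only_segregating_sites_mask():
    seq = _rand_seq(5000, seed=3)
    ref, site, tmpl = _template(seq, 2020)
    near_pos = 1530                      # template offset 30
    segregating = VariantSite("c1", near_pos, seq[near_pos], ("T",),
                              {"a": (0, 0), "b": (1, 1)})
    monomorphic = VariantSite("c1", 1600, seq[1600], ("T",),
                              {"a": (0, 0), "b": (0, 0)})
    out = mask_variants(tmpl, [segregating, monomorphic], _pair())
    assert out.excluded_regions == [(29, 32, "variant")]   # ±1 bp guard
    # heterozygous and missing genotypes mask conservatively
    for gts in ({"a": (0, 1), "b": (0, 0)},
                {"a": (MISSING, MISSING), "b": (0, 0)}):
        messy = VariantSite("c1", near_pos, seq[near_pos], ("T",), gts)
        assert mask_variants(tmpl, [messy], _pair()).excluded_regions


def test_mask_variants_no_nearby_sites_is_identity():
    _, _, tmpl = _template(_rand_seq(5000, seed=4), 2020)
    assert mask_variants(tmpl, [], _pair()).excluded_regions == []


def test_mask_low_depth_run_lengths_and_vacuous_threshold():
    _, _, tmpl = _template(_rand_seq(5000, seed=5), 2020)
    track = DepthTrack()
    # template spans [1500, 2541); a hole at template offsets 10..15
    track.add_interval("c1", 1500, 1510, 30)
    track.add_interval("c1", 1516, 2541, 30)
    track._finalize()
    out = mask_low_depth(tmpl, track, min_depth=5)
    assert out.excluded_regions == [(10, 16, "low_depth")]
    assert mask_low_depth(tmpl, track, min_depth=0).excluded_regions == []
    uniform = DepthTrack()
    uniform.add_interval("c1", 0, 5000, 30)
    uniform._finalize()
    assert mask_low_depth(tmpl, uniform, 5).excluded_regions == []


def test_mask_low_depth_oracle_random_tracks():
    """Exclusions equal a naive per-position run-length scan."""
    rng = random.Random(7)
    _, _, tmpl = _template(_rand_seq(5000, seed=6), 2020)
    for _ in range(10):
        depths = [rng.choice([0, 2, 8, 30]) for _ in range(len(tmpl.seq))]
        track = DepthTrack()
        for i, d in enumerate(depths):
            track.add_interval("c1", tmpl.start + i, tmpl.start + i + 1, d)
        track._finalize()
        out = mask_low_depth(tmpl, track, min_depth=5)
        expected = []
        i = 0
        while i < len(depths):
            if depths[i] < 5:
                j = i
                while j < len(depths) and depths[j] < 5:
                    j += 1
                expected.append((i, j, "low_depth"))
                i = j
            else:
                i += 1
        assert out.excluded_regions == expected


def test_exclusions_are_merged_sorted_disjoint_and_idempotent():
    _, _, tmpl = _template(_rand_seq(5000, seed=8), 2020)
    regions = [(50, 60, "variant"), (55, 70, "low_depth"),
               (10, 20, "variant"), (-5, 3, "variant"),
               (900, 9999, "low_depth"), (2000, 3000, "variant")]
    once = add_exclusions(tmpl, regions)
    assert once.excluded_regions == [
        (0, 3, "variant"), (10, 20, "variant"),
        (50, 70, "low_depth+variant"), (900, len(tmpl.seq), "low_depth")]
    twice = add_exclusions(once, regions)
    assert twice.excluded_regions == once.excluded_regions
    for s, e, _ in once.excluded_regions:
        assert 0 <= s < e <= len(tmpl.seq)


# ---------------------------------------------------------------------------
# CAPS trimming
# ---------------------------------------------------------------------------

def _caps_template(seed, extra_left=None, extra_right=None):
    """A template whose target carries a GAATTC destroyed by the alt."""
    seq = list(_rand_seq(5000, seed=seed))
    pos = 2020
    seq[pos:pos + 6] = list("GAATTC")
    if extra_left is not None:
        seq[extra_left:extra_left + 6] = list("GAATTC")
    if extra_right is not None:
        seq[extra_right:extra_right + 6] = list("GAATTC")
    seq = "".join(seq)
    ref = Reference({"c1": seq})
    var_pos = pos + 3                     # break the first T
    site = VariantSite("c1", var_pos, "T", ("C",),
                       {"a": (0, 0), "b": (1, 1)})
    tmpl = build_template(ref, extract_target(ref, site, _pair()))
    return tmpl


def test_trim_caps_no_extra_sites_is_identity():
    tmpl = _caps_template(seed=11)
    out = trim_caps_template(tmpl, ECORI, "T")
    assert (out.start, out.end) == (tmpl.start, tmpl.end)


@pytest.mark.parametrize("extra_left,extra_right", [
    (1820, None), (None, 2400), (1700, 2300)])
def test_trim_caps_scan_trim_rescan(extra_left, extra_right):
    """After trimming, the digested-allele template has exactly one site."""
    tmpl = _caps_template(seed=12, extra_left=extra_left,
                          extra_right=extra_right)
    realized_before = tmpl.realize_allele("T")
    assert len(scan_sites(realized_before, ECORI)) >= 2
    out = trim_caps_template(tmpl, ECORI, "T")
    assert len(scan_sites(out.realize_allele("T"), ECORI)) == 1
    # trimming removed the extra site entirely, target stayed intact
    assert out.target_end - out.target_start == \
        tmpl.target_end - tmpl.target_start
    assert out.start >= tmpl.start and out.end <= tmpl.end


def test_trim_caps_two_sites_inside_target_is_error():
    seq = list(_rand_seq(5000, seed=13))
    seq[2014:2020] = list("GAATTC")       # second site inside ±20 window
    seq[2024:2030] = list("GAATTC")
    ref = Reference({"c1": "".join(seq)})
    site = VariantSite("c1", 2027, "T", ("C",), {"a": (0, 0), "b": (1, 1)})
    tmpl = build_template(ref, extract_target(ref, site, _pair()))
    with pytest.raises(TrimError):
        trim_caps_template(tmpl, ECORI, "T")
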