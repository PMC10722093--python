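"""Shared fixtures: generated inputs and cached pipeline runs."""

from __future__ import annotations

import pytest

from markerforge.design_loop import DesignParams
from markerforge.fixtures import make_fixture
from markerforge.pipeline import PipelineConfig, run_pipeline

MODES = (("indel", "indel_ok"), ("caps", "caps_ok"), ("snp", "snp_ok"))


@pytest.fixture(scope="session")
def mixed_fixture(tmp_path_factory):
    """The 30-locus planted fixture (200 kb genome, depth track), seed 1."""
    return make_fixture("mixed", tmp_path_factory.mktemp("mixed"), seed=1)


def pipeline_config(fx, mode: str) -> PipelineConfig:
    """A PipelineConfig reflecting the fixture's stated settings."""
    s = fx.settings
    kwargs = dict(
        ref_path=str(fx.ref_path), vcf_path=str(fx.vcf_path),
        depth_path=str(fx.depth_path) if fx.depth_path else None,
        marker_type=mode,
        indel_min=s.get("indel_min", 3), indel_max=s.get("indel_max", 50),
        min_depth=s.get("min_depth", 0),
        design=DesignParams(product_min=s["product_min"],
                            product_max=s["product_max"]),
    )
    if s.get("enzymes"):
        kwargs["enzymes"] = s["enzymes"]
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def mixed_results(mixed_fixture):
    """Pipeline results for all three marker modes on the mixed fixture."""
    return {mode: run_pipeline(pipeline_config(mixed_fixture, mode))
            for mode, _ in MODES}
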