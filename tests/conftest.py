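"""Shared fixtures: phantoms are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from vesselwalk import synthetic


@pytest.fixture(scope="session")
def suite_specs():
    return synthetic.default_test_suite_specs()


@pytest.fixture(scope="session")
def bundles(suite_specs):
    """The five canonical phantom bundles, keyed 'a'..'e'."""
    return {k: synthetic.generate_phantom(s)
            for k, s in zip("abcde", suite_specs)}


@pytest.fixture(scope="session")
def pipeline_results(bundles):
    """Full pipeline runs on every canonical phantom (computed once)."""
    from vesselwalk import PipelineConfig
    from vesselwalk.pipeline import segment_image

    cfg = PipelineConfig()
    return {k: segment_image(b.rgb, cfg) for k, b in bundles.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
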