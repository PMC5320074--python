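"""Shared fixtures: phantoms and one cached baseline segmentation run.

The level-set evolution costs a few seconds per frame, so the expensive runs
(baseline pullback, full-combined pullback) are computed once per session and
shared between the tests that assert different properties of the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from octlumen import phantom, pipeline


@pytest.fixture(scope="session")
def baseline_run():
    """10-frame clean phantom, segmented with default parameters."""
    spec = phantom.baseline(seed=0, n_frames=10)
    frames, truth = phantom.generate_pullback(spec)
    results = pipeline.segment_pullback(frames, pipeline.PipelineConfig())
    return spec, frames, truth, results


@pytest.fixture(scope="session")
def small_frame():
    """A single small polar frame with a bright wall band (fast DRLS runs)."""
    spec = phantom.PhantomSpec(n_frames=1, n_radii=160, n_angles=72,
                               r0=90.0, seed=11)
    frames, truth = phantom.generate_pullback(spec)
    return frames[0], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
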