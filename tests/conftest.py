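"""Shared fixtures: phantom scenes analysed once per session."""

import numpy as np
import pytest

from spinemetry import benchmarks, phantom, spines, track4d
from spinemetry.config import AnalysisConfig


def start_of(spec):
    """Dendrite start point at the edge of the ROI, on the tube axis."""
    return (spec.field_of_view[0] / 2, spec.field_of_view[1] / 2, 0.3)


@pytest.fixture(scope="session")
def fixed_cfg():
    return AnalysisConfig.fixed()


@pytest.fixture(scope="session")
def live_cfg():
    return AnalysisConfig.live()


@pytest.fixture(scope="session")
def mixed_scene():
    spec = benchmarks.mixed_phantom_spec(noisy=False, seed=1)
    vol, truth = phantom.rasterize(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def mixed_analysis(mixed_scene):
    spec, vol, truth = mixed_scene
    trace, records = spines.analyze(vol, start_of(spec))
    return trace, records


@pytest.fixture(scope="session")
def noisy_scene():
    spec = benchmarks.mixed_phantom_spec(noisy=True, seed=1)
    vol, truth = phantom.rasterize(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_analysis(noisy_scene):
    spec, vol, truth = noisy_scene
    trace, records = spines.analyze(vol, start_of(spec))
    return trace, records


@pytest.fixture(scope="session")
def remodeling_result():
    spec, script = benchmarks.remodeling_script(seed=3)
    vols, truth = phantom.rasterize_series(spec, script)
    traces, per_time, tracks = track4d.track_series(
        vols, start_of(spec), AnalysisConfig.live())
    return spec, script, vols, truth, traces, per_time, tracks
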