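"""Dendrite segmentation and centerline extraction on analytic tubes."""

import numpy as np
import pytest

from spinemetry import phantom, trace as trace_mod
from spinemetry.config import AnalysisConfig
from spinemetry.phantom import PhantomSpec, SpineSpec
from spinemetry.trace import SegmentationError, segment, extract_centerline


CFG = AnalysisConfig()


def _trace_of(spec, start=None):
    vol, _ = phantom.rasterize(spec)
    if start is None:
        start = (spec.field_of_view[0] / 2, spec.field_of_view[1] / 2, 0.3)
    mask = segment(vol, start, CFG)
    return extract_centerline(mask, start, vol.voxel_size, CFG,
                              intensity=vol.data)


def test_straight_tube_length_and_radius():
    """40 um straight tube: length within 2%, mean radius within 1 voxel."""
    spec = PhantomSpec(field_of_view=(3.0, 3.0, 40.0), spines=[])
    tr = _trace_of(spec)
    assert tr.length == pytest.approx(40.0, rel=0.02)
    assert abs(tr.radii.mean() - 0.6) <= 0.1075


def test_sine_tube_matches_analytic_arclength():
    spec = PhantomSpec(
        field_of_view=(3.0, 6.0, 30.0),
        dendrite={"kind": "sine", "amplitude": 1.0, "period": 12.0},
        spines=[],
    )
    path = spec.build_path()
    tr = _trace_of(spec, start=(1.5, path.points[0][1], 0.3))
    assert tr.length == pytest.approx(path.length, rel=0.02)


def test_spine_branch_excluded_from_dendrite_path():
    """A mushroom (head 0.6 um < 0.75 um) never joins the dendrite path."""
    spec = PhantomSpec(
        field_of_view=(3.6, 6.0, 20.0),
        spines=[SpineSpec(10.0, np.pi / 2, 1.5, 0.6, 0.2)],
    )
    tr = _trace_of(spec)
    # all dendrite-path points stay within a radius of the tube axis
    yc, zc = 3.0, 1.8
    d_axis = np.hypot(tr.points[:, 0] - zc, tr.points[:, 1] - yc)
    assert d_axis.max() < 0.6
    assert tr.length == pytest.approx(20.0, rel=0.03)


def test_constant_image_errors():
    from spinemetry.imgio import VolumeImage
    vol = VolumeImage(np.full((5, 5, 5), 3.0), (0.15, 0.1075, 0.1075))
    with pytest.raises(SegmentationError, match="constant"):
        segment(vol, (0.3, 0.3, 0.3), CFG)


def test_start_point_in_background_errors():
    spec = PhantomSpec(field_of_view=(3.0, 3.0, 12.0), spines=[])
    vol, _ = phantom.rasterize(spec)
    with pytest.raises(SegmentationError, match="background"):
        segment(vol, (0.2, 0.2, 0.2), CFG)


def test_connectivity_selects_object_at_start():
    """With two disjoint bright tubes, only the start point's is kept."""
    spec1 = PhantomSpec(field_of_view=(3.0, 6.0, 12.0), spines=[])
    vol, _ = phantom.rasterize(spec1)
    img = vol.data.copy()
    shifted = np.roll(img, 20, axis=1)       # a second tube 2.15 um away
    two = np.maximum(img, shifted)
    from spinemetry.imgio import VolumeImage
    vol2 = VolumeImage(two, vol.voxel_size)
    mask = segment(vol2, (1.5, 3.0, 0.3), CFG)
    labeled_y = np.argwhere(mask)[:, 1] * vol.voxel_size[1]
    assert labeled_y.max() < 4.5             # second tube (y ~ 5.2) excluded


def test_length_invariant_under_subvoxel_translation():
    base = PhantomSpec(field_of_view=(3.0, 3.0, 30.0), spines=[])
    lengths = []
    for dy in (0.0, 0.04, 0.07):
        spec = PhantomSpec(
            field_of_view=(3.0, 3.0, 30.0),
            dendrite={"kind": "polyline",
                      "points": [[1.5, 1.5 + dy, 0.0], [1.5, 1.5 + dy, 30.0]]},
            spines=[],
        )
        lengths.append(_trace_of(spec).length)
    assert max(lengths) / min(lengths) - 1 < 0.02


def test_dilating_tube_never_shortens_trace():
    lengths = []
    for r in (0.5, 0.6, 0.7):
        spec = PhantomSpec(field_of_view=(3.2, 3.2, 25.0), spines=[],
                           dendrite_radius=r)
        lengths.append(_trace_of(spec).length)
    iso = 0.1075
    assert lengths[1] >= lengths[0] - iso
    assert lengths[2] >= lengths[1] - iso


def test_short_roi_warns():
    spec = PhantomSpec(field_of_view=(3.0, 3.0, 4.0), spines=[])
    with pytest.warns(UserWarning, match="um long"):
        _trace_of(spec)
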