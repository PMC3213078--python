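"""Phantom generator: rendering accuracy, determinism, event bookkeeping."""

import numpy as np
import pytest

from spinemetry import classify, phantom
from spinemetry.config import AnalysisConfig
from spinemetry.phantom import (
    PhantomSpec, RemodelScript, SpineEvent, SpineSpec, Sphere,
    rasterize, rasterize_series, rasterize_solids,
)

VOX = (0.1075, 0.1075, 0.1075)


def test_sphere_occupancy_matches_analytic_volume():
    """Partial-volume rendering: voxel sum within 5% of (4/3) pi r^3."""
    r = 0.3
    occ = rasterize_solids([Sphere((1.0, 1.0, 1.0), r)], (19, 19, 19), VOX)
    rendered = occ.sum() * np.prod(VOX)
    analytic = 4.0 / 3.0 * np.pi * r ** 3
    assert rendered == pytest.approx(analytic, rel=0.05)


def _tiny_spec(**kw):
    defaults = dict(
        field_of_view=(3.0, 4.0, 8.0),
        spines=[SpineSpec(4.0, np.pi / 2, 1.2, 0.5, 0.2)],
        seed=7,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


def test_zero_spines_gives_empty_truth_and_tube_only():
    vol, truth = rasterize(_tiny_spec(spines=[]))
    assert len(truth) == 0
    assert vol.data.max() > vol.data.min()          # the tube is there


def test_same_seed_is_bit_identical():
    spec = _tiny_spec(noise=("gaussian", 50.0))
    v1, t1 = rasterize(spec)
    v2, t2 = rasterize(spec)
    assert np.array_equal(v1.data, v2.data)
    assert t1.equals(t2)
    v3, _ = rasterize(_tiny_spec(noise=("gaussian", 50.0), seed=8))
    assert not np.array_equal(v1.data, v3.data)


def test_spine_outside_fov_is_rejected_with_id():
    spec = _tiny_spec(spines=[SpineSpec(4.0, np.pi / 2, 3.0, 0.5, 0.2)])
    with pytest.raises(ValueError, match="spine 0"):
        rasterize(spec)


def test_blur_and_noise_do_not_change_truth():
    base, t0 = rasterize(_tiny_spec())
    _, t1 = rasterize(_tiny_spec(psf_sigma=(0.1, 0.1, 0.1),
                                 noise=("poisson", 0.1)))
    cols = [c for c in t0.columns]
    assert t0[cols].equals(t1[cols])


def test_extreme_anisotropy_warns():
    spec = _tiny_spec(voxel_size=(0.6, 0.1, 0.1))
    with pytest.warns(UserWarning, match="anisotropy"):
        spec.validate()


def test_generated_classes_match_classifier():
    """Generator-classifier consistency on every truth row."""
    from spinemetry import benchmarks
    spec = benchmarks.mixed_phantom_spec(seed=0)
    _, truth = rasterize(spec)
    live = AnalysisConfig.live()
    for _, row in truth.iterrows():
        assert row["class"] == classify(
            row.length_um, row.head_width_um, row.neck_width_um, live)


def test_declared_class_must_match_geometry():
    with pytest.raises(ValueError, match="classifies as"):
        SpineSpec(4.0, 0.0, 3.0, 0.3, 0.25, shape_class="mushroom").validate()


# ---------------------------------------------------------------------------
# 4D series
# ---------------------------------------------------------------------------

def test_series_prune_bookkeeping():
    spec = _tiny_spec()
    script = RemodelScript(n_time=13, jitter_amplitude=0.0,
                           events={0: [SpineEvent("prune", 6)]})
    vols, truth = rasterize_series(spec, script)
    assert len(vols) == 13
    present = truth[truth.spine_id == 0].sort_values("time")["present"]
    assert present.tolist() == [True] * 6 + [False] * 7


def test_series_no_events_no_jitter_is_static():
    spec = _tiny_spec(noise=None)
    script = RemodelScript(n_time=4, jitter_amplitude=0.0)
    vols, _ = rasterize_series(spec, script)
    for v in vols[1:]:
        assert np.array_equal(vols[0].data, v.data)


def test_series_morph_changes_truth_class():
    spec = _tiny_spec(field_of_view=(3.0, 10.0, 8.0),
                      spines=[SpineSpec(4.0, np.pi / 2, 3.0, 0.25, 0.2)])
    geom = {"length": 2.0, "head_diameter": 0.6, "neck_diameter": 0.2}
    script = RemodelScript(n_time=13, jitter_amplitude=0.0,
                           events={0: [SpineEvent("morph", 6, geom)]})
    _, truth = rasterize_series(spec, script)
    cls = truth.sort_values("time")["class"].tolist()
    assert cls[:6] == ["thin"] * 6
    assert cls[6:] == ["mushroom"] * 7


def test_series_invalid_morph_names_spine_and_time():
    spec = _tiny_spec()
    geom = {"length": 0.1, "head_diameter": 0.6, "neck_diameter": 0.2}
    script = RemodelScript(n_time=5, events={0: [SpineEvent("morph", 2, geom)]})
    with pytest.raises(ValueError, match="spine 0 at t=2"):
        rasterize_series(spec, script)


def test_script_validation_rejects_bad_events():
    spec = _tiny_spec()
    with pytest.raises(ValueError, match="outside series"):
        RemodelScript(n_time=5, events={0: [SpineEvent("prune", 9)]}).validate(spec)
    with pytest.raises(ValueError, match="appear must precede"):
        RemodelScript(
            n_time=5,
            events={0: [SpineEvent("appear", 3), SpineEvent("prune", 2)]},
        ).validate(spec)
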