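"""Tracking, fates, transition and fate-group analytics."""

import itertools

import numpy as np
import pytest

from spinemetry import benchmarks, track4d
from spinemetry.spines import SpineRecord
from spinemetry.track4d import (
    SpineTrack, fate_group_geometry, fates, link, transitions,
)


def _rec(s, az=0.0, cls="thin", head=0.3, neck=0.25, length=2.0, t=0):
    return SpineRecord(
        id=0, attachment_point=np.array([1.0, 1.0, s]),
        attachment_arclength=s, azimuth=az, tip_point=np.zeros(3),
        path_points=np.zeros((2, 3)), path_diameters=np.zeros(2),
        path_arclength=np.zeros(2), surface_offset=0.5, tip_diameter=0.3,
        length=length, head_width=head, neck_width=neck, head_volume=0.01,
        spine_class=cls, time_index=t,
    )


def _track(frames, classes, track_id=0):
    recs = {t: _rec(1.0, cls=c, t=t) for t, c in zip(frames, classes)}
    return SpineTrack(track_id=track_id, records=recs)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def test_link_matches_brute_force_assignment():
    """Gated assignment minimizes total cost (checked by enumeration)."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(2, 6))
        s0 = np.sort(rng.uniform(0, 10, n))
        s1 = s0 + rng.uniform(-0.3, 0.3, n)
        f0 = [_rec(s) for s in s0]
        f1 = [_rec(s, t=1) for s in rng.permutation(s1)]
        tracks = link([f0, f1], gate=1.0, azimuth_weight=0.5)
        full = [tr for tr in tracks if len(tr.records) == 2]
        got = sum(
            abs(tr.records[0].attachment_arclength
                - tr.records[1].attachment_arclength)
            for tr in full
        )
        best = min(
            sum(abs(a.attachment_arclength - f1[p].attachment_arclength)
                for a, p in zip(f0, perm))
            for perm in itertools.permutations(range(n))
        )
        assert len(full) == n
        assert got == pytest.approx(best, abs=1e-9)


def test_link_respects_gate():
    f0 = [_rec(1.0)]
    f1 = [_rec(3.0, t=1)]          # 2 um shift > 1 um gate
    tracks = link([f0, f1], gate=1.0)
    assert len(tracks) == 2
    assert all(len(tr.records) == 1 for tr in tracks)


def test_link_crossing_spines_resolved_by_total_cost():
    """Two spines 0.4 um apart with crossing jitter keep their identities."""
    f0 = [_rec(5.0), _rec(5.4)]
    f1 = [_rec(5.45, t=1), _rec(5.08, t=1)]   # nearly swapped positions
    tracks = link([f0, f1], gate=1.0)
    pairs = {
        tr.records[0].attachment_arclength: tr.records[1].attachment_arclength
        for tr in tracks if len(tr.records) == 2
    }
    assert pairs == {5.0: 5.08, 5.4: 5.45}


def test_link_warns_on_trace_drift():
    class _T:
        def __init__(self, L):
            self.length = L
    f = [[_rec(1.0)], [_rec(1.0, t=1)]]
    with pytest.warns(UserWarning, match="drift"):
        link(f, traces_per_time=[_T(40.0), _T(25.0)])


# ---------------------------------------------------------------------------
# fates
# ---------------------------------------------------------------------------

def test_fate_labels_and_accounting():
    tracks = [
        _track(range(13), ["thin"] * 13, 0),           # stable
        _track(range(6), ["thin"] * 6, 1),             # pruned
        _track(range(3, 9), ["thin"] * 6, 2),          # transient
        _track(range(8, 13), ["mushroom"] * 5, 3),     # new
    ]
    fates(tracks, 13)
    assert [tr.fate for tr in tracks] == ["stable", "pruned", "transient",
                                          "new"]


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def test_scripted_transition_fractions():
    """10 thin at t0: 4 to mushroom, 3 pruned, 3 unchanged."""
    tracks = []
    for i in range(4):
        tracks.append(_track(range(13), ["thin"] * 6 + ["mushroom"] * 7, i))
    for i in range(4, 7):
        tracks.append(_track(range(6), ["thin"] * 6, i))
    for i in range(7, 10):
        tracks.append(_track(range(13), ["thin"] * 13, i))
    fates(tracks, 13)
    summ = transitions(tracks)
    row = summ.by_class.loc["thin"]
    assert row["to_mushroom"] == pytest.approx(0.4)
    assert row["pruned"] == pytest.approx(0.3)
    assert row["to_thin"] == pytest.approx(0.3)
    assert summ.by_class.loc["thin", track4d.OUTCOMES].sum() \
        == pytest.approx(1.0, abs=1e-9)
    assert summ.incidence[track4d.OUTCOMES].to_numpy().sum() \
        == pytest.approx(1.0, abs=1e-9)


def test_all_stable_is_diagonal():
    tracks = [_track(range(5), ["mushroom"] * 5, i) for i in range(6)]
    fates(tracks, 5)
    summ = transitions(tracks)
    assert summ.by_class.loc["mushroom", "to_mushroom"] == 1.0
    assert summ.by_class.loc["mushroom", "pruned"] == 0.0


def test_absent_class_row_is_undefined_not_zero():
    tracks = [_track(range(5), ["thin"] * 5)]
    fates(tracks, 5)
    summ = transitions(tracks)
    assert np.isnan(summ.by_class.loc["stubby", "to_stubby"])
    assert summ.by_class.loc["stubby", "n"] == 0


def test_new_spines_excluded_from_transitions():
    tracks = [
        _track(range(5), ["thin"] * 5, 0),
        _track(range(2, 5), ["mushroom"] * 3, 1),   # newly formed
    ]
    fates(tracks, 5)
    assert transitions(tracks).n_t0 == 1


# ---------------------------------------------------------------------------
# fate-group geometry
# ---------------------------------------------------------------------------

def test_fate_group_means_equal_sample_means():
    rng = np.random.default_rng(5)
    tracks = []
    necks = {"stable": [], "pruned": []}
    for i in range(8):
        group = "stable" if i < 5 else "pruned"
        nw = float(rng.uniform(0.15, 0.35))
        necks[group].append(nw)
        frames = range(5) if group == "stable" else range(3)
        recs = {t: _rec(1.0, cls="mushroom", head=0.6, neck=nw, t=t)
                for t in frames}
        tracks.append(SpineTrack(track_id=i, records=recs))
    fates(tracks, 5)
    g = fate_group_geometry(tracks, "mushroom")
    for name in ("stable", "pruned"):
        assert g.loc[name, "neck_width_um"] == pytest.approx(
            np.mean(necks[name]))
        assert g.loc[name, "n"] == len(necks[name])
    assert "remodeled" not in g.index      # empty group omitted


def test_identical_geometries_give_equal_means_and_exact_ratio():
    tracks = [
        _track(range(3), ["mushroom"] * 3, 0),
        _track(range(2), ["mushroom"] * 2, 1),
    ]
    for tr in tracks:
        for rec in tr.records.values():
            rec.head_width, rec.neck_width = 0.6, 0.2
            rec.spine_class = "mushroom"
    fates(tracks, 3)
    g = fate_group_geometry(tracks, "mushroom")
    assert g["head_neck_ratio"].tolist() == pytest.approx([3.0, 3.0])


# ---------------------------------------------------------------------------
# end-to-end on the scripted phantom series
# ---------------------------------------------------------------------------

def test_phantom_series_identity_and_transitions(remodeling_result):
    """13-frame series, 0.1 um jitter: identities and the scripted
    transition matrix are recovered exactly."""
    spec, script, vols, truth, traces, per_time, tracks = remodeling_result
    assert benchmarks.identity_agreement(tracks, per_time, truth) == 1.0
    summ = transitions(tracks)
    row = summ.by_class.loc["thin"]
    assert row["to_mushroom"] == pytest.approx(0.4)
    assert row["pruned"] == pytest.approx(0.3)
    assert row["to_thin"] == pytest.approx(0.3)
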