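"""Statistics: KS, regression, summary stats, detection scoring."""

import numpy as np
import pandas as pd
import pytest

from spinemetry import validate
from spinemetry.spines import SpineRecord


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def ks_brute_force(a, b):
    """sup |ECDF_a - ECDF_b| evaluated at every pooled sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pts = np.concatenate([a, b])
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in pts
    )


def test_ks_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n, m = rng.integers(2, 40, 2)
        a = rng.normal(0, 1, n)
        b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), m)
        d, _ = validate.ks_two_sample(a, b)
        assert d == pytest.approx(ks_brute_force(a, b), abs=1e-12)


def test_ks_known_values():
    assert validate.ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0
    assert validate.ks_two_sample([1, 2, 3], [10, 11])[0] == 1.0
    d, _ = validate.ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
    assert d == pytest.approx(1 / 3)


def test_ks_empty_sample_errors():
    with pytest.raises(ValueError):
        validate.ks_two_sample([], [1.0])


# ---------------------------------------------------------------------------
# regression of paired counts
# ---------------------------------------------------------------------------

def test_regression_identity_and_scaling():
    x = np.arange(10, dtype=float)
    r = validate.regress_counts(x, x)
    assert r.slope == pytest.approx(1.0)
    assert r.pvalue < 1e-6
    assert validate.regress_counts(x, 2 * x).slope == pytest.approx(2.0)


def test_regression_matches_normal_equations():
    rng = np.random.default_rng(3)
    x = rng.uniform(10, 60, 28)
    y = 0.8 * x + rng.normal(0, 4, 28)
    r = validate.regress_counts(x, y)
    xc = x - x.mean()
    beta = float((xc * (y - y.mean())).sum() / (xc ** 2).sum())
    assert r.slope == pytest.approx(beta, abs=1e-10)
    assert r.intercept == pytest.approx(y.mean() - beta * x.mean(), abs=1e-10)


def test_regression_degenerate_inputs():
    with pytest.raises(ValueError):
        validate.regress_counts([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        validate.regress_counts([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def test_summary_constant_sample():
    s = validate.summary_stats([2.0, 2.0, 2.0])
    assert s.sd == 0.0 and s.cv == 0.0
    assert np.isnan(s.skewness)


def test_summary_symmetric_sample_zero_skew():
    assert validate.summary_stats([1.0, 2.0, 3.0]).skewness \
        == pytest.approx(0.0, abs=1e-12)


def test_summary_matches_direct_formulas():
    x = np.array([1.0, 1.0, 1.0, 5.0])
    s = validate.summary_stats(x)
    n = len(x)
    mean = x.mean()
    sd = np.sqrt(((x - mean) ** 2).sum() / (n - 1))
    m3 = ((x - mean) ** 3).mean()
    m2 = ((x - mean) ** 2).mean()
    g1 = m3 / m2 ** 1.5
    adj = np.sqrt(n * (n - 1)) / (n - 2) * g1     # adjusted Fisher-Pearson
    assert s.mean == pytest.approx(mean, abs=1e-12)
    assert s.sd == pytest.approx(sd, abs=1e-12)
    assert s.cv == pytest.approx(sd / mean, abs=1e-12)
    assert s.skewness == pytest.approx(adj, abs=1e-12)
    assert s.range == pytest.approx(4.0)


def test_summary_zero_mean_flags_cv():
    assert np.isnan(validate.summary_stats([-1.0, 1.0]).cv)


def test_agreement_bundles_both_sides():
    a = np.linspace(0, 1, 50)
    b = np.linspace(0.5, 1.5, 60)
    res = validate.agreement(a, b)
    assert res.stats_a.n == 50 and res.stats_b.n == 60
    assert 0 < res.ks_d <= 1


def test_ecdf_table_is_monotone():
    t = validate.ecdf_table([3.0, 1.0, 2.0])
    assert t["x"].is_monotonic_increasing
    assert t["ecdf"].iloc[-1] == 1.0


# ---------------------------------------------------------------------------
# detection scoring
# ---------------------------------------------------------------------------

def _rec(i, z=1.0, y=1.0, x=1.0):
    return SpineRecord(
        id=i, attachment_point=np.array([z, y, x]),
        attachment_arclength=x, azimuth=0.0, tip_point=np.zeros(3),
        path_points=np.zeros((2, 3)), path_diameters=np.zeros(2),
        path_arclength=np.zeros(2), surface_offset=0.5, tip_diameter=0.3,
        length=1.0, head_width=0.5, neck_width=0.2, head_volume=0.05,
        spine_class="mushroom",
    )


def _truth(xs):
    return pd.DataFrame({
        "spine_id": range(len(xs)), "time": 0, "present": True,
        "attach_z_um": 1.0, "attach_y_um": 1.0, "attach_x_um": xs,
        "length_um": 1.0, "head_width_um": 0.5, "neck_width_um": 0.2,
        "head_volume_um3": 0.05, "class": "mushroom",
    })


def test_perfect_detection():
    xs = [1.0, 3.0, 5.0]
    score = validate.score_detection([_rec(i, x=x) for i, x in enumerate(xs)],
                                     _truth(xs))
    assert score.precision == 1.0 and score.recall == 1.0


def test_one_missed_of_ten():
    xs = list(np.arange(1.0, 11.0))
    dets = [_rec(i, x=x) for i, x in enumerate(xs[:-1])]
    score = validate.score_detection(dets, _truth(xs))
    assert score.recall == pytest.approx(0.9)
    assert score.precision == 1.0


def test_jitter_vs_tolerance():
    xs = [1.0, 3.0, 5.0]
    dets = [_rec(i, x=x + 0.2) for i, x in enumerate(xs)]
    assert validate.score_detection(dets, _truth(xs), tol=0.5).tp == 3
    assert validate.score_detection(dets, _truth(xs), tol=0.1).tp == 0


def test_swapping_sides_swaps_precision_recall():
    xs = list(np.arange(1.0, 6.0))
    dets = [_rec(i, x=x) for i, x in enumerate(xs[:-1])]
    s = validate.score_detection(dets, _truth(xs))
    assert (s.precision, s.recall) == (1.0, 0.8)


def test_nonpositive_tolerance_errors():
    with pytest.raises(ValueError):
        validate.score_detection([], _truth([1.0]), tol=0.0)
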