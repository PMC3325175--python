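"""Assessment metrics: R-squared fits, tuning-peak tracking, scaling
regression, Kaiser dimensionality, effort normalization."""

import numpy as np
import pytest

from quadbalance.assessment import (
    TuningCurve,
    effort_report,
    force_fit,
    pca_dimensionality,
    r_squared,
    scaling_regression,
    tuning_peak_metrics,
    wrap_angle_deg,
)

DIRS = np.arange(12) * 30.0


def test_r_squared_definition():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert r_squared(obs, obs) == 1.0
    assert r_squared(obs, np.full(4, obs.mean())) == 0.0
    assert np.isnan(r_squared(np.full(4, 2.0), obs))  # zero variance


def test_r_squared_hand_example():
    """12-point spreadsheet oracle: SSres and SStot computed by hand."""
    obs = np.array([3, 5, 4, 6, 7, 5, 4, 3, 2, 4, 5, 6], dtype=float)
    pred = obs + np.array([1, -1, 0, 1, -1, 0, 1, -1, 0, 1, -1, 0], dtype=float)
    ss_res = 8.0  # eight unit residuals
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    assert np.isclose(r_squared(obs, pred), 1.0 - ss_res / ss_tot)


def test_circular_r_squared_wraps_residuals():
    """A 350 vs 10 degree disagreement is a 20 degree residual, not 340."""
    obs = np.array([350.0, 10.0, 30.0, 50.0])
    pred = np.array([10.0, 10.0, 30.0, 50.0])
    r_wrapped = r_squared(obs, pred, circular=True)
    resid = wrap_angle_deg(pred - obs)
    assert np.allclose(np.abs(resid), [20.0, 0.0, 0.0, 0.0])
    assert r_wrapped > 0  # raw residual of 340 deg would force r << 0


def test_noise_decreases_expected_r_squared():
    rng = np.random.default_rng(0)
    obs = np.sin(np.deg2rad(DIRS)) + 2.0
    r_clean = r_squared(obs, obs)
    r_noisy = np.mean([
        r_squared(obs, obs + rng.normal(0, 0.3, obs.size)) for _ in range(200)
    ])
    assert r_clean == 1.0
    assert r_noisy < 0.95


def test_force_fit_perfect_prediction():
    rng = np.random.default_rng(1)
    forces = rng.normal(size=(12, 4, 3))
    forces[..., 2] = np.abs(forces[..., 2])
    report = force_fit(forces, forces)
    for v in report.as_dict().values():
        assert np.isclose(v, 1.0)


def _cosine_curve(peak, amp=1.0):
    return TuningCurve(muscle="VM", directions_deg=DIRS,
                       values=amp * np.clip(np.cos(np.deg2rad(DIRS - peak)), 0, None))


def test_peak_shift_zero_for_identical_curves():
    metrics = tuning_peak_metrics([_cosine_curve(30.0)] * 3)
    assert metrics.max_shift_deg == 0.0
    assert np.allclose(metrics.peak_values, 1.0)


def test_peak_shift_detects_rotation():
    curves = [_cosine_curve(30.0), _cosine_curve(30.0), _cosine_curve(60.0)]
    metrics = tuning_peak_metrics(curves)
    assert np.isclose(metrics.max_shift_deg, 30.0)


def test_peak_tracking_follows_dominant_lobe():
    """When the global max switches lobes in another stance, the tracked
    peak stays in the preferred-configuration lobe."""
    lobe_a = np.clip(np.cos(np.deg2rad(DIRS - 0.0)), 0, None)
    lobe_b = np.clip(np.cos(np.deg2rad(DIRS - 180.0)), 0, None)
    pref = TuningCurve("LG", DIRS, 1.0 * lobe_a + 0.4 * lobe_b)
    other = TuningCurve("LG", DIRS, 0.5 * lobe_a + 0.9 * lobe_b)  # global max flips
    metrics = tuning_peak_metrics([pref, other])
    assert np.isclose(metrics.peak_directions_deg[1], 0.0)  # tracked, not 180
    # rectified lobes do not overlap: tracked value is the 0-deg lobe alone
    assert np.isclose(metrics.peak_values[1], 0.5)


def test_peak_shift_rotation_equivariance():
    base = [_cosine_curve(30.0), _cosine_curve(50.0), _cosine_curve(40.0)]
    rotated = [_cosine_curve(30.0 + 60.0), _cosine_curve(50.0 + 60.0),
               _cosine_curve(40.0 + 60.0)]
    m1 = tuning_peak_metrics(base)
    m2 = tuning_peak_metrics(rotated)
    assert np.isclose(m1.max_shift_deg, m2.max_shift_deg)


def test_all_zero_curve_excluded():
    zero = TuningCurve("TA", DIRS, np.zeros(12))
    metrics = tuning_peak_metrics([zero, zero])
    assert metrics.excluded


def test_scaling_regression_oracle():
    assert np.isclose(scaling_regression(np.array([1.0, 1.1, 1.2, 1.3])), 0.1)
    assert scaling_regression(np.array([2.0, 2.0, 2.0])) == 0.0
    # increasing activation at shorter stance (higher code) => positive slope
    assert scaling_regression(np.array([0.5, 0.7, 0.9, 1.4])) > 0
    with pytest.raises(ValueError):
        scaling_regression(np.array([1.0, 2.0]))


def test_kaiser_dimensionality_rank_one():
    base = np.clip(np.cos(np.deg2rad(DIRS - 45.0)), 0, None) + 0.1
    X = np.outer(base, np.linspace(0.5, 2.0, 8))  # identical up to scaling
    assert pca_dimensionality(X) == 1


def test_kaiser_dimensionality_rank_two_fixture():
    """Noiseless mixtures of two orthogonal basis curves across 10
    muscles have exactly two correlation eigenvalues >= 1."""
    b1 = np.cos(np.deg2rad(DIRS))
    b2 = np.sin(np.deg2rad(DIRS))
    # mixture angles spread evenly over a quadrant: the 10x10 correlation
    # matrix is cos(phi_j - phi_k), whose two nonzero eigenvalues are the
    # eigenvalues of [[sum cos^2, sum cos sin], [sum cos sin, sum sin^2]]
    # ~ (8.2, 1.8), both at or above 1
    phi = np.deg2rad(np.linspace(0.0, 90.0, 10))
    X = np.column_stack([np.cos(p) * b1 + np.sin(p) * b2 for p in phi])
    assert pca_dimensionality(X) == 2


def test_kaiser_dimensionality_scale_invariance():
    rng = np.random.default_rng(9)
    X = rng.uniform(0, 1, size=(12, 6))
    scales = rng.uniform(0.1, 10.0, 6)
    assert pca_dimensionality(X) == pca_dimensionality(X * scales)


def test_kaiser_dimensionality_degenerate_columns():
    X = np.zeros((12, 5))
    X[:, 0] = np.arange(12)
    assert pca_dimensionality(X) == 1  # <2 usable columns


def test_effort_report_normalization():
    rep = effort_report({"MMe_preferred": 2.0, "SMe_preferred": 4.4,
                         "SMc_preferred": 5.0})
    assert rep.percentages["MMe_preferred"] == 100.0
    assert np.isclose(rep.percentages["SMe_preferred"], 220.0)
    with pytest.raises(ValueError):
        effort_report({"SMe_preferred": 4.4})
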