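"""Endpoint, baseline, hump and aggregation conventions."""
import numpy as np
import pytest
from scipy import stats

from t1aniso import (
    AngularProfile,
    aggregate,
    baseline,
    endpoints,
    hump,
    percent_of_mean,
    quantify,
    round_half_up,
)
from t1aniso.phantom import GroundTruthAngularModel, _sin_weighted_bin_means


def make_profile(means, bin_width=9.0, n_per_bin=100, label="t1"):
    means = np.asarray(means, dtype=float)
    nbins = means.size
    centers = (np.arange(nbins) + 0.5) * bin_width
    return AngularProfile(
        bin_width=bin_width,
        bin_centers=centers,
        mean=means,
        sd=np.zeros(nbins),
        n=np.full(nbins, n_per_bin, dtype=int),
        quantity_label=label,
    )


def linear_means(slope, intercept, bin_width=9.0):
    centers = (np.arange(round(90 / bin_width)) + 0.5) * bin_width
    return slope * centers + intercept


# --------------------------------------------------------------------- endpoints

def test_endpoints_exact_on_lines():
    p = make_profile(linear_means(0.3, 500.0))
    v0, v90 = endpoints(p, extrapolate=True, extrapolate_high=True)
    assert v0 == pytest.approx(500.0, abs=1e-12)
    assert v90 == pytest.approx(500.0 + 27.0, abs=1e-12)


def test_endpoints_flat_profile():
    p = make_profile(np.full(10, 610.0))
    v0, v90 = endpoints(p)
    assert v0 == v90 == pytest.approx(610.0)


def test_endpoints_hand_extrapolation():
    """Means 560 at 4.5 deg and 562 at 13.5 deg extrapolate to 559 at 0 deg."""
    means = np.full(10, 565.0)
    means[0], means[1] = 560.0, 562.0
    p = make_profile(means)
    v0, v90 = endpoints(p, extrapolate=True, extrapolate_high=False)
    assert v0 == pytest.approx(559.0)
    assert v90 == pytest.approx(565.0)  # last-bin mean, no high-end extrapolation


def test_endpoints_unpopulated_anchor_is_named():
    means = linear_means(0.1, 550.0)
    p = make_profile(means)
    p.n[1] = 0
    with pytest.raises(ValueError, match="13.5"):
        endpoints(p, extrapolate=True)


# --------------------------------------------------------------------- baseline

def test_baseline_flat_and_linear():
    flat = make_profile(np.full(10, 620.0))
    b = baseline(flat)
    assert b.slope == pytest.approx(0.0, abs=1e-12)
    assert b.intercept == pytest.approx(620.0)
    lin = make_profile(linear_means(0.25, 480.0))
    b2 = baseline(lin)
    resid = lin.mean - b2.value(lin.bin_centers)
    np.testing.assert_allclose(resid, 0.0, atol=1e-10)


def test_baseline_hand_anchors():
    """Bins 4.5:560, 13.5:562 (anchor (9, 561)) and 85.5:590 give the
    two-anchor line through (9, 561) and (85.5, 590)."""
    means = np.full(10, 575.0)
    means[0], means[1], means[-1] = 560.0, 562.0, 590.0
    p = make_profile(means)
    p.n[np.arange(2, 9)] = 0  # only the anchor bins are populated
    b = baseline(p)
    assert b.anchor_low == (pytest.approx(9.0), pytest.approx(561.0))
    assert b.anchor_high == (pytest.approx(85.5), pytest.approx(590.0))
    slope = (590.0 - 561.0) / (85.5 - 9.0)
    assert b.slope == pytest.approx(slope)
    assert b.value(9.0) == pytest.approx(561.0)


def test_baseline_empty_window_raises():
    p = make_profile(linear_means(0.1, 500.0))
    p.n[-2:] = 0
    with pytest.raises(ValueError, match="80"):
        baseline(p)


# ------------------------------------------------------------------------- hump

def test_hump_gaussian_residual_recovery():
    """A pure Gaussian residual sampled on 9-degree bins recovers its
    amplitude within 2 percent and FWHM within 2 degrees (dense-grid oracle:
    the same Gaussian evaluated continuously)."""
    A, F = 23.5, 34.2
    centers = (np.arange(10) + 0.5) * 9.0
    resid = A * np.exp(-4 * np.log(2) * (centers - 40.0) ** 2 / F**2)
    p = make_profile(resid)
    flat = baseline(make_profile(np.zeros(10)))
    h = hump(p, flat)
    assert h.amplitude == pytest.approx(A, rel=0.02)
    assert h.fwhm == pytest.approx(F, abs=2.0)
    assert h.peak_angle == pytest.approx(40.5)


def test_hump_flat_residual_zero_amplitude():
    p = make_profile(np.full(10, 700.0))
    h = hump(p, baseline(p))
    assert h.amplitude == 0.0
    assert not h.fwhm_bounded and np.isnan(h.fwhm)


def test_hump_triangle_fwhm():
    """A symmetric triangle peaking 10 at 45 deg, reaching 0 at 27/63 deg,
    has FWHM 18 deg (bin centers on the apex with 6-degree bins)."""
    centers = (np.arange(15) + 0.5) * 6.0
    resid = np.clip(10.0 * (1.0 - np.abs(centers - 45.0) / 18.0), 0.0, None)
    p = make_profile(resid, bin_width=6.0)
    flat = baseline(make_profile(np.zeros(15), bin_width=6.0))
    h = hump(p, flat)
    assert h.amplitude == pytest.approx(10.0)
    assert h.peak_angle == pytest.approx(45.0)
    assert h.fwhm == pytest.approx(18.0, abs=1e-9)


def test_hump_dip_sense():
    centers = (np.arange(10) + 0.5) * 9.0
    dip = 1.5 - 0.04 * np.exp(-4 * np.log(2) * (centers - 40.0) ** 2 / 30.0**2)
    p = make_profile(dip, label="r1")
    h = hump(p, baseline(p), sense="dip")
    assert h.amplitude > 0.03
    assert h.peak_angle == pytest.approx(40.5)


def test_hump_unbounded_crossing_flagged():
    """A residual still above half max at the profile edge has no bracketed
    crossing: FWHM is flagged unbounded."""
    centers = (np.arange(10) + 0.5) * 9.0
    resid = 10.0 + 5.0 * np.exp(-4 * np.log(2) * (centers - 40.0) ** 2 / 30.0**2)
    p = make_profile(resid)
    flat = baseline(make_profile(np.zeros(10)))
    h = hump(p, flat)
    assert not h.fwhm_bounded and np.isnan(h.fwhm)


# --------------------------------------------------------------------- quantify

def test_quantify_sign_conventions_and_percent():
    t1_means = linear_means(0.3, 550.0)
    r1_means = 1000.0 / t1_means
    f = quantify(
        make_profile(t1_means, label="t1"),
        make_profile(r1_means, label="r1"),
        mean_t1=float(t1_means.mean()),
        mean_r1=float(r1_means.mean()),
    )
    assert f["t1"].delta_0_90 > 0          # T1 rises towards 90 degrees
    assert f["r1"].delta_0_90 > 0          # R1 falls towards 90 degrees: 0 - 90 > 0
    assert f["t1"].pct_delta == pytest.approx(
        100 * abs(f["t1"].delta_0_90) / f["t1"].mean_value
    )
    assert f["t1"].hump_amplitude == pytest.approx(0.0, abs=1e-9)
    assert f["t1"].pct_hump == pytest.approx(0.0, abs=1e-9)


def test_quantify_recovers_constructed_features():
    """Pipeline-convention recovery on a noiseless constructed profile: the
    binned measurement agrees with the dense-grid oracle (amplitude within
    2 percent, FWHM within 2 degrees, delta near-exactly)."""
    model = GroundTruthAngularModel.calibrated(27.0, 23.5, 34.0, 564.1)
    centers, t1_means = _sin_weighted_bin_means(model.t1_of_theta)
    _, r1_means = _sin_weighted_bin_means(lambda th: 1000.0 / model.t1_of_theta(th))
    f = quantify(
        make_profile(t1_means, label="t1"),
        make_profile(r1_means, label="r1"),
        mean_t1=model.sphere_mean_t1(),
        mean_r1=float(r1_means.mean()),
    )
    assert f["t1"].delta_0_90 == pytest.approx(27.0, rel=5e-3)
    assert f["t1"].hump_amplitude == pytest.approx(23.5, rel=0.02)
    assert f["t1"].fwhm == pytest.approx(34.0, abs=2.0)


def test_r1_dip_matches_reciprocal_propagation():
    """First-order propagation: amp_R1 ~ amp_T1 / T1^2 * 1e6 within 15 percent
    for humps below 5 percent of the mean."""
    model = GroundTruthAngularModel.calibrated(27.0, 23.5, 34.0, 564.1)
    _, t1_means = _sin_weighted_bin_means(model.t1_of_theta)
    _, r1_means = _sin_weighted_bin_means(lambda th: 1000.0 / model.t1_of_theta(th))
    f = quantify(
        make_profile(t1_means, label="t1"),
        make_profile(r1_means, label="r1"),
        mean_t1=model.sphere_mean_t1(),
        mean_r1=float(r1_means.mean()),
    )
    # dR1 = 1000/T1^2 * dT1 with T1 in ms and R1 in 1/s
    predicted = f["t1"].hump_amplitude * 1000.0 / model.sphere_mean_t1() ** 2
    assert f["r1"].hump_amplitude == pytest.approx(predicted, rel=0.15)


def test_rounding_half_up():
    assert round_half_up(4.85) == 4.9
    assert round_half_up(4.25) == 4.3   # half goes up, not to even
    assert round_half_up(1.84) == 1.8


# -------------------------------------------------------------------- aggregate

def fs(delta, label="t1"):
    from t1aniso import AngularFeatureSet

    return AngularFeatureSet(
        quantity_label=label, delta_0_90=delta, hump_amplitude=delta / 2,
        peak_angle=40.5, fwhm=34.0, mean_value=560.0,
        pct_delta=100 * abs(delta) / 560.0, pct_hump=100 * (delta / 2) / 560.0,
        baseline_anchor_low=(9.0, 550.0), baseline_anchor_high=(85.5, 580.0),
        endpoint_0=550.0, endpoint_90=550.0 + delta,
    )


def test_aggregate_identical_sets_zero_sd():
    out = aggregate([fs(27.0), fs(27.0), fs(27.0)])
    assert out.loc["delta_0_90", "mean"] == pytest.approx(27.0)
    assert out.loc["delta_0_90", "sd"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc["delta_0_90", "n"] == 3


def test_aggregate_two_values():
    out = aggregate([fs(1.0), fs(3.0)])
    assert out.loc["delta_0_90", "mean"] == pytest.approx(2.0)
    assert out.loc["delta_0_90", "sd"] == pytest.approx(np.sqrt(2.0))


def test_aggregate_two_groups_matches_textbook_t():
    a_vals, b_vals = [25.0, 27.0, 30.0, 26.0], [33.0, 36.0, 31.0, 35.0]
    out = aggregate([fs(v) for v in a_vals], [fs(v) for v in b_vals], paired=True)
    t_ref, p_ref = stats.ttest_ind(a_vals, b_vals, equal_var=False)
    assert out.loc["delta_0_90", "t_welch"] == pytest.approx(t_ref)
    assert out.loc["delta_0_90", "p_welch"] == pytest.approx(p_ref)
    t_pref, _ = stats.ttest_rel(a_vals, b_vals)
    assert out.loc["delta_0_90", "t_paired"] == pytest.approx(t_pref)


def test_aggregate_rejects_mixed_labels_and_unequal_paired():
    with pytest.raises(ValueError, match="mixed"):
        aggregate([fs(1.0, "t1"), fs(2.0, "r1")])
    with pytest.raises(ValueError, match="paired"):
        aggregate([fs(1.0), fs(2.0)], [fs(3.0)], paired=True)


def test_percent_of_mean_guards_zero():
    with pytest.raises(ValueError):
        percent_of_mean(1.0, 0.0)
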