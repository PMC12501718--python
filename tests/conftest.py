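"""Shared fixtures: phantom runs reused across test modules.

The end-to-end runs mirror the analysis chain on synthetic data: sample a
fiber field, simulate a magnitude TI series, fit T1/R1 with polarity
restoration, compute the angle map, bin profiles and quantify the angular
features.
"""
from __future__ import annotations

import numpy as np
import pytest

from t1aniso import (
    GroundTruthAngularModel,
    NoiseSpec,
    TwoPoolModel,
    compute_theta_map,
    fa_mask,
    fit_map,
    profile_1d,
    quantify,
    sample_fiber_field,
    simulate_ti_series,
)
from t1aniso.phantom import PRESET_PROTOCOLS


def run_pipeline(
    preset: str,
    delta: float,
    hump_amp: float,
    hump_fwhm: float,
    mean_t1: float,
    seed: int,
    shape=(48, 48, 48),
    sigma: float = 20.0,
):
    """Full simulate -> fit -> theta -> profile -> quantify chain."""
    ss = np.random.SeedSequence(seed)
    s_fiber, s_noise = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    fiber = sample_fiber_field(shape, fa_range_high=(0.5, 0.8), frac_high=1.0, seed=s_fiber)
    truth = GroundTruthAngularModel.calibrated(delta, hump_amp, hump_fwhm, mean_t1)
    protocol = PRESET_PROTOCOLS[preset]
    noise = NoiseSpec("rician", sigma, s_noise) if sigma > 0 else NoiseSpec()
    sim = simulate_ti_series(fiber, truth, protocol, amplitude=1000.0, noise=noise)
    res = fit_map(sim.series, "all_ti")
    theta = compute_theta_map(fiber, protocol.b0_direction)
    mask = fa_mask(fiber, 0.5, 0.8) & res.success_mask & theta.valid_mask
    p_t1 = profile_1d(res.t1_map, theta, mask, 9.0, "t1")
    p_r1 = profile_1d(res.r1_map, theta, mask, 9.0, "r1")
    mean_t1_fit = float(np.nanmean(res.t1_map[mask]))
    mean_r1_fit = float(np.nanmean(res.r1_map[mask]))
    feats = quantify(p_t1, p_r1, mean_t1_fit, mean_r1_fit)
    return {
        "fiber": fiber,
        "truth": truth,
        "sim": sim,
        "result": res,
        "theta": theta,
        "mask": mask,
        "profile_t1": p_t1,
        "profile_r1": p_r1,
        "features": feats,
        "injected": {"delta": delta, "hump": hump_amp, "fwhm": hump_fwhm, "mean_t1": mean_t1},
    }


@pytest.fixture(scope="session")
def e2e_15t():
    """48^3 phantom with the 1.5 T feature values, Rician SNR 50."""
    return run_pipeline("1.5T", 27.0, 23.5, 34.0, 564.1, seed=11)


@pytest.fixture(scope="session")
def e2e_7t():
    """48^3 phantom with the 7 T feature values, Rician SNR 50."""
    return run_pipeline("7T", 41.0, 16.5, 27.0, 911.3, seed=13)


@pytest.fixture(scope="session")
def twopool_15t():
    """Noiseless two-pool 1.5 T phantom (short T1 120 ms) fitted both ways.

    The short-pool fraction dips at 40 degrees, which lengthens the apparent
    T1 there and produces the 40-degree hump carried by pre-null TI signals.
    """
    shape = (24, 24, 24)
    fiber = sample_fiber_field(shape, fa_range_high=(0.5, 0.8), frac_high=1.0, seed=7)
    truth = TwoPoolModel(
        t1_short=120.0,
        t1_long=564.1,
        fraction_short_baseline=0.25,
        fraction_short_hump_amplitude=-0.15,
        hump_center=40.0,
        hump_fwhm=34.0,
    )
    protocol = PRESET_PROTOCOLS["1.5T"]
    sim = simulate_ti_series(fiber, truth, protocol, amplitude=1000.0)
    theta = compute_theta_map(fiber, protocol.b0_direction)
    res_all = fit_map(sim.series, "all_ti")
    res_long = fit_map(sim.series, "long_ti")
    mask = fa_mask(fiber, 0.5, 0.8) & theta.valid_mask
    return {
        "fiber": fiber,
        "truth": truth,
        "protocol": protocol,
        "sim": sim,
        "theta": theta,
        "mask": mask,
        "all_ti": res_all,
        "long_ti": res_long,
    }
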