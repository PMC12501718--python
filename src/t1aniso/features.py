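"""Quantification of the two angular relaxation features.

From a binned angular profile of T1 (or R1) the pipeline extracts:

* the 0-to-90-degree difference, via profile endpoints — by default the 0
  degree value is estimated by linear extrapolation through the first two bin
  centers (4.5 and 13.5 degrees for 9 degree bins) and the 90 degree value is
  the last-bin mean (extrapolation at the 90 end is switchable);
* the broad ~40 degree hump (T1) or dip (R1): a two-anchor baseline joins the
  mean of profile values over 0-20 degrees to the mean over 80-90 degrees,
  and the residual's maximum inside a search window gives the amplitude, peak
  angle and interpolated full width at half maximum.

Percent features are expressed relative to the mask-wide mean T1 (or R1), and
group summaries aggregate per-dataset feature sets with mean, SD and t tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import AngularProfile

__all__ = [
    "BaselineLine",
    "HumpResult",
    "AngularFeatureSet",
    "endpoints",
    "baseline",
    "hump",
    "quantify",
    "aggregate",
    "percent_of_mean",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching tabulated one-decimal reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_of_mean(feature: float, mean_value: float) -> float:
    """Feature magnitude as a percentage of the mask-wide mean value."""
    if mean_value == 0:
        raise ValueError("mean value must be non-zero")
    return 100.0 * abs(feature) / abs(mean_value)


@dataclass(frozen=True)
class BaselineLine:
    """Straight line through the low-angle and high-angle anchor points."""

    slope: float
    intercept: float
    anchor_low: tuple[float, float]
    anchor_high: tuple[float, float]

    def value(self, theta):
        return self.slope * np.asarray(theta, dtype=float) + self.intercept


@dataclass(frozen=True)
class HumpResult:
    amplitude: float
    peak_angle: float
    fwhm: float
    fwhm_bounded: bool


def _require_populated(profile: AngularProfile, indices, what: str) -> None:
    for i in indices:
        if profile.n[i] < 1:
            raise ValueError(
                f"{what}: bin at {profile.bin_centers[i]:g} degrees is unpopulated"
            )


def endpoints(
    profile: AngularProfile,
    extrapolate: bool = True,
    extrapolate_high: Optional[bool] = None,
) -> tuple[float, float]:
    """Profile values at 0 and 90 degrees.

    With extrapolation the endpoint is the straight line through the two
    nearest bin centers continued to the boundary; otherwise it is the
    boundary bin's mean.  ``extrapolate_high`` defaults to ``extrapolate``
    so a single flag extrapolates both ends; pass ``False`` to keep the
    last-bin mean at 90 degrees while extrapolating at 0.
    """
    if extrapolate_high is None:
        extrapolate_high = extrapolate
    m = profile.mean
    c = profile.bin_centers
    if extrapolate:
        _require_populated(profile, (0, 1), "0-degree extrapolation")
        slope = (m[1] - m[0]) / (c[1] - c[0])
        v0 = m[0] - slope * c[0]
    else:
        _require_populated(profile, (0,), "0-degree endpoint")
        v0 = m[0]
    if extrapolate_high:
        _require_populated(profile, (-2, -1), "90-degree extrapolation")
        slope = (m[-1] - m[-2]) / (c[-1] - c[-2])
        v90 = m[-1] + slope * (90.0 - c[-1])
    else:
        _require_populated(profile, (-1,), "90-degree endpoint")
        v90 = m[-1]
    return float(v0), float(v90)


def baseline(
    profile: AngularProfile,
    low_window: tuple[float, float] = (0.0, 20.0),
    high_window: tuple[float, float] = (80.0, 90.0),
) -> BaselineLine:
    """Two-anchor baseline of an angular profile.

    Each anchor sits at the mean center of the populated bins inside its
    window, at the unweighted mean of those bins' means; the baseline is the
    unique straight line through the two anchors.
    """
    c = profile.bin_centers
    anchors = []
    for lo, hi in (low_window, high_window):
        sel = (c >= lo) & (c <= hi) & profile.populated
        if not sel.any():
            raise ValueError(f"no populated bins in the [{lo:g}, {hi:g}] degree anchor window")
        anchors.append((float(c[sel].mean()), float(profile.mean[sel].mean())))
    (x0, y0), (x1, y1) = anchors
    slope = (y1 - y0) / (x1 - x0)
    return BaselineLine(
        slope=slope, intercept=y0 - slope * x0, anchor_low=anchors[0], anchor_high=anchors[1]
    )


def hump(
    profile: AngularProfile,
    base: BaselineLine,
    window: tuple[float, float] = (20.0, 70.0),
    sense: str = "peak",
) -> HumpResult:
    """Amplitude, peak angle and FWHM of the baseline-subtracted feature.

    ``sense="peak"`` measures an elevation (T1 hump), ``sense="dip"`` a
    depression (R1 dip); the residual is oriented so the feature is positive.
    The FWHM is found by linear interpolation between adjacent bin centers on
    each side of the peak; a crossing that is not bracketed inside [0, 90]
    leaves the FWHM NaN with ``fwhm_bounded=False``.
    """
    if sense not in ("peak", "dip"):
        raise ValueError("sense must be 'peak' or 'dip'")
    c = profile.bin_centers
    pop = profile.populated
    resid = profile.mean - base.value(c)
    if sense == "dip":
        resid = -resid
    win = (c >= window[0]) & (c <= window[1]) & pop
    if win.sum() < 3:
        raise ValueError("need at least 3 populated bins inside the hump window")
    w_idx = np.flatnonzero(win)
    peak_local = int(np.nanargmax(resid[w_idx]))
    ipk = int(w_idx[peak_local])
    amplitude = float(resid[ipk])
    if amplitude <= 0:
        return HumpResult(amplitude=0.0, peak_angle=float(c[ipk]), fwhm=float("nan"),
                          fwhm_bounded=False)
    half = amplitude / 2.0

    def crossing(direction: int) -> float:
        i = ipk
        while True:
            j = i + direction
            if j < 0 or j >= c.size or not pop[j]:
                return float("nan")
            if resid[j] < half:
                frac = (half - resid[i]) / (resid[j] - resid[i])
                return float(c[i] + frac * (c[j] - c[i]))
            i = j

    left = crossing(-1)
    right = crossing(+1)
    bounded = math.isfinite(left) and math.isfinite(right)
    return HumpResult(
        amplitude=amplitude,
        peak_angle=float(c[ipk]),
        fwhm=right - left if bounded else float("nan"),
        fwhm_bounded=bounded,
    )


@dataclass(frozen=True)
class AngularFeatureSet:
    """The two angular features of one T1 or R1 profile.

    ``delta_0_90`` is oriented so the physiological direction is positive:
    for T1 it is value(90) - value(0) (T1 grows towards perpendicular), for
    R1 it is value(0) - value(90).  Percent features are relative to the
    mask-wide mean of the quantity.
    """

    quantity_label: str
    delta_0_90: float
    hump_amplitude: float
    peak_angle: float
    fwhm: float
    mean_value: float
    pct_delta: float
    pct_hump: float
    baseline_anchor_low: tuple[float, float]
    baseline_anchor_high: tuple[float, float]
    endpoint_0: float
    endpoint_90: float
    fwhm_bounded: bool = True

    _NUMERIC = (
        "delta_0_90", "hump_amplitude", "peak_angle", "fwhm",
        "mean_value", "pct_delta", "pct_hump", "endpoint_0", "endpoint_90",
    )

    def to_row(self) -> dict:
        row = {"quantity": self.quantity_label}
        row.update({k: getattr(self, k) for k in self._NUMERIC})
        row["fwhm_bounded"] = self.fwhm_bounded
        return row


def _quantify_one(
    profile: AngularProfile,
    mean_value: float,
    sense: str,
    extrapolate: bool,
    extrapolate_high: Optional[bool],
    window: tuple[float, float],
) -> AngularFeatureSet:
    v0, v90 = endpoints(profile, extrapolate=extrapolate, extrapolate_high=extrapolate_high)
    delta = (v90 - v0) if sense == "peak" else (v0 - v90)
    base = baseline(profile)
    h = hump(profile, base, window=window, sense=sense)
    return AngularFeatureSet(
        quantity_label=profile.quantity_label,
        delta_0_90=float(delta),
        hump_amplitude=h.amplitude,
        peak_angle=h.peak_angle,
        fwhm=h.fwhm,
        mean_value=float(mean_value),
        pct_delta=percent_of_mean(delta, mean_value),
        pct_hump=percent_of_mean(h.amplitude, mean_value),
        baseline_anchor_low=base.anchor_low,
        baseline_anchor_high=base.anchor_high,
        endpoint_0=v0,
        endpoint_90=v90,
        fwhm_bounded=h.fwhm_bounded,
    )


def quantify(
    profile_t1: AngularProfile,
    profile_r1: AngularProfile,
    mean_t1: float,
    mean_r1: float,
    extrapolate: bool = True,
    extrapolate_high: Optional[bool] = False,
    window: tuple[float, float] = (20.0, 70.0),
) -> dict[str, AngularFeatureSet]:
    """Feature sets for paired T1 and R1 profiles from the same mask.

    T1 features use sense "peak" (hump), R1 features sense "dip"; both record
    their endpoints and baseline anchors for audit.  Returns
    ``{"t1": ..., "r1": ...}``.
    """
    return {
        "t1": _quantify_one(profile_t1, mean_t1, "peak", extrapolate, extrapolate_high, window),
        "r1": _quantify_one(profile_r1, mean_r1, "dip", extrapolate, extrapolate_high, window),
    }


def aggregate(
    feature_sets: Sequence[AngularFeatureSet],
    group_b: Optional[Sequence[AngularFeatureSet]] = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Across-subject summary of feature sets (mean, SD, n per field).

    With a second group, Welch's two-sample t statistic is added per field,
    plus the paired t statistic when ``paired=True`` (requires equal sizes).
    All sets must quantify the same quantity.
    """
    if len(feature_sets) == 0:
        raise ValueError("need at least one feature set")
    labels = {fs.quantity_label for fs in feature_sets} | (
        {fs.quantity_label for fs in group_b} if group_b else set()
    )
    if len(labels) > 1:
        raise ValueError(f"mixed quantity labels: {sorted(labels)}")

    def table(sets):
        return pd.DataFrame([{k: getattr(fs, k) for k in AngularFeatureSet._NUMERIC} for fs in sets])

    ta = table(feature_sets)
    out = pd.DataFrame(
        {"mean": ta.mean(), "sd": ta.std(ddof=1), "n": len(ta)}
    )
    if group_b is not None:
        tb = table(group_b)
        out["mean_b"] = tb.mean()
        out["sd_b"] = tb.std(ddof=1)
        out["n_b"] = len(tb)
        t_w, p_w = stats.ttest_ind(ta, tb, equal_var=False)
        out["t_welch"] = t_w
        out["p_welch"] = p_w
        if paired:
            if len(ta) != len(tb):
                raise ValueError("paired test requires equally sized groups")
            t_p, p_p = stats.ttest_rel(ta, tb)
            out["t_paired"] = t_p
            out["p_paired"] = p_p
    return out
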