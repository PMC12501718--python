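"""Angular binning of voxel quantities against the fiber-to-field angle.

Profiles are simple binned statistics: for each angle bin ``[k*w, (k+1)*w)``
(the last bin closed at 90 degrees) the mean, SD and count of a per-voxel
quantity over the masked, valid voxels.  The default bin width of 9 degrees
places bin centers at 4.5, 13.5, ..., 85.5 degrees, the anchor angles used by
the feature-quantification conventions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import TISeries
from .geometry import ThetaMap

__all__ = [
    "AngularProfile",
    "Angular2DGrid",
    "profile_1d",
    "profile_2d",
    "ti_signal_profiles",
    "profile_to_frame",
    "profile_from_frame",
    "plot_profile",
]


@dataclass
class AngularProfile:
    """Binned mean/SD/count of a quantity versus fiber-to-field angle."""

    bin_width: float
    bin_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    quantity_label: str = "t1"

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (self.bin_centers.shape == self.mean.shape == self.sd.shape == self.n.shape):
            raise ValueError("profile arrays must share one shape")

    @property
    def populated(self) -> np.ndarray:
        return self.n > 0


@dataclass
class Angular2DGrid:
    """Cell means of a quantity over (FA band) x (angle bin)."""

    bin_width: float
    theta_centers: np.ndarray
    fa_edges: np.ndarray
    mean: np.ndarray  # (n_fa_cells, n_theta_bins), NaN where empty
    n: np.ndarray
    quantity_label: str = "t1"

    @property
    def empty_cells(self) -> np.ndarray:
        return self.n == 0


def _check_bin_width(bin_width: float) -> int:
    nbins = round(90.0 / bin_width)
    if not np.isclose(nbins * bin_width, 90.0):
        raise ValueError("90 must be divisible by bin_width")
    return int(nbins)


def _bin_index(theta: np.ndarray, bin_width: float, nbins: int) -> np.ndarray:
    idx = np.floor(theta / bin_width).astype(int)
    return np.clip(idx, 0, nbins - 1)  # theta == 90 goes to the last bin


def profile_1d(
    values: np.ndarray,
    theta: ThetaMap,
    mask: Optional[np.ndarray] = None,
    bin_width: float = 9.0,
    quantity_label: str = "t1",
) -> AngularProfile:
    """1-D angular profile of a scalar volume.

    Voxels enter a bin when they are inside ``mask``, their angle is valid and
    their value is finite (NaNs from failed fits are dropped).  SD is the
    across-voxel sample SD (ddof=1), defined only where n >= 2.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != theta.theta.shape:
        raise ValueError("values and theta shapes differ")
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape differs from values")
    nbins = _check_bin_width(bin_width)
    sel = mask & theta.valid_mask & np.isfinite(values)
    if not sel.any():
        warnings.warn("empty mask: profile has no voxels", stacklevel=2)
    th = theta.theta[sel]
    v = values[sel]
    idx = _bin_index(th, bin_width, nbins)
    n = np.bincount(idx, minlength=nbins)
    s1 = np.bincount(idx, weights=v, minlength=nbins)
    s2 = np.bincount(idx, weights=v * v, minlength=nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - n * mean**2) / np.maximum(n - 1, 1), np.nan)
    sd = np.sqrt(np.maximum(var, 0.0), where=np.isfinite(var), out=np.full(nbins, np.nan))
    centers = (np.arange(nbins) + 0.5) * bin_width
    return AngularProfile(
        bin_width=bin_width, bin_centers=centers, mean=mean, sd=sd, n=n,
        quantity_label=quantity_label,
    )


def profile_2d(
    values: np.ndarray,
    theta: ThetaMap,
    fa: np.ndarray,
    fa_edges: Sequence[float],
    mask: Optional[np.ndarray] = None,
    bin_width: float = 9.0,
    quantity_label: str = "t1",
) -> Angular2DGrid:
    """2-D grid of cell means over FA bands and angle bins.

    FA cell membership is ``edges[i] < FA <= edges[i+1]`` (strict lower bound,
    consistent with the FA-cutoff masks).  Empty cells carry NaN means and are
    flagged via ``empty_cells``.
    """
    fa = np.asarray(fa, dtype=float)
    edges = np.asarray(fa_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("fa_edges must be ascending with at least two values")
    if edges[0] < 0 or edges[-1] > 1:
        raise ValueError("fa_edges must lie within [0, 1]")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    nbins = _check_bin_width(bin_width)
    n_cells = edges.size - 1
    means = np.full((n_cells, nbins), np.nan)
    counts = np.zeros((n_cells, nbins), dtype=int)
    for i in range(n_cells):
        cell_mask = np.asarray(mask, bool) & (fa > edges[i]) & (fa <= edges[i + 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = profile_1d(values, theta, cell_mask, bin_width, quantity_label)
        means[i] = p.mean
        counts[i] = p.n
    centers = (np.arange(nbins) + 0.5) * bin_width
    return Angular2DGrid(
        bin_width=bin_width, theta_centers=centers, fa_edges=edges,
        mean=means, n=counts, quantity_label=quantity_label,
    )


def ti_signal_profiles(
    series: TISeries,
    theta: ThetaMap,
    mask: Optional[np.ndarray] = None,
    bin_width: float = 9.0,
) -> list[AngularProfile]:
    """One angular profile of the magnitude signal per inversion time."""
    out = []
    for k, ti in enumerate(series.protocol.ti_list):
        out.append(
            profile_1d(
                series.data[..., k], theta, mask, bin_width,
                quantity_label=f"ti_signal:{ti:g}",
            )
        )
    return out


def profile_to_frame(profile: AngularProfile) -> pd.DataFrame:
    """Tabular view (bin_center, mean, sd, n) for TSV output."""
    return pd.DataFrame(
        {
            "bin_center": profile.bin_centers,
            "mean": profile.mean,
            "sd": profile.sd,
            "n": profile.n,
        }
    )


def profile_from_frame(df: pd.DataFrame, quantity_label: str = "t1") -> AngularProfile:
    centers = df["bin_center"].to_numpy(dtype=float)
    if centers.size < 2:
        raise ValueError("profile table needs at least two bins")
    width = float(centers[1] - centers[0])
    return AngularProfile(
        bin_width=width,
        bin_centers=centers,
        mean=df["mean"].to_numpy(dtype=float),
        sd=df["sd"].to_numpy(dtype=float),
        n=df["n"].to_numpy(dtype=int),
        quantity_label=quantity_label,
    )


def plot_profile(profile: AngularProfile, ax=None, **errorbar_kw):
    """Mean +/- SD versus angle on a matplotlib axis (created on demand)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    keep = profile.populated
    ax.errorbar(
        profile.bin_centers[keep], profile.mean[keep],
        yerr=np.where(np.isfinite(profile.sd[keep]), profile.sd[keep], 0.0),
        fmt="o-", capsize=2, **errorbar_kw,
    )
    ax.set_xlabel("fiber-to-field angle (deg)")
    ax.set_ylabel(profile.quantity_label)
    ax.set_xlim(0, 90)
    return ax
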