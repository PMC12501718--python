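"""Fiber-to-field angle maps, FA masks and volume downsampling.

The fiber-to-field angle theta is the angle between the local axon-fiber
direction (principal diffusion eigenvector V1) and the main magnetic field
B0.  V1 is sign-ambiguous, so the angle is folded into [0, 90] degrees by
taking the absolute value of the dot product.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FiberField

__all__ = ["ThetaMap", "compute_theta_map", "fa_mask", "downsample_volume"]

#: tolerance on |v1| for a voxel to count as carrying a valid unit vector
UNIT_NORM_TOL = 1e-3


@dataclass
class ThetaMap:
    """Fiber-to-field angle in degrees, folded to [0, 90], plus validity."""

    theta: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.theta.shape != self.valid_mask.shape:
            raise ValueError("theta and valid_mask shapes differ")


def compute_theta_map(fiber: FiberField, b0_direction=(0.0, 0.0, 1.0)) -> ThetaMap:
    """Angle between V1 and B0, folded to [0, 90] degrees.

    Voxels whose V1 norm is outside ``1 +/- UNIT_NORM_TOL`` (e.g. zero vectors
    outside the brain) are marked invalid and excluded from downstream
    profiles.
    """
    b0 = np.asarray(b0_direction, dtype=float)
    nrm = np.linalg.norm(b0)
    if nrm == 0:
        raise ValueError("b0_direction must be non-zero")
    if abs(nrm - 1.0) > 1e-9:
        raise ValueError("b0_direction must be a unit vector")
    v1 = fiber.v1
    vnorm = np.linalg.norm(v1, axis=-1)
    valid = np.abs(vnorm - 1.0) <= UNIT_NORM_TOL
    dot = np.abs(v1 @ b0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(valid, dot / np.where(vnorm > 0, vnorm, 1.0), 0.0)
    theta = np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))
    return ThetaMap(theta=theta, valid_mask=valid)


def fa_mask(fiber: FiberField, fa_low: float = 0.5, fa_high: float = 0.8) -> np.ndarray:
    """Boolean mask of voxels with ``fa_low < FA <= fa_high``.

    The lower bound is strict (an "FA > 0.5" cutoff excludes FA == 0.5);
    the upper bound is closed.
    """
    if not (0.0 <= fa_low < fa_high <= 1.0):
        raise ValueError("require 0 <= fa_low < fa_high <= 1")
    return (fiber.fa > fa_low) & (fiber.fa <= fa_high)


def downsample_volume(vol: np.ndarray, factor: int, voxel_size=None):
    """Non-overlapping block-mean downsampling by an integer factor.

    Trailing partial blocks are averaged over the voxels they do contain.
    When ``voxel_size`` is given, returns ``(volume, scaled_voxel_size)``;
    otherwise just the downsampled volume.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D scalar volume")
    if any(s < 1 for s in vol.shape):
        raise ValueError("degenerate volume")
    if factor == 1:
        out = vol.copy()
    else:
        pad = [(0, (-s) % factor) for s in vol.shape]
        padded = np.pad(vol, pad, mode="constant", constant_values=np.nan)
        nx, ny, nz = (s // factor for s in padded.shape)
        blocks = padded.reshape(nx, factor, ny, factor, nz, factor)
        with np.errstate(invalid="ignore"):
            out = np.nanmean(blocks, axis=(1, 3, 5))
    if voxel_size is not None:
        return out, tuple(float(v) * factor for v in voxel_size)
    return out
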