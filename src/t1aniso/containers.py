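"""Shared in-memory containers used across the pipeline.

All volumes are plain :class:`numpy.ndarray` objects on a common voxel grid;
the pipeline assumes every input (TI series, principal eigenvectors, FA) is
already co-registered, and refuses mismatched shapes rather than resampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionProtocol", "TISeries", "FiberField"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Inversion-recovery acquisition descriptor.

    Parameters
    ----------
    field_label:
        Nominal field strength label ("1.5T", "3T", "7T" or any custom tag).
    ti_list:
        Inversion times in ms, strictly increasing, at least four values.
    tr:
        Repetition time in ms (descriptive; the mono-exponential model
        assumes full recovery between inversions).
    read_flip:
        Nominal readout flip angle in degrees (descriptive).
    b0_direction:
        Unit vector of the main field B0 in voxel-grid coordinates.  The
        default is the grid's third axis (scanner z), matching acquisitions
        without angulation.
    """

    field_label: str
    ti_list: tuple[float, ...]
    tr: float = 5000.0
    read_flip: float = 4.0
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        tis = tuple(float(t) for t in self.ti_list)
        object.__setattr__(self, "ti_list", tis)
        if len(tis) < 4:
            raise ValueError("ti_list must contain at least 4 inversion times")
        if any(t <= 0 for t in tis):
            raise ValueError("all inversion times must be positive")
        if any(b >= a for a, b in zip(tis[1:], tis[:-1])):
            raise ValueError("ti_list must be strictly increasing")
        b0 = np.asarray(self.b0_direction, dtype=float)
        if b0.shape != (3,):
            raise ValueError("b0_direction must be a 3-vector")
        if abs(np.linalg.norm(b0) - 1.0) > 1e-9:
            raise ValueError("b0_direction must be a unit vector (|b0| = 1 within 1e-9)")
        object.__setattr__(self, "b0_direction", tuple(float(x) for x in b0))

    @property
    def n_ti(self) -> int:
        return len(self.ti_list)

    def to_dict(self) -> dict:
        return {
            "field_label": self.field_label,
            "ti_list": list(self.ti_list),
            "tr": self.tr,
            "read_flip": self.read_flip,
            "b0_direction": list(self.b0_direction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            field_label=d["field_label"],
            ti_list=tuple(d["ti_list"]),
            tr=float(d.get("tr", 5000.0)),
            read_flip=float(d.get("read_flip", 4.0)),
            b0_direction=tuple(d.get("b0_direction", (0.0, 0.0, 1.0))),
        )


@dataclass
class TISeries:
    """Stack of magnitude volumes, one per inversion time.

    ``data`` has shape ``(nx, ny, nz, n_ti)`` with the TI axis last, ordered
    like ``protocol.ti_list``.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("TISeries.data must be 4-D (x, y, z, ti)")
        if self.data.shape[-1] != self.protocol.n_ti:
            raise ValueError(
                f"series has {self.data.shape[-1]} volumes but protocol lists "
                f"{self.protocol.n_ti} inversion times"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_ti(self) -> int:
        return self.data.shape[-1]


@dataclass
class FiberField:
    """Per-voxel principal diffusion direction and fractional anisotropy.

    ``v1`` is a sign-ambiguous unit vector per voxel, shape ``(nx, ny, nz, 3)``;
    ``fa`` is the fractional anisotropy in [0, 1], shape ``(nx, ny, nz)``.
    Voxels outside the brain may carry zero vectors; they are flagged invalid
    by :func:`t1aniso.geometry.compute_theta_map`.
    """

    v1: np.ndarray
    fa: np.ndarray

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.v1.ndim != 4 or self.v1.shape[-1] != 3:
            raise ValueError("v1 must have shape (nx, ny, nz, 3)")
        if self.fa.shape != self.v1.shape[:-1]:
            raise ValueError("fa shape must match the spatial shape of v1")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fa.shape
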