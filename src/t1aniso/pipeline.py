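"""Configured, seeded end-to-end runs and all file I/O conventions.

Volumes are NIfTI-1 (3-D scalars, or 4-D with TIs / vector components on the
fourth axis) with world coordinates reduced to voxel size — all inputs are
assumed co-registered on one grid.  Tables are TSV with a header row; run
parameters travel in JSON sidecars.  A run writes a manifest with the paths
and SHA-256 hashes of every artifact, so a re-run from the same config and
seed can be verified bit for bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .containers import AcquisitionProtocol, FiberField, TISeries
from .features import quantify
from .geometry import compute_theta_map, fa_mask
from .phantom import (
    PRESET_PROTOCOLS,
    SHORT_T1_BY_FIELD,
    GroundTruthAngularModel,
    NoiseSpec,
    TwoPoolModel,
    sample_fiber_field,
    simulate_ti_series,
)
from .profiles import profile_1d, profile_to_frame, ti_signal_profiles
from .relaxometry import fit_map

__all__ = [
    "RunConfig",
    "StageError",
    "run_all",
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "load_fiber_field",
]

log = logging.getLogger("t1aniso")


class StageError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# NIfTI / table I/O

def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, path)
    return path


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), vox


def save_series(out_dir, series: TISeries, per_ti_files: bool = False,
                extra_sidecar: Optional[dict] = None) -> dict:
    """Write a TI series as one 4-D NIfTI (default) or one file per TI,
    plus a JSON sidecar with the acquisition protocol."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if per_ti_files:
        for k, ti in enumerate(series.protocol.ti_list):
            p = out_dir / f"ti_{int(round(ti)):05d}.nii.gz"
            save_volume(p, series.data[..., k], series.voxel_size)
            paths[f"ti_{k}"] = p
    else:
        p = out_dir / "ti_series.nii.gz"
        save_volume(p, series.data, series.voxel_size)
        paths["ti_series"] = p
    sidecar = {"protocol": series.protocol.to_dict()}
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    sp = out_dir / "ti_series.json"
    sp.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = sp
    return paths


def load_series(path, sidecar_path=None) -> TISeries:
    """Load a 4-D TI series NIfTI plus its JSON protocol sidecar."""
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.parent / "ti_series.json"
    sidecar = json.loads(Path(sidecar_path).read_text())
    protocol = AcquisitionProtocol.from_dict(sidecar["protocol"])
    data, vox = load_volume(path)
    if data.ndim != 4:
        raise ValueError("TI series NIfTI must be 4-D")
    return TISeries(data=data, protocol=protocol, voxel_size=vox)


def load_fiber_field(v1_path, fa_path) -> FiberField:
    """Load a 3-component V1 NIfTI and an FA NIfTI into a FiberField."""
    v1, _ = load_volume(v1_path)
    fa, _ = load_volume(fa_path)
    return FiberField(v1=v1, fa=fa)


def _write_tsv(path, df) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Fully serializable description of a simulate-and-analyze run.

    A run re-executed from its emitted config and seed is bit-identical:
    the master ``seed`` deterministically derives the per-stage child seeds.
    """

    preset: str = "1.5T"
    ti_list: Optional[list[float]] = None  # overrides the preset schedule
    shape: tuple[int, int, int] = (32, 32, 32)
    truth: dict = field(default_factory=lambda: {
        "kind": "single_pool",
        "mean_t1": 564.1,
        "delta_0_90": 27.0,
        "hump_amplitude": 23.5,
        "hump_center": 40.0,
        "hump_fwhm": 34.0,
        "calibrated": True,
    })
    amplitude: float = 1000.0
    inv_efficiency: float = 0.96
    noise_sigma: float = 20.0
    frac_high: float = 1.0
    fa_range: tuple[float, float] = (0.5, 0.8)
    fa_range_low: tuple[float, float] = (0.2, 0.5)
    bin_width: float = 9.0
    fit_modes: tuple[str, ...] = ("all_ti",)
    t1_bounds: tuple[float, float] = (100.0, 5000.0)
    feature_window: tuple[float, float] = (20.0, 70.0)
    extrapolate: bool = True
    extrapolate_high: bool = False
    per_ti_files: bool = False
    seed: int = 0
    out_dir: str = "t1aniso_run"

    def protocol(self) -> AcquisitionProtocol:
        if self.preset not in PRESET_PROTOCOLS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESET_PROTOCOLS)}")
        proto = PRESET_PROTOCOLS[self.preset]
        if self.ti_list:
            proto = AcquisitionProtocol(
                field_label=proto.field_label, ti_list=tuple(self.ti_list),
                tr=proto.tr, read_flip=proto.read_flip, b0_direction=proto.b0_direction,
            )
        return proto

    def truth_model(self):
        t = dict(self.truth)
        kind = t.pop("kind", "single_pool")
        if kind == "single_pool":
            calibrated = t.pop("calibrated", True)
            mean_t1 = t.pop("mean_t1", None)
            if calibrated:
                if mean_t1 is None:
                    raise ValueError("calibrated truth requires mean_t1")
                return GroundTruthAngularModel.calibrated(
                    delta_0_90=t["delta_0_90"],
                    hump_amplitude=t["hump_amplitude"],
                    hump_fwhm=t.get("hump_fwhm", 34.0),
                    mean_t1=mean_t1,
                    hump_center=t.get("hump_center", 40.0),
                    bin_width=self.bin_width,
                    window=self.feature_window,
                    extrapolate=self.extrapolate,
                    extrapolate_high=self.extrapolate_high,
                )
            if mean_t1 is not None and "t1_parallel" not in t:
                return GroundTruthAngularModel.for_mask_mean(
                    mean_t1, t["delta_0_90"], t["hump_amplitude"],
                    t.get("hump_center", 40.0), t.get("hump_fwhm", 34.0),
                )
            return GroundTruthAngularModel(**t)
        if kind == "two_pool":
            t.setdefault("t1_short", SHORT_T1_BY_FIELD.get(self.preset, 120.0))
            return TwoPoolModel(**t)
        raise ValueError(f"unknown truth kind {kind!r}")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if isinstance(v, list) and f.name in (
                    "shape", "fa_range", "fa_range_low", "fit_modes",
                    "t1_bounds", "feature_window",
                ):
                    v = tuple(v)
                kw[f.name] = v
        return cls(**kw)

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        fiber, noise = ss.spawn(2)
        return {
            "fiber": int(fiber.generate_state(1)[0] % (2**31)),
            "noise": int(noise.generate_state(1)[0] % (2**31)),
        }


# ---------------------------------------------------------------------------
# Orchestration

def run_all(config: RunConfig) -> dict:
    """Execute simulate -> fit -> theta -> profile -> quantify and write a manifest.

    Every stage failure is re-raised as a :class:`StageError` naming the
    stage.  Returns the manifest (also written to ``out_dir/manifest.json``)
    with artifact paths and SHA-256 hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    artifacts: dict[str, Path] = {}
    seeds = config.stage_seeds()
    try:
        # --- simulate ------------------------------------------------------
        try:
            log.info("stage simulate: grid %s preset %s", config.shape, config.preset)
            fiber = sample_fiber_field(
                config.shape, fa_range_high=config.fa_range,
                fa_range_low=config.fa_range_low, frac_high=config.frac_high,
                seed=seeds["fiber"],
            )
            noise = (
                NoiseSpec("rician", config.noise_sigma, seeds["noise"])
                if config.noise_sigma > 0 else NoiseSpec()
            )
            sim = simulate_ti_series(
                fiber, config.truth_model(), config.protocol(),
                amplitude=config.amplitude, inv_efficiency=config.inv_efficiency,
                noise=noise,
            )
            paths = save_series(
                out, sim.series, per_ti_files=config.per_ti_files,
                extra_sidecar={"seed": config.seed, "stage_seeds": seeds,
                               "truth": config.truth, "noise_sigma": config.noise_sigma},
            )
            artifacts.update(paths)
            artifacts["v1"] = save_volume(out / "v1.nii.gz", fiber.v1)
            artifacts["fa"] = save_volume(out / "fa.nii.gz", fiber.fa)
            artifacts["t1_true"] = save_volume(out / "t1_true.nii.gz", sim.t1_true)
        except StageError:
            raise
        except Exception as e:
            raise StageError("simulate", str(e)) from e

        # --- theta map -----------------------------------------------------
        try:
            theta = compute_theta_map(fiber, config.protocol().b0_direction)
            mask = fa_mask(fiber, *config.fa_range)
            artifacts["theta"] = save_volume(out / "theta.nii.gz", theta.theta)
            artifacts["fa_mask"] = save_volume(out / "fa_mask.nii.gz", mask.astype(np.float32))
        except Exception as e:
            raise StageError("theta", str(e)) from e

        # --- fit + profiles + features per mode ---------------------------
        feature_rows = []
        for mode in config.fit_modes:
            try:
                log.info("stage fit: mode %s", mode)
                res = fit_map(sim.series, mode=mode, mask=mask, t1_bounds=config.t1_bounds)
                tag = mode
                artifacts[f"t1_{tag}"] = save_volume(out / f"t1_{tag}.nii.gz", res.t1_map)
                artifacts[f"r1_{tag}"] = save_volume(out / f"r1_{tag}.nii.gz", res.r1_map)
                artifacts[f"sse_{tag}"] = save_volume(out / f"sse_{tag}.nii.gz", res.sse_map)
                artifacts[f"success_{tag}"] = save_volume(
                    out / f"success_{tag}.nii.gz", res.success_mask.astype(np.float32))
            except Exception as e:
                raise StageError("fit", f"mode {mode}: {e}") from e
            try:
                good = mask & res.success_mask
                p_t1 = profile_1d(res.t1_map, theta, good, config.bin_width, "t1")
                p_r1 = profile_1d(res.r1_map, theta, good, config.bin_width, "r1")
                artifacts[f"profile_t1_{tag}"] = _write_tsv(
                    out / f"profile_t1_{tag}.tsv", profile_to_frame(p_t1))
                artifacts[f"profile_r1_{tag}"] = _write_tsv(
                    out / f"profile_r1_{tag}.tsv", profile_to_frame(p_r1))
                import pandas as pd

                sig_profiles = ti_signal_profiles(sim.series, theta, good, config.bin_width)
                sig = pd.concat(
                    [profile_to_frame(p).assign(quantity=p.quantity_label) for p in sig_profiles],
                    ignore_index=True,
                )
                artifacts[f"profiles_ti_{tag}"] = _write_tsv(out / f"profiles_ti_{tag}.tsv", sig)
            except Exception as e:
                raise StageError("profile", f"mode {mode}: {e}") from e
            try:
                mean_t1 = float(np.nanmean(res.t1_map[good]))
                mean_r1 = float(np.nanmean(res.r1_map[good]))
                feats = quantify(
                    p_t1, p_r1, mean_t1, mean_r1,
                    extrapolate=config.extrapolate,
                    extrapolate_high=config.extrapolate_high,
                    window=config.feature_window,
                )
                for q in ("t1", "r1"):
                    row = feats[q].to_row()
                    row["fit_mode"] = mode
                    feature_rows.append(row)
            except Exception as e:
                raise StageError("features", f"mode {mode}: {e}") from e

        import pandas as pd

        artifacts["features"] = _write_tsv(out / "features.tsv", pd.DataFrame(feature_rows))
        artifacts["config"] = config.to_yaml(out / "config.yaml")

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "artifacts": {k: str(p) for k, p in artifacts.items()},
            "hashes": {k: _sha256(p) for k, p in artifacts.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    finally:
        log.removeHandler(fh)
        fh.close()
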