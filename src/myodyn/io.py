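"""Readers and writers for the on-disk formats used by the pipeline.

Volumes travel as NIfTI-1 (via nibabel), metadata as JSON sidecars,
tables as CSV, configuration as YAML.  Velocity inputs are accepted either
already decoded to cm/s or as raw phase images in [-pi, pi], in which case
they are decoded as v = phase / pi * venc (venc being the velocity that
maps to a phase of pi).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VelocitySeries",
    "RoiMask",
    "DEFAULT_LABEL_MAP",
    "read_velocity_series",
    "write_velocity_series",
    "read_roi_mask",
    "write_mask",
    "write_map",
    "read_map",
    "run_log",
]

logger = logging.getLogger("myodyn")

DEFAULT_LABEL_MAP: dict[int, str] = {
    1: "soleus",
    2: "medial_gastrocnemius",
    3: "lateral_gastrocnemius",
    4: "subcutaneous_fat",
}


@dataclass
class VelocitySeries:
    """Three-directional voxel velocity over one stimulation cycle.

    data : (3, T, X, Y, Z) array in cm/s, component order x, y, z (world).
    venc : cm/s, the velocity-encoding limit (phase of pi).
    frame_interval : ms between frames.
    """

    data: np.ndarray
    venc: float
    frame_interval: float
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray = field(
        default_factory=lambda: np.eye(4, dtype=float)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[0] != 3:
            raise ValueError("velocity data must be (3, T, X, Y, Z)")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval)


@dataclass
class RoiMask:
    """Integer label volume aligned to a reference image."""

    label_volume: np.ndarray
    label_map: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )
    affine: np.ndarray = field(
        default_factory=lambda: np.eye(4, dtype=float)
    )

    def labels_present(self) -> dict[int, int]:
        vals, counts = np.unique(self.label_volume, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v != 0}


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine, dtype=float), spacing


def read_velocity_series(
    paths: Sequence[str | Path],
    sidecar: str | Path,
    dialect: Literal["auto", "cm_s", "phase"] = "auto",
) -> VelocitySeries:
    """Assemble a VelocitySeries from three 4-D component volumes.

    ``paths`` name the x, y, z component volumes (each X, Y, Z, T);
    ``sidecar`` is a JSON file holding at least ``venc_cm_s`` and
    ``frame_interval_ms``.  Phase-valued inputs (range within [-pi, pi])
    are auto-detected and decoded to cm/s; pass ``dialect`` to override.
    """
    if len(paths) != 3:
        raise ValueError("exactly three component volumes expected")
    meta = json.loads(Path(sidecar).read_text())
    if "venc_cm_s" not in meta:
        raise ValueError("sidecar is missing venc_cm_s")
    if "frame_interval_ms" not in meta:
        raise ValueError("sidecar is missing frame_interval_ms")
    venc = float(meta["venc_cm_s"])
    dt = float(meta["frame_interval_ms"])

    vols, affines, spacings = [], [], []
    for p in paths:
        d, a, s = _load_nifti(p)
        if d.ndim != 4:
            raise ValueError(f"{p}: expected a 4-D volume, got {d.ndim}-D")
        vols.append(d)
        affines.append(a)
        spacings.append(s)
    ref = vols[0].shape
    for ax in range(4):
        if any(v.shape[ax] != ref[ax] for v in vols):
            name = ("x", "y", "z", "frame")[ax]
            raise ValueError(f"component volumes disagree on the {name} axis")
    if any(not np.allclose(a, affines[0], atol=1e-5) for a in affines[1:]):
        raise ValueError("component volumes disagree on the affine")

    data = np.stack([np.moveaxis(v, 3, 0) for v in vols])  # (3, T, X, Y, Z)
    if dialect == "auto":
        amax = np.nanmax(np.abs(data))
        dialect = "phase" if amax <= np.pi + 1e-6 and venc > np.pi else "cm_s"
        logger.info("velocity dialect auto-detected as %s (max |v|=%.3g)",
                    dialect, amax)
    if dialect == "phase":
        data = data / np.pi * venc
    return VelocitySeries(
        data=data, venc=venc, frame_interval=dt,
        voxel_spacing=spacings[0], affine=affines[0],
    )


def write_velocity_series(v: VelocitySeries, out_dir: str | Path,
                          stem: str = "vel") -> list[Path]:
    """Write one 4-D NIfTI per component plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for i, comp in enumerate("xyz"):
        vol = np.moveaxis(v.data[i], 0, 3)  # (X, Y, Z, T)
        img = nib.Nifti1Image(vol.astype(np.float32), v.affine)
        img.header.set_zooms(v.voxel_spacing + (v.frame_interval,))
        p = out / f"{stem}_{comp}.nii.gz"
        nib.save(img, str(p))
        paths.append(p)
    sidecar = out / f"{stem}.json"
    sidecar.write_text(json.dumps({
        "venc_cm_s": v.venc,
        "frame_interval_ms": v.frame_interval,
        "n_frames": v.n_frames,
    }, indent=2))
    paths.append(sidecar)
    return paths


def read_roi_mask(
    path: str | Path,
    reference_shape: Sequence[int] | None = None,
    reference_affine: np.ndarray | None = None,
    label_map: Mapping[int, str] | None = None,
) -> RoiMask:
    """Read and validate an integer ROI mask.

    Unknown labels are dropped with a warning; a geometry mismatch with
    the reference image is an error.
    """
    data, affine, _ = _load_nifti(path)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: mask is not integer-valued")
    data = np.round(data).astype(np.int32)
    if reference_shape is not None and tuple(data.shape) != tuple(
            reference_shape):
        raise ValueError(
            f"mask shape {data.shape} does not match reference "
            f"{tuple(reference_shape)}"
        )
    if reference_affine is not None and not np.allclose(
            affine, reference_affine, atol=1e-4):
        raise ValueError("mask affine does not match the reference image")
    lm = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)
    known = set(lm) | {0}
    present = set(np.unique(data).tolist())
    unknown = sorted(present - known)
    if unknown:
        logger.warning("dropping unknown mask labels %s", unknown)
        data = np.where(np.isin(data, list(unknown)), 0, data)
    mask = RoiMask(label_volume=data, label_map=lm, affine=affine)
    logger.info("mask labels present: %s", mask.labels_present())
    return mask


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    img = nib.Nifti1Image(mask.label_volume.astype(np.int16), mask.affine)
    nib.save(img, str(path))
    return Path(path)


def write_map(
    volume: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    missing: float | None = None,
) -> Path:
    """Write a float32 map as NIfTI, affine preserved.

    Non-finite values are only allowed when ``missing`` declares the
    sentinel to store in their place (NaN itself is a valid sentinel).
    """
    volume = np.asarray(volume, dtype=np.float32)
    bad = ~np.isfinite(volume)
    if bad.any():
        if missing is None:
            raise ValueError(
                "map contains non-finite values and no missing-value "
                "sentinel was given"
            )
        volume = np.where(bad, np.float32(missing), volume)
    img = nib.Nifti1Image(volume, np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return Path(path)


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return (np.asarray(img.dataobj, dtype=np.float32),
            np.asarray(img.affine, dtype=float))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_log(inputs: Sequence[str | Path] = (), config: Mapping | None = None,
            seed: int | None = None) -> dict:
    """Provenance record for a CLI run: input hashes, config, seed, versions."""
    import scipy
    import pandas

    record = {
        "inputs": {str(p): _sha256(Path(p)) for p in inputs
                   if Path(p).is_file()},
        "config": dict(config) if config else {},
        "seed": seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "nibabel": nib.__version__,
        },
    }
    logger.info("run: %s", json.dumps(record, sort_keys=True))
    return record
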