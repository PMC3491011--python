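"""NIfTI readers and writers, run configuration, and provenance manifests."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import LabelVolume, ScalarVolume
from .imgreg import DisplacementField

logger = logging.getLogger(__name__)

__all__ = ["read_volume", "write_volume", "read_field", "write_field",
           "RunConfig", "write_manifest"]


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, k])) for k in range(3))


def read_volume(path) -> ScalarVolume:
    """Read a 3D NIfTI scalar (or integer label) volume."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise OSError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    return ScalarVolume(np.asarray(data, dtype=float),
                        _voxel_size_from_affine(affine), affine)


def write_volume(volume: ScalarVolume, path) -> None:
    """Write a ScalarVolume as NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    """Read a displacement field stored as a 4D NIfTI (last axis = vector
    component, values in mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # tolerate (X,Y,Z,1,3) layouts
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected an (X, Y, Z, 3) displacement field")
    return DisplacementField(np.asarray(data, dtype=float),
                             _voxel_size_from_affine(np.asarray(img.affine)))


def write_field(fld: DisplacementField, path) -> None:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = fld.voxel_size
    img = nib.Nifti1Image(np.asarray(fld.vectors, dtype=np.float64), aff)
    nib.save(img, str(path))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Statistical defaults follow the reference protocol: FA threshold 0.2,
    5000 permutations, alpha 0.05, TFCE E=0.5 / H=2.
    """

    strategy: str = "GW"
    fa_threshold: float = 0.2
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    n_permutations: int = 5000
    alpha: float = 0.05
    max_search_mm: float = 8.0
    seed: int = 0
    # phantom-cohort parameters (used when no input images are supplied)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_tracts: int = 3
    n_per_group: int = 10
    warp_amplitude: float = 4.0
    warp_smoothness: float = 8.0
    noise_sd: float = 0.02
    atrophy_severity: float = 7.0
    out_dir: str = "gwtbss-out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        for key in ("grid_shape", "voxel_size_mm"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def write_manifest(path, config: RunConfig | dict, **entries) -> None:
    """Persist a machine-readable record of parameters, seeds and outputs."""
    import gwtbss
    payload = {
        "gwtbss_version": getattr(gwtbss, "__version__", "unknown"),
        "config": config.to_dict() if isinstance(config, RunConfig) else dict(config),
    }
    payload.update(entries)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
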