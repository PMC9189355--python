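"""Volume/label data model, NIfTI persistence and run configuration.

Axis convention used throughout the package: arrays are indexed ``(z, y, x)``
with ``z`` the slice axis; ``spacing`` and ``origin`` follow the same order.
NIfTI stores data ``(x, y, z)``, so arrays are transposed on read/write.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

log = logging.getLogger("cbctkit")

#: HU value assigned to everything outside the patient.
AIR_HU = -1000.0

#: Canonical organ-name → label-integer table for the pelvic anatomy.
DEFAULT_ORGAN_TABLE: dict[str, int] = {
    "body": 1,
    "bladder": 2,
    "spinal_cord": 3,
    "femoral_head_l": 4,
    "femoral_head_r": 5,
    "bone_marrow": 6,
}


@dataclasses.dataclass
class ImageVolume:
    """A 3D intensity grid in Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels
        3D float array indexed ``(z, y, x)``.
    spacing
        Voxel size ``(sz, sy, sx)`` in mm; all components positive.
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm, order ``(oz, oy, ox)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all dimensions must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def like(self, voxels: np.ndarray) -> "ImageVolume":
        """New volume with the same geometry but different voxel data."""
        return ImageVolume(voxels, self.spacing, self.origin)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.voxels.copy(), self.spacing, self.origin)


@dataclasses.dataclass
class LabelMap:
    """Integer organ labels on the grid of a reference :class:`ImageVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_table: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ORGAN_TABLE)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        self.organ_table = dict(self.organ_table)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def copy(self) -> "LabelMap":
        return LabelMap(self.labels.copy(), self.spacing, self.origin, dict(self.organ_table))


def extract_mask(lm: LabelMap, organ: str) -> np.ndarray:
    """Boolean mask, true exactly where ``lm`` carries the organ's label."""
    if organ not in lm.organ_table:
        raise KeyError(f"organ {organ!r} not in organ table {sorted(lm.organ_table)}")
    return lm.labels == lm.organ_table[organ]


def _affine(spacing, origin) -> np.ndarray:
    # NIfTI affine maps (i,j,k)=(x,y,z) voxel indices to mm; our order is (z,y,x).
    sz, sy, sx = spacing
    oz, oy, ox = origin
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI file into an :class:`ImageVolume` ((z,y,x) order)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]  # (sx, sy, sz)
    trans = img.affine[:3, 3]
    return ImageVolume(
        np.ascontiguousarray(data.T, dtype=np.float32),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=(float(trans[2]), float(trans[1]), float(trans[0])),
    )


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1 (float32)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    img = nib.Nifti1Image(vol.voxels.T.astype(np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))


def read_labels(path: str | Path, organ_table: Mapping[str, int] | None = None) -> LabelMap:
    """Read an integer label volume; ``organ_table`` defaults to the pelvic table."""
    vol = read_volume(path)
    return LabelMap(
        np.rint(vol.voxels).astype(np.int16),
        vol.spacing,
        vol.origin,
        organ_table or dict(DEFAULT_ORGAN_TABLE),
    )


def write_labels(lm: LabelMap, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    img = nib.Nifti1Image(lm.labels.T.astype(np.int16), _affine(lm.spacing, lm.origin))
    img.header.set_zooms((lm.spacing[2], lm.spacing[1], lm.spacing[0]))
    nib.save(img, str(path))


def read_field(path: str | Path) -> np.ndarray:
    """Read a displacement field stored as 4D NIfTI, returning (nz,ny,nx,3)."""
    img = nib.load(str(Path(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"expected a 4D field with 3 components, got shape {data.shape}")
    return np.ascontiguousarray(data.transpose(2, 1, 0, 3), dtype=np.float32)


def write_field(field: np.ndarray, spacing, path: str | Path) -> None:
    """Write a (nz,ny,nx,3) displacement field as 4D NIfTI."""
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[3] != 3:
        raise ValueError(f"expected (nz,ny,nx,3), got {field.shape}")
    img = nib.Nifti1Image(field.transpose(2, 1, 0, 3), _affine(spacing, (0, 0, 0)))
    nib.save(img, str(Path(path)))


_PRESETS = ("desk", "paper")


@dataclasses.dataclass
class RunConfig:
    """Top-level run configuration shared by the CLI entry points."""

    seed: int = 0
    scale_preset: str = "desk"
    out_dir: str = "."
    sections: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.scale_preset not in _PRESETS:
            raise ValueError(f"scale_preset must be one of {_PRESETS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in ("seed", "scale_preset", "out_dir") if k in raw}
        return cls(sections=raw, **known)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "scale_preset": self.scale_preset,
            "out_dir": self.out_dir,
            **self.sections,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
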