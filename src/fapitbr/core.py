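"""Core in-memory containers for volumes and masks.

Volumes carry a 4x4 voxel-to-world affine (mm) and an explicit value kind
so that activity concentrations are never silently treated as SUVs.
Voxel indices are 0-based; world coordinates are millimetres via the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALUE_KINDS = ("Bq/mL", "SUV", "CT")
MASK_LABELS = ("myocardium", "blood_pool", "efm")


class GridMismatchError(ValueError):
    """Two objects do not live on the same voxel grid."""


class GeometryError(ValueError):
    """Inconsistent spatial configuration (e.g. lesion outside the shell)."""


class ConfigError(ValueError):
    """Invalid configuration values."""


class CalibrationError(ValueError):
    """Missing or invalid SUV calibration data."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm mapping (NIfTI convention).
    kind : str
        One of ``"Bq/mL"`` (activity concentration), ``"SUV"`` or ``"CT"``.
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str = "SUV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine)
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.kind!r}; expected one of {VALUE_KINDS}")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])) / 1000.0)

    def same_grid(self, other: "ImageVolume | RoiMask", tol: float = 1e-6) -> bool:
        return self.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to world mm coordinates (n, 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "ImageVolume":
        return ImageVolume(data=data, affine=self.affine.copy(), kind=kind or self.kind)


@dataclass
class RoiMask:
    """A binary region-of-interest mask on a stated grid."""

    data: np.ndarray
    affine: np.ndarray
    label: str = "myocardium"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be binary")
            arr = arr.astype(bool)
        self.data = arr
        self.affine = _check_affine(self.affine)
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}; expected one of {MASK_LABELS}")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])) / 1000.0)

    @property
    def volume_ml(self) -> float:
        return self.count * self.voxel_volume_ml

    @property
    def is_empty(self) -> bool:
        return self.count == 0

    def same_grid(self, other: "ImageVolume | RoiMask", tol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def centroid_mm(self) -> np.ndarray:
        """World-space centroid of the in-mask voxel centers."""
        if self.is_empty:
            raise ValueError("centroid of an empty mask is undefined")
        ijk = np.argwhere(self.data).astype(float)
        world = (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]
        return world.mean(axis=0)


def make_affine(spacing: float | tuple[float, float, float], origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Axis-aligned affine from isotropic or per-axis spacing and an origin."""
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = origin
    return affine
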