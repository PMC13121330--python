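"""Blood-pool VOI construction and per-VOI SUV statistics."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import GeometryError, GridMismatchError, ImageVolume, RoiMask

#: Default spherical blood-pool VOI radius (mm). Large enough for a stable
#: across-voxel standard deviation on a 3 mm grid, small enough to stay
#: clear of the myocardial wall in the phantom cavity.
DEFAULT_BP_RADIUS_MM = 10.0

#: Smallest VOI for which an across-voxel sd is considered meaningful.
MIN_VOI_VOXELS = 10


@dataclass
class VoiSpec:
    """Serializable sphere-VOI description (world mm)."""

    center_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_BP_RADIUS_MM

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VoiSpec":
        d = json.loads(Path(path).read_text())
        return cls(center_mm=tuple(d["center_mm"]), radius_mm=d["radius_mm"])


@dataclass
class VoiStats:
    """Summary statistics over the in-mask voxels of one volume."""

    mean: float
    sd: float
    max: float
    n: int


@dataclass
class BloodPoolStats:
    """Blood-pool SUV statistics anchoring the EFM threshold at one time."""

    suv_mean: float
    suv_std: float
    n_voxels: int
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    time_min: float | None = None

    def __post_init__(self) -> None:
        if self.suv_std < 0:
            raise ValueError("SUVstd cannot be negative")
        if self.n_voxels < MIN_VOI_VOXELS:
            raise ValueError(
                f"blood-pool VOI has {self.n_voxels} voxels; "
                f"at least {MIN_VOI_VOXELS} required for a stable SUVstd"
            )


def make_sphere_voi(
    center_mm,
    radius_mm: float,
    grid: ImageVolume | RoiMask,
    *,
    min_voxels: int = MIN_VOI_VOXELS,
) -> RoiMask:
    """Spherical VOI on the grid: a voxel is included iff its center lies
    within ``radius_mm`` of ``center_mm`` (no partial-volume weighting)."""
    center = np.asarray(center_mm, dtype=float)
    if radius_mm <= 0:
        raise GeometryError("VOI radius must be positive")
    affine = np.asarray(grid.affine)
    shape = grid.data.shape
    inv = np.linalg.inv(affine)
    cv = inv[:3, :3] @ center + inv[:3, 3]
    if np.any(cv < -0.5) or np.any(cv > np.asarray(shape) - 0.5):
        raise GeometryError(f"VOI center {tuple(center)} mm is outside the field of view")

    # bounding box in voxel space keeps this O(radius^3)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    pad = np.ceil(radius_mm / spacing).astype(int) + 1
    lo = np.maximum(np.floor(cv).astype(int) - pad, 0)
    hi = np.minimum(np.floor(cv).astype(int) + pad + 1, shape)

    out = np.zeros(shape, dtype=bool)
    sub = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
    ijk = np.stack([s.ravel() for s in sub], axis=1).astype(float)
    world = (affine[:3, :3] @ ijk.T).T + affine[:3, 3]
    inside = np.sum((world - center) ** 2, axis=1) <= radius_mm**2
    out[sub[0].ravel()[inside], sub[1].ravel()[inside], sub[2].ravel()[inside]] = True

    n = int(out.sum())
    if n < min_voxels:
        raise GeometryError(
            f"VOI of radius {radius_mm} mm contains only {n} voxel(s); "
            f"minimum is {min_voxels}"
        )
    return RoiMask(out, affine.copy(), label="blood_pool")


def voi_stats(volume: ImageVolume, mask: RoiMask, *, ddof: int = 0) -> VoiStats:
    """Mean / sd / max / n over the in-mask voxels.

    The sd uses the population (1/n) denominator by default: the VOI is
    treated as the full background distribution feeding the threshold, not
    a sample from it. Pass ``ddof=1`` for the sample convention.
    """
    if mask.is_empty:
        raise ValueError("cannot compute statistics over an empty mask")
    if not volume.same_grid(mask):
        raise GridMismatchError("volume and mask are on different grids")
    vals = volume.data[mask.data]
    return VoiStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=ddof)),
        max=float(vals.max()),
        n=int(vals.size),
    )


def blood_pool_stats(
    volume: ImageVolume,
    voi: RoiMask,
    *,
    spec: VoiSpec | None = None,
    time_min: float | None = None,
    ddof: int = 0,
) -> BloodPoolStats:
    """Blood-pool statistics for one acquisition time point."""
    s = voi_stats(volume, voi, ddof=ddof)
    return BloodPoolStats(
        suv_mean=s.mean,
        suv_std=s.sd,
        n_voxels=s.n,
        center_mm=None if spec is None else tuple(spec.center_mm),
        radius_mm=None if spec is None else spec.radius_mm,
        time_min=time_min,
    )
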