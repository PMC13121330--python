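"""NIfTI I/O, SUV conversion and mask resampling.

SUV follows the body-weight convention: tissue activity concentration
divided by injected dose per body mass, with the dose decay-corrected
(default: to acquisition start) using the Ga-68 half-life. Masks are
resampled nearest-neighbour so binarity is preserved; images trilinear.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .core import CalibrationError, ImageVolume, RoiMask

GA68_HALF_LIFE_MIN = 67.71


@dataclass
class SuvCalibration:
    """Dose/weight/timing data needed to convert Bq/mL to SUV.

    Times are minutes on a common clock; ``decay_reference`` selects whether
    the injected dose is decay-corrected to the acquisition start (field
    default) or left at injection time.
    """

    injected_dose_mbq: float
    body_weight_kg: float
    injection_time_min: float = 0.0
    acquisition_start_min: float = 0.0
    half_life_min: float = GA68_HALF_LIFE_MIN
    decay_reference: str = "acquisition"  # or "injection"

    def __post_init__(self) -> None:
        if self.injected_dose_mbq is None or self.injected_dose_mbq <= 0:
            raise CalibrationError("injected dose must be positive")
        if self.body_weight_kg is None or self.body_weight_kg <= 0:
            raise CalibrationError("body weight must be positive")
        if self.acquisition_start_min < self.injection_time_min:
            raise CalibrationError("acquisition cannot precede injection")
        if self.half_life_min <= 0:
            raise CalibrationError("half-life must be positive")
        if self.decay_reference not in ("acquisition", "injection"):
            raise CalibrationError("decay_reference must be 'acquisition' or 'injection'")

    @property
    def uptake_time_min(self) -> float:
        return self.acquisition_start_min - self.injection_time_min

    def decayed_dose_bq(self) -> float:
        dose_bq = self.injected_dose_mbq * 1e6
        if self.decay_reference == "injection":
            return dose_bq
        return dose_bq * 2.0 ** (-self.uptake_time_min / self.half_life_min)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SuvCalibration":
        return cls(**json.loads(Path(path).read_text()))


def activity_to_suv(volume: ImageVolume, cal: SuvCalibration) -> ImageVolume:
    """Convert an activity-concentration volume (Bq/mL) to unitless SUV.

    SUV = C / (decayed dose / body mass in g); negative reconstructed values
    are clamped to zero so downstream VOI standard deviations are not
    corrupted by reconstruction artifacts.
    """
    if volume.kind != "Bq/mL":
        raise CalibrationError(
            f"expected an activity-concentration volume, got kind={volume.kind!r}"
        )
    norm = cal.decayed_dose_bq() / (cal.body_weight_kg * 1000.0)  # Bq per g
    suv = np.maximum(volume.data, 0.0) / norm
    return volume.with_data(suv, kind="SUV")


def read_volume(path: str | Path, kind: str = "SUV") -> ImageVolume:
    """Read a 3-D NIfTI volume; 4-D files are rejected."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return ImageVolume(data, img.affine, kind=kind)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "myocardium") -> RoiMask:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read NIfTI mask {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    return RoiMask(data > 0.5, img.affine, label=label)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def resample_mask(mask: RoiMask, target: ImageVolume) -> RoiMask:
    """Nearest-neighbour resample a mask onto the target grid.

    Voxels of the target grid whose world position falls outside the source
    field of view are background. A resample that produces an empty mask
    (disjoint fields of view) emits a warning.
    """
    if mask.same_grid(target):
        return RoiMask(mask.data.copy(), mask.affine.copy(), label=mask.label)
    # compose: target voxel -> world -> source voxel
    src_inv = np.linalg.inv(mask.affine)
    composed = src_inv @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src_idx = composed[:3, :3] @ idx + composed[:3, 3:4]
    vals = map_coordinates(
        mask.data.astype(np.float32), src_idx, order=0, mode="constant", cval=0.0
    )
    out = vals.reshape(target.shape) > 0.5
    result = RoiMask(out, target.affine.copy(), label=mask.label)
    if result.is_empty and not mask.is_empty:
        warnings.warn(
            "mask resampling produced an empty mask (non-overlapping fields of view)",
            RuntimeWarning,
            stacklevel=2,
        )
    return result


def resample_volume(volume: ImageVolume, target: ImageVolume) -> ImageVolume:
    """Trilinear resample an intensity volume onto the target grid."""
    if volume.same_grid(target):
        return volume.with_data(volume.data.copy())
    src_inv = np.linalg.inv(volume.affine)
    composed = src_inv @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src_idx = composed[:3, :3] @ idx + composed[:3, 3:4]
    vals = map_coordinates(volume.data, src_idx, order=1, mode="constant", cval=0.0)
    return ImageVolume(vals.reshape(target.shape), target.affine.copy(), kind=volume.kind)
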