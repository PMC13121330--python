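"""Multi-time-point rigid alignment and series assembly.

The later acquisitions are rigidly registered to the first (60-min) frame
on the structural CT-like channel; the resulting transform then carries
the blood-pool VOI and myocardial mask to each time point, where blood
statistics, thresholds and EFM masks are recomputed. Missing time points
are represented explicitly and never imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import GeometryError, ImageVolume, RoiMask
from .efm import EfmMetrics
from .voi import BloodPoolStats


class RegistrationError(RuntimeError):
    """Registration failed to converge; carries the final metric value."""


def _direction_and_spacing(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    direction = affine[:3, :3] / spacing
    return direction, spacing


def volume_to_sitk(volume: ImageVolume | RoiMask) -> sitk.Image:
    """View one of our volumes as a SimpleITK image (same world frame)."""
    data = volume.data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    direction, spacing = _direction_and_spacing(np.asarray(volume.affine))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in volume.affine[:3, 3]))
    img.SetDirection(tuple(direction.ravel()))
    return img


def sitk_to_array(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


@dataclass
class RigidTransform:
    """World-space rigid map y = R x + t from fixed-frame to moving-frame mm.

    Resampling the moving image through this transform brings it onto the
    fixed grid; the inverse carries fixed-frame VOIs to the moving frame.
    """

    matrix: np.ndarray
    translation_mm: np.ndarray
    fixed_label: str = "60min"
    moving_label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if not np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-5):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.matrix) < 0:
            raise ValueError("rotation matrix must have determinant +1")

    @property
    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.matrix) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (self.matrix @ xyz.T).T + self.translation_mm

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix.T
        return RigidTransform(
            rinv, -rinv @ self.translation_mm, self.moving_label, self.fixed_label
        )

    def as_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.matrix.ravel()))
        t.SetTranslation(tuple(self.translation_mm))
        return t

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix": self.matrix.tolist(),
                    "translation_mm": self.translation_mm.tolist(),
                    "fixed_label": self.fixed_label,
                    "moving_label": self.moving_label,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["matrix"]),
            np.asarray(d["translation_mm"]),
            d.get("fixed_label", ""),
            d.get("moving_label", ""),
        )

    @classmethod
    def identity(cls, fixed_label: str = "", moving_label: str = "") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), fixed_label, moving_label)

    @classmethod
    def from_euler(
        cls,
        angles_deg: tuple[float, float, float],
        translation_mm: tuple[float, float, float],
        center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
        fixed_label: str = "",
        moving_label: str = "",
    ) -> "RigidTransform":
        """Rigid map rotating by ZYX Euler angles about ``center_mm``."""
        e = sitk.Euler3DTransform()
        e.SetCenter(center_mm)
        e.SetRotation(*[math.radians(a) for a in angles_deg])
        e.SetTranslation(translation_mm)
        m = np.asarray(e.GetMatrix()).reshape(3, 3)
        c = np.asarray(center_mm)
        b = c + np.asarray(translation_mm) - m @ c
        return cls(m, b, fixed_label, moving_label)


def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    *,
    iterations: int = 100,
    shrink_factors: tuple[int, ...] = (4, 2),
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0),
    convergence_tol: float = 1e-8,
    threads: int = 1,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Mean-squares metric with dense sampling (deterministic), multi-resolution
    gradient descent. Raises :class:`RegistrationError` when the optimized
    transform does not improve the metric over the identity.
    """
    f_img = volume_to_sitk(fixed)
    m_img = volume_to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        f_img,
        m_img,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetGlobalDefaultNumberOfThreads(threads)
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: bit-reproducible
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=iterations,
        gradientMagnitudeTolerance=convergence_tol,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=False)

    final = reg.Execute(f_img, m_img)

    # sanity: optimized metric must beat the identity transform
    final_metric = reg.GetMetricValue()
    identity_metric = _mean_squares(f_img, m_img, sitk.Transform(3, sitk.sitkIdentity))
    if final_metric > identity_metric + 1e-12 and identity_metric > 1e-12:
        raise RegistrationError(
            f"registration did not improve similarity "
            f"(final metric {final_metric:.6g} vs identity {identity_metric:.6g})"
        )

    if final.GetName() == "CompositeTransform":
        final = sitk.CompositeTransform(final).GetNthTransform(0)
    e = sitk.Euler3DTransform(final.Downcast())
    m = np.asarray(e.GetMatrix()).reshape(3, 3)
    c = np.asarray(e.GetCenter())
    b = c + np.asarray(e.GetTranslation()) - m @ c
    return RigidTransform(m, b, fixed_label="fixed", moving_label="moving")


def _mean_squares(fixed: sitk.Image, moving: sitk.Image, transform: sitk.Transform) -> float:
    resampled = sitk.Resample(moving, fixed, transform, sitk.sitkLinear, 0.0)
    diff = sitk.GetArrayFromImage(fixed) - sitk.GetArrayFromImage(resampled)
    return float(np.mean(diff**2))


def apply_transform(
    moving: ImageVolume,
    transform: RigidTransform,
    reference: ImageVolume,
    *,
    interpolation: str = "linear",
) -> ImageVolume:
    """Resample ``moving`` through ``transform`` onto the reference grid."""
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        volume_to_sitk(moving), volume_to_sitk(reference), transform.as_sitk(), interp, 0.0
    )
    return ImageVolume(
        sitk_to_array(out).astype(float), reference.affine.copy(), kind=moving.kind
    )


def propagate_voi(
    voi: RoiMask, transform: RigidTransform, target: ImageVolume
) -> RoiMask:
    """Carry a fixed-frame VOI to the moving frame's grid.

    The registration transform maps fixed-frame points to moving-frame
    points, so the VOI lands on the target grid through the forward map
    (equivalently, the mask image is resampled through its inverse),
    nearest-neighbour so binarity is preserved. An empty result means the
    VOI left the target field of view.
    """
    out = sitk.Resample(
        volume_to_sitk(voi),
        volume_to_sitk(target),
        transform.inverse().as_sitk(),
        sitk.sitkNearestNeighbor,
        0.0,
    )
    mask = RoiMask(sitk_to_array(out) > 0.5, target.affine.copy(), label=voi.label)
    if mask.is_empty and not voi.is_empty:
        raise GeometryError("propagated VOI left the target field of view")
    return mask


@dataclass
class TimepointEntry:
    time_min: float
    metrics: EfmMetrics
    blood: BloodPoolStats


@dataclass
class TimepointSeries:
    """Ordered per-patient series of per-time-point quantifications."""

    patient_id: str
    entries: list[TimepointEntry]
    expected_times: tuple[float, ...] = (60.0, 70.0, 120.0)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(e.time_min for e in self.entries)

    @property
    def missing_times(self) -> tuple[float, ...]:
        present = set(self.times)
        return tuple(t for t in self.expected_times if t not in present)

    @property
    def is_complete(self) -> bool:
        return not self.missing_times


def build_series(
    patient_id: str,
    entries: list[TimepointEntry],
    expected_times: tuple[float, ...] = (60.0, 70.0, 120.0),
) -> TimepointSeries:
    """Sort per-time-point results into a completeness-flagged series."""
    if not entries:
        raise ValueError("a series needs at least one time point")
    times = [e.time_min for e in entries]
    if len(set(times)) != len(times):
        raise ValueError(f"duplicate time points in series for {patient_id}: {times}")
    ordered = sorted(entries, key=lambda e: e.time_min)
    return TimepointSeries(patient_id, ordered, tuple(expected_times))
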