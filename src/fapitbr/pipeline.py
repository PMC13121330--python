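"""End-to-end orchestration: simulate -> quantify -> classify -> stats.

Each stage is a plain function writing plain-text artifacts (CSV / JSON /
NIfTI) into a run directory, so partial pipelines are re-runnable from
files. All randomness flows from one root seed recorded in the manifest;
a rerun with the same seed reproduces every artifact bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imageio
from .cohort import CohortConfig, generate_cohort
from .core import ImageVolume, RoiMask
from .efm import (
    ThresholdConfig,
    compute_threshold,
    efm_metrics,
    extract_efm,
    metrics_frame,
    metrics_row,
)
from .outcomes import CriteriaConfig, classify_cohort, delta_table, records_from_frame
from .phantom import KineticsConfig, PhantomConfig, PhantomResult, generate_phantom
from .stats import cohort_report, write_report
from .timepoints import (
    RigidTransform,
    TimepointEntry,
    build_series,
    propagate_voi,
    register_rigid,
)
from .voi import DEFAULT_BP_RADIUS_MM, VoiSpec, blood_pool_stats, make_sphere_voi

log = logging.getLogger("fapitbr")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    n_patients: int = 19
    times_min: tuple[float, ...] = (60.0, 70.0, 120.0)
    bp_radius_mm: float = DEFAULT_BP_RADIUS_MM
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    # simulated inter-acquisition patient repositioning (uniform bounds)
    motion_max_translation_mm: float = 6.0
    motion_max_rotation_deg: float = 3.0
    write_volumes: bool = False

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, extra: dict | None = None) -> dict:
    """Checksum every artifact under ``outdir`` into manifest.json."""
    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _draw_motion(rng: np.random.Generator, cfg: RunConfig) -> RigidTransform:
    t = rng.uniform(-cfg.motion_max_translation_mm, cfg.motion_max_translation_mm, 3)
    a = rng.uniform(-cfg.motion_max_rotation_deg, cfg.motion_max_rotation_deg, 3)
    return RigidTransform.from_euler(tuple(a), tuple(t))


@dataclass
class PatientImages:
    """One patient's multi-time-point acquisition (possibly repositioned)."""

    patient_id: str
    times_min: tuple[float, ...]
    pet: dict[float, ImageVolume]
    ct: dict[float, ImageVolume]
    myo_60: RoiMask
    voi_spec: VoiSpec
    true_motion: dict[float, RigidTransform]


def simulate_patient(
    patient_id: str,
    phantom_cfg: PhantomConfig,
    kinetics: KineticsConfig,
    run_cfg: RunConfig,
    rng: np.random.Generator,
    times: tuple[float, ...],
) -> PatientImages:
    """Generate one patient's phantom series with inter-scan repositioning.

    The 60-min frame is the reference; later frames are rigidly moved by a
    random transform (bounded by the run config) before quantification, so
    the registration stage has real work to do.
    """
    t0 = times[0]
    motion: dict[float, RigidTransform] = {t0: RigidTransform.identity()}
    motion_mats: dict[float, np.ndarray] = {}
    for t in times[1:]:
        m = _draw_motion(rng, run_cfg)
        motion[t] = m
        minv = m.inverse()
        mat = np.eye(4)
        mat[:3, :3] = minv.matrix
        mat[:3, 3] = minv.translation_mm
        motion_mats[t] = mat
    kin = KineticsConfig(
        times_min=times,
        blood_half_time_min=kinetics.blood_half_time_min,
        myo_half_time_min=kinetics.myo_half_time_min,
    )
    result: PhantomResult = generate_phantom(phantom_cfg, kin, motions=motion_mats)
    pet = {t: result.suv[t] for t in times}
    ct = {t: result.ct[t] for t in times}
    voi_spec = VoiSpec(center_mm=result.truth.blood_center_mm, radius_mm=run_cfg.bp_radius_mm)
    return PatientImages(
        patient_id=patient_id,
        times_min=times,
        pet=pet,
        ct=ct,
        myo_60=result.truth.myo_mask,
        voi_spec=voi_spec,
        true_motion=motion,
    )


def quantify_patient(
    images: PatientImages,
    thr_cfg: ThresholdConfig,
) -> tuple[list[dict], "object"]:
    """Register later frames, propagate VOI and mask, score every time point."""
    t0 = images.times_min[0]
    ct60 = images.ct[t0]
    voi60 = make_sphere_voi(
        images.voi_spec.center_mm, images.voi_spec.radius_mm, images.pet[t0]
    )
    entries = []
    rows = []
    for t in images.times_min:
        pet_t = images.pet[t]
        if t == t0:
            voi_t, myo_t = voi60, images.myo_60
        else:
            transform = register_rigid(ct60, images.ct[t])
            voi_t = propagate_voi(voi60, transform, pet_t)
            myo_t = propagate_voi(images.myo_60, transform, pet_t)
        bp = blood_pool_stats(pet_t, voi_t, spec=images.voi_spec, time_min=t)
        thr = compute_threshold(bp, thr_cfg)
        efm_mask = extract_efm(pet_t, myo_t, thr)
        m = efm_metrics(pet_t, efm_mask, bp, threshold=thr, time_min=t)
        entries.append(TimepointEntry(time_min=t, metrics=m, blood=bp))
        rows.append(metrics_row(images.patient_id, m))
    series = build_series(images.patient_id, entries, images.times_min)
    return rows, series


def run_demo(
    seed: int,
    outdir: str | Path,
    *,
    run_cfg: RunConfig | None = None,
    cohort_cfg: CohortConfig | None = None,
) -> dict:
    """Full study-scale pipeline on a synthetic cohort.

    Simulates the default 19-patient cohort at 60/70/120 min (two patients
    missing the 120-min scan), quantifies every scan through registration,
    VOI propagation, thresholding and TBR, classifies one-year responders,
    runs the cohort statistics and writes all artifacts plus a checksum
    manifest under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_cfg = run_cfg or RunConfig(seed=seed)
    cohort_cfg = cohort_cfg or CohortConfig(seed=seed)
    kinetics = KineticsConfig(times_min=run_cfg.times_min)
    rng = np.random.default_rng(seed)

    table, phantom_cfgs = generate_cohort(cohort_cfg)
    table.to_csv(outdir / "clinical.csv", index=False)
    run_cfg.to_json(outdir / "run_config.json")

    all_rows: list[dict] = []
    for i, (pid, pcfg) in enumerate(zip(table["patient_id"], phantom_cfgs)):
        times = run_cfg.times_min if table["has_120min"].iloc[i] else run_cfg.times_min[:-1]
        log.info("simulating and quantifying %s (times %s)", pid, times)
        images = simulate_patient(pid, pcfg, kinetics, run_cfg, rng, times)
        rows, _ = quantify_patient(images, run_cfg.threshold)
        all_rows.extend(rows)
        if run_cfg.write_volumes:
            pdir = outdir / "volumes" / pid
            pdir.mkdir(parents=True, exist_ok=True)
            for t in times:
                imageio.write_volume(images.pet[t], pdir / f"pet_{int(t):03d}min.nii")
                imageio.write_volume(images.ct[t], pdir / f"ct_{int(t):03d}min.nii")

    metrics = metrics_frame(all_rows)
    metrics.to_csv(outdir / "metrics.csv", index=False)

    records = records_from_frame(table)
    outcomes = classify_cohort(records, run_cfg.criteria)
    outcomes.to_csv(outdir / "outcomes.csv", index=False)
    deltas = delta_table(records)
    deltas.to_csv(outdir / "deltas.csv", index=False)

    report = cohort_report(metrics, outcomes, table)
    write_report(report, outdir / "report.json")

    manifest = write_manifest(outdir, extra={"seed": seed, "n_patients": run_cfg.n_patients})
    return manifest


# ---------------------------------------------------------------------------
# file-based stages (CLI re-runnable pipeline)


def simulate_to_dir(
    seed: int,
    outdir: str | Path,
    *,
    run_cfg: RunConfig | None = None,
    cohort_cfg: CohortConfig | None = None,
) -> Path:
    """Write a simulated cohort (volumes, masks, VOI specs, clinical table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_cfg = run_cfg or RunConfig(seed=seed)
    cohort_cfg = cohort_cfg or CohortConfig(seed=seed)
    kinetics = KineticsConfig(times_min=run_cfg.times_min)
    rng = np.random.default_rng(seed)

    table, phantom_cfgs = generate_cohort(cohort_cfg)
    table.to_csv(outdir / "clinical.csv", index=False)
    run_cfg.to_json(outdir / "run_config.json")

    for i, (pid, pcfg) in enumerate(zip(table["patient_id"], phantom_cfgs)):
        times = run_cfg.times_min if table["has_120min"].iloc[i] else run_cfg.times_min[:-1]
        images = simulate_patient(pid, pcfg, kinetics, run_cfg, rng, times)
        pdir = outdir / pid
        pdir.mkdir(exist_ok=True)
        for t in times:
            imageio.write_volume(images.pet[t], pdir / f"pet_{int(t):03d}min.nii")
            imageio.write_volume(images.ct[t], pdir / f"ct_{int(t):03d}min.nii")
        imageio.write_mask(images.myo_60, pdir / "myocardium_060min.nii")
        images.voi_spec.to_json(pdir / "blood_voi.json")
        (pdir / "times.json").write_text(json.dumps(list(times)))
    write_manifest(outdir, extra={"seed": seed})
    return outdir


def quantify_dir(run_dir: str | Path, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Quantify a simulated run directory into a long-format metrics table."""
    run_dir = Path(run_dir)
    cfg_path = run_dir / "run_config.json"
    thr_cfg = ThresholdConfig()
    if cfg_path.exists():
        d = json.loads(cfg_path.read_text())
        thr_cfg = ThresholdConfig(**d.get("threshold", {}))
    all_rows: list[dict] = []
    for pdir in sorted(p for p in run_dir.iterdir() if p.is_dir() and p.name != "volumes"):
        times = json.loads((pdir / "times.json").read_text())
        pet = {t: imageio.read_volume(pdir / f"pet_{int(t):03d}min.nii") for t in times}
        ct = {
            t: imageio.read_volume(pdir / f"ct_{int(t):03d}min.nii", kind="CT")
            for t in times
        }
        myo = imageio.read_mask(pdir / "myocardium_060min.nii", label="myocardium")
        spec = VoiSpec.from_json(pdir / "blood_voi.json")
        images = PatientImages(
            patient_id=pdir.name,
            times_min=tuple(times),
            pet=pet,
            ct=ct,
            myo_60=myo,
            voi_spec=spec,
            true_motion={},
        )
        rows, _ = quantify_patient(images, thr_cfg)
        all_rows.extend(rows)
    metrics = metrics_frame(all_rows)
    if out_csv is not None:
        metrics.to_csv(out_csv, index=False)
    return metrics


def classify_file(
    clinical_csv: str | Path,
    out_csv: str | Path | None = None,
    criteria: CriteriaConfig | None = None,
) -> pd.DataFrame:
    table = pd.read_csv(clinical_csv)
    outcomes = classify_cohort(records_from_frame(table), criteria)
    if out_csv is not None:
        outcomes.to_csv(out_csv, index=False)
    return outcomes


def stats_files(
    metrics_csv: str | Path,
    clinical_csv: str | Path,
    outcomes_csv: str | Path | None,
    out_json: str | Path | None = None,
) -> dict:
    metrics = pd.read_csv(metrics_csv)
    clinical = pd.read_csv(clinical_csv)
    outcomes = pd.read_csv(outcomes_csv) if outcomes_csv else None
    report = cohort_report(metrics, outcomes, clinical)
    if out_json is not None:
        write_report(report, out_json)
    return report
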