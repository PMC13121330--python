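"""Composite one-year responder endpoint after TAVI.

Five pre-specified improvement criteria are evaluated per patient:

a. NT-proBNP decrease >= 30%
b. NYHA improvement >= 1 class
c. hsCRP decrease >= 15%, evaluated only if baseline hsCRP is elevated
d. patient-reported dyspnea "much better"
e. LVEF increase >= 5 percentage points, only if baseline LVEF < 60%

A patient is a responder iff at least 2 criteria are met. Conditional
criteria (c, e) are excluded from the numerator when ineligible, but the
">= 2" requirement is never relaxed. Patients without follow-up data are
excluded from outcome analysis, not classified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CRITERION_IDS = ("a", "b", "c", "d", "e")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class CriteriaConfig:
    """Thresholds of the composite endpoint (pre-specified study defaults)."""

    nt_probnp_drop_frac: float = 0.30
    nyha_improvement_classes: int = 1
    hscrp_drop_frac: float = 0.15
    hscrp_elevated_cutoff_mg_l: float = 5.0  # "elevated" is undefined upstream; config
    dyspnea_required: str = "much better"
    lvef_gain_points: float = 5.0
    lvef_eligibility_below: float = 60.0
    min_criteria_met: int = 2


@dataclass
class ClinicalRecord:
    """Baseline and follow-up clinical covariates for one patient.

    ``hscrp_unit`` is mandatory whenever hsCRP values are present because
    source tables in this field mix mg/L and mg/dL.
    """

    patient_id: str
    nt_probnp_baseline: float | None = None
    nt_probnp_followup: float | None = None
    hscrp_baseline: float | None = None
    hscrp_followup: float | None = None
    hscrp_unit: str | None = None  # "mg/L" or "mg/dL"
    nyha_baseline: int | None = None
    nyha_followup: int | None = None
    dyspnea_response: str | None = None
    lvef_baseline: float | None = None
    lvef_followup: float | None = None
    followup_months: float | None = None

    def __post_init__(self) -> None:
        for v, name in ((self.nyha_baseline, "baseline"), (self.nyha_followup, "follow-up")):
            if not _missing(v) and int(v) not in (1, 2, 3, 4):
                raise ValueError(f"NYHA {name} class must be I-IV, got {v}")
        for v in (self.lvef_baseline, self.lvef_followup):
            if not _missing(v) and not (0 < v <= 100):
                raise ValueError(f"LVEF must be in (0, 100], got {v}")
        for v in (
            self.nt_probnp_baseline,
            self.nt_probnp_followup,
            self.hscrp_baseline,
            self.hscrp_followup,
        ):
            if not _missing(v) and v < 0:
                raise ValueError("biomarker values must be non-negative")
        if (
            not _missing(self.hscrp_baseline) or not _missing(self.hscrp_followup)
        ) and self.hscrp_unit not in ("mg/L", "mg/dL"):
            raise ValueError("hscrp_unit must be 'mg/L' or 'mg/dL' when hsCRP is present")

    def hscrp_baseline_mg_l(self) -> float | None:
        if _missing(self.hscrp_baseline):
            return None
        return self.hscrp_baseline * (10.0 if self.hscrp_unit == "mg/dL" else 1.0)

    @property
    def has_followup(self) -> bool:
        return any(
            not _missing(v)
            for v in (
                self.nt_probnp_followup,
                self.nyha_followup,
                self.hscrp_followup,
                self.lvef_followup,
                self.dyspnea_response,
            )
        )


@dataclass
class CriterionResult:
    criterion_id: str
    eligible: bool
    met: bool

    def __post_init__(self) -> None:
        if self.met and not self.eligible:
            raise ValueError("a criterion cannot be met while ineligible")


@dataclass
class OutcomeRecord:
    patient_id: str
    criteria: list[CriterionResult]
    n_eligible: int
    n_met: int
    responder: bool


def evaluate_criteria(
    rec: ClinicalRecord, config: CriteriaConfig | None = None
) -> list[CriterionResult]:
    """Evaluate the five composite criteria for one patient."""
    cfg = config or CriteriaConfig()
    results: list[CriterionResult] = []

    # (a) NT-proBNP relative decrease
    base, fu = rec.nt_probnp_baseline, rec.nt_probnp_followup
    if _missing(base) or _missing(fu):
        results.append(CriterionResult("a", False, False))
    elif base == 0:
        warnings.warn(
            f"{rec.patient_id}: baseline NT-proBNP is 0, relative change undefined; "
            "criterion (a) marked ineligible",
            RuntimeWarning,
            stacklevel=2,
        )
        results.append(CriterionResult("a", False, False))
    else:
        met = (base - fu) / base >= cfg.nt_probnp_drop_frac
        results.append(CriterionResult("a", True, bool(met)))

    # (b) NYHA class improvement
    if _missing(rec.nyha_baseline) or _missing(rec.nyha_followup):
        results.append(CriterionResult("b", False, False))
    else:
        met = (int(rec.nyha_baseline) - int(rec.nyha_followup)) >= cfg.nyha_improvement_classes
        results.append(CriterionResult("b", True, bool(met)))

    # (c) hsCRP decrease, only if elevated at baseline
    base_mg_l = rec.hscrp_baseline_mg_l()
    if (
        base_mg_l is None
        or _missing(rec.hscrp_followup)
        or base_mg_l <= cfg.hscrp_elevated_cutoff_mg_l
    ):
        results.append(CriterionResult("c", False, False))
    else:
        fu_mg_l = rec.hscrp_followup * (10.0 if rec.hscrp_unit == "mg/dL" else 1.0)
        met = (base_mg_l - fu_mg_l) / base_mg_l >= cfg.hscrp_drop_frac
        results.append(CriterionResult("c", True, bool(met)))

    # (d) patient-reported dyspnea
    if _missing(rec.dyspnea_response):
        results.append(CriterionResult("d", False, False))
    else:
        met = str(rec.dyspnea_response).strip().lower() == cfg.dyspnea_required
        results.append(CriterionResult("d", True, bool(met)))

    # (e) LVEF gain, only if baseline LVEF < 60%
    if (
        _missing(rec.lvef_baseline)
        or _missing(rec.lvef_followup)
        or rec.lvef_baseline >= cfg.lvef_eligibility_below
    ):
        results.append(CriterionResult("e", False, False))
    else:
        met = (rec.lvef_followup - rec.lvef_baseline) >= cfg.lvef_gain_points
        results.append(CriterionResult("e", True, bool(met)))

    return results


def classify_responder(
    patient_id: str,
    results: list[CriterionResult],
    config: CriteriaConfig | None = None,
) -> OutcomeRecord:
    """Responder iff the number of met criteria reaches the composite bar."""
    cfg = config or CriteriaConfig()
    if len(results) != len(CRITERION_IDS):
        raise ValueError(f"expected {len(CRITERION_IDS)} criterion results, got {len(results)}")
    n_eligible = sum(r.eligible for r in results)
    n_met = sum(r.met for r in results)
    return OutcomeRecord(
        patient_id=patient_id,
        criteria=list(results),
        n_eligible=n_eligible,
        n_met=n_met,
        responder=n_met >= cfg.min_criteria_met,
    )


def classify_cohort(
    records: list[ClinicalRecord], config: CriteriaConfig | None = None
) -> pd.DataFrame:
    """Classify every patient with follow-up; others are excluded.

    Returns one row per classified patient with per-criterion booleans.
    """
    rows = []
    for rec in records:
        if not rec.has_followup:
            continue
        results = evaluate_criteria(rec, config)
        out = classify_responder(rec.patient_id, results, config)
        row = {"patient_id": out.patient_id}
        for r in out.criteria:
            row[f"criterion_{r.criterion_id}_eligible"] = r.eligible
            row[f"criterion_{r.criterion_id}_met"] = r.met
        row["n_eligible"] = out.n_eligible
        row["n_met"] = out.n_met
        row["responder"] = out.responder
        rows.append(row)
    return pd.DataFrame(rows)


def delta_table(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Per-patient signed changes (negative = improvement for biomarkers).

    Missing values propagate as NaN; no patient is dropped here.
    """
    rows = []
    for rec in records:
        def rel(base, fu):
            if _missing(base) or _missing(fu) or base == 0:
                return math.nan
            return 100.0 * (fu - base) / base

        rows.append(
            {
                "patient_id": rec.patient_id,
                "delta_nt_probnp_pct": rel(rec.nt_probnp_baseline, rec.nt_probnp_followup),
                "delta_nyha_classes": (
                    math.nan
                    if _missing(rec.nyha_baseline) or _missing(rec.nyha_followup)
                    else float(rec.nyha_followup) - float(rec.nyha_baseline)
                ),
                "delta_hscrp_pct": rel(rec.hscrp_baseline, rec.hscrp_followup),
                "delta_lvef_points": (
                    math.nan
                    if _missing(rec.lvef_baseline) or _missing(rec.lvef_followup)
                    else rec.lvef_followup - rec.lvef_baseline
                ),
            }
        )
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    """Build clinical records from a cohort table (CSV-compatible schema)."""
    recs = []
    for _, row in df.iterrows():
        def get(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return v

        nyha_b, nyha_f = get("nyha_baseline"), get("nyha_followup")
        recs.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                nt_probnp_baseline=get("nt_probnp_baseline"),
                nt_probnp_followup=get("nt_probnp_followup"),
                hscrp_baseline=get("hscrp_baseline"),
                hscrp_followup=get("hscrp_followup"),
                hscrp_unit=get("hscrp_unit"),
                nyha_baseline=None if nyha_b is None else int(nyha_b),
                nyha_followup=None if nyha_f is None else int(nyha_f),
                dyspnea_response=get("dyspnea_response"),
                lvef_baseline=get("lvef_baseline"),
                lvef_followup=get("lvef_followup"),
                followup_months=get("followup_months"),
            )
        )
    return recs
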