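"""Cohort-level statistics on pipeline outputs.

Implements the analysis plan applied to the per-time-point metrics and
outcome labels: repeated-measures tests of time stability (mixed models
when series are unbalanced), biomarker associations (Pearson/Spearman with
OLS), responder group comparisons (exact Mann-Whitney in the small-sample
regime), and change-from-baseline ANCOVA. All tests are two-sided.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM


@dataclass
class StatsReport:
    analysis_id: str
    test_name: str
    effect: dict
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    n: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# time-point stability


def timepoint_stability(
    df: pd.DataFrame,
    value: str,
    *,
    subject: str = "patient",
    time: str = "time_min",
    posthoc: str | None = "bonferroni",
) -> StatsReport:
    """Repeated-measures test of a metric across acquisition times.

    Balanced complete series -> one-way repeated-measures ANOVA; unbalanced
    series (e.g. missing 120-min scans) -> linear mixed model with a
    subject-level random intercept and a Wald test on the time terms.
    Missing metric values are dropped, never imputed.
    """
    data = df[[subject, time, value]].dropna()
    if data.empty:
        raise ValueError(f"no non-missing values for {value!r}")
    n_subj = data[subject].nunique()
    n_times = data[time].nunique()
    if n_subj < 3 or n_times < 2:
        raise ValueError("need >= 3 subjects and >= 2 time points")

    counts = data.groupby(subject)[time].count()
    balanced = (counts == n_times).all()

    # degenerate case: metric exactly constant within every subject -> no
    # time effect by construction (the F statistic is 0/0 there)
    if (data.groupby(subject)[value].agg(np.ptp) == 0).all():
        means = data.groupby(time)[value].mean().to_dict()
        return StatsReport(
            analysis_id=f"stability_{value}",
            test_name="repeated-measures (degenerate: no within-subject variation)",
            effect={"group_means": {str(k): float(v) for k, v in means.items()}},
            statistic=0.0,
            p_value=1.0,
            n=int(n_subj),
            note="metric constant within every subject",
        )

    if balanced:
        res = AnovaRM(data, depvar=value, subject=subject, within=[time]).fit()
        row = res.anova_table.iloc[0]
        stat, p = float(row["F Value"]), float(row["Pr > F"])
        test_name = "repeated-measures ANOVA"
        note = ""
    else:
        model = smf.mixedlm(f"{value} ~ C({time})", data, groups=data[subject])
        fit = model.fit(reml=False, method="lbfgs")
        names = [n for n in fit.params.index if n.startswith(f"C({time})")]
        r_matrix = np.zeros((len(names), len(fit.params)))
        for i, nme in enumerate(names):
            r_matrix[i, list(fit.params.index).index(nme)] = 1.0
        wald = fit.wald_test(r_matrix, scalar=True)
        stat, p = float(wald.statistic), float(wald.pvalue)
        test_name = "linear mixed model (subject random intercept), Wald chi2"
        note = "unbalanced series; mixed model used"

    means = data.groupby(time)[value].mean().to_dict()
    effect = {"group_means": {str(k): float(v) for k, v in means.items()}}

    p_adj = None
    if posthoc == "bonferroni":
        times = sorted(data[time].unique())
        pairs = list(itertools.combinations(times, 2))
        raw = []
        wide = data.pivot_table(index=subject, columns=time, values=value)
        for t1, t2 in pairs:
            sub = wide[[t1, t2]].dropna()
            if len(sub) >= 3:
                raw.append(float(sps.ttest_rel(sub[t1], sub[t2]).pvalue))
        if raw:
            effect["posthoc_bonferroni"] = [min(1.0, len(raw) * pv) for pv in raw]
        p_adj = None  # omnibus p is unadjusted; post-hocs carry the correction

    return StatsReport(
        analysis_id=f"stability_{value}",
        test_name=test_name,
        effect=effect,
        statistic=stat,
        p_value=p,
        p_adjusted=p_adj,
        n=int(n_subj),
        note=note,
    )


# ---------------------------------------------------------------------------
# associations


def association(
    x,
    y,
    *,
    method: str = "pearson",
    log_y: bool = False,
    analysis_id: str = "association",
) -> StatsReport:
    """Correlation plus OLS fit of y on x (optionally on log y).

    Missing pairs are dropped. Spearman ignores ``log_y`` (rank-invariant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    yy = np.log(y) if (log_y and method == "pearson") else y
    if method == "pearson":
        r, p = sps.pearsonr(x, yy)
        test_name = "Pearson correlation"
    elif method == "spearman":
        r, p = sps.spearmanr(x, yy)
        test_name = "Spearman correlation"
    else:
        raise ValueError(f"unknown method {method!r}")

    ols = sm.OLS(yy, sm.add_constant(x)).fit()
    ci = ols.conf_int()
    effect = {
        "r": float(r),
        "slope": float(ols.params[1]),
        "intercept": float(ols.params[0]),
        "slope_ci": [float(ci[1][0]), float(ci[1][1])],
        "log_y": bool(log_y and method == "pearson"),
    }
    return StatsReport(
        analysis_id=analysis_id,
        test_name=test_name,
        effect=effect,
        statistic=float(r),
        p_value=float(p),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# group comparison


def exact_mannwhitney_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full rank-assignment enumeration.

    Midranks handle ties, so fully tied data give p = 1. Returns (U of the
    first sample, p). Intended for the small-sample regime (n <= ~10 per
    group); cost is C(n1+n2, n1) subset sums.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)

    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    sums = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
    count = int(np.sum(np.abs(sums - mu) >= dev - 1e-9))
    return u_obs, count / len(sums)


@dataclass
class GroupComparison:
    report: StatsReport


def group_compare(
    a,
    b,
    *,
    method: str = "auto",
    exact_max_n: int = 10,
    normality_alpha: float = 0.05,
    analysis_id: str = "group_compare",
) -> StatsReport:
    """Two-group comparison: Student t or Mann-Whitney U.

    ``method='auto'`` applies a Shapiro-Wilk gate at ``normality_alpha`` to
    each group and falls back to Mann-Whitney when either rejects. The
    Mann-Whitney p is exact (full enumeration, midranks) when both groups
    have <= ``exact_max_n`` observations, otherwise the tie-corrected
    normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(b, dtype=float)
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if method == "auto":
        normal = True
        for g in (a, b):
            if g.size >= 3 and np.ptp(g) > 0:
                if sps.shapiro(g).pvalue < normality_alpha:
                    normal = False
        method = "ttest" if normal else "mannwhitney"

    desc = {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)) if b.size > 1 else 0.0,
    }

    if method == "ttest":
        res = sps.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        test_name = "Student t test"
        desc["cohens_d"] = float(
            (a.mean() - b.mean())
            / math.sqrt(
                (
                    (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
                )
                / (a.size + b.size - 2)
            )
        ) if a.size + b.size > 2 and (a.var(ddof=1) + b.var(ddof=1)) > 0 else math.nan
    elif method == "mannwhitney":
        if a.size <= exact_max_n and b.size <= exact_max_n:
            u, p = exact_mannwhitney_p(a, b)
            stat = u
            test_name = "Mann-Whitney U (exact, enumeration)"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
            test_name = "Mann-Whitney U (normal approximation, tie-corrected)"
        desc["rank_biserial"] = float(1.0 - 2.0 * stat / (a.size * b.size))
    else:
        raise ValueError(f"unknown method {method!r}")

    return StatsReport(
        analysis_id=analysis_id,
        test_name=test_name,
        effect=desc,
        statistic=stat,
        p_value=p,
        n=int(a.size + b.size),
    )


# ---------------------------------------------------------------------------
# ANCOVA


def ancova_change(
    change,
    biomarker,
    baseline_covariate,
    *,
    analysis_id: str = "ancova_change",
) -> StatsReport:
    """Change-from-baseline ANCOVA.

    OLS of the follow-up change on the baseline biomarker, adjusting for the
    baseline value of the changing covariate; reports the adjusted biomarker
    slope with its p-value.
    """
    df = pd.DataFrame(
        {
            "change": np.asarray(change, dtype=float),
            "biomarker": np.asarray(biomarker, dtype=float),
            "baseline": np.asarray(baseline_covariate, dtype=float),
        }
    ).dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 complete cases")
    for col in ("biomarker", "baseline"):
        if np.ptp(df[col].to_numpy()) == 0:
            raise ValueError(f"covariate {col!r} has zero variance")
    r_cov = abs(np.corrcoef(df["biomarker"], df["baseline"])[0, 1])
    if r_cov > 0.999:
        raise ValueError("collinear covariates: biomarker and baseline covariate")

    fit = smf.ols("change ~ biomarker + baseline", data=df).fit()
    return StatsReport(
        analysis_id=analysis_id,
        test_name="ANCOVA (OLS, baseline-adjusted)",
        effect={
            "adjusted_slope": float(fit.params["biomarker"]),
            "baseline_slope": float(fit.params["baseline"]),
            "intercept": float(fit.params["Intercept"]),
        },
        statistic=float(fit.tvalues["biomarker"]),
        p_value=float(fit.pvalues["biomarker"]),
        n=int(len(df)),
    )


# ---------------------------------------------------------------------------
# report assembly


def cohort_report(
    metrics: pd.DataFrame | None,
    outcomes: pd.DataFrame | None,
    clinical: pd.DataFrame | None,
) -> dict:
    """Assemble the full analysis set into one machine-readable report.

    Sections: time-course stability of TBR and SUVmean(EFM); TBR vs
    NT-proBNP associations per time point (log and raw); responder group
    separation per time point; ANCOVA of one-year NT-proBNP change on
    baseline TBR. Sections whose inputs are absent or underpowered are
    recorded with a note instead of a result.
    """
    report: dict = {"analyses": []}

    def add(fn, *args, **kwargs):
        try:
            report["analyses"].append(fn(*args, **kwargs).to_dict())
        except (ValueError, KeyError) as exc:
            report["analyses"].append(
                {"analysis_id": kwargs.get("analysis_id", fn.__name__), "note": str(exc)}
            )

    if metrics is not None and not metrics.empty:
        long = metrics.rename(columns={"patient_id": "patient"})
        for metric in ("tbr_efm", "suvmean_efm"):
            if metric in long:
                add(timepoint_stability, long, metric)

    if (
        metrics is not None
        and clinical is not None
        and not metrics.empty
        and not clinical.empty
        and "nt_probnp_baseline" in clinical
    ):
        merged = metrics.merge(
            clinical[["patient_id", "nt_probnp_baseline"]], on="patient_id"
        )
        for t, sub in merged.groupby("time_min"):
            add(
                association,
                sub["tbr_efm"],
                sub["nt_probnp_baseline"],
                method="pearson",
                log_y=True,
                analysis_id=f"tbr_vs_log_ntprobnp_{int(t)}min",
            )
            add(
                association,
                sub["tbr_efm"],
                sub["nt_probnp_baseline"],
                method="spearman",
                analysis_id=f"tbr_vs_ntprobnp_spearman_{int(t)}min",
            )

    if (
        metrics is not None
        and outcomes is not None
        and not metrics.empty
        and not outcomes.empty
    ):
        merged = metrics.merge(
            outcomes[["patient_id", "responder"]], on="patient_id"
        )
        for t, sub in merged.groupby("time_min"):
            resp = sub.loc[sub["responder"] == True, "tbr_efm"]  # noqa: E712
            nonresp = sub.loc[sub["responder"] == False, "tbr_efm"]  # noqa: E712
            if len(resp) and len(nonresp):
                add(
                    group_compare,
                    resp,
                    nonresp,
                    method="mannwhitney",
                    analysis_id=f"responder_tbr_{int(t)}min",
                )

    if (
        metrics is not None
        and clinical is not None
        and not metrics.empty
        and not clinical.empty
        and {"nt_probnp_baseline", "nt_probnp_followup"} <= set(clinical.columns)
    ):
        base60 = metrics[metrics["time_min"] == 60.0][["patient_id", "tbr_efm"]]
        merged = base60.merge(clinical, on="patient_id")
        merged = merged.dropna(subset=["nt_probnp_followup"])
        if len(merged) >= 4:
            change_pct = (
                100.0
                * (merged["nt_probnp_followup"] - merged["nt_probnp_baseline"])
                / merged["nt_probnp_baseline"]
            )
            add(
                ancova_change,
                change_pct,
                merged["tbr_efm"],
                np.log(merged["nt_probnp_baseline"]),
                analysis_id="ancova_delta_ntprobnp_on_tbr60",
            )

    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
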