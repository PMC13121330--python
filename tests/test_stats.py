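"""Cohort statistics: stability tests, associations, group comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fapitbr.cohort import generate_metric_timeseries
from fapitbr.phantom import KineticsConfig
from fapitbr.stats import (
    ancova_change,
    association,
    cohort_report,
    exact_mannwhitney_p,
    group_compare,
    read_report,
    timepoint_stability,
    write_report,
)


def long_frame(values_by_patient):
    rows = []
    for pid, series in values_by_patient.items():
        for t, v in series:
            rows.append({"patient": pid, "time_min": t, "value": v})
    return pd.DataFrame(rows)


class TestTimepointStability:
    def test_constant_metric_gives_p_one(self):
        df = long_frame({p: [(60, v), (70, v), (120, v)] for p, v in zip("abcd", [1, 2, 3, 4])})
        rep = timepoint_stability(df, "value")
        assert rep.p_value == 1.0

    def test_two_timepoints_match_hand_computed_paired_t(self):
        # subjects (1, 2), (2, 2.5), (3, 3.1): diffs 1.0, 0.5, 0.1
        df = long_frame({"s1": [(60, 1.0), (70, 2.0)], "s2": [(60, 2.0), (70, 2.5)], "s3": [(60, 3.0), (70, 3.1)]})
        diffs = np.array([1.0, 0.5, 0.1])
        t_stat = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(3))
        p_expected = 2 * sps.t.sf(abs(t_stat), df=2)
        rep = timepoint_stability(df, "value", posthoc=None)
        assert rep.statistic == pytest.approx(t_stat**2, rel=1e-6)  # F = t^2
        assert rep.p_value == pytest.approx(p_expected, rel=1e-6)

    def test_unbalanced_series_use_mixed_model(self):
        df = generate_metric_timeseries(30, KineticsConfig(), rng=3)
        df = df.rename(columns={"tbr": "value"})
        # drop the 120-min rows of two patients
        drop = (df["patient"].isin(["P001", "P002"])) & (df["time_min"] == 120.0)
        rep = timepoint_stability(df[~drop], "value")
        assert "mixed" in rep.test_name.lower()
        assert 0.0 <= rep.p_value <= 1.0

    def test_strong_time_effect_detected(self):
        rng = np.random.default_rng(0)
        df = long_frame(
            {
                f"p{i}": [(60, 4 + e[0]), (70, 3 + e[1]), (120, 2 + e[2])]
                for i, e in enumerate(rng.normal(0, 0.1, size=(12, 3)))
            }
        )
        assert timepoint_stability(df, "value").p_value < 1e-6

    def test_all_missing_errors(self):
        df = long_frame({"a": [(60, np.nan)], "b": [(60, np.nan)]})
        with pytest.raises(ValueError):
            timepoint_stability(df, "value")


class TestAssociation:
    def test_perfect_line_r_one(self):
        x = np.arange(10.0)
        rep = association(x, 2 * x + 1)
        assert rep.effect["r"] == pytest.approx(1.0)
        assert rep.effect["slope"] == pytest.approx(2.0)
        assert rep.effect["intercept"] == pytest.approx(1.0)

    def test_random_permutation_kills_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        y = rng.permutation(2 * x + 1)
        assert abs(association(x, y).effect["r"]) < 0.08

    def test_known_r_recovered_at_large_n(self):
        rho = 0.65
        rng = np.random.default_rng(12)
        x = rng.standard_normal(1000)
        y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(1000)
        assert association(x, y).effect["r"] == pytest.approx(rho, abs=0.05)

    def test_spearman_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r1 = association(x, y, method="spearman")
        r2 = association(np.exp(x), y**3, method="spearman")
        assert r1.effect["r"] == pytest.approx(r2.effect["r"], abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            association([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def mannwhitney_pair_counting_oracle(a, b):
    """Independent exact p: U computed by pair counting (wins + half-ties)
    over every assignment of the pooled observations to the first group."""
    pooled = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)

    def u_of(indices):
        ga = [pooled[i] for i in indices]
        gb = [pooled[i] for i in range(n) if i not in indices]
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    mu = n1 * (n - n1) / 2.0
    dev = abs(u_of(tuple(range(n1))) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(comb) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestGroupCompare:
    def test_identical_groups_give_p_one(self):
        rep = group_compare([2.0, 2.0, 2.0, 2.0], [2.0, 2.0, 2.0, 2.0], method="mannwhitney")
        assert rep.p_value == 1.0

    def test_complete_separation_minimal_exact_p(self):
        # 5 vs 6 fully separated: the two most extreme of C(11,5)=462
        # orderings -> two-sided p = 2/462
        a = [1.0, 1.1, 1.2, 1.3, 1.4]
        b = [2.0, 2.1, 2.2, 2.3, 2.4, 2.5]
        rep = group_compare(a, b, method="mannwhitney")
        assert rep.p_value == pytest.approx(2.0 / 462.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=4).astype(float)  # coarse values force ties
        b = rng.integers(0, 4, size=5).astype(float)
        _, p = exact_mannwhitney_p(a, b)
        assert p == pytest.approx(mannwhitney_pair_counting_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = rng.normal(size=6), rng.normal(size=7)
        _, p = exact_mannwhitney_p(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_fig5_calibration_separates_groups_in_most_replicates(self):
        """Responder-vs-non-responder TBR calibration (1.7+/-0.2 vs
        2.9+/-0.9, n=5/6) yields p < 0.05 in the majority of replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(60):
            a = rng.normal(1.7, 0.2, 5)
            b = rng.normal(2.9, 0.9, 6)
            if group_compare(a, b, method="mannwhitney").p_value < 0.05:
                hits += 1
        assert hits > 30

    def test_auto_gate_and_errors(self):
        rng = np.random.default_rng(9)
        rep = group_compare(rng.normal(size=12), rng.normal(size=12), method="auto")
        assert rep.test_name.startswith(("Student", "Mann-Whitney"))
        with pytest.raises(ValueError, match="non-empty"):
            group_compare([], [1.0])

    def test_rank_biserial_range(self):
        rep = group_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], method="mannwhitney")
        assert rep.effect["rank_biserial"] == pytest.approx(1.0)


class TestAncova:
    def test_zero_change_zero_slope(self):
        rng = np.random.default_rng(1)
        rep = ancova_change(np.zeros(20), rng.normal(size=20), rng.normal(size=20))
        assert rep.effect["adjusted_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(2)
        biomarker = rng.normal(size=25)
        baseline = rng.normal(size=25)
        rep = ancova_change(3.0 * biomarker, biomarker, baseline)
        assert rep.effect["adjusted_slope"] == pytest.approx(3.0, abs=1e-9)

    def test_known_slope_recovered_within_2se(self):
        rng = np.random.default_rng(3)
        biomarker = rng.normal(size=500)
        baseline = rng.normal(size=500)
        change = 1.8 * biomarker + 0.5 * baseline + rng.normal(0, 1.0, 500)
        rep = ancova_change(change, biomarker, baseline)
        se = 1.0 / math.sqrt(500)  # approximate slope SE with unit-variance x
        assert rep.effect["adjusted_slope"] == pytest.approx(1.8, abs=2.5 * se)

    def test_collinear_covariates_named(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            ancova_change(np.ones(10), x, 2 * x)


class TestReport:
    def test_empty_cohort_valid_report(self):
        rep = cohort_report(None, None, None)
        assert rep == {"analyses": []}

    def test_report_round_trips(self, tmp_path):
        metrics = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(8) for _ in range(2)],
                "time_min": [60.0, 70.0] * 8,
                "tbr_efm": np.random.default_rng(0).normal(2.2, 0.4, 16),
                "suvmean_efm": np.random.default_rng(1).normal(3.8, 0.5, 16),
            }
        )
        clinical = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(8)],
                "nt_probnp_baseline": np.random.default_rng(2).lognormal(7, 1, 8),
            }
        )
        rep = cohort_report(metrics, None, clinical)
        ids = [a["analysis_id"] for a in rep["analyses"]]
        assert "stability_tbr_efm" in ids
        assert any(i.startswith("tbr_vs_log_ntprobnp") for i in ids)
        write_report(rep, tmp_path / "r.json")
        assert read_report(tmp_path / "r.json") == rep

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(7)
        rep = group_compare(rng.normal(size=8), rng.normal(size=8), method="mannwhitney")
        assert rep.p_adjusted is None or rep.p_adjusted >= rep.p_value


class TestCalibrationQuick:
    """Reduced-replicate null calibration; the full Monte-Carlo version
    runs in the acceptance suite."""

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(77)
        rej_mw = rej_r = 0
        n_rep = 200
        for _ in range(n_rep):
            if group_compare(
                rng.normal(size=20), rng.normal(size=20), method="mannwhitney"
            ).p_value < 0.05:
                rej_mw += 1
            if association(rng.normal(size=19), rng.normal(size=19)).p_value < 0.05:
                rej_r += 1
        assert 0.01 <= rej_mw / n_rep <= 0.10
        assert 0.01 <= rej_r / n_rep <= 0.10
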