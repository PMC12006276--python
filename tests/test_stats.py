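"""Statistical pipeline: normality gating, branch selection, exact
small-sample behavior, and report integrity."""

import json

import numpy as np
import pandas as pd
import pytest

from lexsyn import (
    AnalysisConfig,
    CohortDataset,
    bonferroni_alpha,
    correlate_changes,
    cross_sectional,
    longitudinal_change,
    normality_gate,
    run_full_analysis,
    severity_zscores,
)
from lexsyn.features import FEATURE_NAMES

from oracles import exact_mannwhitney_p, exact_signed_rank_p


def make_dataset(group_values: dict, feature: str = "mlu", followup=None) -> CohortDataset:
    """Build a minimal dataset: one feature, baseline values per group,
    optional followup values aligned by position."""
    rows = []
    for g, vals in group_values.items():
        for i, v in enumerate(vals):
            rows.append(
                {"subject_id": f"{g}{i}", "group": g, "timepoint": "baseline", feature: v}
            )
            if followup is not None:
                rows.append(
                    {
                        "subject_id": f"{g}{i}",
                        "group": g,
                        "timepoint": "followup",
                        feature: followup[g][i],
                    }
                )
    return CohortDataset(pd.DataFrame(rows))


class TestNormalityGate:
    def test_large_normal_sample_passes(self):
        x = np.random.default_rng(42).normal(0, 1, 5000)
        assert normality_gate(x).normal

    def test_large_exponential_sample_fails(self):
        x = np.random.default_rng(42).exponential(1.0, 5000)
        assert not normality_gate(x).normal

    def test_constant_sample_fails(self):
        res = normality_gate([3.0] * 20)
        assert not res.normal
        assert res.note == "zero variance"

    def test_tiny_sample_routes_nonparametric_with_warning(self):
        with pytest.warns(UserWarning, match="n=3"):
            res = normality_gate([1.0, 2.0, 3.0])
        assert not res.normal

    def test_plain_ks_mode_available(self):
        x = np.random.default_rng(0).normal(5, 2, 300)
        res = normality_gate(x, method="ks")
        assert res.method == "ks"
        assert res.normal

    def test_gate_decision_recorded(self):
        res = normality_gate(np.random.default_rng(1).normal(0, 1, 100))
        assert res.p_value is not None and 0 <= res.p_value <= 1
        assert res.n == 100


class TestBonferroni:
    def test_three_feature_family_threshold(self):
        assert round(bonferroni_alpha(0.05, 3), 4) == 0.0167

    def test_identity_and_arithmetic(self):
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.01, 5) == pytest.approx(0.002)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 3)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestCrossSectional:
    def test_identical_groups_no_posthoc(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        ds = make_dataset({"a": vals, "b": vals, "c": vals})
        res = cross_sectional(ds, "mlu")
        assert res.p_value > 0.9
        assert res.pairwise == []
        assert "withheld" in res.note

    def test_separated_groups_nonparametric_extreme_u(self):
        ds = make_dataset({"lo": [1, 2, 3, 4, 5], "hi": [6, 7, 8, 9, 10]})
        res = cross_sectional(ds, "mlu", normality_method="nonparametric")
        assert res.test == "kruskal"
        assert res.p_value < 0.05
        (pw,) = res.pairwise
        assert pw.test == "mannwhitneyu"
        assert pw.statistic in (0.0, 25.0)
        assert pw.p_value == pytest.approx(
            exact_mannwhitney_p([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        )

    def test_parametric_branch_uses_anova_and_lsd(self):
        rng = np.random.default_rng(5)
        ds = make_dataset(
            {
                "a": rng.normal(0, 1, 25),
                "b": rng.normal(0, 1, 25),
                "c": rng.normal(2, 1, 25),
            }
        )
        res = cross_sectional(ds, "mlu")
        assert res.test == "anova"
        assert res.p_value < 0.05
        assert {p.test for p in res.pairwise} == {"fisher_lsd"}
        assert len(res.pairwise) == 3
        # the separated pair must be the strongest contrast
        by_pair = {(p.group_a, p.group_b): p.p_value for p in res.pairwise}
        assert by_pair[("a", "c")] < by_pair[("a", "b")]

    def test_small_group_excluded_with_reason(self):
        ds = make_dataset({"a": [1.0, 2.0, 3.0, 2.5], "b": [2.0], "c": [1.5, 2.5, 3.5, 2.0]})
        res = cross_sectional(ds, "mlu")
        assert "b" in res.excluded
        assert set(res.groups) == {"a", "c"}

    def test_mixed_normality_routes_whole_feature_nonparametric(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(
            {"a": rng.normal(0, 1, 60), "b": rng.exponential(1.0, 60) ** 3}
        )
        res = cross_sectional(ds, "mlu")
        assert res.test == "kruskal"


class TestLongitudinalChange:
    def test_identical_followup_is_no_evidence(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        ds = make_dataset({"g": vals}, followup={"g": vals})
        res = longitudinal_change(ds, "mlu", "g")
        assert res.test == "no_evidence"
        assert res.p_value == 1.0
        assert res.mean_change == 0.0

    def test_all_positive_differences_exact_signed_rank(self):
        base = [10.0, 10.0, 10.0, 10.0, 10.0, 10.0]
        diffs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        ds = make_dataset(
            {"g": base}, followup={"g": [b + d for b, d in zip(base, diffs)]}
        )
        res = longitudinal_change(ds, "mlu", "g", normality_method="nonparametric")
        assert res.test == "wilcoxon"
        assert res.p_value == pytest.approx(2 / 64)  # minimum two-sided tail, n=6
        assert res.p_value == pytest.approx(exact_signed_rank_p(diffs))

    def test_too_few_pairs_excluded(self):
        ds = make_dataset({"g": [1.0, 2.0, 3.0]}, followup={"g": [2.0, 3.0, 4.0]})
        res = longitudinal_change(ds, "mlu", "g")
        assert res.test == "excluded"
        assert "fewer than 4" in res.note

    def test_parametric_branch_on_normal_differences(self):
        rng = np.random.default_rng(3)
        base = rng.normal(10, 1, 40)
        ds = make_dataset(
            {"g": base}, followup={"g": base + rng.normal(0.8, 0.5, 40)}
        )
        res = longitudinal_change(ds, "mlu", "g")
        assert res.test == "paired_t"
        assert res.p_value < 0.001
        assert res.mean_change > 0.5

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_signed_rank_matches_enumeration_for_small_n(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(8):
            # distinct magnitudes, no zeros: exact enumeration applies
            mags = np.sort(rng.uniform(0.5, 10, n)) * rng.choice([-1, 1], n)
            base = rng.normal(20, 3, n)
            ds = make_dataset(
                {"g": list(base)}, followup={"g": list(base + mags)}
            )
            res = longitudinal_change(ds, "mlu", "g", normality_method="nonparametric")
            assert res.test == "wilcoxon"
            assert res.p_value == pytest.approx(exact_signed_rank_p(mags), rel=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (4, 4), (5, 3), (4, 8), (6, 5)])
    def test_mannwhitney_matches_enumeration_for_small_n(self, n1, n2):
        rng = np.random.default_rng(10 * n1 + n2)
        for _ in range(5):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            ds = make_dataset({"a": list(x), "b": list(y)})
            # alpha=1 disables omnibus protection so the post hoc always runs
            res = cross_sectional(ds, "mlu", alpha=1.0, normality_method="nonparametric")
            if not res.pairwise:  # omnibus p exactly 1 (degenerate draw)
                continue
            (pw,) = res.pairwise
            assert pw.p_value == pytest.approx(exact_mannwhitney_p(x, y), rel=1e-12)


class TestCorrelateChanges:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 3.5, 4.0, 6.0, 7.0])
        for y, expected in ((x.copy(), 1.0), (-x, -1.0)):
            res = correlate_changes(x, y)
            assert res.r == pytest.approx(expected)

    def test_zero_variance_excluded(self):
        res = correlate_changes([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert res.test == "excluded"
        assert "zero-variance" in res.note

    def test_too_few_pairs_excluded(self):
        res = correlate_changes([1, 2, 3], [3, 2, 1])
        assert res.test == "excluded"

    def test_spearman_chosen_for_skewed_input(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(1, 300) ** 3
        y = x + rng.exponential(1, 300)
        res = correlate_changes(x, y)
        assert res.test == "spearman"

    def test_pearson_recovers_known_rho(self):
        rng = np.random.default_rng(7)
        rho, n, reps = 0.3, 92, 500
        rs = []
        cov = [[1, rho], [rho, 1]]
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = correlate_changes(xy[:, 0], xy[:, 1])
            rs.append(res.r)
        se = np.std(rs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(rs) - rho) < 3 * se


class TestPipelineCalibration:
    def test_gated_paired_type_I_error_within_band(self):
        """Under Normal and Exponential nulls the adaptive paired test
        keeps its size near the nominal 0.05."""
        rng = np.random.default_rng(123)
        n, reps = 30, 2000
        for sampler in (rng.standard_normal, rng.standard_exponential):
            rejections = 0
            for _ in range(reps):
                base = sampler(n)
                fup = sampler(n)
                ds = make_dataset({"g": list(base)}, followup={"g": list(fup)})
                res = longitudinal_change(ds, "mlu", "g")
                if res.p_value < 0.05:
                    rejections += 1
            rate = rejections / reps
            assert 0.03 <= rate <= 0.07


class TestRunFullAnalysis:
    def small_dataset(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("control", "treated"):
            for i in range(n):
                for tp in ("baseline", "followup"):
                    row = {"subject_id": f"{g}{i}", "group": g, "timepoint": tp}
                    for feat in FEATURE_NAMES:
                        row[feat] = float(rng.normal(10, 2))
                    row["moca"] = float(rng.normal(26, 2))
                    rows.append(row)
        return CohortDataset(pd.DataFrame(rows))

    def test_report_structure_and_flags(self):
        ds = self.small_dataset()
        config = AnalysisConfig(correlation_pairs=(("mlu", "moca"),))
        report = run_full_analysis(ds, config)
        assert report.adjusted_alpha == pytest.approx(0.05 / 3)
        d = report.to_dict()
        json.dumps(d)  # serializable
        assert set(d["cross_sectional"]) == set(FEATURE_NAMES)
        assert set(d["longitudinal"]) == {"control", "treated"}
        for feat in FEATURE_NAMES:
            assert d["cross_sectional"][feat]["p_value"] is None or (
                0 <= d["cross_sectional"][feat]["p_value"] <= 1
            )
        assert len(report.correlations) == 2  # one pair x two groups
        tsv = report.summary_tsv()
        assert tsv.startswith("analysis\tfeature")
        assert "longitudinal\tmlu\ttreated" in tsv

    def test_missing_feature_column_excluded_everywhere(self):
        ds = self.small_dataset()
        df = ds.df.drop(columns=["mattr"])
        report = run_full_analysis(CohortDataset(df))
        assert report.cross_sectional["mattr"].test == "excluded"
        assert "absent" in report.cross_sectional["mattr"].note
        for g in ("control", "treated"):
            assert report.longitudinal[g]["mattr"].test == "excluded"
        assert not report.flags["cross_sectional"]["mattr"]["significant_raw"]

    def test_row_order_and_relabeling_invariance(self):
        ds = self.small_dataset(seed=9)
        report1 = run_full_analysis(ds)
        shuffled = ds.df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        report2 = run_full_analysis(CohortDataset(shuffled))
        relabeled = ds.df.copy()
        relabeled["subject_id"] = "x_" + relabeled["subject_id"]
        report3 = run_full_analysis(CohortDataset(relabeled))
        for feat in FEATURE_NAMES:
            p1 = report1.cross_sectional[feat].p_value
            assert report2.cross_sectional[feat].p_value == pytest.approx(p1)
            assert report3.cross_sectional[feat].p_value == pytest.approx(p1)
            for g in ("control", "treated"):
                q1 = report1.longitudinal[g][feat].p_value
                assert report2.longitudinal[g][feat].p_value == pytest.approx(q1)
                assert report3.longitudinal[g][feat].p_value == pytest.approx(q1)

    def test_dataset_schema_violations_fail_fast(self):
        df = self.small_dataset().df
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            CohortDataset(dup)
        orphan = df[~((df.subject_id == "control0") & (df.timepoint == "baseline"))]
        with pytest.raises(ValueError, match="followup rows without baseline"):
            CohortDataset(orphan)
        with pytest.raises(ValueError, match="missing required columns"):
            CohortDataset(df.drop(columns=["group"]))


class TestSeverityZscores:
    def test_reference_group_baseline_centered_and_oriented(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, mu in (("control", 10.0), ("treated", 8.0)):
            for i in range(40):
                for tp in ("baseline", "followup"):
                    rows.append(
                        {
                            "subject_id": f"{g}{i}", "group": g, "timepoint": tp,
                            "mlu": float(rng.normal(mu, 1)),
                            "dependency_length": float(rng.normal(mu / 10, 0.1)),
                        }
                    )
        ds = CohortDataset(pd.DataFrame(rows))
        z = severity_zscores(ds, reference_group="control")
        ctrl_base = z[(z.group == "control") & (z.timepoint == "baseline")]
        assert abs(ctrl_base["mlu"].mean()) < 1e-9
        # lower MLU than controls = worse performance = higher severity
        assert z[z.group == "treated"]["mlu"].mean() > 0.5
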