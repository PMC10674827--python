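"""Cross-scale statistics: observation alignment, pairwise-complete
correlations, Tukey HSD with compact letters, margin summaries, report."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from fieldscale.errors import ValidationError
from fieldscale.stats import (align_observations, anova_tukey, build_report,
                              correlation_matrix, summary_stats)

#: per-treatment yield values as printed in the trial's yield table (t/ha)
TABLE1 = pd.DataFrame({
    "treatment": [100, 80, 40],
    "marketable": [73.0, 68.2, 50.4],
    "unripen": [23.2, 19.6, 11.4],
    "rotten": [3.9, 6.4, 13.1],
    "total": [100.2, 94.3, 74.9],
})


def yield_table(means, sd, reps=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = [{"treatment": t, "replicate": i, "value": m + rng.normal(0, sd)}
            for t, m in means.items() for i in range(reps)]
    return pd.DataFrame(rows)


class TestAlign:
    def src(self, name, dats, plot="A", **cols):
        return pd.DataFrame({"plot_id": plot, "dat": dats,
                             name: cols.get(name, np.arange(len(dats), dtype=float))})

    def test_identical_keys_fully_dense(self):
        out = align_observations({"x": self.src("x", [56, 62]),
                                  "y": self.src("y", [56, 62])})
        assert len(out) == 2 and out[["x", "y"]].notna().all().all()

    def test_nearest_join_within_tolerance(self):
        out = align_observations({"x": self.src("x", [62]),
                                  "y": self.src("y", [63])}, tolerance=1)
        assert len(out) == 1 and out[["x", "y"]].notna().all().all()

    def test_zero_tolerance_keeps_rows_separate(self):
        out = align_observations({"x": self.src("x", [62]),
                                  "y": self.src("y", [63])}, tolerance=0)
        assert len(out) == 2
        assert out["x"].notna().sum() == 1 and out["y"].notna().sum() == 1

    def test_duplicate_keys_rejected(self):
        bad = pd.DataFrame({"plot_id": ["A", "A"], "dat": [56, 56], "x": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="duplicate"):
            align_observations({"x": bad})

    def test_duplicate_variable_rejected(self):
        with pytest.raises(ValidationError, match="two sources"):
            align_observations({"a": self.src("x", [56]), "b": self.src("x", [62])})


class TestCorrelation:
    def test_exact_linear_relations(self):
        x = np.linspace(0, 1, 20)
        tbl = pd.DataFrame({"plot_id": "A", "dat": range(20),
                            "x": x, "y": 2 * x + 1, "z": -x})
        cm = correlation_matrix(tbl, ["x", "y", "z"])
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert cm.r.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cm.r.values), 1.0)
        assert np.allclose(cm.r.values, cm.r.values.T)

    def test_recovers_generated_correlation(self, rng):
        cov = [[1.0, -0.8], [-0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        tbl = pd.DataFrame({"r": xy[:, 0], "cwsi": xy[:, 1]})
        cm = correlation_matrix(tbl, ["r", "cwsi"])
        assert cm.r.loc["r", "cwsi"] == pytest.approx(-0.8, abs=0.1)
        assert cm.n.loc["r", "cwsi"] == 200

    def test_constant_column_missing_with_warning(self):
        tbl = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": 5.0})
        with pytest.warns(UserWarning, match="constant"):
            cm = correlation_matrix(tbl, ["x", "c"])
        assert np.isnan(cm.r.loc["x", "c"])

    def test_minimum_pair_count_enforced(self):
        tbl = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan],
                            "y": [np.nan, 4.0, 1.0, np.nan]})
        cm = correlation_matrix(tbl, ["x", "y"], min_pairs=3)
        assert np.isnan(cm.r.loc["x", "y"]) and cm.n.loc["x", "y"] == 1


class TestTukey:
    def test_identical_groups_share_one_letter(self):
        tbl = pd.DataFrame({"treatment": [100, 100, 80, 80, 40, 40],
                            "total": [5.0] * 6})
        res = anova_tukey(tbl, "total")
        assert set(res.letters.values()) == {"a"}

    def test_deficit_group_separates(self):
        tbl = yield_table({100: 100.2, 80: 94.3, 40: 74.9}, sd=3.0, seed=2)
        res = anova_tukey(tbl, "value")
        assert res.letters[40] == "b"
        assert res.letters[100] == res.letters[80] == "a"

    def test_agrees_with_reference_implementation(self):
        tbl = yield_table({100: 100.2, 80: 94.3, 40: 74.9}, sd=3.0, seed=2)
        res = anova_tukey(tbl, "value")
        ref = pairwise_tukeyhsd(tbl["value"], tbl["treatment"], alpha=0.05)
        pairs = [(int(r[0]), int(r[1])) for r in ref.summary().data[1:]]
        for (a, b), p in zip(pairs, ref.pvalues):
            assert res.pairwise_p.loc[a, b] == pytest.approx(p, abs=1e-6)

    def test_two_group_case_matches_anova(self):
        tbl = yield_table({100: 100.0, 40: 60.0}, sd=2.0, seed=4)
        res = anova_tukey(tbl, "value")
        assert res.letters[100] != res.letters[40]
        assert res.anova_p < 0.05
        # Tukey p for k=2 equals the ANOVA/t-test p
        assert res.pairwise_p.loc[100, 40] == pytest.approx(res.anova_p, abs=1e-9)

    def test_overlapping_chain_gets_bridging_letters(self):
        # adjacent groups indistinguishable, extremes distinct -> a / ab / b
        tbl = yield_table({1: 0.0, 2: 2.6, 3: 5.2}, sd=1.0, reps=4, seed=8)
        res = anova_tukey(tbl, "value")
        p = res.pairwise_p
        letters = res.letters
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                if a >= b:
                    continue
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (p.loc[a, b] > res.alpha)

    def test_single_replicate_rejected(self):
        tbl = pd.DataFrame({"treatment": [100, 40], "total": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            anova_tukey(tbl, "total")


class TestSummaryStats:
    def test_margin_means_match_printed_table(self):
        out = summary_stats(TABLE1)
        assert out.loc["marketable", "mean"].round(1) == 63.9
        assert out.loc["unripen", "mean"].round(1) == 18.1
        assert out.loc["rotten", "mean"].round(1) == 7.8
        assert out.loc["total", "mean"].round(1) == 89.8

    def test_identical_treatments_have_zero_cv(self):
        tbl = pd.DataFrame({"treatment": [100, 80, 40], "total": [10.0] * 3})
        assert summary_stats(tbl, traits=("total",)).loc[
            "total", "cv_across_means_percent"] == pytest.approx(0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            summary_stats(pd.DataFrame())


class TestReport:
    def test_partial_pipeline_marks_sections_absent(self):
        with pytest.warns(UserWarning, match="absent"):
            report = build_report({"rgb_indices": TABLE1.assign(plot_id="A", dat=1)},
                                  seed=3)
        assert report["sections"]["cwsi"] is None
        assert report["sections"]["rgb_indices"] is not None

    def test_report_is_json_serializable(self, default_result):
        import json
        json.dumps(default_result.report)
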