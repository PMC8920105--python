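"""Cohort statistics: outlier classification, group tests, correlations,
and the end-to-end pipeline contract."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from warfarin_pkpd import classify_outliers, compare_groups, correlations, run_pipeline
from warfarin_pkpd.config import PipelineConfig, load_config
from warfarin_pkpd.errors import PipelineError


class TestClassifyOutliers:
    def test_single_far_point(self):
        values = [1.0] * 9 + [1.0001] + [100.0]
        cls = classify_outliers(values)
        assert cls.n_outside == 1
        assert cls.flags[-1] == "outside"
        assert cls.n_within + cls.n_outside == len(values)

    def test_normal_rate_close_to_five_percent(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100_000)
        cls = classify_outliers(x, z=1.96)
        assert cls.n_outside / x.size == pytest.approx(0.05, abs=0.005)

    def test_infinite_z_flags_nothing(self):
        cls = classify_outliers(np.arange(10.0), z=np.inf)
        assert cls.n_outside == 0

    def test_one_sided_options(self):
        x = np.concatenate([np.zeros(20), [10.0], [-10.0], np.ones(20)])
        lower = classify_outliers(x, sided="lower")
        upper = classify_outliers(x, sided="upper")
        assert lower.upper == np.inf and upper.lower == -np.inf
        assert lower.flags[np.argmin(x)] == "outside"
        assert lower.flags[np.argmax(x)] == "within"
        assert upper.flags[np.argmax(x)] == "outside"

    def test_zero_sd_error(self):
        with pytest.raises(ValueError, match="zero SD"):
            classify_outliers([2.0, 2.0, 2.0])


def exact_mannwhitney_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group labels
    (independent oracle for small samples, no ties)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx_a):
        ranks = stats.rankdata(pooled)
        u = sum(ranks[i] for i in idx_a) - n_a * (n_a + 1) / 2
        return u

    observed = u_stat(range(n_a))
    mu = n_a * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(combo) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        df = pd.DataFrame({"x": np.arange(20.0), "flag": [0, 1] * 10})
        out = compare_groups(df, df.copy(), numeric_vars=["x"],
                             categorical_vars=["flag"])
        assert (out["p_value"] >= 0.95).all()

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame({"x": rng.normal(0, 1, 50)})
        b = pd.DataFrame({"x": rng.normal(5, 1, 50)})
        out = compare_groups(a, b, numeric_vars=["x"])
        assert out["p_value"].iloc[0] < 1e-6

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        a = pd.DataFrame({"x": rng.normal(0, 1, 30), "c": rng.integers(0, 2, 30)})
        b = pd.DataFrame({"x": rng.normal(0.5, 1, 25), "c": rng.integers(0, 2, 25)})
        p_ab = compare_groups(a, b, ["x"], ["c"])["p_value"].to_numpy()
        p_ba = compare_groups(b, a, ["x"], ["c"])["p_value"].to_numpy()
        np.testing.assert_allclose(p_ab, p_ba, rtol=1e-12)

    def test_mannwhitney_matches_exact_enumeration(self):
        a = [1.3, 2.9, 0.4, 5.6]
        b = [3.1, 4.8, 6.2, 7.7, 2.2]
        out = compare_groups(
            pd.DataFrame({"x": a}), pd.DataFrame({"x": b}), numeric_vars=["x"]
        )
        # compare against brute-force permutation null of the U statistic
        expected = exact_mannwhitney_p(a, b)
        got = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
        assert got == pytest.approx(expected, abs=1e-12)
        # the table's asymptotic/exact choice must agree with scipy's default
        assert out["p_value"].iloc[0] == pytest.approx(
            float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), abs=1e-12
        )

    def test_small_group_variable_skipped(self):
        a = pd.DataFrame({"x": [1.0], "y": [1.0, 2.0, 3.0][:1]})
        b = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = compare_groups(a, b, numeric_vars=["x"])
        assert len(out) == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(pd.DataFrame(), pd.DataFrame({"x": [1.0]}), ["x"])

    def test_holm_column_monotone(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame({f"v{i}": rng.normal(0, 1, 40) for i in range(4)})
        b = pd.DataFrame({f"v{i}": rng.normal(0.8, 1, 40) for i in range(4)})
        out = compare_groups(a, b, numeric_vars=[f"v{i}" for i in range(4)])
        assert (out["p_holm"] >= out["p_value"] - 1e-15).all()


class TestCorrelations:
    def test_perfect_linear(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"]
        out = correlations(df, [("x", "y")])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_negative_limit(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 500)
        df = pd.DataFrame({"x": x, "y": -x + rng.normal(0, 1e-6, 500)})
        assert correlations(df, [("x", "y")])["r"].iloc[0] == pytest.approx(-1.0, abs=1e-6)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x": rng.normal(size=10_000), "y": rng.normal(size=10_000)})
        assert abs(correlations(df, [("x", "y")])["r"].iloc[0]) < 0.05

    def test_closed_form_oracle(self):
        """r matches the explicit sum formula (independent of scipy)."""
        rng = np.random.default_rng(12)
        x = rng.normal(2, 1.5, 50)
        y = 0.6 * x + rng.normal(0, 1, 50)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        df = pd.DataFrame({"x": x, "y": y})
        assert correlations(df, [("x", "y")])["r"].iloc[0] == pytest.approx(
            r_hand, abs=1e-12
        )

    def test_constant_vector_error(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            correlations(df, [("x", "y")])


@pytest.fixture(scope="module")
def small_report(tmp_path_factory):
    cfg = load_config(None, generator={"n_patients": 30, "seed": 13})
    out = tmp_path_factory.mktemp("report")
    report = run_pipeline(cfg, out)
    return cfg, out, report


class TestRunPipeline:

    def test_bundle_files_written(self, small_report):
        _, out, _ = small_report
        for name in ("summary.tsv", "comparisons.tsv", "correlations.tsv",
                     "report.json", "parameters.tsv", "indices.tsv", "truth.tsv"):
            assert (out / name).exists(), name
        assert any(out.glob("outliers_*.tsv"))

    def test_group_counts_conserve_cohort_size(self, small_report):
        cfg, _, report = small_report
        n = cfg.generator.n_patients
        for param, info in report["outliers"].items():
            assert info["n_within"] + info["n_outside"] == n

    def test_report_p_values_and_r_in_range(self, small_report):
        _, _, report = small_report
        for row in report["comparisons"]:
            assert 0.0 <= row["p_value"] <= 1.0
        for row in report["correlations"]:
            assert -1.0 <= row["r"] <= 1.0
            assert 0.0 <= row["p_value"] <= 1.0

    def test_determinism_byte_identical(self, tmp_path):
        cfg = load_config(None, generator={"n_patients": 12, "seed": 99})
        run_pipeline(cfg, tmp_path / "a")
        run_pipeline(cfg, tmp_path / "b")
        for name in ("summary.tsv", "comparisons.tsv", "correlations.tsv",
                     "report.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_empty_cohort_clean_error(self, tmp_path):
        with pytest.raises(ValueError):
            load_config(None, generator={"n_patients": 0})
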