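"""Agreement statistics against independent oracles, and bootstrap machinery.

The ICC oracle estimates variance components from an explicit two-way
ANOVA written with plain Python loops; the kappa oracle evaluates the
weighted observed/expected disagreement by looping over all rater pairs.
Both routes are algebraically independent of the vectorized
implementations, and reference implementations (pingouin, scikit-learn)
are consulted as a third opinion on a subset of tables.
"""

import numpy as np
import pandas as pd
import pytest

from ihirate.evaluation import (
    UndefinedMetricError,
    bootstrap_metric,
    cohen_kappa,
    compare_methods,
    evaluate_run,
    icc,
    icc_metric,
)
from ihirate.ratings import Criterion, criterion_grid


# ---------------------------------------------------------------------------
# oracles

def icc_oracle(a, b, variant="icc2"):
    """Variance-components route: estimate sigma^2 terms from the ANOVA."""
    data = [[float(x), float(y)] for x, y in zip(a, b)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    var_subject = (msr - mse) / k
    var_rater = (msc - mse) / n
    if variant == "icc2":
        return var_subject / (var_subject + var_rater + mse)
    return var_subject / (var_subject + mse)  # consistency: rater variance excluded


def kappa_oracle(a, b, weighting, categories):
    """All-pairs route: observed disagreement vs disagreement between all
    (a_i, b_j) pairs (the empirical chance expectation)."""
    cats = sorted(categories)
    index = {c: i for i, c in enumerate(cats)}
    m = len(cats)

    def w(i, j):
        if weighting == "quadratic":
            return (i - j) ** 2 / (m - 1) ** 2
        return 0.0 if i == j else 1.0

    n = len(a)
    observed = sum(w(index[x], index[y]) for x, y in zip(a, b)) / n
    expected = sum(
        w(index[x], index[y]) for x in a for y in b
    ) / (n * n)
    return 1.0 - observed / expected


def random_rating_table(rng):
    n = int(rng.integers(6, 25))
    a = rng.normal(0, 1, n)
    b = 0.7 * a + rng.normal(0.2, 0.6, n)
    return a, b


# ---------------------------------------------------------------------------

class TestIcc:
    def test_perfect_agreement(self):
        a = np.array([0.0, 1, 2, 3, 4, 5.5])
        assert icc(a, a) == pytest.approx(1.0)

    def test_six_subject_toy_table_matches_oracle(self):
        a = [9.0, 6.0, 8.0, 7.0, 10.0, 6.0]
        b = [2.0, 1.0, 4.0, 1.0, 5.0, 2.0]
        assert icc(a, b, "icc2") == pytest.approx(icc_oracle(a, b, "icc2"), abs=1e-10)
        assert icc(a, b, "icc3") == pytest.approx(icc_oracle(a, b, "icc3"), abs=1e-10)

    def test_oracle_agreement_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b = random_rating_table(rng)
            for variant in ("icc2", "icc3"):
                assert icc(a, b, variant) == pytest.approx(
                    icc_oracle(a, b, variant), abs=1e-10
                )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        for _ in range(5):
            a, b = random_rating_table(rng)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(len(a)), 2),
                    "raters": np.tile([0, 1], len(a)),
                    "ratings": np.column_stack([a, b]).ravel(),
                }
            )
            res = pg.intraclass_corr(
                df, targets="targets", raters="raters", ratings="ratings"
            )
            ref2 = float(res.loc[res.Type == "ICC(A,1)", "ICC"].iloc[0])
            ref3 = float(res.loc[res.Type == "ICC(C,1)", "ICC"].iloc[0])
            assert icc(a, b, "icc2") == pytest.approx(ref2, abs=1e-9)
            assert icc(a, b, "icc3") == pytest.approx(ref3, abs=1e-9)

    def test_absolute_agreement_penalizes_constant_shift(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 40)
        b = a + 3.0  # systematic offset, perfect consistency
        assert icc(a, b, "icc3") == pytest.approx(1.0, abs=1e-9)
        assert icc(a, b, "icc2") < icc(a, b, "icc3")

    def test_degenerate_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            icc(np.ones(10), np.ones(10))


class TestKappa:
    def test_perfect_agreement(self):
        a = [0, 1, 2, 0, 1]
        assert cohen_kappa(a, a, "none", [0, 1, 2]) == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        # confusion [[45, 5], [5, 45]]: p_o = 0.9, p_e = 0.5 -> kappa 0.8
        a = [0] * 50 + [1] * 50
        b = [0] * 45 + [1] * 5 + [0] * 5 + [1] * 45
        assert cohen_kappa(a, b, "none", [0, 1]) == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("weighting", ["none", "quadratic"])
    def test_oracle_agreement_on_random_tables(self, weighting):
        rng = np.random.default_rng(21)
        cats = list(criterion_grid(Criterion.C1))
        for _ in range(100):
            n = int(rng.integers(8, 40))
            a = rng.choice(cats, n)
            b = rng.choice(cats, n)
            try:
                ours = cohen_kappa(a, b, weighting, cats)
            except UndefinedMetricError:
                continue
            assert ours == pytest.approx(kappa_oracle(a, b, weighting, cats), abs=1e-10)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(22)
        cats = [0.0, 0.5, 1.0, 1.5, 2.0]
        for _ in range(10):
            a = rng.choice(cats, 30)
            b = rng.choice(cats, 30)
            ref = sk.cohen_kappa_score(
                (np.asarray(a) * 2).astype(int),
                (np.asarray(b) * 2).astype(int),
                labels=[0, 1, 2, 3, 4],
                weights="quadratic",
            )
            assert cohen_kappa(a, b, "quadratic", cats) == pytest.approx(ref, abs=1e-10)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(23)
        a = rng.choice([0, 1, 2], 2000)
        b = rng.choice([0, 1, 2], 2000)
        assert abs(cohen_kappa(a, b, "none", [0, 1, 2])) < 0.1

    def test_unobserved_categories_weight_correctly(self):
        # declared 5-level grid, only extremes observed: quadratic weights
        # must still use the full grid span
        a = [0.0, 2.0, 0.0, 2.0, 0.0]
        b = [0.0, 2.0, 2.0, 0.0, 0.0]
        cats = [0.0, 0.5, 1.0, 1.5, 2.0]
        assert cohen_kappa(a, b, "quadratic", cats) == pytest.approx(
            kappa_oracle(a, b, "quadratic", cats), abs=1e-12
        )

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cohen_kappa([1, 1, 1], [1, 1, 1], "none", [0, 1, 2])

    def test_off_grid_values_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            cohen_kappa([0.3, 1.0], [0.0, 1.0], "none", [0.0, 0.5, 1.0])


class TestBootstrap:
    def test_constant_perfect_agreement(self):
        truth = np.tile([1.0, 3.0], 25)
        res = bootstrap_metric(icc_metric(), truth, truth, seed=4)
        assert res.point == pytest.approx(1.0)
        assert res.boot_se == pytest.approx(0.0, abs=1e-12)
        assert res.ci_upper - res.ci_lower == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(30)
        truth = rng.normal(0, 1, 60)
        pred = truth + rng.normal(0, 0.5, 60)
        r1 = bootstrap_metric(icc_metric(), truth, pred, seed=9)
        r2 = bootstrap_metric(icc_metric(), truth, pred, seed=9)
        assert r1.boot_mean == r2.boot_mean and r1.boot_se == r2.boot_se
        np.testing.assert_array_equal(r1.indices, r2.indices)

    def test_ci_ordering_over_many_datasets(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            truth = rng.normal(0, 1, n)
            pred = truth + rng.normal(0, rng.uniform(0.1, 2.0), n)
            res = bootstrap_metric(icc_metric(), truth, pred, seed=int(rng.integers(1 << 31)))
            assert res.ci_lower <= res.ci_upper

    def test_monotone_degradation_with_noise(self):
        rng = np.random.default_rng(32)
        truth = rng.normal(0, 1, 300)
        means = []
        for sd in (0.1, 0.5, 1.0, 2.0):
            vals = []
            for seed in range(5):
                noise = np.random.default_rng(seed).normal(0, sd, 300)
                vals.append(
                    bootstrap_metric(icc_metric(), truth, truth + noise, seed=seed).boot_mean
                )
            means.append(np.mean(vals))
        assert all(np.diff(means) < 0)


class TestCompareMethods:
    def test_identical_predictions_not_significant(self):
        rng = np.random.default_rng(40)
        truth = rng.normal(0, 1, 80)
        pred = truth + rng.normal(0, 0.4, 80)
        res = compare_methods(truth, pred, pred, icc_metric(), seed=1)
        assert res.mean_difference == 0.0
        assert res.p == 1.0 and not res.significant

    def test_obviously_better_method_significant_after_correction(self):
        rng = np.random.default_rng(41)
        truth = rng.normal(0, 1, 200)
        good = truth.copy()
        bad = truth + rng.normal(0, 2.0, 200)
        res = compare_methods(truth, good, bad, icc_metric(), seed=2, m_tests=5)
        assert res.significant and res.mean_difference > 0

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(42)
        truth = rng.normal(0, 1, 100)
        a = truth + rng.normal(0, 0.5, 100)
        b = truth + rng.normal(0, 0.6, 100)
        r1 = compare_methods(truth, a, b, icc_metric(), seed=3, m_tests=1)
        r4 = compare_methods(truth, a, b, icc_metric(), seed=3, m_tests=4)
        assert r4.p_adjusted == pytest.approx(min(1.0, 4 * r1.p))
        assert r1.p == r4.p

    def test_replicates_share_index_sets(self):
        # same seed => bootstrap_metric and compare_methods agree replicate
        # by replicate for the common method
        rng = np.random.default_rng(43)
        truth = rng.normal(0, 1, 50)
        a = truth + rng.normal(0, 0.3, 50)
        b = truth + rng.normal(0, 0.3, 50)
        res_a = bootstrap_metric(icc_metric(), truth, a, seed=7)
        res_b = bootstrap_metric(icc_metric(), truth, b, seed=7)
        comp = compare_methods(truth, a, b, icc_metric(), seed=7)
        np.testing.assert_allclose(
            comp.differences, res_a.replicates - res_b.replicates
        )


class TestEvaluateRun:
    def _tables(self, n=40, seed=50, cohorts=("a", "b")):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            for hemi in ("left", "right"):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "hemisphere": hemi,
                        "c1": rng.choice([0, 0.5, 1, 1.5, 2]),
                        "c2": rng.choice([0, 0.5, 1, 1.5, 2]),
                        "c3": rng.choice([0, 0.5, 1, 1.5, 2]),
                        "c5": rng.choice([0, 1, 2]),
                        "rater_id": "CC",
                        "cohort": cohorts[i % len(cohorts)],
                    }
                )
        frame = pd.DataFrame(rows)
        frame["composite"] = frame[["c1", "c2", "c3", "c5"]].sum(axis=1)
        frame["ihi_flag"] = (frame["composite"] >= 4).astype(int)
        return frame

    def test_perfect_predictions(self):
        truth = self._tables()
        report = evaluate_run(truth, truth.copy(), n_boot=20, seed=0)
        assert np.allclose(report.rows["point"], 1.0)
        assert (report.confusion[["fp", "fn"]].to_numpy() == 0).all()

    def test_report_shape(self):
        truth = self._tables()
        report = evaluate_run(truth, truth.copy(), n_boot=10, seed=0)
        # 2 hemispheres x 3 groups (pooled + 2 cohorts) x 5 metrics
        assert len(report.rows) == 2 * 3 * 5
        assert len(report.confusion) == 2 * 3

    def test_single_cohort_collapses_to_pooled(self):
        truth = self._tables(cohorts=("only",))
        report = evaluate_run(truth, truth.copy(), n_boot=10, seed=0)
        assert set(report.rows["group"]) == {"pooled"}

    def test_unrounded_predictions_rejected(self):
        truth = self._tables()
        pred = truth.copy()
        pred.loc[0, "c1"] = 0.37
        with pytest.raises(ValueError, match="off-grid"):
            evaluate_run(truth, pred)
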