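"""Stratification, MC splitting, metrics, nested CV and report aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spectroml import FeatureSpec, GaussianProcessBasisRegressor, get_preset
from spectroml.baselines import LinearBaselineRegressor
from spectroml.evaluation import (
    SplitPlan,
    learning_curve,
    mc_evaluate,
    mc_split,
    metrics,
    nested_cv_select,
    stratify,
)


class TestStratify:
    def test_quantile_blocking(self):
        strata = stratify(np.arange(1, 51), 25)
        # labels 1..50 -> blocks {1,2},{3,4},...
        np.testing.assert_array_equal(strata, np.repeat(np.arange(25), 2))

    def test_degenerate_ties(self):
        strata = stratify(np.ones(10), 4)
        sizes = np.bincount(strata)
        assert sizes.max() - sizes.min() <= 1

    def test_singleton_strata(self):
        strata = stratify(np.random.default_rng(0).normal(size=8), 8)
        assert sorted(strata) == list(range(8))

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            stratify([1.0, 2.0], 3)

    def test_stable_tie_order(self):
        strata = stratify([5.0, 5.0, 5.0, 5.0], 2)
        np.testing.assert_array_equal(strata, [0, 0, 1, 1])


class TestMcSplit:
    def setup_method(self):
        self.labels = np.random.default_rng(1).normal(size=60)
        self.plan = SplitPlan(n_strata=25, n_test=25, n_mc=10, seed=3)
        self.strata = stratify(self.labels, 25)

    def test_sizes_and_disjointness(self):
        train, test = mc_split(self.strata, self.plan, 0)
        assert len(test) == 25
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 60

    def test_determinism(self):
        a = mc_split(self.strata, self.plan, 4)
        b = mc_split(self.strata, self.plan, 4)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        c = mc_split(self.strata, self.plan, 5)
        assert not np.array_equal(a[1], c[1])

    def test_one_per_stratum_when_matched(self):
        labels = np.random.default_rng(2).normal(size=50)
        strata = stratify(labels, 25)
        _, test = mc_split(strata, SplitPlan(25, 25, 1, 0), 0)
        assert sorted(strata[test]) == list(range(25))

    def test_binomial_test_frequency(self):
        """Over many reps each molecule is tested at rate ≈ n_test/n (4σ bound)."""
        labels = np.random.default_rng(3).normal(size=50)
        strata = stratify(labels, 25)
        plan = SplitPlan(25, 25, 400, seed=9)
        counts = np.zeros(50)
        for rep in range(plan.n_mc):
            _, test = mc_split(strata, plan, rep)
            counts[test] += 1
        p = 0.5  # strata of size 2, one tested each rep
        sigma = np.sqrt(plan.n_mc * p * (1 - p))
        assert np.all(np.abs(counts - plan.n_mc * p) <= 4 * sigma)


class TestMetrics:
    def test_perfect_prediction(self):
        assert metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_hand_computed(self):
        m = metrics([0.0, 2.0], [1.0, 1.0])
        assert m.mae == 1.0 and m.rmse == 1.0 and m.r_e == 50.0

    def test_constant_error(self):
        m = metrics([1.0, 2.0, 4.0], [1.5, 2.5, 4.5])
        assert m.mae == pytest.approx(m.rmse) == pytest.approx(0.5)

    def test_fixed_range_denominator(self):
        m = metrics([0.0, 1.0], [0.5, 1.5], y_range=10.0)
        assert m.r_e == pytest.approx(100 * m.rmse / 10.0)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0, 1.0], [1.0, 2.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            metrics([1.0], [1.0, 2.0])


MATCHED = FeatureSpec("matched", "Re", ("g_bar", "p_bar"), augment=False)


def _gp(seed=0, restarts=2):
    return GaussianProcessBasisRegressor(
        kernel="matern52", basis="linear", n_restarts=restarts, random_state=seed
    )


class TestNestedCv:
    def test_single_candidate(self, tiny_dataset):
        ds, _ = tiny_dataset
        mols = ds.molecules()
        idx = np.arange(len(mols))
        winner, diag = nested_cv_select(mols, idx[:30], [(MATCHED, _gp())], seed=1)
        assert winner == 0
        assert np.isfinite(diag.loc[0, "cv_rmse"])

    def test_deterministic_given_seed(self, tiny_dataset):
        ds, _ = tiny_dataset
        mols = ds.molecules()
        idx = np.arange(30)
        cands = [(MATCHED, _gp()), (get_preset("table1_Re_lr"), LinearBaselineRegressor())]
        w1, d1 = nested_cv_select(mols, idx, cands, seed=2)
        w2, d2 = nested_cv_select(mols, idx, cands, seed=2)
        assert w1 == w2
        pd.testing.assert_frame_equal(d1, d2)

    def test_true_model_beats_misspecified(self, smooth_dataset):
        """The generating-surface GP wins the CV against a wrong linear rule."""
        ds, _ = smooth_dataset
        mols = ds.molecules()
        cands = [(MATCHED, _gp()), (get_preset("table1_Re_lr"), LinearBaselineRegressor())]
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(len(mols), size=80, replace=False))
            winner, _ = nested_cv_select(mols, idx, cands, seed=seed)
            wins += winner == 0
        assert wins >= 4


class TestMcEvaluate:
    def test_count_conservation(self, tiny_dataset):
        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=2, seed=1)
        report = mc_evaluate(ds, MATCHED, _gp(), plan)
        pm = report.per_molecule
        np.testing.assert_array_equal(pm["n_train"] + pm["n_test"], 2)
        assert (report.per_rep["test_rmse"] > 0).all()

    def test_metric_sd_positive_when_splits_differ(self, tiny_dataset):
        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=4, seed=2)
        report = mc_evaluate(ds, get_preset("table1_Re_lr"), LinearBaselineRegressor(), plan)
        assert report.per_rep["test_mae"].std() > 0

    def test_bit_reproducible(self, tiny_dataset):
        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=3, seed=5)
        r1 = mc_evaluate(ds, MATCHED, _gp(), plan)
        r2 = mc_evaluate(ds, MATCHED, _gp(), plan)
        pd.testing.assert_frame_equal(r1.per_rep, r2.per_rep)
        pd.testing.assert_frame_equal(r1.per_molecule, r2.per_molecule)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)

    def test_aggregation_identity(self, tiny_dataset):
        """Count-weighted per-molecule means reproduce pooled metrics exactly."""
        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=5, seed=3)
        report = mc_evaluate(ds, get_preset("table1_Re_lr"), LinearBaselineRegressor(), plan)
        pm = report.per_molecule
        pooled_from_molecules = (
            (pm["test_abs_err_mean"] * pm["n_test"]).sum() / pm["n_test"].sum()
        )
        # recompute pooled MAE from the stored per-rep prediction matrix
        errs = np.abs(report.predictions - pm["y_true"].to_numpy())
        pooled_from_reps = errs[report.roles == 1].mean()
        assert pooled_from_molecules == pytest.approx(pooled_from_reps, abs=1e-12)
        assert report.per_rep["test_mae"].mean() == pytest.approx(
            pooled_from_reps, abs=1e-12
        )

    def test_hat_feature_runs_leakage_free(self, tiny_dataset):
        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=2, seed=4)
        spec = get_preset("table1_we_gp_hat")
        report = mc_evaluate(ds, spec, _gp(), plan)
        assert len(report.per_rep) == 2

    def test_report_json_serializable(self, tiny_dataset):
        import json

        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=2, seed=6)
        report = mc_evaluate(ds, get_preset("table1_Re_lr"), LinearBaselineRegressor(), plan)
        doc = json.loads(report.to_json())
        assert doc["metadata"]["plan"]["n_mc"] == 2
        assert len(doc["per_molecule"]) == len(report.per_molecule)


class TestLearningCurve:
    def test_full_size_consistent_with_mc_evaluate(self, tiny_dataset):
        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=4, seed=8)
        table = learning_curve(ds, MATCHED, _gp(), sizes=[30], n_mc=4, plan=plan)
        report = mc_evaluate(ds, MATCHED, _gp(), plan)
        # N = full training size (40 - 10) subsamples nothing beyond the split
        assert table.loc[0, "test_rmse_mean"] == pytest.approx(
            report.per_rep["test_rmse"].mean(), rel=0.35
        )

    def test_small_sizes_skipped(self, tiny_dataset, caplog):
        ds, _ = tiny_dataset
        plan = SplitPlan(n_strata=10, n_test=10, n_mc=2, seed=9)
        with caplog.at_level("WARNING"):
            table = learning_curve(ds, MATCHED, _gp(), sizes=[2, 15], n_mc=2, plan=plan)
        assert list(table["N"]) == [15]

    def test_variance_band_shrinks_with_reps(self, tiny_dataset):
        """sd of the mean scales like 1/√n_mc (CLT): 4× reps → ≈2× narrower."""
        ds, _ = tiny_dataset
        spec = get_preset("table1_Re_lr")
        model = LinearBaselineRegressor()
        sds = {}
        for n_mc in (4, 16):
            plan = SplitPlan(n_strata=10, n_test=10, n_mc=n_mc, seed=10)
            t = learning_curve(ds, spec, model, sizes=[25], n_mc=n_mc, plan=plan)
            sds[n_mc] = t.loc[0, "test_rmse_sd"] / np.sqrt(n_mc)
        ratio = sds[4] / sds[16]
        assert 1.0 < ratio < 4.0  # ≈2 with MC slack
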