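"""Correlation screening, the replication split, model fits and metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import uavpheno as up
from uavpheno.errors import ValidationError
from uavpheno.indices import INDEX_ORDER
from uavpheno.modeling import MP_COLUMNS, fit_model, regression_metrics


def vectors_with_exact_r(n, r, seed=0):
    """Two vectors whose sample Pearson correlation is exactly r (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n)
    e = rng.normal(size=n)
    y = (y - y.mean()) / y.std()
    e = e - e.mean()
    e -= (e @ y) / (y @ y) * y
    e /= np.sqrt((e**2).mean())
    x = r * y + np.sqrt(1 - r**2) * e
    return x, y


class TestPearsonScreen:
    def test_identity_and_antisymmetry(self):
        y = np.arange(10.0)
        table = up.pearson_screen(pd.DataFrame({"same": y, "neg": -y}), y)
        t = table.set_index("feature")
        assert t.loc["same", "r"] == pytest.approx(1.0)
        assert t.loc["neg", "r"] == pytest.approx(-1.0)
        assert t.loc["same", "p"] < 1e-10 and bool(t.loc["same", "significant"])

    def test_critical_r_at_n48(self):
        """At n=48 the alpha=0.01 critical |r| is t/sqrt(t^2+46) ~ 0.368."""
        t_crit = stats.t.ppf(0.995, 46)
        r_crit = t_crit / np.sqrt(t_crit**2 + 46)
        assert r_crit == pytest.approx(0.368, abs=0.001)
        x40, y = vectors_with_exact_r(48, 0.40)
        x35, _ = vectors_with_exact_r(48, 0.35)
        table = up.pearson_screen(pd.DataFrame({"strong": x40, "weak": x35}), y)
        t = table.set_index("feature")
        assert bool(t.loc["strong", "significant"])
        assert not bool(t.loc["weak", "significant"])

    def test_zero_variance_flagged(self):
        y = np.arange(6.0)
        with pytest.warns(UserWarning, match="zero variance"):
            table = up.pearson_screen(pd.DataFrame({"flat": np.ones(6)}), y)
        assert np.isnan(table["r"].iloc[0]) and not table["significant"].iloc[0]

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            up.pearson_screen(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1.0, 2.0]))


class TestTopVISelection:
    def make_table(self, rs):
        return pd.DataFrame({"feature": list(INDEX_ORDER), "r": rs, "p": 0.0, "significant": True})

    def test_ordering(self):
        rs = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        assert up.select_top_vis(self.make_table(rs)) == list(INDEX_ORDER[:5])

    def test_absolute_value_and_tie_break(self):
        # GLA and GLI tie at |r|=0.7 for 5th place; GLA is earlier in registry
        rs = [0.9, -0.85, 0.8, 0.75, 0.7, -0.7, 0.1, 0.1, 0.1, 0.1]
        top = up.select_top_vis(self.make_table(rs))
        assert top == ["R", "G", "B", "GRRI", "GLA"]

    def test_k_equals_all(self):
        rs = np.linspace(0.9, 0.1, 10)
        assert up.select_top_vis(self.make_table(rs), k=10) == list(INDEX_ORDER)

    def test_mps_never_selected(self):
        table = self.make_table(np.linspace(0.9, 0.1, 10))
        table = pd.concat(
            [table, pd.DataFrame({"feature": ["H_cm"], "r": [0.99], "p": [0.0], "significant": [True]})]
        )
        assert "H_cm" not in up.select_top_vis(table)

    def test_insufficient_finite(self):
        table = self.make_table([0.9, 0.8, np.nan] + [np.nan] * 7)
        with pytest.raises(ValidationError):
            up.select_top_vis(table)


class TestReplicationSplit:
    def test_default_design_sizes(self, design):
        df = pd.DataFrame({"plot_id": [r.plot_id for _, r in design], "replication": [r.replication for _, r in design]})
        train, val = up.split_by_replication(df)
        assert len(train) == 32 and len(val) == 16
        assert set(train["replication"]) == {1, 3} and set(val["replication"]) == {2}
        assert len(pd.concat([train, val])) == 48
        assert not set(train["plot_id"]) & set(val["plot_id"])

    def test_missing_partition_rejected(self):
        with pytest.raises(ValidationError, match="training"):
            up.split_by_replication(pd.DataFrame({"replication": [2, 2, 2]}))
        with pytest.raises(ValidationError, match="validation"):
            up.split_by_replication(pd.DataFrame({"replication": [1, 3]}))


class TestFitModel:
    def test_mlr_exact_linear(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = 1.5 + X @ np.array([2.0, -1.0, 0.5])
        m = fit_model("MLR", X, y)
        assert np.allclose(m.predict(X), y, atol=1e-9)
        assert np.allclose(m.coef_, [2.0, -1.0, 0.5], atol=1e-9)

    def test_mlr_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(32, 2))
        y = 2 * X[:, 0] - X[:, 1] + rng.normal(0, 0.1, 32)
        m = fit_model("MLR", X, y)
        A = np.column_stack([np.ones(32), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose([m.intercept_, *m.coef_], beta, atol=1e-9)
        # coefficients recover the generating model within 3 SE
        sigma2 = np.sum((y - A @ beta) ** 2) / (32 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))
        assert abs(beta[1] - 2.0) < 3 * se[1] and abs(beta[2] + 1.0) < 3 * se[2]

    def test_mlr_singular_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = 2.0
        with pytest.raises(ValidationError, match="singular"):
            fit_model("MLR", X, np.arange(10.0))

    def test_knn_k1_memorizes(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        m = fit_model("KNN", X, y, hyper={"k": 1})
        assert np.allclose(m.predict(X), y)

    def test_knn_k_too_large(self):
        with pytest.raises(ValidationError, match="k <= n_train"):
            fit_model("KNN", np.zeros((3, 1)), np.zeros(3), hyper={"k": 5})

    def test_training_row_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, 0.5, -0.5]) + rng.normal(0, 0.2, 30)
        Xq = rng.normal(size=(5, 3))
        perm = rng.permutation(30)
        # KNN is exactly order-free; RF is deterministic under a fixed seed
        # and order-free only up to bootstrap-resampling noise
        a = fit_model("KNN", X, y).predict(Xq)
        b = fit_model("KNN", X[perm], y[perm]).predict(Xq)
        assert np.allclose(a, b, atol=1e-9)
        rf1 = fit_model("RF", X, y, seed=7).predict(Xq)
        rf2 = fit_model("RF", X, y, seed=7).predict(Xq)
        assert np.array_equal(rf1, rf2)
        rf3 = fit_model("RF", X[perm], y[perm], seed=7).predict(Xq)
        assert np.allclose(rf1, rf3, atol=0.25)

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValidationError, match="missing"):
            fit_model("MLR", np.vstack([X] * 5), np.zeros(5))


class TestMetrics:
    def test_perfect(self):
        m = regression_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert (m.r2, m.rmse, m.nrmse) == (1.0, 0.0, 0.0)

    def test_hand_computed(self):
        m = regression_metrics(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert m.r2 == pytest.approx(0.5)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.nrmse == pytest.approx(np.sqrt(1 / 3) / 2 * 100)

    def test_null_model_r2_zero(self):
        y = np.array([1.0, 2, 3, 4])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            m = regression_metrics(np.ones(4), np.zeros(4))
        assert np.isnan(m.r2)


class TestSummarize:
    def test_hand_arithmetic(self):
        s = up.summarize_ground_truth(np.array([1.0, 2.0, 3.0]))
        assert s == {"max": 3.0, "min": 1.0, "mean": 2.0, "sd": 1.0, "cv_pct": 50.0}

    def test_constant_vector(self):
        s = up.summarize_ground_truth(np.full(5, 7.0))
        assert s["sd"] == 0.0 and s["cv_pct"] == 0.0


def make_truth_level_features(design, stage, seed):
    """A feature/truth pair built from the truth sampler alone (no render)."""
    t = up.sample_truth(design, stage, seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    df = t.plots.copy()
    feats = pd.DataFrame({"plot_id": df["plot_id"], "stage": stage})
    for i, name in enumerate(INDEX_ORDER):
        sign = -1 if name in ("NDI", "GRRI", "R", "B") else 1
        feats[name] = sign * df["true_pnc"] + rng.normal(0, 0.6 + 0.05 * i, len(df))
    feats["H_cm"] = df["true_h_cm"]
    feats["CC"] = df["true_cc"]
    feats["CV"] = df["true_cc"] * df["true_h_cm"]
    truth = df.rename(columns={"true_pnc": "pnc"})[["plot_id", "replication", "pnc"]]
    truth["stage"] = stage
    return feats, truth


class TestModelSuite:
    def test_cardinality_and_partitions(self, design):
        feats, truth = make_truth_level_features(design, "S1", seed=0)
        reports = up.run_model_suite(feats, truth, stages=("S1",), feature_sets=("VIs+MPs",), hyper={"n_trees": 50})
        assert len(reports) == 3  # one per method
        for r in reports:
            assert r.n_train == 32 and r.n_val == 16
            assert len(r.features) == 8  # top-5 VIs + 3 MPs
            assert r.calibration.rmse >= 0 and r.validation.nrmse >= 0
            assert r.calibration.r2 <= 1

    def test_single_mp_sets(self, design):
        feats, truth = make_truth_level_features(design, "S1", seed=1)
        reports = up.run_model_suite(feats, truth, stages=("S1",), methods=("MLR",), feature_sets=("H", "CC", "CV"))
        assert [r.features for r in reports] == [["H_cm"], ["CC"], ["CV"]]

    def test_join_failure_reported(self, design):
        feats, truth = make_truth_level_features(design, "S1", seed=2)
        truth = truth[truth["plot_id"] != "s05"]
        with pytest.raises(ValidationError, match="s05"):
            up.run_model_suite(feats, truth, stages=("S1",), methods=("MLR",), feature_sets=("MPs",))

    def test_permuted_response_destroys_signal(self, design):
        """Shuffling PNC across plots must drop validation R^2 to ~0
        (guards against leakage through the replication split)."""
        meds = []
        for seed in range(10):
            feats, truth = make_truth_level_features(design, "S1", seed=3)
            rng = np.random.default_rng(seed)
            truth = truth.copy()
            truth["pnc"] = rng.permutation(truth["pnc"].to_numpy())
            r = up.run_model_suite(feats, truth, stages=("S1",), methods=("MLR",), feature_sets=("MPs",))
            meds.append(r[0].validation.r2)
        assert np.median(meds) <= 0.1
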