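import numpy as np
import pytest

from sfstrat.io_formats import AffinityTable, FeatureTable
from sfstrat.scoring import (
    CYSCORE4,
    SF_NAMES,
    VINA6,
    XSCORE6,
    XSCORE_CONSTITUENTS,
    XVC16,
    ModelSpec,
    fit_mlr,
    fit_mlr_vina,
    fit_mlr_xscore,
    fit_scoring_function,
    fit_tree_ensemble,
    load_model,
    predict,
    save_model,
)

from conftest import linear_table


def normal_equations(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def table(ids, columns, values):
    return FeatureTable(ids, columns, np.asarray(values, dtype=float))


class TestFitMlr:
    def test_exact_line(self):
        X = table(["a001", "a002", "a003"], ["f"], [[0.0], [1.0], [2.0]])
        y = AffinityTable({"a001": 1.0, "a002": 3.0, "a003": 5.0})
        model = fit_mlr(X, y)
        coef, intercept, _ = model.parameters[0]
        assert coef[0] == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        preds = predict(model, X)
        assert preds["a002"] == pytest.approx(3.0)

    def test_constant_target(self, rng):
        X, _ = linear_table(rng, 10, ["f1", "f2"], [0, 0])
        y = AffinityTable({i: 4.2 for i in X.ids})
        coef, intercept, _ = fit_mlr(X, y).parameters[0]
        np.testing.assert_allclose(coef, 0.0, atol=1e-10)
        assert intercept == pytest.approx(4.2)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            X, y = linear_table(rng, 50, list("abcd"), rng.normal(size=4),
                                intercept=rng.normal(), noise=0.5)
            coef, intercept, _ = fit_mlr(X, y).parameters[0]
            expected = normal_equations(X.values, y.vector_for(X.ids))
            np.testing.assert_allclose(np.r_[intercept, coef], expected, atol=1e-8)

    def test_too_few_rows_rejected(self, rng):
        X, y = linear_table(rng, 3, list("abcd"), np.ones(4))
        with pytest.raises(ValueError, match="at least"):
            fit_mlr(X, y)

    def test_rank_deficiency_names_collinear_column(self, rng):
        X0, _ = linear_table(rng, 30, ["a", "b"], [1.0, 1.0])
        values = np.column_stack([X0.values, X0.values[:, 0] * 2.0])
        X = table(X0.ids, ["a", "b", "dup"], values)
        y = AffinityTable({i: v for i, v in zip(X.ids, values @ [1.0, 1.0, 0.5])})
        with pytest.raises(ValueError, match="collinear"):
            fit_mlr(X, y)


class TestXscoreConsensus:
    def _xscore_table(self, rng, n, tie_hydrophobic=False):
        values = rng.normal(size=(n, 6))
        if tie_hydrophobic:
            values[:, 4] = values[:, 3]
            values[:, 5] = values[:, 3]
        ids = [f"x{i:03x}" for i in range(n)]
        X = table(ids, list(XSCORE6), values)
        y = AffinityTable(dict(zip(ids, 5 + values @ rng.normal(size=6))))
        return X, y

    def test_identical_hydrophobic_columns_collapse_to_single_mlr(self, rng):
        X, y = self._xscore_table(rng, 60, tie_hydrophobic=True)
        consensus = fit_mlr_xscore(X, y)
        single = fit_mlr(X.select_columns(["VDW", "HB", "RT", "HP"]), y)
        pc = predict(consensus, X)
        ps = predict(single, X)
        for i in X.ids:
            assert pc[i] == pytest.approx(ps[i], abs=1e-8)

    def test_prediction_is_mean_of_constituents(self, rng):
        X, y = self._xscore_table(rng, 100)
        consensus = fit_mlr_xscore(X, y)
        # independent oracle: refit the three constituent regressions separately
        oracle = [fit_mlr(X.select_columns(list(cols)), y) for cols in XSCORE_CONSTITUENTS]
        expected = {
            i: np.mean([predict(m, X)[i] for m in oracle]) for i in X.ids
        }
        got = predict(consensus, X)
        for i in X.ids:
            assert got[i] == pytest.approx(expected[i], abs=1e-10)


class TestVinaQuasiMlr:
    def _vina_table(self, rng, n, nrot=None):
        values = rng.normal(size=(n, 6))
        nrot_col = list(VINA6).index("Nrot")
        values[:, nrot_col] = rng.uniform(0, 12, size=n) if nrot is None else nrot
        ids = [f"v{i:03x}" for i in range(n)]
        X = table(ids, list(VINA6), values)
        y = AffinityTable(dict(zip(ids, 5 + values[:, :5] @ rng.normal(size=5))))
        return X, y

    def test_zero_nrot_equals_plain_mlr_on_terms(self, rng):
        X, y = self._vina_table(rng, 50, nrot=0.0)
        vina = fit_mlr_vina(X, y, nrot_weight=0.05846)
        terms = [c for c in VINA6 if c != "Nrot"]
        plain = fit_mlr(X.select_columns(terms), y)
        cv, iv, _ = vina.parameters[0]
        cp, ip, _ = plain.parameters[0]
        np.testing.assert_allclose(cv, cp, atol=1e-10)
        assert iv == pytest.approx(ip, abs=1e-10)

    def test_matches_transform_then_ols_oracle(self, rng):
        X, y = self._vina_table(rng, 80)
        w = 0.05846
        vina = fit_mlr_vina(X, y, nrot_weight=w)
        nrot = X.select_columns(["Nrot"]).values[:, 0]
        terms = [c for c in VINA6 if c != "Nrot"]
        Z = X.select_columns(terms).values / (1 + w * nrot)[:, None]
        expected = normal_equations(Z, y.vector_for(X.ids))
        got = predict(vina, X)
        for k, i in enumerate(X.ids):
            assert got[i] == pytest.approx(expected[0] + Z[k] @ expected[1:], abs=1e-8)

    def test_raising_nrot_shrinks_prediction_toward_intercept(self, rng):
        X, y = self._vina_table(rng, 50)
        vina = fit_mlr_vina(X, y)
        _, intercept, _ = vina.parameters[0]
        row = FeatureTable([X.ids[0]], X.columns, X.values[:1].copy())
        base = predict(vina, row)[X.ids[0]]
        boosted = row.values.copy()
        boosted[0, list(VINA6).index("Nrot")] *= 10
        more = predict(vina, FeatureTable([X.ids[0]], X.columns, boosted))[X.ids[0]]
        assert abs(more - intercept) < abs(base - intercept)

    def test_nonpositive_denominator_rejected(self, rng):
        X, y = self._vina_table(rng, 20, nrot=0.0)
        values = X.values.copy()
        values[0, list(VINA6).index("Nrot")] = -100.0
        bad = FeatureTable(X.ids, X.columns, values)
        with pytest.raises(ValueError, match="Nrot"):
            fit_mlr_vina(bad, y)


class TestTreeEnsembles:
    def _interaction_data(self, rng, n):
        values = rng.normal(size=(n, len(XVC16)))
        ids = [f"z{i:03x}" for i in range(n)]
        X = table(ids, list(XVC16), values)
        y = AffinityTable(dict(zip(ids, values[:, 0] * values[:, 1])))
        return X, y

    @pytest.mark.parametrize("sf_name", ["RF::XVC", "XGB::XVC"])
    def test_same_seed_is_bit_identical(self, rng, sf_name):
        X, y = self._interaction_data(rng, 80)
        spec = ModelSpec(sf_name, hyperparams={"n_estimators": 40}, seed=11)
        p1 = predict(fit_tree_ensemble(X, y, spec), X)
        p2 = predict(fit_tree_ensemble(X, y, spec), X)
        assert p1 == p2

    def test_constant_target_predicts_constant(self, rng):
        X, _ = self._interaction_data(rng, 30)
        y = AffinityTable({i: 3.3 for i in X.ids})
        for sf_name in ("RF::XVC", "XGB::XVC"):
            spec = ModelSpec(sf_name, hyperparams={"n_estimators": 20}, seed=0)
            preds = predict(fit_tree_ensemble(X, y, spec), X)
            np.testing.assert_allclose(list(preds.values()), 3.3, atol=1e-5)

    def test_rf_beats_mlr_on_pure_interaction(self, rng):
        X, y = self._interaction_data(rng, 700)
        train = X.select_ids(X.ids[:500])
        test = X.select_ids(X.ids[500:])
        obs = {i: y[i] for i in test.ids}
        rf = fit_tree_ensemble(train, y, ModelSpec("RF::XVC", seed=1))
        mlr = fit_mlr(train, y)
        def rmse(preds):
            return np.sqrt(np.mean([(preds[i] - obs[i]) ** 2 for i in test.ids]))
        assert rmse(predict(rf, test)) < rmse(predict(mlr, test))

    def test_non_tree_spec_rejected(self, rng):
        X, y = self._interaction_data(rng, 30)
        with pytest.raises(ValueError, match="tree-ensemble"):
            fit_tree_ensemble(X, y, ModelSpec("MLR::Vina"))


class TestUnifiedContract:
    def test_all_eight_scoring_functions_train_and_predict(self, small_benchmark):
        b = small_benchmark
        for sf_name in SF_NAMES:
            spec = ModelSpec(sf_name, hyperparams={"n_estimators": 30}, seed=3)
            model = fit_scoring_function(spec, b.train_features, b.train_affinities)
            preds = predict(model, b.test_features)
            assert len(preds) == b.test_features.n
            assert all(np.isfinite(v) for v in preds.values())

    def test_predict_names_missing_column(self, small_benchmark):
        b = small_benchmark
        model = fit_scoring_function(ModelSpec("MLR::Cyscore"),
                                     b.train_features, b.train_affinities)
        crippled = b.test_features.select_columns(list(XSCORE6))
        with pytest.raises(ValueError, match="ligand_entropy"):
            predict(model, crippled)

    def test_unknown_sf_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scoring function"):
            ModelSpec("SVM::Xscore")

    @pytest.mark.parametrize("sf_name", ["MLR::Xscore", "MLR::Vina", "RF::Cyscore"])
    def test_serialization_round_trip(self, tmp_path, small_benchmark, sf_name):
        b = small_benchmark
        spec = ModelSpec(sf_name, hyperparams={"n_estimators": 20}, seed=5)
        model = fit_scoring_function(spec, b.train_features, b.train_affinities)
        path = tmp_path / "model.bin"
        save_model(model, path)
        restored = load_model(path)
        assert predict(restored, b.test_features) == predict(model, b.test_features)
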