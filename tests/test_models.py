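"""The model zoo: metric definitions, fitting contracts, graph batches,
GNN structural properties, screening."""

import math

import numpy as np
import pytest

import heatburden as hb
from heatburden.gnn import GNNRegressor, build_graph_batch


def _loop_metrics(y, yhat):
    """Independent loop-based oracle for the five metrics (single output)."""
    n = len(y)
    sq = sum((yhat[i] - y[i]) ** 2 for i in range(n))
    ab = sum(abs(yhat[i] - y[i]) for i in range(n))
    rel = [(yhat[i] - y[i]) / y[i] for i in range(n) if y[i] != 0]
    ybar = sum(y) / n
    ss_tot = sum((y[i] - ybar) ** 2 for i in range(n))
    return {
        "rmse": math.sqrt(sq / n),
        "mae": ab / n,
        "mape": sum(abs(r) for r in rel) / len(rel),
        "rmspe": math.sqrt(sum(r * r for r in rel) / len(rel)),
        "r2": 1 - sq / ss_tot,
    }


class TestMetrics:
    def test_hand_example(self):
        # errors (-3, -4) on actuals (3, 4): relative errors are (-1, -1)
        ev = hb.compute_metrics(np.array([3.0, 4.0]), np.array([0.0, 0.0]))
        assert ev.rmse == pytest.approx(3.5355339059)
        assert ev.mae == pytest.approx(3.5)
        assert ev.mape == pytest.approx(1.0)
        assert ev.rmspe == pytest.approx(1.0)

    def test_halved_predictions_give_half_relative_error(self):
        y = np.array([6.0, 8.0])
        ev = hb.compute_metrics(y, y / 2)
        assert ev.mape == pytest.approx(0.5)
        assert ev.rmspe == pytest.approx(0.5)
        assert ev.rmse == pytest.approx(math.sqrt((9 + 16) / 2))
        assert ev.mae == pytest.approx(3.5)

    def test_perfect_prediction(self):
        y = np.random.default_rng(0).normal(5, 2, size=(40, 5))
        ev = hb.compute_metrics(y, y.copy())
        assert (ev.rmse, ev.mae, ev.mape, ev.rmspe) == (0, 0, 0, 0)
        assert ev.r2 == 1.0

    def test_constant_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        yhat = np.full_like(y, y.mean())
        assert hb.compute_metrics(y, yhat).r2 == pytest.approx(0.0)

    def test_agrees_with_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(3, 40)
            y = rng.normal(3, 2, size=n)
            y[y == 0] = 1.0
            yhat = y + rng.normal(0, 1, size=n)
            ev = hb.compute_metrics(y, yhat)
            oracle = _loop_metrics(list(y), list(yhat))
            for key, val in oracle.items():
                assert getattr(ev, key) == pytest.approx(val, abs=1e-10)

    def test_metric_inequalities(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            y = rng.normal(2, 1, size=30)
            yhat = y + rng.normal(0, 0.5, size=30)
            ev = hb.compute_metrics(y, yhat)
            assert ev.rmse >= ev.mae >= 0
            assert ev.rmspe >= ev.mape >= 0
            assert ev.r2 <= 1

    def test_zero_actuals_excluded_and_counted(self):
        y = np.array([0.0, 2.0, 4.0])
        yhat = np.array([1.0, 1.0, 2.0])
        ev = hb.compute_metrics(y, yhat)
        assert ev.n_zero_actual == 1
        assert ev.mape == pytest.approx((0.5 + 0.5) / 2)

    def test_macro_vs_pooled(self):
        rng = np.random.default_rng(3)
        y = rng.normal(4, 1, size=(30, 5))
        yhat = y + rng.normal(0, 1, size=(30, 5))
        macro = hb.compute_metrics(y, yhat, pooling="macro")
        pooled = hb.compute_metrics(y, yhat, pooling="pooled")
        per_col = [hb.compute_metrics(y[:, j], yhat[:, j]) for j in range(5)]
        assert macro.rmse == pytest.approx(np.mean([m.rmse for m in per_col]))
        assert pooled.rmse == pytest.approx(np.sqrt(np.mean((yhat - y) ** 2)))


class TestFitting:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            hb.PredictorSpec("deep_thought")

    def test_requires_normalized_panel(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(ValueError, match="normalized"):
            hb.fit(hb.PredictorSpec("linear_regression"), panel)

    def test_linear_exact_on_noiseless_data(self, catalog, pathway):
        model = hb.default_structural_model(catalog, pathway).with_noise_scales(0.0)
        panel, _ = hb.generate_panel(catalog, pathway, model, n_countries=14,
                                     region_sizes={r: 2 for r in hb.REGIONS}, seed=5)
        normalized = hb.apply_minmax(panel, hb.fit_minmax(panel))
        train, test = hb.split_train_test(normalized, 0.7, seed=1)
        fitted = hb.fit(hb.PredictorSpec("linear_regression"), train)
        assert hb.evaluate(fitted, test).rmse < 1e-6

    @pytest.mark.parametrize("name", ["random_forest", "xgboost", "decision_tree"])
    def test_deterministic_given_seed(self, small_linear_model, small_normalized, name):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        a = hb.fit(hb.PredictorSpec(name, seed=5), train).predict(test)
        b = hb.fit(hb.PredictorSpec(name, seed=5), train).predict(test)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_single_output_models_fit_per_cause(self, small_normalized):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        fitted = hb.fit(hb.PredictorSpec("svr"), train)
        assert len(fitted._estimators) == 5
        assert fitted.predict(test).shape == (test.n_rows, 5)

    def test_out_of_sample_r2_positive(self, small_normalized):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        fitted = hb.fit(hb.PredictorSpec("random_forest"), train)
        assert hb.evaluate(fitted, test).r2 > 0


class TestGraphBatch:
    def test_shapes_and_masking(self, pathway, small_normalized):
        normalized, _, _ = small_normalized
        rows = normalized.frame.head(3)
        batch = build_graph_batch(pathway, rows)
        assert batch.n_rows == 3
        assert batch.n_edges == pathway.n_edges
        idx = {n: i for i, n in enumerate(batch.node_order)}
        for name in list(hb.CAUSES) + [hb.TOTAL_BURDEN]:
            assert (batch.node_features[:, idx[name]] == 0).all()

    def test_missing_variable_rejected(self, pathway, small_normalized):
        normalized, _, _ = small_normalized
        rows = normalized.frame.drop(columns=["sanitation"]).head(2)
        with pytest.raises(ValueError, match="lack"):
            build_graph_batch(pathway, rows)


class TestGNN:
    def test_non_ancestor_cannot_influence_prediction(self, pathway, small_normalized):
        """Message passing is edge-directed, so perturbing a variable with no
        directed path to a cause leaves that cause's prediction unchanged."""
        normalized, _, _ = small_normalized
        rows = normalized.frame.head(4).copy()
        gnn = GNNRegressor(pathway, max_epochs=1, patience=1, seed=0)
        gnn.fit(build_graph_batch(pathway, rows),
                rows[list(hb.CAUSES)].to_numpy())
        base = gnn.predict(build_graph_batch(pathway, rows))
        # road infrastructure is an ancestor of injuries only
        perturbed = rows.copy()
        perturbed["road_infrastructure_construction"] += 0.3
        pred = gnn.predict(build_graph_batch(pathway, perturbed))
        cause_pos = {c: k for k, c in enumerate(hb.CAUSES)}
        for cause in hb.CAUSES:
            if cause == "injuries_burden":
                continue
            np.testing.assert_array_equal(pred[:, cause_pos[cause]],
                                          base[:, cause_pos[cause]])
        # a variable with no outgoing edges influences nothing
        perturbed2 = rows.copy()
        perturbed2["gdp_per_capita"] += 0.5
        np.testing.assert_array_equal(
            gnn.predict(build_graph_batch(pathway, perturbed2)), base
        )

    def test_target_values_do_not_leak(self, pathway, small_normalized):
        normalized, _, _ = small_normalized
        rows = normalized.frame.head(4).copy()
        gnn = GNNRegressor(pathway, max_epochs=1, patience=1, seed=0)
        gnn.fit(build_graph_batch(pathway, rows), rows[list(hb.CAUSES)].to_numpy())
        base = gnn.predict(build_graph_batch(pathway, rows))
        doctored = rows.copy()
        doctored[list(hb.CAUSES)] = 99.0
        doctored[hb.TOTAL_BURDEN] = 99.0
        np.testing.assert_array_equal(
            gnn.predict(build_graph_batch(pathway, doctored)), base
        )

    def test_fit_deterministic(self, pathway, small_normalized):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        spec = hb.PredictorSpec("gnn", hyperparameters={"max_epochs": 30}, seed=3)
        a = hb.fit(spec, train, pathway=pathway).predict(test)
        b = hb.fit(spec, train, pathway=pathway).predict(test)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_requires_pathway(self, small_normalized):
        normalized, _, _ = small_normalized
        train, _ = hb.split_train_test(normalized, 0.7, seed=7)
        with pytest.raises(ValueError, match="pathway"):
            hb.fit(hb.PredictorSpec("gnn"), train)


class TestScreen:
    def test_ranking_is_permutation_and_sorted(self, small_normalized, pathway):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        specs = [hb.PredictorSpec(n) for n in
                 ("linear_regression", "decision_tree", "random_forest")]
        result = hb.screen(specs, train, test)
        assert sorted(s.name for s, _ in result.ranking) == sorted(s.name for s in specs)
        rmses = [ev.rmse for _, ev in result.ranking]
        assert rmses == sorted(rmses)

    def test_single_spec_selected(self, small_normalized):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        result = hb.screen([hb.PredictorSpec("linear_regression")], train, test)
        assert result.best[0].name == "linear_regression"

    def test_failure_recorded_not_fatal(self, small_normalized):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        bad = hb.PredictorSpec("svr", hyperparameters={"C": -1})
        result = hb.screen([bad, hb.PredictorSpec("linear_regression")], train, test)
        assert len(result.failures) == 1
        assert result.failures[0][0].name == "svr"
        assert result.best[0].name == "linear_regression"

    def test_empty_specs_rejected(self, small_normalized):
        normalized, _, _ = small_normalized
        train, test = hb.split_train_test(normalized, 0.7, seed=7)
        with pytest.raises(ValueError):
            hb.screen([], train, test)
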