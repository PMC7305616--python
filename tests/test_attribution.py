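"""Attribution integrals: closed forms, completeness, refinement, batching."""

import numpy as np
import pytest

import gradpath as gp


def make_bilinear():
    return gp.FunctionModel(lambda x: x[0] * x[1], p=2,
                            grad=lambda x: np.array([x[1], x[0]]))


class TestClosedForms:
    def test_linear_model_exact_on_any_path(self, linear_model, trained,
                                            tabular):
        w, F = linear_model
        x_prime = np.array([0.5, -1.0, 2.0, 0.0])
        x = np.array([2.0, 1.0, -1.0, 3.0])
        expect = w * (x - x_prime)
        # straight line and a detoured polyline both integrate exactly
        for path in [
            gp.linear_path(x_prime, x, 7),
            gp.Path(
                np.vstack([x_prime, x_prime + [5, 5, 5, 5], x]),
                np.array([0.0, 0.4, 1.0]), "O-N",
            ),
        ]:
            av = gp.path_attributions(F, path)
            assert np.allclose(av.values, expect, atol=1e-10)
            assert av.completeness_gap < 1e-10

    def test_linear_model_is_step_count_invariant(self, linear_model):
        w, F = linear_model
        x_prime, x = np.zeros(4), np.array([1.0, 2.0, 3.0, 4.0])
        a2 = gp.path_attributions(F, gp.linear_path(x_prime, x, 2))
        a1000 = gp.path_attributions(F, gp.linear_path(x_prime, x, 1000))
        assert np.allclose(a2.values, a1000.values, atol=1e-12)

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (-1.5, 0.7)])
    def test_bilinear_from_zero_baseline_splits_evenly(self, a, b):
        F = make_bilinear()
        path = gp.linear_path(np.zeros(2), np.array([a, b]), 250)
        av = gp.path_attributions(F, path)
        expect = np.array([a * b / 2, a * b / 2])
        assert np.all(np.abs(av.values - expect) <= 1e-6 * np.abs(expect))

    def test_zero_length_path_gives_zero_attribution(self):
        F = make_bilinear()
        x = np.array([1.0, 2.0])
        av = gp.path_attributions(F, gp.linear_path(x, x, 10))
        assert np.all(av.values == 0.0)
        assert av.completeness_gap == 0.0

    def test_nonfinite_gradient_reports_step(self):
        F = gp.FunctionModel(
            lambda x: 1.0 / x[0], p=1, grad=lambda x: np.array([-1.0 / x[0] ** 2])
        )
        path = gp.linear_path(np.array([-1.0]), np.array([1.0]), 11)
        with pytest.raises(FloatingPointError, match="step"):
            gp.path_attributions(F, path)


class TestSensitivityAndCompleteness:
    def test_differing_feature_receives_nonzero_attribution(self):
        F = gp.FunctionModel(lambda x: np.tanh(x[1]), p=2,
                             grad=lambda x: np.array([0.0, 1 - np.tanh(x[1]) ** 2]))
        x_prime, x = np.array([0.0, 0.0]), np.array([0.0, 2.0])
        av = gp.path_attributions(F, gp.linear_path(x_prime, x, 100))
        assert av.values[1] != 0.0
        assert av.values[0] == 0.0

    @pytest.mark.parametrize("kind", ["O-L", "H-L", "O-N", "H-N"])
    def test_completeness_on_smooth_reference_model(self, kind, trained,
                                                    tabular):
        codec, predictor = trained
        X = tabular.features.to_numpy()
        y = tabular.labels
        graph = None
        if kind in ("O-N", "H-N"):
            graph = gp.knn_graph(X, 10, codec=codec if kind == "H-N" else None,
                                 ensure_connected=True)
        cfg = gp.PathConfig(kind=kind, n_steps=250,
                            codec=codec if kind == "H-L" else None, graph=graph)
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = X[rng.choice(np.flatnonzero(y == 1))]
            x_prime = X[rng.choice(np.flatnonzero(y == 0))]
            av = gp.path_attributions(predictor, gp.build_path(x_prime, x, cfg))
            df = abs(predictor.evaluate(x) - predictor.evaluate(x_prime))
            assert av.completeness_gap <= 0.01 * max(df, 1e-8)


class TestRefineUntil:
    def test_linear_model_converges_immediately(self, linear_model):
        w, F = linear_model
        x = np.array([1.0, -1.0, 0.5, 2.0])
        av = gp.refine_until(F, lambda n: gp.linear_path(np.zeros(4), x, n),
                             tol=1e-6)
        assert av.converged
        assert av.completeness_gap < 1e-10

    def test_oscillatory_model_matches_dense_quadrature(self):
        F = gp.FunctionModel(lambda x: np.sin(5 * x[0]), p=1,
                             grad=lambda x: np.array([5 * np.cos(5 * x[0])]))
        x_prime, x = np.array([0.0]), np.array([2.0])
        tol = 1e-5
        av = gp.refine_until(F, lambda n: gp.linear_path(x_prime, x, n), tol=tol)
        dense = gp.path_attributions(F, gp.linear_path(x_prime, x, 100_000))
        assert av.converged
        assert abs(av.values[0] - dense.values[0]) <= tol * abs(dense.values[0])

    def test_zero_tolerance_rejected(self, linear_model):
        _, F = linear_model
        with pytest.raises(ValueError):
            gp.refine_until(F, lambda n: gp.linear_path(np.zeros(4), np.ones(4), n),
                            tol=0.0)

    def test_nonconvergence_flags_instead_of_raising(self):
        F = gp.FunctionModel(lambda x: np.sin(50 * x[0]), p=1,
                             grad=lambda x: np.array([50 * np.cos(50 * x[0])]))
        with pytest.warns(UserWarning, match="not converged"):
            av = gp.refine_until(
                F, lambda n: gp.linear_path(np.zeros(1), np.full(1, 3.0), n),
                tol=1e-12, max_steps=200,
            )
        assert not av.converged


class TestClassAttributions:
    def test_single_baseline_matches_per_row_integration(self, linear_model):
        w, F = linear_model
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 4))
        bs = gp.zero_baseline(4)
        am = gp.class_attributions(F, X, bs, gp.PathConfig("O-L", 50))
        for i, x in enumerate(X):
            av = gp.path_attributions(F, gp.linear_path(np.zeros(4), x, 50))
            assert np.allclose(am.values.iloc[i].to_numpy(), av.values)

    def test_duplicate_baseline_points_equal_single(self, linear_model):
        w, F = linear_model
        X = np.random.default_rng(6).normal(size=(3, 4))
        b = np.full((1, 4), 0.5)
        one = gp.BaselineSet(b, "median", {"m": 1})
        two = gp.BaselineSet(np.vstack([b, b]), "median", {"m": 2})
        a1 = gp.class_attributions(F, X, one, gp.PathConfig("O-L", 50))
        a2 = gp.class_attributions(F, X, two, gp.PathConfig("O-L", 50))
        assert np.allclose(a1.values.to_numpy(), a2.values.to_numpy())

    def test_linear_model_multi_baseline_closed_form(self, linear_model):
        w, F = linear_model
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 4))
        B = rng.normal(size=(3, 4))
        bs = gp.BaselineSet(B, "random", {"m": 3})
        am = gp.class_attributions(F, X, bs, gp.PathConfig("O-L", 50))
        expect = w * (X - B.mean(axis=0))
        assert np.allclose(am.values.to_numpy(), expect, atol=1e-10)

    def test_mean_over_baselines_equals_batch_result(self, linear_model):
        w, F = linear_model
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3, 4))
        B = rng.normal(size=(2, 4))
        bs = gp.BaselineSet(B, "random", {"m": 2})
        batch = gp.class_attributions(F, X, bs, gp.PathConfig("O-L", 64))
        for i, x in enumerate(X):
            per = [
                gp.path_attributions(F, gp.linear_path(b, x, 64)).values
                for b in B
            ]
            assert np.allclose(batch.values.iloc[i].to_numpy(),
                               np.mean(per, axis=0))

    def test_close_strategy_recomputes_per_sample(self, linear_model):
        w, F = linear_model
        rng = np.random.default_rng(9)
        class_points = rng.normal(size=(10, 4))
        X = rng.normal(size=(2, 4))
        bs = gp.close_baseline(class_points, X[0], m=2)
        am = gp.class_attributions(F, X, bs, gp.PathConfig("O-L", 32))
        for i, x in enumerate(X):
            b_i = gp.close_baseline(class_points, x, m=2).points
            expect = w * (x - b_i.mean(axis=0))
            assert np.allclose(am.values.iloc[i].to_numpy(), expect, atol=1e-10)

    def test_feature_names_propagate(self, tabular, trained):
        _, predictor = trained
        bs = gp.zero_baseline(30)
        am = gp.class_attributions(predictor, tabular.features.iloc[:3], bs,
                                   gp.PathConfig("O-L", 30))
        assert am.feature_names == list(tabular.features.columns)

    def test_tsv_round_trip_preserves_values_and_provenance(
        self, tmp_path, linear_model
    ):
        w, F = linear_model
        X = np.random.default_rng(10).normal(size=(3, 4))
        am = gp.class_attributions(F, X, gp.zero_baseline(4),
                                   gp.PathConfig("O-L", 16),
                                   provenance={"seed": 1})
        f = tmp_path / "attr.tsv"
        gp.attribution.write_attributions(am, f)
        back = gp.attribution.read_attributions(f)
        assert np.allclose(back.values.to_numpy(), am.values.to_numpy())
        assert back.provenance["path"] == "O-L"
        assert back.provenance["seed"] == "1"
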