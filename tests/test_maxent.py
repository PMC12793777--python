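import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from maxsdm import (
    FeatureSpec,
    MaxentModel,
    build_features,
    fit_maxent,
    jackknife_gains,
    permutation_importance,
    predict,
    response_curve,
)
from maxsdm.maxent import beta_class


class TestBuildFeatures:
    def test_linear_is_minmax_scaled(self):
        bg = pd.DataFrame({"v": [0.0, 10.0]})
        spec = FeatureSpec.from_background(bg, "L")
        F, names, classes = build_features(pd.DataFrame({"v": [5.0]}), spec)
        assert names == ["L:v"] and classes == ["L"]
        assert F[0, 0] == 0.5

    def test_values_clamped_to_training_range(self):
        bg = pd.DataFrame({"v": [0.0, 10.0]})
        spec = FeatureSpec.from_background(bg, "L")
        F, _, _ = build_features(pd.DataFrame({"v": [-5.0, 15.0]}), spec)
        assert F[:, 0].tolist() == [0.0, 1.0]

    @pytest.mark.parametrize(
        "classes,k,expected",
        [
            ("LQ", 3, 6),            # 2k columns
            ("LQHP", 3, 6 + 3 + 12), # + k(k-1)/2 products + 2*hinge_knots*k
            ("L", 5, 5),
        ],
    )
    def test_column_combinatorics(self, classes, k, expected):
        rng = np.random.default_rng(0)
        bg = pd.DataFrame(rng.uniform(0, 1, (20, k)),
                          columns=[f"v{i}" for i in range(k)])
        spec = FeatureSpec.from_background(bg, classes, hinge_knots=2)
        F, names, _ = build_features(bg, spec)
        assert F.shape[1] == expected
        assert len(names) == len(set(names))  # deterministic unique naming

    def test_forward_hinge_definition(self):
        bg = pd.DataFrame({"v": [0.0, 10.0]})
        spec = FeatureSpec.from_background(bg, "H", hinge_knots=2)
        F, names, _ = build_features(pd.DataFrame({"v": [2.5, 7.5]}), spec)
        col = names.index("HF:v@0.5000")
        # max(0, x' - 0.5) / (1 - 0.5): 0 below the knot, half-span above
        assert F[0, col] == 0.0
        assert F[1, col] == pytest.approx(0.5)

    def test_threshold_steps(self):
        bg = pd.DataFrame({"v": [0.0, 10.0]})
        spec = FeatureSpec.from_background(bg, "T", threshold_knots=3)
        F, names, _ = build_features(pd.DataFrame({"v": [3.0, 8.0]}), spec)
        # thresholds at 0.25 / 0.5 / 0.75 of the scaled range
        assert F[0].tolist() == [1.0, 0.0, 0.0]
        assert F[1].tolist() == [1.0, 1.0, 1.0]

    def test_zero_range_covariate_constant_and_flagged(self):
        bg = pd.DataFrame({"v": [3.0, 3.0, 3.0]})
        spec = FeatureSpec.from_background(bg, "LQ")
        assert spec.zero_range() == ["v"]
        F, _, _ = build_features(pd.DataFrame({"v": [1.0, 9.0]}), spec)
        assert np.ptp(F, axis=0).max() == 0.0


def penalized_objective(lam, F_pr, F_bg, beta):
    """Independent evaluation of the penalized maxent log-likelihood."""
    return (
        F_pr.mean(axis=0) @ lam
        - logsumexp(F_bg @ lam)
        - beta @ np.abs(lam)
    )


def betas_for(F_bg, classes, rm, n_presence):
    sd = F_bg.std(axis=0, ddof=0)
    base = np.array([beta_class(c, n_presence) for c in classes])
    return np.maximum(rm * base * sd / np.sqrt(n_presence), 1e-6)


class TestFit:
    def test_empty_covariate_set_gives_uniform_distribution(self):
        pres = pd.DataFrame(index=range(6))
        bg = pd.DataFrame(index=range(40))
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        raw = predict(model, pd.DataFrame(index=range(40)), "raw")
        assert np.allclose(raw, 1 / 40)
        assert model.entropy_H == pytest.approx(np.log(40))

    def test_single_binary_feature_matches_1d_brute_force(self):
        """λ for one binary feature agrees with a dense grid search of the
        penalized objective, across small and large regularization."""
        bg = pd.DataFrame({"v": [0.0] * 25 + [1.0] * 25})
        pres = pd.DataFrame({"v": [1.0] * 10})
        grid = np.linspace(-2.0, 8.0, 100001)  # step 1e-4
        lam_prev = np.inf
        for rm in (0.2, 1.0, 5.0):
            model = fit_maxent(pres, bg, rm=rm, classes="L")
            F_bg, _, cl = build_features(bg, model.feature_spec)
            F_pr, _, _ = build_features(pres, model.feature_spec)
            beta = betas_for(F_bg, cl, rm, len(pres))
            vals = (
                F_pr.mean() * grid
                - logsumexp(F_bg @ grid[None, :], axis=0)
                - beta[0] * np.abs(grid)
            )
            lam_star = grid[int(np.argmax(vals))]
            assert model.lambdas[0] == pytest.approx(lam_star, abs=1e-3)
            # stronger regularization shrinks the coefficient
            assert abs(model.lambdas[0]) <= abs(lam_prev) + 1e-9
            lam_prev = model.lambdas[0]

    def test_two_feature_fit_matches_2d_brute_force(self):
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 50), "b": rng.uniform(0, 1, 50)})
        pres = pd.DataFrame({"a": rng.uniform(0.5, 1, 12),
                             "b": rng.uniform(0, 0.6, 12)})
        rm = 1.0
        model = fit_maxent(pres, bg, rm=rm, classes="L")
        F_bg, _, cl = build_features(bg, model.feature_spec)
        F_pr, _, _ = build_features(pres, model.feature_spec)
        beta = betas_for(F_bg, cl, rm, len(pres))

        def best_on(ax, bx):
            aa, bb = np.meshgrid(ax, bx, indexing="ij")
            lam = np.stack([aa.ravel(), bb.ravel()])  # (2, N)
            vals = (
                F_pr.mean(axis=0) @ lam
                - logsumexp(F_bg @ lam, axis=0)
                - beta @ np.abs(lam)
            )
            i = int(np.argmax(vals))
            return lam[0, i], lam[1, i]

        a0, b0 = best_on(np.arange(-4, 4, 0.02), np.arange(-4, 4, 0.02))
        a1, b1 = best_on(np.arange(a0 - 0.03, a0 + 0.03, 5e-4),
                         np.arange(b0 - 0.03, b0 + 0.03, 5e-4))
        assert model.lambdas[0] == pytest.approx(a1, abs=1e-3)
        assert model.lambdas[1] == pytest.approx(b1, abs=1e-3)

    def test_background_duplication_invariance(self, toy_pb):
        pres, bg = toy_pb
        m1 = fit_maxent(pres, bg, rm=1.0, classes="LQ")
        m2 = fit_maxent(pres, pd.concat([bg, bg], ignore_index=True),
                        rm=1.0, classes="LQ")
        np.testing.assert_allclose(m1.lambdas, m2.lambdas, atol=2e-4)

    def test_huge_rm_recovers_uniform_limit(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1e6, classes="LQ")
        assert np.abs(model.lambdas).max() < 1e-6
        raw = predict(model, bg, "raw")
        assert np.allclose(raw, 1 / len(bg), rtol=1e-4)

    def test_objective_trace_is_monotone(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.0, classes="LQ")
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)  # minimized objective descends

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_raw_scores_sum_to_one_on_every_fit(self, seed):
        rng = np.random.default_rng(seed)
        bg = pd.DataFrame({"x": rng.uniform(0, 1, 60),
                           "y": rng.uniform(0, 1, 60)})
        pres = bg.iloc[rng.choice(60, 10, replace=False)].reset_index(drop=True)
        model = fit_maxent(pres, bg, rm=float(rng.uniform(0.5, 3)), classes="LQ")
        assert predict(model, bg, "raw").sum() == pytest.approx(1.0, abs=1e-6)
        assert model.entropy_H <= np.log(len(bg)) + 1e-9

    def test_rejects_bad_inputs(self, toy_pb):
        pres, bg = toy_pb
        with pytest.raises(ValueError):
            fit_maxent(pres, bg, rm=0.0)
        with pytest.raises(ValueError):
            fit_maxent(pres.head(3), bg, rm=1.0)

    def test_identical_presences_warn_but_fit(self, toy_pb):
        _, bg = toy_pb
        pres = pd.DataFrame({"x": [5.0] * 6, "noise": [0.5] * 6})
        with pytest.warns(UserWarning, match="identical"):
            fit_maxent(pres, bg, rm=1.0, classes="L")


class TestPredictTransforms:
    def uniform_model(self, n_bg=50):
        pres = pd.DataFrame(index=range(6))
        bg = pd.DataFrame(index=range(n_bg))
        return fit_maxent(pres, bg, rm=1.0, classes="L"), n_bg

    def test_uniform_logistic_is_half(self):
        model, n = self.uniform_model()
        out = predict(model, pd.DataFrame(index=range(3)), "logistic")
        assert np.allclose(out, 0.5)

    def test_uniform_cloglog_is_1_minus_inv_e(self):
        model, n = self.uniform_model()
        out = predict(model, pd.DataFrame(index=range(3)), "cloglog")
        assert np.allclose(out, 1 - np.exp(-1))

    def test_transforms_preserve_ordering_and_bounds(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.0, classes="LQ")
        raw = predict(model, bg, "raw")
        for t in ("logistic", "cloglog"):
            s = predict(model, bg, t)
            assert np.all((s >= 0) & (s <= 1))
            order = np.argsort(raw)
            assert np.all(np.diff(s[order]) >= -1e-15)

    def test_unknown_transform_rejected(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        with pytest.raises(ValueError, match="transform"):
            predict(model, bg, "probit")

    def test_serialization_round_trip_predicts_identically(self, toy_pb, tmp_path):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.5, classes="LQH")
        model.save(tmp_path / "m.json")
        back = MaxentModel.load(tmp_path / "m.json")
        np.testing.assert_array_equal(
            predict(model, bg, "cloglog"), predict(back, bg, "cloglog")
        )


class TestDiagnostics:
    def test_single_driver_gets_all_importance(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        imp = permutation_importance(model, pres, bg, n_reps=3, seed=0)
        by = imp.set_index("covariate")["importance_pct"]
        assert by["x"] > 95
        assert by.sum() == pytest.approx(100.0, abs=1e-6)

    def test_constant_covariate_has_zero_drop(self, toy_pb):
        pres, bg = toy_pb
        pres = pres.assign(const=1.0)
        bg = bg.assign(const=1.0)
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        imp = permutation_importance(model, pres, bg, n_reps=2, seed=0)
        assert imp.set_index("covariate")["mean_auc_drop"]["const"] == 0.0

    def test_jackknife_ranks_informative_variable(self, toy_pb):
        pres, bg = toy_pb
        gains = jackknife_gains(pres, bg, classes="LQ", rm=1.0)
        by = gains.set_index("covariate")
        assert by["gain_only"].idxmax() == "x"
        assert (by["gain_full"] >= -1e-9).all()

    def test_redundant_duplicate_leaves_without_gain_at_full(self, toy_pb):
        pres, bg = toy_pb
        pres = pres.assign(x2=pres["x"])
        bg = bg.assign(x2=bg["x"])
        gains = jackknife_gains(pres, bg, classes="L", rm=1.0)
        by = gains.set_index("covariate")
        assert by.loc["x", "gain_without"] == pytest.approx(
            by.loc["x", "gain_full"], abs=0.05
        )

    def test_uniform_model_gain_is_zero(self):
        pres = pd.DataFrame(index=range(6))
        bg = pd.DataFrame(index=range(30))
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        from maxsdm.maxent import _gain

        assert _gain(model, pres) == pytest.approx(0.0, abs=1e-12)


class TestResponseCurves:
    def test_positive_linear_driver_monotone_increasing(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        curve = response_curve(model, "x", n_points=50)
        assert np.all(np.diff(curve["suitability"]) >= -1e-12)
        assert curve["suitability"].between(0, 1).all()

    def test_quadratic_exponent_peaks_at_closed_form_vertex(self):
        # hand-built model: eta = 2 x' - 2 x'^2 peaks at x' = 0.5 -> v = 5
        spec = FeatureSpec(classes="LQ", covariates=["v"],
                           ranges={"v": (0.0, 10.0)}, means={"v": 5.0})
        model = MaxentModel(
            feature_spec=spec, feature_names=["L:v", "Q:v"],
            feature_classes=["L", "Q"], lambdas=np.array([2.0, -2.0]),
            linear_predictor_normalizer=0.0, density_normalizer=1.0,
            entropy_H=0.0, rm=1.0, n_presence=10, n_background=100,
        )
        curve = response_curve(model, "v", n_points=201, transform="raw")
        assert curve.loc[curve["suitability"].idxmax(), "v"] == pytest.approx(
            5.0, abs=0.05
        )

    def test_marginal_curve_requires_background(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        with pytest.raises(ValueError):
            response_curve(model, "x", kind="marginal")
        curve = response_curve(model, "x", kind="marginal", background=bg)
        assert len(curve) == 100

    def test_unknown_covariate(self, toy_pb):
        pres, bg = toy_pb
        model = fit_maxent(pres, bg, rm=1.0, classes="L")
        with pytest.raises(KeyError):
            response_curve(model, "nope")
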