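"""Path-model machinery: implied covariance, ML fit, robust statistics,
fit indices, pruning, standardization."""

import numpy as np
import pandas as pd
import pytest

from radsym import PathModel, prepare_covariates, prune_model
from radsym.path_sem import SEMConvergenceError, duplication_matrix, vech


def simulate_recursive(rng, n, exog_names, coefs, resid_sd, exog_corr=0.2):
    k = len(exog_names)
    C = np.full((k, k), exog_corr)
    np.fill_diagonal(C, 1.0)
    X = rng.multivariate_normal(np.zeros(k), C, size=n)
    df = pd.DataFrame(X, columns=exog_names)
    for endo, cmap in coefs.items():
        df[endo] = sum(b * df[v] for v, b in cmap.items()) \
            + resid_sd[endo] * rng.standard_normal(n)
    return df


class TestModelStructure:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModel.from_edges([("a", "b"), ("b", "a")])

    def test_exog_endog_partition(self):
        m = PathModel.from_edges([("x", "y"), ("z", "y"), ("y", "w")])
        assert set(m.exogenous) == {"x", "z"}
        assert set(m.endogenous) == {"y", "w"}

    def test_from_spec_text(self):
        m = PathModel.from_spec(
            "# comment\n temp -> W \n lat -> C\n W ~~ C\n")
        assert ("temp", "W") in m.edges
        assert ("W", "C") in m.resid_covs

    def test_df_counts_moments_minus_params(self):
        m = PathModel.from_edges([("x", "y")])
        # p=2 -> 3 moments; params: 1 edge + var(x) + resid(y) = 3
        assert m.df == 0


class TestImpliedCovariance:
    def test_empty_edges_diagonal(self):
        m = PathModel(variables=["a", "b"], edges=[], exog_cov=False)
        S = m.implied_covariance(np.array([2.0, 3.0]))
        assert np.allclose(S, np.diag([2.0, 3.0]))

    def test_single_path_hand_matrix(self):
        m = PathModel.from_edges([("x", "y")])
        b = 0.7
        S = m.implied_covariance(np.array([b, 1.0, 1.0]))
        assert np.allclose(S, [[1, b], [b, b**2 + 1]])

    def test_saturated_model_reproduces_sample_cov(self, rng):
        df = simulate_recursive(
            rng, 300, ["x", "z"], {"y": {"x": 0.5, "z": -0.3}}, {"y": 0.8})
        m = PathModel.from_edges([("x", "y"), ("z", "y")])
        fit = m.fit(df)
        S = np.cov(df[m.variables].to_numpy(), rowvar=False, ddof=1)
        assert np.allclose(m.implied_covariance(fit.params.to_numpy()), S,
                           atol=1e-6)
        assert fit.T_ML == pytest.approx(0.0, abs=1e-6)
        assert fit.CFI == 1.0

    def test_wrong_param_count_rejected(self):
        m = PathModel.from_edges([("x", "y")])
        with pytest.raises(ValueError):
            m.implied_covariance(np.array([1.0]))


class TestFit:
    def test_single_path_matches_ols(self, rng):
        x = rng.standard_normal(150)
        y = 0.6 * x + 0.5 * rng.standard_normal(150)
        df = pd.DataFrame({"x": x, "y": y})
        fit = PathModel.from_edges([("x", "y")]).fit(df)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(150), x]), y, rcond=None)[0][1]
        assert fit.params["x->y"] == pytest.approx(ols, abs=1e-6)

    def test_every_equation_matches_ols(self, rng):
        df = simulate_recursive(
            rng, 400, ["a", "b", "c"],
            {"y": {"a": 0.4, "b": -0.2}, "w": {"c": 0.3, "y": 0.5}},
            {"y": 0.7, "w": 0.7})
        edges = [("a", "y"), ("b", "y"), ("c", "w"), ("y", "w")]
        fit = PathModel.from_edges(edges, variables=list(df.columns)).fit(df)
        for endo, parents in (("y", ["a", "b"]), ("w", ["c", "y"])):
            X = np.column_stack([np.ones(len(df))] + [df[p] for p in parents])
            b = np.linalg.lstsq(X, df[endo], rcond=None)[0][1:]
            for p, bi in zip(parents, b):
                assert fit.params[f"{p}->{endo}"] == pytest.approx(
                    bi, abs=1e-5)

    def test_missing_variable_rejected(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50)})
        with pytest.raises(KeyError):
            PathModel.from_edges([("x", "y")]).fit(df)

    def test_small_n_warns(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(10),
                           "y": rng.standard_normal(10)})
        with pytest.warns(UserWarning, match="fragile"):
            PathModel.from_edges([("x", "y")]).fit(df)

    def test_nested_models_lr_consistent(self, rng):
        df = simulate_recursive(
            rng, 500, ["a", "b"], {"y": {"a": 0.5, "b": 0.3}}, {"y": 0.8})
        full = PathModel.from_edges([("a", "y"), ("b", "y")]).fit(df)
        restricted = PathModel.from_edges(
            [("a", "y")], variables=["a", "b", "y"]).fit(df)
        assert restricted.T_ML >= full.T_ML - 1e-8


class TestSatorraBentler:
    def test_scaling_near_one_under_normality(self, rng):
        df = simulate_recursive(
            rng, 2000, ["a", "b", "c"], {"y": {"a": 0.4}}, {"y": 0.8})
        m = PathModel.from_edges(
            [("a", "y")], variables=["a", "b", "c", "y"])
        fit = m.fit(df)
        assert fit.df > 0
        assert 0.85 <= fit.scaling_factor <= 1.15

    def test_heavy_tails_inflate_scaling(self, rng):
        # multivariate t5 (shared scale mixing): every fourth moment is
        # inflated by (nu-2)/(nu-4) = 3 relative to the normal, so the
        # scaling factor should clearly exceed 1
        cs = []
        for _ in range(50):
            z = rng.standard_normal((400, 3))
            mix = np.sqrt(rng.chisquare(5, size=400) / 5)[:, None]
            t5 = z / mix
            df = pd.DataFrame(t5, columns=["a", "b", "y"])
            df["y"] = 0.4 * df["a"] + df["y"]
            m = PathModel.from_edges([("a", "y")],
                                     variables=["a", "b", "y"])
            cs.append(m.fit(df).scaling_factor)
        assert np.mean(cs) > 1.0

    def test_tsb_equals_tml_when_c_one(self, rng):
        df = simulate_recursive(
            rng, 800, ["a", "b"], {"y": {"a": 0.4}}, {"y": 0.8})
        m = PathModel.from_edges([("a", "y")], variables=["a", "b", "y"])
        fit = m.fit(df)
        assert fit.T_SB == pytest.approx(fit.T_ML / fit.scaling_factor)


class TestFitIndices:
    def test_independence_target_cfi_zero(self, rng):
        df = simulate_recursive(
            rng, 300, ["a", "b"], {"y": {"a": 0.8, "b": 0.5}}, {"y": 0.5})
        indep = PathModel(variables=["a", "b", "y"], edges=[],
                          exog_cov=False)
        fit = indep.fit(df)
        assert fit.CFI == pytest.approx(0.0, abs=1e-9)

    def test_aic_prefers_true_edge(self, rng):
        hits = 0
        for _ in range(20):
            df = simulate_recursive(
                rng, 500, ["a", "b"], {"y": {"a": 0.5, "b": 0.5}},
                {"y": 0.8})
            with_edge = PathModel.from_edges(
                [("a", "y"), ("b", "y")]).fit(df)
            without = PathModel.from_edges(
                [("a", "y")], variables=["a", "b", "y"]).fit(df)
            hits += with_edge.AIC < without.AIC
        assert hits >= 18

    def test_aic_definition(self, rng):
        df = simulate_recursive(
            rng, 300, ["a", "b"], {"y": {"a": 0.4}}, {"y": 0.8})
        m = PathModel.from_edges([("a", "y")], variables=["a", "b", "y"])
        fit = m.fit(df)
        assert fit.AIC == pytest.approx(fit.T_ML + 2 * m.n_params)


class TestStandardize:
    def test_hand_arithmetic(self):
        m = PathModel.from_edges([("x", "y")])
        # b=2, var(x)=1, resid(y)=... choose resid so sd(y)=2: 4-... wait
        # sd(y)^2 = b^2 var(x) + resid -> resid 0 gives sd(y) = 2
        theta = np.array([2.0, 1.0, 1e-9])
        Sigma = m.implied_covariance(theta)
        sd = np.sqrt(np.diag(Sigma))
        assert 2.0 * sd[0] / sd[1] == pytest.approx(1.0, abs=1e-6)

    def test_unit_variance_data_unchanged(self, rng):
        x = rng.standard_normal(5000)
        y = 0.5 * x + rng.standard_normal(5000) * np.sqrt(0.75)
        df = pd.DataFrame({"x": x / x.std(), "y": y / y.std()})
        fit = PathModel.from_edges([("x", "y")]).fit(df)
        assert fit.standardized()["x->y"] == pytest.approx(
            fit.params["x->y"], abs=1e-2)


class TestPrune:
    def test_drops_planted_null_edge(self, rng):
        dropped = 0
        for _ in range(20):
            df = simulate_recursive(
                rng, 500, ["a", "b", "c"],
                {"y": {"a": 0.5, "b": 0.4}}, {"y": 0.8})
            model = PathModel.from_edges(
                [("a", "y"), ("b", "y"), ("c", "y")])
            pruned, fit = prune_model(model, df)
            dropped += ("c", "y") not in pruned.edges
        assert dropped >= 16

    def test_minimal_model_unchanged(self, rng):
        df = simulate_recursive(
            rng, 500, ["a"], {"y": {"a": 0.8}}, {"y": 0.5})
        model = PathModel.from_edges([("a", "y")])
        pruned, _ = prune_model(model, df)
        assert pruned.edges == model.edges


class TestPrepareCovariates:
    def test_log_precipitation(self):
        env = pd.DataFrame({"precipitation": [1000.0], "temperature": [20.0]})
        out = prepare_covariates(env)
        assert out["precipitation_log"].iloc[0] == pytest.approx(
            np.log(1000), abs=1e-9)
        assert out["temperature"].iloc[0] == 20.0

    def test_nonpositive_rejected_naming_rows(self):
        env = pd.DataFrame({"precipitation": [100.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            prepare_covariates(env)

    def test_other_columns_bit_identical(self, rng):
        env = pd.DataFrame({"precipitation": [10.0, 20.0],
                            "altitude": [1.23456789, 9.87654321]})
        out = prepare_covariates(env)
        assert (out["altitude"].to_numpy()
                == env["altitude"].to_numpy()).all()


def test_duplication_matrix_roundtrip(rng):
    A = rng.standard_normal((4, 4))
    S = A + A.T
    D = duplication_matrix(4)
    assert np.allclose(D @ vech(S), S.flatten())
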