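"""Likelihood correctness, fitting, AICc, covariance structures, serialization."""

import math
from dataclasses import replace

import numpy as np
import pytest

from prevtrend.model import (
    FittedModel,
    ModelSpec,
    _ModelMatrices,
    aicc,
    country_cov,
    fit,
    marginal_loglik,
    select_model,
)
from prevtrend.predict import PredictionRequest, predict_point
from prevtrend.preprocess import build_design
from prevtrend.synthetic import SimConfig, generate

from .conftest import make_tiny_records, make_two_country_records
from .oracles import dense_loglik

TINY_SPEC = ModelSpec(n_country_splines=1, knot_spacing_years=10.0)


class TestAicc:
    def test_formula_value(self):
        assert aicc(-50, 10, 100) == pytest.approx(100 + 20 + 220 / 89)

    def test_large_n_limit_is_aic(self):
        assert aicc(-50, 10, 10**9) == pytest.approx(100 + 20, abs=1e-5)

    def test_zero_params(self):
        assert aicc(-50, 0, 100) == 100.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-50, 10, 11)


class TestCountryCov:
    def test_compound_symmetry_definition(self):
        G = country_cov("compound_symmetry", 2, (2.0, 0.5))
        np.testing.assert_allclose(G, [[2, 1, 1], [1, 2, 1], [1, 1, 2]])

    def test_cs_with_zero_rho_is_diagonal(self):
        G = country_cov("compound_symmetry", 3, (1.5, 0.0))
        np.testing.assert_allclose(G, np.diag([1.5] * 4))

    def test_cs_correlation_bound(self):
        with pytest.raises(ValueError):
            country_cov("compound_symmetry", 2, (1.0, -0.6))

    def test_unstructured_identity(self):
        # log-Cholesky of I: zero logs on the diagonal, zero off-diagonals
        G = country_cov("unstructured", 2, [0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(G, np.eye(3))

    def test_diagonal(self):
        np.testing.assert_allclose(
            country_cov("diagonal", 1, (0.3, 0.7)), np.diag([0.3, 0.7])
        )


class TestMarginalLoglik:
    @pytest.mark.parametrize("estimation", ["REML", "ML"])
    def test_matches_dense_oracle(self, estimation):
        rng = np.random.default_rng(42)
        spec = replace(TINY_SPEC, estimation=estimation)
        G = country_cov("compound_symmetry", 1, (0.4, 0.3))
        for _ in range(5):
            design = build_design(make_tiny_records(rng))
            ll = marginal_loglik(0.3, 0.2, G, design, spec)
            assert ll == pytest.approx(
                dense_loglik(design, spec, 0.3, 0.2, G), abs=1e-10
            )

    def test_degenerate_limit_is_ols_loglik(self):
        """σ²_a = 0, G = 0, κ = 0 reduces to the homoscedastic OLS likelihood."""
        design = build_design(make_tiny_records(np.random.default_rng(9)))
        spec = replace(TINY_SPEC, estimation="ML", sse_multiplier=0.0)
        s2e = 0.17
        ll = marginal_loglik(0.0, s2e, np.zeros((2, 2)), design, spec)
        mm = _ModelMatrices(design, spec)
        beta = np.linalg.lstsq(mm.X, mm.y, rcond=None)[0]
        rss = float(np.sum((mm.y - mm.X @ beta) ** 2))
        ll0 = -0.5 * (mm.n * math.log(2 * math.pi * s2e) + rss / s2e)
        assert ll == pytest.approx(ll0, abs=1e-10)

    def test_s_enters_only_through_kappa(self):
        """With κ = 0 the likelihood ignores the sampling SEs entirely."""
        records = make_tiny_records(np.random.default_rng(10))
        doubled = [replace_sse(r, 2 * r.sse) for r in records]
        spec = replace(TINY_SPEC, sse_multiplier=0.0)
        G = country_cov("compound_symmetry", 1, (0.4, 0.3))
        ll1 = marginal_loglik(0.3, 0.2, G, build_design(records), spec)
        ll2 = marginal_loglik(0.3, 0.2, G, build_design(doubled), spec)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_non_psd_G_rejected(self):
        design = build_design(make_tiny_records(np.random.default_rng(11)))
        G_bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError):
            marginal_loglik(0.3, 0.2, G_bad, design, TINY_SPEC)


def replace_sse(rec, new_sse):
    from dataclasses import replace as dreplace

    return dreplace(rec, sse=new_sse)


class TestFit:
    def test_refit_is_bit_identical(self):
        design = build_design(make_two_country_records())
        spec = ModelSpec(n_country_splines=2, knot_spacing_years=10.0)
        f1 = fit(design, spec)
        f2 = fit(design, spec)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        assert f1.loglik == f2.loglik
        assert f1.sigma2_resid == f2.sigma2_resid

    def test_no_random_effects_constant_s_is_wls(self):
        """With variances frozen at zero and constant s the GLS collapses to
        ordinary weighted least squares."""
        from dataclasses import replace as dreplace

        records = [dreplace(r, sse=0.01) for r in make_two_country_records(seed=5)]
        design = build_design(records)
        spec = ModelSpec(n_country_splines=1, knot_spacing_years=10.0)
        d = spec.country_dim
        f = fit(design, spec, fix={"sigma2_a": 0.0, "G": np.zeros((d, d))})
        mm = _ModelMatrices(design, spec)
        w = 1.0 / (f.sigma2_resid + mm.s2)
        Xw = mm.X * w[:, None]
        beta_wls = np.linalg.solve(mm.X.T @ Xw, Xw.T @ mm.y)
        np.testing.assert_allclose(f.beta, beta_wls, atol=1e-6)

    def test_profile_consistency(self, small_fit):
        """The returned β̂ zeroes the GLS score at the fitted variances."""
        f, design = small_fit
        from .oracles import dense_pieces

        mm, U, Sigma, R, V = dense_pieces(
            design, f.spec, f.sigma2_spline, f.sigma2_resid, f.G
        )
        Vi = np.linalg.inv(V)
        score = mm.X.T @ Vi @ (mm.y - mm.X @ f.beta)
        assert np.max(np.abs(score)) < 1e-6 * max(1.0, np.max(np.abs(mm.X.T @ Vi @ mm.y)))

    def test_blups_shrink_to_zero_with_tiny_G(self):
        design = build_design(make_two_country_records())
        spec = ModelSpec(n_country_splines=1, knot_spacing_years=10.0)
        d = spec.country_dim
        f = fit(design, spec, fix={"G": 1e-12 * np.eye(d)})
        for c in f.countries:
            assert np.max(np.abs(f.blups[c])) < 1e-4

    def test_too_few_countries_rejected(self):
        records = [r for r in make_two_country_records() if r.country_id == "A"]
        with pytest.raises(ValueError):
            fit(build_design(records), ModelSpec(knot_spacing_years=10.0))

    def test_parameter_recovery_single_replicate(self):
        """One well-specified replicate lands near the generating values."""
        cfg = SimConfig(n_countries=15, surveys_per_country_mean=3.0, seed=77)
        records, truth = generate(cfg)
        f = fit(build_design(records), ModelSpec())
        est = dict(zip(f.x_names, f.beta))
        for name, true_val in truth.beta.items():
            assert est[name] == pytest.approx(true_val, abs=0.6)
        assert 0.1 < f.g_params["sigma2"] / cfg.g_sigma2 < 5.0


class TestSerialization:
    def test_round_trip_predictions_bit_identical(self, small_fit, tmp_path):
        f, _ = small_fit
        path = tmp_path / "model.json"
        f.save(path)
        f2 = FittedModel.load(path)
        req = PredictionRequest(country_id=f.countries[0], years=(1995.0, 2010.0))
        t1 = predict_point(f, req)
        t2 = predict_point(f2, req)
        np.testing.assert_array_equal(t1.estimate, t2.estimate)
        np.testing.assert_array_equal(t1.pi_low, t2.pi_low)
        assert f2.aicc == f.aicc


class TestSelectModel:
    def test_single_candidate(self, small_sim):
        records, _ = small_sim
        design = build_design(records)
        best, table = select_model(design, [ModelSpec(n_country_splines=2)])
        assert len(table) == 1
        assert bool(table["selected"].iloc[0])
        assert best.spec.estimation == "REML"
        assert best.spec.n_country_splines == 2

    def test_aicc_consistent_with_formula(self, small_sim):
        records, _ = small_sim
        design = build_design(records)
        best, table = select_model(design, [ModelSpec(n_country_splines=2)])
        row = table.iloc[0]
        assert row["aicc"] == pytest.approx(
            aicc(row["loglik_ml"], int(row["k"]), int(row["n"]))
        )

    def test_empty_candidate_list_rejected(self, small_sim):
        records, _ = small_sim
        with pytest.raises(ValueError):
            select_model(build_design(records), [])
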