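"""Diversification model likelihoods, nesting, and the DeltaAIC test."""

import subprocess

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import divshift as ds
from divshift.divmodels import (CONSTANT_RATE_MODELS, VARIABLE_RATE_MODELS,
                                _bd_loglik, fit_all, fit_model)
from divshift.trees import InternodeIntervals


@pytest.fixture(scope="module")
def yule_tree():
    return ds.simulate_pure_birth(60, 0.3, seed=101)


class TestPureBirth:
    def test_closed_form_example(self):
        iv = InternodeIntervals(np.array([1.0, 1.0]))  # n=3, T=5
        fit = fit_model("PB", iv)
        assert fit.params["lambda"] == pytest.approx(0.2)

    def test_mle_matches_numerical_optimum(self):
        for seed in range(10):
            iv = ds.simulate_pure_birth(30, 0.4, seed=seed).internode_intervals()
            fit = fit_model("PB", iv)
            k = np.arange(2, iv.n + 1)
            logk = np.sum(np.log(k[:-1]))

            def nll(lam):
                return -(logk + (iv.n - 2) * np.log(lam) - lam * iv.T)

            res = minimize_scalar(nll, bounds=(1e-6, 100), method="bounded",
                                  options={"xatol": 1e-12})
            assert fit.params["lambda"] == pytest.approx(res.x, rel=1e-6)
            assert fit.loglik == pytest.approx(-res.fun, rel=1e-9)

    def test_aic_counts_one_parameter(self, yule_tree):
        fit = fit_model("PB", yule_tree)
        assert fit.aic == pytest.approx(2 - 2 * fit.loglik)


class TestNesting:
    def test_variable_rate_models_dominate_pb(self, yule_tree):
        fits = fit_all(yule_tree)
        for m in VARIABLE_RATE_MODELS:
            assert fits[m].loglik >= fits["PB"].loglik - 1e-8

    def test_bd_at_mu_zero_equals_pb_likelihood(self, yule_tree):
        iv = yule_tree.internode_intervals()
        pb = fit_model("PB", iv)
        lam = pb.params["lambda"]
        assert _bd_loglik(iv.branching_times(), lam, 0.0) == pytest.approx(
            pb.loglik, rel=1e-12)

    def test_bd_fit_at_least_pb(self, yule_tree):
        fits = fit_all(yule_tree)
        assert fits["BD"].loglik >= fits["PB"].loglik - 1e-8

    def test_ddx_at_x_zero_is_pb(self, yule_tree):
        iv = yule_tree.internode_intervals()
        pb = fit_model("PB", iv)
        ddx = fit_model("DDX", iv)
        if ddx.params["x"] == 0.0:
            assert ddx.loglik == pytest.approx(pb.loglik, rel=1e-12)

    def test_ddl_boundary_reported_as_pb(self):
        # strongly accelerating data pushes the carrying capacity to infinity
        iv = InternodeIntervals(np.linspace(2.0, 0.05, 30))
        with pytest.warns(UserWarning, match="pure-birth-equivalent"):
            ddl = fit_model("DDL", iv)
        assert ddl.loglik == pytest.approx(fit_model("PB", iv).loglik)


class TestBD:
    def test_matches_ape_birthdeath(self, tmp_path):
        """Independent oracle: ape::birthdeath on birth-death trees."""
        rows = []
        trees = []
        for s in (1, 2, 3):
            tr = ds.simulate_birth_death(40, 1.0, 0.4, seed=s)
            trees.append(tr.to_newick(digits=17))
            fit = fit_model("BD", tr)
            rows.append((fit.params["a"], fit.params["r"], fit.loglik))
        f = tmp_path / "t.nwk"
        f.write_text("\n".join(trees) + "\n")
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(ape)); trs <- read.tree("{f}");'
             'for (tr in trs) { b <- birthdeath(tr);'
             ' cat(b$para["d/b"], b$para["b-d"], -b$dev/2, "\\n") }'],
            capture_output=True, text=True, check=True)
        for mine, line in zip(rows, r.stdout.strip().splitlines()):
            a_r, r_r, ll_r = map(float, line.split())
            assert mine[0] == pytest.approx(a_r, abs=2e-3)
            assert mine[1] == pytest.approx(r_r, rel=2e-3)
            assert mine[2] == pytest.approx(ll_r, rel=1e-6)

    def test_mu_bounded_below_lambda(self, yule_tree):
        fit = fit_model("BD", yule_tree)
        assert 0 <= fit.params["mu"] < fit.params["lambda"]


class TestRescaling:
    def test_pb_loglik_equivariance(self, yule_tree):
        # t -> c t with lam -> lam/c shifts loglik by -(n-2) log c
        iv = yule_tree.internode_intervals()
        c = 3.7
        scaled = InternodeIntervals(c * iv.g)
        f1, f2 = fit_model("PB", iv), fit_model("PB", scaled)
        n = iv.n
        assert f2.params["lambda"] == pytest.approx(f1.params["lambda"] / c)
        assert f2.loglik == pytest.approx(f1.loglik - (n - 2) * np.log(c),
                                          rel=1e-9)

    def test_delta_aic_scale_free(self, yule_tree):
        iv = yule_tree.internode_intervals()
        scaled = InternodeIntervals(5.0 * iv.g)
        d1 = {m: f.aic for m, f in fit_all(iv).items()}
        d2 = {m: f.aic for m, f in fit_all(scaled).items()}
        shift = 2 * (iv.n - 2) * np.log(5.0)
        for m in d1:
            assert d2[m] - d1[m] == pytest.approx(shift, rel=1e-6)


class TestY2R:
    def test_rate_ratio_recovery(self):
        # lam 0.1 -> 0.4 after the first third of splits: the fitted ratio
        # concentrates near 4
        ratios = []
        for s in range(40):
            tr = ds.simulate_rate_shift(150, 0.1, 0.4, k_shift=40, seed=s)
            fit = fit_model("Y2R", tr)
            ratios.append(fit.params["lambda2"] / fit.params["lambda1"])
        assert 2.5 <= np.median(ratios) <= 6.0

    def test_shift_time_inside_tree(self, yule_tree):
        fit = fit_model("Y2R", yule_tree)
        assert 0 < fit.params["t_shift"] < yule_tree.root_age

    def test_needs_four_tips(self):
        with pytest.raises(ValueError):
            fit_model("Y2R", InternodeIntervals(np.array([1.0, 1.0])))


class TestSurvivalFactorFlag:
    def test_flag_changes_pb_estimate_consistently(self, yule_tree):
        iv = yule_tree.internode_intervals()
        with_f = fit_model("PB", iv, condition_on_survival=True)
        without = fit_model("PB", iv, condition_on_survival=False)
        n, g = iv.n, iv.g
        T_full = iv.T
        T_trim = T_full - n * g[-1]
        assert with_f.params["lambda"] == pytest.approx((n - 2) / T_full)
        assert without.params["lambda"] == pytest.approx((n - 2) / T_trim)


class TestDeltaAIC:
    def test_rank_p_value_and_fields(self, yule_tree):
        res = ds.delta_aic_test(yule_tree, yule_tree.n, 0, reps=100, seed=7)
        assert 0 < res.p <= 1
        assert res.best_model in ds.MODELS
        assert res.null_deltas.size == 100

    def test_detects_decelerating_diversification(self):
        # genuine early burst: 4x rate drop after the first third of splits
        hits = 0
        for s in range(10):
            tr = ds.simulate_rate_shift(120, 0.4, 0.1, k_shift=40, seed=200 + s)
            res = ds.delta_aic_test(tr, 120, 0, reps=100, seed=s)
            hits += res.p < 0.05
        assert hits >= 8

    def test_best_model_on_shifted_data_is_variable_rate(self):
        best = []
        for s in range(6):
            tr = ds.simulate_rate_shift(120, 0.4, 0.1, k_shift=40, seed=300 + s)
            best.append(ds.DiversificationModel(tr).fit().best_model)
        assert sum(b in VARIABLE_RATE_MODELS for b in best) >= 5


class TestFacade:
    def test_results_surface(self, yule_tree):
        res = ds.DiversificationModel(yule_tree).fit()
        assert set(res.fits) == set(ds.MODELS)
        df = res.aic_table()
        assert list(df["model"]) == sorted(ds.MODELS,
                                           key=lambda m: res.fits[m].aic)
        assert "best model" in res.summary()
        assert res.delta_aic == pytest.approx(
            min(res.fits[m].aic for m in CONSTANT_RATE_MODELS)
            - min(res.fits[m].aic for m in VARIABLE_RATE_MODELS))
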