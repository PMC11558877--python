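import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi

import smallgee as sg
from smallgee.data_model import ClusterBlock
from smallgee.errors import ConvergenceWarning, SingularDesignError
from smallgee.gee import (
    link_inverse_and_derivatives,
    logistic_mle,
    score_and_information,
    solve_estimating_equation,
)
from smallgee.working_correlation import CorrelationModel

from conftest import make_blocks


class TestLinkDerivatives:
    def test_values_at_zero(self):
        mu, d1, d2, d3 = link_inverse_and_derivatives(np.array([0.0]))
        assert (mu[0], d1[0], d2[0], d3[0]) == (0.5, 0.25, 0.0, -0.125)

    def test_saturation_without_overflow(self):
        mu, d1, d2, d3 = link_inverse_and_derivatives(np.array([30.0, -30.0]))
        assert abs(mu[0] - 1) < 1e-12 and abs(mu[1]) < 1e-12
        assert np.all(d1 >= 0) and np.all(d1 < 1e-12)
        assert np.all(np.isfinite([d2, d3]))

    def test_derivatives_match_finite_differences(self):
        eta = np.random.default_rng(0).normal(scale=2.0, size=50)
        h = 1e-5
        mu_p = link_inverse_and_derivatives(eta + h)
        mu_m = link_inverse_and_derivatives(eta - h)
        _, d1, d2, d3 = link_inverse_and_derivatives(eta)
        np.testing.assert_allclose((mu_p[0] - mu_m[0]) / (2 * h), d1, atol=1e-6)
        np.testing.assert_allclose((mu_p[1] - mu_m[1]) / (2 * h), d2, atol=1e-6)
        np.testing.assert_allclose((mu_p[2] - mu_m[2]) / (2 * h), d3, atol=1e-6)


class TestScoreAndInformation:
    def test_score_vanishes_at_logistic_mle_under_independence(
        self, independent_design
    ):
        beta_hat = logistic_mle(independent_design.y, independent_design.X)
        corr = CorrelationModel(kind="independence", scale_fixed=True)
        U, _, _ = score_and_information(beta_hat, independent_design.blocks, corr)
        assert np.abs(U).max() < 1e-8

    def test_hand_arithmetic_single_observation(self):
        # one cluster, n=1, x=1, y=1, beta=0: mu=1/2, U = 0.5, Phi = 0.25
        block = ClusterBlock(0, np.array([1.0]), np.array([[1.0]]),
                             np.array([0]), np.array([0]))
        corr = CorrelationModel(kind="independence", scale_fixed=True)
        U, Phi, _ = score_and_information(np.array([0.0]), [block], corr)
        assert U[0] == pytest.approx(0.5)
        assert Phi[0, 0] == pytest.approx(0.25)

    def test_information_matches_per_cluster_summation_oracle(
        self, toy_blocks, toy_corr
    ):
        beta = np.array([0.2, -0.4])
        _, Phi, quants = score_and_information(beta, toy_blocks, toy_corr)
        brute = np.zeros((2, 2))
        for q in quants:
            brute += q.D.T @ q.Vinv @ q.D
        np.testing.assert_allclose(Phi, brute, atol=1e-12)


class TestFitGee:
    def test_independence_equals_logistic_mle(self, independent_design):
        fit = sg.fit_gee(independent_design, corstr="independence",
                         scale_fix=True, tol=1e-9)
        glm = smapi.GLM(independent_design.y, independent_design.X,
                        family=smapi.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-6)

    def test_matches_statsmodels_gee_exchangeable(self):
        """Full cross-validation against the independent GEE implementation."""
        from statsmodels.genmod.cov_struct import Exchangeable
        from statsmodels.genmod.generalized_estimating_equations import GEE

        spec = sg.SimulationSpec(
            K=80, n=4, beta=np.array([-0.3, 0.4, -0.15, -0.3, -0.45]),
            kind="exchangeable", rho=0.25, seed=3,
        )
        df = sg.generate(spec)
        mine = sg.fit(df, spec.formula, id="id", repeated="occasion",
                      corstr="exchangeable", beta_method="GEE", se_method="SA")
        sm_fit = GEE(
            mine.design.y, mine.design.X, groups=mine.design.frame["id"].values,
            family=smapi.families.Binomial(), cov_struct=Exchangeable(),
        ).fit()
        np.testing.assert_allclose(mine.fit.beta, sm_fit.params, atol=2e-5)
        np.testing.assert_allclose(mine.cov.se, sm_fit.bse, rtol=2e-4)
        assert mine.fit.alpha == pytest.approx(sm_fit.cov_struct.dep_params, abs=1e-6)

    def test_root_finder_oracle_on_toy_problem(self):
        from scipy.optimize import fsolve

        blocks = make_blocks(K=3, n=3, p=2, seed=8)
        corr = CorrelationModel(kind="exchangeable", n_occasions=3)
        fit = solve_estimating_equation(
            blocks, ["a", "b"], corr, init=np.zeros(2), tol=1e-10
        )
        # freeze the converged nuisance values and solve U(beta)=0 generically
        froz = CorrelationModel(kind="exchangeable", alpha=fit.alpha,
                                phi=fit.phi, n_occasions=3)
        root = fsolve(
            lambda b: score_and_information(b, blocks, froz)[0], np.array([1.0, -1.0])
        )
        np.testing.assert_allclose(fit.beta, root, atol=1e-8)

    def test_score_small_at_convergence(self, wheeze_gee_fit):
        assert np.abs(wheeze_gee_fit.score).max() < 1e-6
        assert wheeze_gee_fit.converged

    def test_invariant_to_cluster_order_and_relabeling(self, wheeze_df):
        res1 = sg.fit(wheeze_df, "Wheeze ~ City + C(Age)", id="ID",
                      repeated="Age", corstr="ar1", beta_method="GEE")
        shuffled = (
            wheeze_df.assign(ID=wheeze_df["ID"].map(lambda i: f"c{99 - i}"))
            .sort_values(["ID", "Age"], kind="stable")
            .reset_index(drop=True)
        )
        res2 = sg.fit(shuffled, "Wheeze ~ City + C(Age)", id="ID",
                      repeated="Age", corstr="ar1", beta_method="GEE")
        np.testing.assert_allclose(res1.fit.beta, res2.fit.beta, atol=1e-10)

    def test_duplicating_clusters_scales_score_linearly(self, wheeze_df):
        # at fixed nuisance values the estimating equation scales linearly in
        # the cluster set, so its root is unchanged under duplication; the
        # fitted values drift only through the -p small-sample corrections
        # in the phi/alpha moment denominators
        res1 = sg.fit(wheeze_df, "Wheeze ~ City + C(Age)", id="ID",
                      repeated="Age", corstr="ar1", beta_method="GEE")
        frozen = CorrelationModel(kind="ar1", alpha=res1.fit.alpha,
                                  phi=res1.fit.phi)
        doubled_blocks = res1.fit.blocks + res1.fit.blocks
        U1, P1, _ = score_and_information(res1.fit.beta, res1.fit.blocks, frozen)
        U2, P2, _ = score_and_information(res1.fit.beta, doubled_blocks, frozen)
        np.testing.assert_allclose(U2, 2 * U1, atol=1e-10)
        np.testing.assert_allclose(P2, 2 * P1, atol=1e-8)
        doubled = pd.concat(
            [wheeze_df, wheeze_df.assign(ID=wheeze_df["ID"] + 100)],
            ignore_index=True,
        )
        res2 = sg.fit(doubled, "Wheeze ~ City + C(Age)", id="ID",
                      repeated="Age", corstr="ar1", beta_method="GEE")
        np.testing.assert_allclose(res1.fit.beta, res2.fit.beta, atol=0.02)

    def test_independence_beta_invariant_to_scale_estimation(self, independent_design):
        fit_fix = sg.fit_gee(independent_design, corstr="independence",
                             scale_fix=True, tol=1e-9)
        fit_est = sg.fit_gee(independent_design, corstr="independence",
                             scale_fix=False, tol=1e-9)
        np.testing.assert_allclose(fit_fix.beta, fit_est.beta, atol=1e-8)

    def test_rank_deficient_design_errors(self):
        df = pd.DataFrame(
            {"id": [1, 2, 3, 4], "y": [0, 1, 0, 1], "x": [1.0, 1.0, 1.0, 1.0]}
        )
        des = sg.prepare(df, "y ~ 1", id="id")
        des.X = np.c_[des.X, des.X]  # force duplicated column past the encoder
        des.column_names = ["a", "b"]
        for b in des.blocks:
            b.X = np.c_[b.X, b.X]
        with pytest.raises(SingularDesignError):
            sg.fit_gee(des)

    def test_nonconvergence_warns_and_returns_fit(self, separated_design):
        with pytest.warns(ConvergenceWarning):
            fit = sg.fit_gee(separated_design, corstr="independence",
                             scale_fix=True)
        assert not fit.converged
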