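"""Cross-lagged panel fit, fit indices and Fisher Z stratum comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from crosslagmed import (
    EstimationError,
    build_two_wave_panel,
    child_two_wave_config,
    compute_fit_indices,
    fisher_z_compare,
    fit_cross_lagged,
    simulate_cohort,
)


def brute_force_ml_paths(panel: pd.DataFrame) -> np.ndarray:
    """Independent oracle: numerically maximize the multivariate-normal
    likelihood over *all* free parameters (exogenous Cholesky, 6 paths, 2
    log error variances) and return the 2x3 path matrix."""
    fy = panel["followup_years"].to_numpy()
    fz = (fy - fy.mean()) / fy.std(ddof=1)
    data = np.column_stack([panel["bmi_z_base"], panel["ua_z_base"], fz,
                            panel["bmi_z_fu"], panel["ua_z_fu"]])
    S = np.cov(data, rowvar=False, ddof=1)
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)

    def implied(theta):
        L = np.zeros((3, 3))
        L[np.tril_indices(3)] = theta[:6]
        Phi = L @ L.T
        B = theta[6:12].reshape(2, 3)
        Psi = np.diag(np.exp(theta[12:14]))
        Sigma = np.empty((5, 5))
        Sigma[:3, :3] = Phi
        Sigma[:3, 3:] = Phi @ B.T
        Sigma[3:, :3] = B @ Phi
        Sigma[3:, 3:] = B @ Phi @ B.T + Psi
        return Sigma

    def f_ml(theta):
        Sigma = implied(theta)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e10
        return logdet - logdet_s + float(np.trace(S @ np.linalg.inv(Sigma))) - p

    theta0 = np.concatenate([[1, 0, 1, 0, 0, 1.0], np.zeros(6), np.zeros(2)])
    opt = optimize.minimize(f_ml, theta0, method="BFGS",
                            options=dict(gtol=1e-12, maxiter=5000))
    opt = optimize.minimize(f_ml, opt.x, method="Nelder-Mead",
                            options=dict(xatol=1e-12, fatol=1e-14,
                                         maxiter=20000, maxfev=40000))
    return opt.x[6:12].reshape(2, 3)


class TestFit:
    def test_ols_equals_brute_force_ml_on_toy_panel(self, toy_panel):
        """Recursive model with uncorrelated errors: OLS point estimates equal
        the numerical ML solution over all free parameters (tol 1e-5)."""
        res = fit_cross_lagged(toy_panel, min_n=2)
        B = brute_force_ml_paths(toy_panel)
        ols = np.array([
            [res.track_bmi.estimate, res.rho1.estimate, res.gamma_bmi.estimate],
            [res.rho2.estimate, res.track_ua.estimate, res.gamma_ua.estimate]])
        assert np.max(np.abs(B - ols)) < 1e-5

    def test_recovers_generative_paths(self, child_cohort):
        panel = build_two_wave_panel(child_cohort, "child")
        res = fit_cross_lagged(panel)
        n = res.n
        assert abs(res.rho2.estimate - 0.145) < 4 / np.sqrt(n)
        assert abs(res.rho1.estimate - 0.0) < 4 / np.sqrt(n)
        assert res.rho2.p < 0.05
        assert 0 <= res.rsq_bmi <= 1 and 0 <= res.rsq_ua <= 1
        assert res.df == 1
        assert res.good_fit  # correctly specified model: CFI high, RMR small

    def test_correlations_reported(self, child_cohort):
        panel = build_two_wave_panel(child_cohort, "child")
        res = fit_cross_lagged(panel)
        assert res.r1 == pytest.approx(np.corrcoef(panel.bmi_z_base, panel.ua_z_base)[0, 1])
        assert res.r2 > res.r3 > res.r1  # BMI tracks more strongly than UA; both above r1

    def test_small_panel_refused(self, toy_panel):
        with pytest.raises(EstimationError, match="at least 30"):
            fit_cross_lagged(toy_panel)

    def test_saturated_variant_has_zero_df(self, child_cohort):
        panel = build_two_wave_panel(child_cohort, "child")
        res = fit_cross_lagged(panel, residual_cov_free=True)
        assert res.df == 0
        assert res.chisq == pytest.approx(0.0, abs=1e-8)
        assert res.cfi == 1.0

    def test_affine_invariance_of_estimates(self, child_cohort):
        """Rescaling raw inputs upstream leaves path estimates unchanged."""
        panel = build_two_wave_panel(child_cohort, "child")
        df2 = child_cohort.copy()
        df2["uric_acid"] = df2["uric_acid"] * 59.48  # mg/dL -> umol/L
        panel2 = build_two_wave_panel(df2, "child")
        r1, r2 = fit_cross_lagged(panel), fit_cross_lagged(panel2)
        assert r1.rho1.estimate == pytest.approx(r2.rho1.estimate, abs=1e-10)
        assert r1.rho2.estimate == pytest.approx(r2.rho2.estimate, abs=1e-10)

    def test_stratified_fit_equals_fit_on_subset(self, child_cohort):
        panel = build_two_wave_panel(child_cohort, "child")
        sub = panel[panel["race"] == "White"].reset_index(drop=True)
        direct = fit_cross_lagged(sub)
        again = fit_cross_lagged(panel[panel["race"] == "White"].reset_index(drop=True))
        assert direct.rho2.estimate == again.rho2.estimate


class TestFitIndices:
    def test_saturated_fit(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        cfi, rmr, chisq = compute_fit_indices(S, S.copy(), n=100, df_model=0)
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert rmr == pytest.approx(0.0, abs=1e-12)
        assert cfi == 1.0

    def test_rmr_matches_elementwise_formula(self):
        S = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.1], [0.2, 0.1, 1.0]])
        Sigma = np.array([[1.05, 0.35, 0.25], [0.35, 0.95, 0.12], [0.25, 0.12, 1.02]])
        # independent elementwise evaluation of the definition
        acc = sum((S[i, j] - Sigma[i, j]) ** 2 for i in range(3) for j in range(i + 1))
        expected_rmr = np.sqrt(acc / 6.0)
        _, rmr, chisq = compute_fit_indices(S, Sigma, n=200, df_model=1)
        assert rmr == pytest.approx(expected_rmr, abs=1e-12)
        # chi-square against the direct ML discrepancy formula
        expected_chi = 199 * (np.log(np.linalg.det(Sigma)) - np.log(np.linalg.det(S))
                              + np.trace(S @ np.linalg.inv(Sigma)) - 3)
        assert chisq == pytest.approx(expected_chi, abs=1e-9)

    def test_rmr_monotone_in_misfit(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        near = np.array([[1.0, 0.35], [0.35, 1.0]])
        far = np.array([[1.0, 0.25], [0.25, 1.0]])
        _, rmr_near, _ = compute_fit_indices(S, near, 100, 1)
        _, rmr_far, _ = compute_fit_indices(S, far, 100, 1)
        assert rmr_far > rmr_near

    def test_cfi_bounds(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        bad = np.eye(2)
        cfi, _, _ = compute_fit_indices(S, bad, 500, df_model=1)
        assert 0.0 <= cfi <= 1.0

    def test_non_pd_input_rejected(self):
        S = np.array([[1.0, 1.2], [1.2, 1.0]])  # not PD
        with pytest.raises(ValueError, match="positive definite"):
            compute_fit_indices(S, np.eye(2), 100, 1)


class TestFisherZ:
    def test_equal_coefficients_give_zero(self):
        cmp_ = fisher_z_compare(0.4, 120, 0.4, 80)
        assert cmp_.z == 0.0
        assert cmp_.p == 1.0

    def test_antisymmetry_under_group_swap(self):
        a = fisher_z_compare(0.5, 103, 0.3, 97)
        b = fisher_z_compare(0.3, 97, 0.5, 103)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_matches_arithmetic_oracle(self):
        """(0.5, n=103) vs (0.3, n=103): independent evaluation of the formula."""
        z_expected = (np.arctanh(0.5) - np.arctanh(0.3)) / np.sqrt(1 / 100 + 1 / 100)
        p_expected = 2 * (1 - stats.norm.cdf(abs(z_expected)))
        cmp_ = fisher_z_compare(0.5, 103, 0.3, 103)
        assert cmp_.z == pytest.approx(z_expected, abs=1e-12)
        assert cmp_.p == pytest.approx(p_expected, abs=1e-12)

    @pytest.mark.parametrize("c1,n1,c2,n2", [(1.0, 50, 0.3, 50), (0.5, 3, 0.3, 50)])
    def test_domain_errors(self, c1, n1, c2, n2):
        with pytest.raises(ValueError):
            fisher_z_compare(c1, n1, c2, n2)


def test_chisq_calibration_against_model_df():
    """Under the correctly specified model the restriction chi-square has mean
    ~ df = 1 across replicates (50 reps here; the deeper 500-rep calibration
    runs in the acceptance suite)."""
    chis = []
    for rep in range(50):
        cfg = child_two_wave_config(n_subjects=500, seed=10_000 + rep)
        panel = build_two_wave_panel(simulate_cohort(cfg), "child")
        chis.append(fit_cross_lagged(panel).chisq)
    chis = np.asarray(chis)
    se = chis.std(ddof=1) / np.sqrt(len(chis))
    assert abs(chis.mean() - 1.0) < 3 * se + 0.2
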