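"""SAEM engine, importance-sampling likelihood, FIM and test statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from bevpkpd.cohort import CohortSpec, dense_plan, generate_cohort, simulate_dataset
from bevpkpd.likelihood import importance_sampling_core, importance_sampling_ll
from bevpkpd.models import pk_reference
from bevpkpd.popmodel import ParameterSpec
from bevpkpd.saem import SAEMConfig, saem_fit
from bevpkpd.stats import (
    LRT_CRITICAL_1DF,
    information_criteria,
    lrt,
    relative_standard_error,
    wald_test,
)
from bevpkpd.uncertainty import compute_se_rse


class TestWald:
    def test_icam1_effect_on_qss_clearance(self):
        """Printed coefficient/SE pair reproduces the reported p-value."""
        _, p = wald_test(-0.33, 0.139)
        assert p == pytest.approx(0.0177, abs=2e-4)

    def test_rs699947_effect_on_baseline_vegf(self):
        _, p = wald_test(-0.851, 0.242)
        assert p == pytest.approx(0.000445, abs=2e-5)

    def test_zero_coefficient(self):
        z, p = wald_test(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestLRT:
    def test_critical_drop_is_five_percent(self):
        drop, p = lrt(103.84, 100.0)
        assert drop == pytest.approx(3.84)
        assert p == pytest.approx(0.05, abs=5e-4)
        assert LRT_CRITICAL_1DF == pytest.approx(3.8415, abs=1e-3)

    def test_zero_drop(self):
        assert lrt(100.0, 100.0)[1] == 1.0

    def test_highly_significant_drop(self):
        _, p = lrt(110.83, 100.0)
        assert p == pytest.approx(0.001, abs=5e-5)

    def test_negative_drop_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            _, p = lrt(100.0, 101.0)
        assert p == 1.0


class TestInformationCriteria:
    def test_hand_example(self):
        aic, bic = information_criteria(100.0, 5, 46)
        assert aic == pytest.approx(110.0)
        assert bic == pytest.approx(100.0 + 5 * np.log(46))

    def test_zero_parameters(self):
        assert information_criteria(50.0, 0, 10) == (50.0, 50.0)

    def test_bic_exceeds_aic_beyond_n8(self):
        for n in (8, 20, 46):
            aic, bic = information_criteria(0.0, 3, n)
            assert bic > aic


class TestRSE:
    @pytest.mark.parametrize("est,se,expected", [
        (0.388, 0.0288, 7.4),     # PK/PD clearance
        (135.0, 46.5, 34.4),      # binding constant
        (5.0, 0.0, 0.0),          # fixed parameter
    ])
    def test_values(self, est, se, expected):
        assert relative_standard_error(est, se) == pytest.approx(expected, abs=0.05)


def _nobsv_spec(sigma=1e-6):
    spec = pk_reference()
    spec.correlations = []
    for p in spec.parameters:
        p.omega_init = 0.0
    spec.error_models["drug"].b = sigma
    return spec


class TestSAEM:
    def test_noise_free_limit_recovers_truth(self):
        """omega=0, sigma -> 0: the fit degenerates to NLS and recovers the
        generating parameters essentially exactly."""
        coh = generate_cohort(CohortSpec(n_subjects=20, p_q2w=1.0), 71)
        ds, _ = simulate_dataset(coh, _nobsv_spec(), 72,
                                 plan=dense_plan(4, observables=(1,)))
        fit_spec = _nobsv_spec(sigma=0.05)
        b0 = fit_spec.init_coeffs() + np.tile([0.15, -0.12], 4)
        fit = saem_fit(ds, fit_spec, SAEMConfig(seed=73), init_coeffs=b0)
        for name, truth in (("CL", 0.200), ("V1", 3.09), ("Q", 0.35), ("V2", 2.39)):
            assert fit.fixed_effects[name] == pytest.approx(truth, rel=1e-3)
        assert fit.covariate_coeffs["beta_CL_RS1799969"] == pytest.approx(-0.423, abs=1e-3)

    def test_deterministic_under_seed(self, small_pk_dataset):
        ds, _ = small_pk_dataset
        cfg = SAEMConfig(k1=40, k2=15, seed=5)
        f1 = saem_fit(ds, pk_reference(), cfg)
        f2 = saem_fit(ds, pk_reference(), cfg)
        np.testing.assert_array_equal(f1.coeffs, f2.coeffs)
        assert f1.omegas == f2.omegas
        assert f1.sigmas == f2.sigmas
        np.testing.assert_array_equal(f1.cond_mean_phi, f2.cond_mean_phi)

    def test_misdeclared_parameters_rejected(self, small_pk_dataset):
        ds, _ = small_pk_dataset
        spec = pk_reference()
        spec.parameters.append(ParameterSpec("Kss", 100.0))
        with pytest.raises(ValueError, match="needs parameters"):
            saem_fit(ds, spec, SAEMConfig(k1=5, k2=5, seed=1))

    def test_prior_penalty_shifts_estimate_toward_center(self, small_pk_dataset):
        """A tight Gaussian prior on log CL pins the estimate at its center."""
        ds, _ = small_pk_dataset
        cfg = SAEMConfig(k1=60, k2=20, seed=6)
        free = saem_fit(ds, pk_reference(), cfg)
        pinned = saem_fit(ds, pk_reference(), cfg,
                          priors={"CL": (0.30, 0.01)})
        assert pinned.fixed_effects["CL"] == pytest.approx(0.30, rel=0.05)
        assert abs(free.fixed_effects["CL"] - 0.30) > 0.05


class TestImportanceSampling:
    def test_linear_gaussian_special_case_matches_closed_form(self):
        """Identity structural function: y_ij = phi_i + eps. The marginal is
        Gaussian with variance omega^2 + sigma^2 and known in closed form."""
        rng = np.random.default_rng(10)
        n, reps = 30, 3
        omega, sigma, mu = 0.5, 0.3, 2.0
        phi_true = mu + omega * rng.standard_normal(n)
        y = np.repeat(phi_true, reps) + sigma * rng.standard_normal(n * reps)
        obs_subj = np.repeat(np.arange(n), reps)

        X = np.ones((n, 1, 1))
        b = np.array([mu])
        om = np.array([[omega ** 2]])
        # conditional posterior of phi given y (conjugate normal)
        prec = 1 / omega ** 2 + reps / sigma ** 2
        post_var = 1 / prec
        ybar = y.reshape(n, reps).mean(axis=1)
        post_mean = post_var * (mu / omega ** 2 + reps * ybar / sigma ** 2)

        ll, se = importance_sampling_core(
            predict=lambda phi: phi[obs_subj, 0],
            y=y, obs_subj=obs_subj,
            sd_of_pred=lambda pred: np.full_like(pred, sigma),
            n_subjects=n, X=X, b=b, omega=om,
            mu=post_mean[:, None], cov=np.full((n, 1, 1), post_var * 1.5),
            n_samples=2000, rng=np.random.default_rng(11))
        est = -2 * ll.sum()

        # closed-form marginal: ybar ~ N(mu, omega^2 + sigma^2/reps) plus
        # within-subject residual component
        exact = 0.0
        for i in range(n):
            yi = y[obs_subj == i]
            V = sigma ** 2 * np.eye(reps) + omega ** 2
            d = yi - mu
            exact += (d @ np.linalg.solve(V, d) + np.linalg.slogdet(V)[1]
                      + reps * np.log(2 * np.pi))
        assert est == pytest.approx(exact, abs=3 * se + 1e-6)

    def test_more_samples_reduce_monte_carlo_error(self, small_pk_dataset, small_pk_fit):
        ds, _ = small_pk_dataset
        vals_small = [importance_sampling_ll(ds, pk_reference(), small_pk_fit,
                                             n_samples=100, seed=s)[0]
                      for s in range(6)]
        vals_big = [importance_sampling_ll(ds, pk_reference(), small_pk_fit,
                                           n_samples=400, seed=s)[0]
                    for s in range(6)]
        assert np.var(vals_big) < np.var(vals_small)

    def test_true_model_beats_covariate_free_model(self):
        """On data simulated with strong covariate effects, the -2LL of the
        generating model is smaller than that of the covariate-free fit."""
        wins = 0
        for rep in range(3):
            coh = generate_cohort(CohortSpec(n_subjects=30, p_q2w=1.0), 80 + rep)
            ds, _ = simulate_dataset(coh, pk_reference(), 90 + rep,
                                     plan=dense_plan(4, observables=(1,)))
            cfg = SAEMConfig(k1=60, k2=20, seed=95 + rep)
            fit_true = saem_fit(ds, pk_reference(), cfg)
            bare = pk_reference()
            bare.covariate_effects = []
            fit_bare = saem_fit(ds, bare, cfg)
            m2_true, _ = importance_sampling_ll(ds, pk_reference(), fit_true,
                                                n_samples=300, seed=rep)
            m2_bare, _ = importance_sampling_ll(ds, bare, fit_bare,
                                                n_samples=300, seed=rep)
            wins += int(m2_true < m2_bare)
        assert wins >= 2


class TestFIM:
    def test_se_and_wald_available_after_fit(self, small_pk_dataset, small_pk_fit):
        ds, _ = small_pk_dataset
        fit = compute_se_rse(ds, pk_reference(), small_pk_fit)
        assert set(fit.wald_p) == {e.label for e in pk_reference().covariate_effects}
        for name in ("CL", "V1", "Q", "V2"):
            assert np.isfinite(fit.se[name]) and fit.se[name] > 0
            assert fit.rse[name] == pytest.approx(
                100 * fit.se[name] / fit.fixed_effects[name])
        # the generating rs1799969 effect is strong enough to be significant
        assert fit.wald_p["beta_CL_RS1799969"] < 0.05

    def test_duplicated_covariate_yields_singular_fim(self, small_pk_dataset):
        ds, _ = small_pk_dataset
        spec = pk_reference()
        spec.covariate_effects = spec.covariate_effects + [
            type(spec.covariate_effects[1])("CL", "RS1799969", "categorical", -0.423)]
        fit = saem_fit(ds, spec, SAEMConfig(k1=30, k2=10, seed=7))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            compute_se_rse(ds, spec, fit)
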