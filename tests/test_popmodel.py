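"""Population layer: covariate equations, random effects, residual error."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bevpkpd.models import pk_reference, pkpd_reference, qss_reference
from bevpkpd.popmodel import (
    CovariateEffect,
    ErrorModel,
    RandomEffectsSpec,
    apply_error,
    individual_params,
    observation_likelihood,
    sample_etas,
)

REF_COV = {"WT": 70.0, "AGE": 63.0, "SEX": 1, "RS699947": 0, "RS1570360": 0,
           "RS2010963": 0, "RS5498": 0, "RS1799969": 0, "REG": 1, "COTX": 1}


class TestIndividualParams:
    def test_reference_subject_recovers_fixed_effects(self):
        """eta = 0 at 70 kg all-wild-type must return the population values."""
        for make in (pk_reference, qss_reference, pkpd_reference):
            spec = make()
            pars = individual_params(spec, spec.init_coeffs(), REF_COV)
            for prm in spec.parameters:
                assert pars[prm.name] == pytest.approx(prm.init, rel=1e-12), prm.name

    @pytest.mark.parametrize("cov,expected", [
        ({}, 0.200),                                   # identity case
        ({"RS1799969": 1}, 0.200 * np.exp(-0.423)),    # mutant carrier: 0.1310
        ({"WT": 80.0}, 0.200 * (80 / 70) ** 1.04),     # 80 kg: 0.2298
    ])
    def test_clearance_covariate_shifts(self, cov, expected):
        spec = pk_reference()
        pars = individual_params(spec, spec.init_coeffs(), {**REF_COV, **cov})
        assert pars["CL"] == pytest.approx(expected, rel=1e-10)

    def test_every_coefficient_shift_reproduced(self):
        """At eta=0 each covariate effect multiplies its target by exp(beta)
        (categorical) or (x/ref)^beta (continuous)."""
        for make in (pk_reference, qss_reference, pkpd_reference):
            spec = make()
            base = individual_params(spec, spec.init_coeffs(), REF_COV)
            for eff in spec.covariate_effects:
                if eff.kind == "categorical":
                    cov = {**REF_COV, eff.covariate: 1}
                    factor = np.exp(eff.coefficient)
                else:
                    cov = {**REF_COV, eff.covariate: eff.reference * 1.3}
                    factor = 1.3 ** eff.coefficient
                pars = individual_params(spec, spec.init_coeffs(), cov)
                assert pars[eff.parameter] == pytest.approx(
                    base[eff.parameter] * factor, rel=1e-10), eff.label

    def test_missing_covariate_named_in_error(self):
        spec = pk_reference()
        cov = {k: v for k, v in REF_COV.items() if k != "RS1799969"}
        with pytest.raises(KeyError, match="RS1799969"):
            individual_params(spec, spec.init_coeffs(), cov)

    def test_laws_guarantee_bounds(self):
        spec = pkpd_reference()
        rng = np.random.default_rng(3)
        for _ in range(200):
            eta = dict(zip(spec.param_names, rng.normal(0, 2, len(spec.parameters))))
            pars = individual_params(spec, spec.init_coeffs(), REF_COV, eta)
            assert all(v > 0 for v in pars.values())
            assert 0 < pars["Imax"] < 1


class TestSampleEtas:
    ORDER = ["CL", "V1", "Q", "V2"]

    def test_zero_omega_degenerate(self):
        spec = RandomEffectsSpec(omegas={p: 0.0 for p in self.ORDER})
        etas = sample_etas(spec, self.ORDER, 10, seed=1)
        assert np.all(etas == 0.0)

    def test_correlation_recovered_at_large_n(self):
        spec = RandomEffectsSpec(
            omegas={"CL": 0.319, "V1": 0.174, "Q": 0.160, "V2": 0.676},
            correlations=[("CL", "Q", -0.999)])
        etas = sample_etas(spec, self.ORDER, 100_000, seed=2)
        r = np.corrcoef(etas[:, 0], etas[:, 2])[0, 1]
        assert r == pytest.approx(-0.999, abs=0.01)
        assert etas[:, 0].std() == pytest.approx(0.319, rel=0.02)

    def test_deterministic_under_seed(self):
        spec = RandomEffectsSpec(omegas={p: 0.3 for p in self.ORDER})
        np.testing.assert_array_equal(
            sample_etas(spec, self.ORDER, 50, seed=9),
            sample_etas(spec, self.ORDER, 50, seed=9))

    def test_non_positive_definite_rejected(self):
        spec = RandomEffectsSpec(
            omegas={"CL": 0.3, "V1": 0.3, "Q": 0.3, "V2": 0.3},
            correlations=[("CL", "Q", 0.99), ("CL", "V1", 0.99),
                          ("Q", "V1", -0.99)])
        with pytest.raises(ValueError, match="positive definite"):
            sample_etas(spec, self.ORDER, 5, seed=1)


class TestErrorModel:
    def test_zero_sigma_returns_prediction(self):
        em = ErrorModel("proportional", b=1e-300)
        pred = np.array([1.0, 50.0])
        np.testing.assert_allclose(apply_error(pred, em, 0), pred)

    def test_loglik_maximized_at_observation_equal_prediction(self):
        em = ErrorModel("proportional", b=0.246)
        pred = np.array([50.0])
        ll_at_mode = observation_likelihood(pred, pred, em)
        for shift in (0.9, 0.99, 1.01, 1.1):
            assert observation_likelihood(pred, pred * shift, em) < ll_at_mode

    def test_proportional_residuals_standard_normal(self):
        em = ErrorModel("proportional", b=0.246)
        pred = np.full(100_000, 80.0)
        obs = apply_error(pred, em, 12)
        z = (obs - pred) / (0.246 * pred)
        assert sps.normaltest(z).pvalue > 0.01
        assert z.std() == pytest.approx(1.0, abs=0.02)

    def test_combined_sd(self):
        em = ErrorModel("combined", a=3.0, b=0.1)
        np.testing.assert_allclose(em.sd(np.array([40.0])),
                                   np.sqrt(9.0 + 16.0))

    def test_proportional_rejects_nonpositive_prediction(self):
        em = ErrorModel("proportional", b=0.2)
        with pytest.raises(ValueError, match="non-positive"):
            em.sd(np.array([0.0]))


class TestYamlRoundTrip:
    def test_spec_round_trips(self, tmp_path):
        spec = qss_reference()
        path = tmp_path / "qss.yaml"
        spec.to_yaml(path)
        spec2 = type(spec).from_yaml(path)
        assert spec2.structural == spec.structural
        assert spec2.param_names == spec.param_names
        assert spec2.coeff_labels == spec.coeff_labels
        np.testing.assert_allclose(spec2.init_coeffs(), spec.init_coeffs())
        assert spec2.error_models["ligand"].b == spec.error_models["ligand"].b
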