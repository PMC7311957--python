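"""Covariate screening, stepwise selection and independence tests."""

import numpy as np
import pandas as pd
import pytest

from bevpkpd.cohort import CohortSpec, dense_plan, generate_cohort, simulate_dataset
from bevpkpd.covariates import (
    correlation_inclusion,
    correlation_rule,
    independence_table,
    independence_tests,
    passes_inclusion,
    screen_covariates,
    stepwise_select,
)
from bevpkpd.models import pk_reference
from bevpkpd.popmodel import CovariateEffect
from bevpkpd.saem import SAEMConfig
from bevpkpd.uncertainty import compute_se_rse


def _eta_frame(values):
    return pd.DataFrame({"eta_CL": values})


class TestScreening:
    def test_type_one_error_near_nominal(self):
        """Independent covariates: flag rate over replicates stays near 5%."""
        rng = np.random.default_rng(42)
        n, reps = 60, 600
        hits = 0
        for _ in range(reps):
            eta = rng.standard_normal(n)
            cov = pd.DataFrame({"RS5498": rng.integers(0, 2, n)})
            tab = screen_covariates(_eta_frame(eta), cov)
            hits += int(tab["candidate"].iloc[0])
        rate = hits / reps
        # binomial 99% band around 0.05 at 600 replicates
        assert 0.027 < rate < 0.075

    def test_true_weight_effect_detected(self):
        """eta_CL carrying the published weight exponent is flagged nearly
        always at n=200."""
        rng = np.random.default_rng(7)
        n, reps, hits = 200, 60, 0
        for _ in range(reps):
            w = 74.5 * np.exp(0.18 * rng.standard_normal(n))
            eta = 1.04 * np.log(w / 70.0) + 0.319 * rng.standard_normal(n)
            cov = pd.DataFrame({"WT": w})
            tab = screen_covariates(_eta_frame(eta), cov)
            hits += int(tab["candidate"].iloc[0])
        assert hits / reps >= 0.95

    def test_identical_group_means_not_flagged(self):
        e = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        cov = pd.DataFrame({"RS5498": [0, 0, 0, 1, 1, 1]})
        tab = screen_covariates(_eta_frame(e), cov)
        assert tab["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tab["p"].iloc[0] == pytest.approx(1.0)

    def test_constant_covariate_skipped_with_note(self):
        e = np.random.default_rng(1).standard_normal(20)
        cov = pd.DataFrame({"COTX": np.ones(20)})
        tab = screen_covariates(_eta_frame(e), cov)
        assert not tab["candidate"].iloc[0]
        assert "constant" in tab["note"].iloc[0]

    def test_screening_on_real_fit_flags_missing_covariate(self, small_pk_fit,
                                                           small_cohort):
        """EBEs from a fit *without* the rs1799969 term correlate with it."""
        from bevpkpd.saem import saem_fit
        # the session fixture fit includes all effects: its EBEs are clean
        tab = screen_covariates(small_pk_fit.ebes[["eta_CL"]],
                                small_cohort[["RS1799969"]])
        assert not tab["candidate"].iloc[0]


class TestInclusionRules:
    def test_both_criteria_required(self):
        assert not passes_inclusion(wald_p=0.04, lrt_drop=3.0)
        assert not passes_inclusion(wald_p=0.06, lrt_drop=10.0)
        assert passes_inclusion(wald_p=0.01, lrt_drop=5.0)

    @pytest.mark.parametrize("r,p,rse,expected", [
        (-0.999, 0.01, 22.0, True),    # published eta(CL,Q) correlation
        (0.3, 0.01, 10.0, False),      # |r| too small
        (-0.9, 0.001, 40.0, False),    # too imprecise
        (-0.9, 0.2, 10.0, False),      # not significant
    ])
    def test_correlation_rule(self, r, p, rse, expected):
        assert correlation_rule(r, p, rse) is expected

    def test_correlation_inclusion_on_fit(self, small_pk_dataset, small_pk_fit):
        ds, _ = small_pk_dataset
        fit = compute_se_rse(ds, pk_reference(), small_pk_fit)
        res = correlation_inclusion(fit, ("CL", "Q"))
        assert set(res) >= {"r", "p", "rse_pct", "include"}
        assert -1 <= res["r"] <= 1


@pytest.fixture(scope="module")
def strong_effect_data():
    """Small cohort simulated with only the (strong) rs1799969 CL effect."""
    spec = pk_reference()
    spec.covariate_effects = [
        CovariateEffect("CL", "RS1799969", "categorical", -0.9)]
    spec.correlations = []
    coh = generate_cohort(CohortSpec(n_subjects=36, p_q2w=1.0,
                                     p_mutant={"RS699947": 0.5,
                                               "RS1570360": 0.5,
                                               "RS2010963": 0.5,
                                               "RS5498": 0.5,
                                               "RS1799969": 0.5}), 30)
    ds, _ = simulate_dataset(coh, spec, 31,
                             plan=dense_plan(6, observables=(1,)))
    return ds


class TestStepwise:
    def _base_and_candidates(self):
        base = pk_reference()
        base.covariate_effects = []
        base.correlations = []
        cands = [CovariateEffect("CL", "RS1799969", "categorical", 0.0),
                 CovariateEffect("CL", "RS5498", "categorical", 0.0)]
        return base, cands

    def test_true_effect_retained_null_effect_dropped(self, strong_effect_data):
        base, cands = self._base_and_candidates()
        trace = stepwise_select(strong_effect_data, base, cands,
                                SAEMConfig(k1=60, k2=20, seed=11),
                                ll_samples=300)
        assert "beta_CL_RS1799969" in trace.retained
        assert "beta_CL_RS5498" not in trace.retained
        assert any(s.action == "add" and s.effect == "beta_CL_RS1799969"
                   for s in trace.steps)

    def test_trace_serializes(self, strong_effect_data, tmp_path):
        base, cands = self._base_and_candidates()
        trace = stepwise_select(strong_effect_data, base, cands[:1],
                                SAEMConfig(k1=50, k2=15, seed=13),
                                ll_samples=200)
        out = tmp_path / "trace.json"
        trace.to_json(out)
        assert out.exists() and "retained" in out.read_text()
        assert "beta_CL_RS1799969" in trace.log()


class TestIndependence:
    def test_balanced_table_all_p_one(self):
        a = np.repeat([0, 0, 1, 1], 25)
        b = np.tile([0, 1], 50)
        res = independence_tests(a, b)
        assert res["chi2_p"] == pytest.approx(1.0)
        assert res["chi2_yates_p"] == pytest.approx(1.0)
        assert res["fisher_p"] == pytest.approx(1.0)
        assert not res["dependent"]

    def test_perfect_association_fisher(self):
        a = np.repeat([0, 1], 20)
        res = independence_tests(a, a)
        assert res["fisher_p"] < 1e-9
        assert res["dependent"]

    def test_empty_level_invalidates_chi_square(self):
        a = np.zeros(10, dtype=int)
        b = np.repeat([0, 1], 5)
        res = independence_tests(a, b)
        assert res["chi2_valid"] is False

    def test_independent_genotypes_rarely_flagged(self):
        """SNPs drawn independently at the study frequencies, n=46: the
        pairwise dependence rate stays near the nominal level."""
        hits = total = 0
        for rep in range(30):
            coh = generate_cohort(CohortSpec(), 500 + rep)
            tab = independence_table(
                coh, columns=["RS699947", "RS1570360", "RS2010963",
                              "RS5498", "RS1799969"])
            hits += int(tab["dependent"].sum())
            total += len(tab)
        assert hits / total < 0.15
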