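"""Structural kinetic cores against independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from bevpkpd.structural import (
    DoseEvent,
    PDParams,
    PKParams,
    QSSParams,
    imax_effect,
    pk2_conc,
    pkpd_simulate,
    qss_free_drug,
    qss_free_target,
    qss_simulate,
)


def _ode_pk2(times, doses, p, rtol=1e-11):
    """Independent oracle: adaptive ODE integration of the 2-cmt system."""
    def rhs(t, y):
        rate = sum(d.amount / d.tinf for d in doses if d.time < t <= d.time + d.tinf)
        a1, a2 = y
        return [rate - (p.CL + p.Q) / p.V1 * a1 + p.Q / p.V2 * a2,
                p.Q / p.V1 * a1 - p.Q / p.V2 * a2]

    breaks = sorted({0.0} | {d.time for d in doses}
                    | {d.time + d.tinf for d in doses} | set(times))
    y, vals = [0.0, 0.0], {0.0: 0.0}
    for a, b in zip(breaks[:-1], breaks[1:]):
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=1e-13,
                        max_step=max((b - a) / 4, 1e-7))
        y = sol.y[:, -1]
        vals[b] = y[0] / p.V1
    return np.array([vals[t] for t in times])


class TestPK2:
    def test_zero_before_first_dose(self):
        p = PKParams(0.2, 3.09, 0.35, 2.39)
        c = pk2_conc([0.0, 0.5, 0.9], [DoseEvent(1.0, 350.0)], p)
        assert np.all(c == 0.0)

    def test_linearity_in_dose(self):
        p = PKParams(0.2, 3.09, 0.35, 2.39)
        t = np.linspace(0.1, 40, 50)
        doses = [DoseEvent(0.0, 350.0), DoseEvent(14.0, 350.0)]
        doubled = [DoseEvent(d.time, 2 * d.amount, d.tinf) for d in doses]
        np.testing.assert_allclose(pk2_conc(t, doubled, p),
                                   2 * pk2_conc(t, doses, p), rtol=1e-12)

    def test_unsorted_times_rejected(self):
        p = PKParams(0.2, 3.09, 0.35, 2.39)
        with pytest.raises(ValueError, match="sorted"):
            pk2_conc([1.0, 0.5], [DoseEvent(0.0, 350.0)], p)

    def test_matches_ode_oracle_random_draws(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.05, 45, 60)
        for _ in range(25):
            p = PKParams(CL=rng.uniform(0.05, 1.0), V1=rng.uniform(1, 8),
                         Q=rng.uniform(0.05, 1.0), V2=rng.uniform(1, 10))
            doses = [DoseEvent(14.0 * i, rng.uniform(100, 600), 0.0625)
                     for i in range(3)]
            c = pk2_conc(t, doses, p)
            ode = _ode_pk2(t, doses, p)
            mask = ode > 1e-9
            assert np.max(np.abs(c[mask] - ode[mask]) / ode[mask]) < 1e-6


class TestQSSAlgebra:
    def test_no_target_returns_total(self):
        assert qss_free_drug(50.0, 0.0, 135.0) == pytest.approx(50.0, rel=1e-12)

    def test_no_drug(self):
        assert qss_free_drug(0.0, 5.0, 135.0) == 0.0

    @settings(deadline=None, max_examples=300)
    @given(st.floats(0, 1e4), st.floats(0, 1e4), st.floats(1e-3, 1e4))
    def test_mass_balance_residual(self, ctot, rtot, kss):
        c = qss_free_drug(ctot, rtot, kss)
        residual = c + rtot * c / (kss + c) - ctot
        assert abs(residual) <= 1e-10 * max(ctot, 1.0)
        assert 0.0 <= c <= ctot + 1e-12

    def test_free_target_limits(self):
        assert qss_free_target(5.0, 0.0, 135.0) == pytest.approx(5.0)
        assert qss_free_target(5.0, 1e12, 135.0) == pytest.approx(0.0, abs=1e-6)
        # monotone decreasing in drug
        c = np.linspace(0, 1000, 50)
        r = qss_free_target(5.0, c, 135.0)
        assert np.all(np.diff(r) < 0)


@pytest.fixture(scope="module")
def qss_params():
    # published binding-model point estimates
    return QSSParams(CL=0.344, V1=5.83, Q=0.136, V2=3.17,
                     Kss=135.0, kout=0.116, BM0=0.0137)


class TestQSSSimulation:
    def test_derived_constants(self, qss_params):
        assert qss_params.kin == pytest.approx(0.0137 * 0.116)
        assert qss_params.kint == pytest.approx(0.344 / 5.83)

    def test_no_doses_constant_baseline(self, qss_params):
        t = np.array([0.0, 5.0, 30.0, 100.0])
        drug, ligand = qss_simulate(t, [], qss_params)
        assert np.all(drug == 0.0)
        np.testing.assert_allclose(ligand, 616.5, rtol=1e-9)

    def test_weak_binding_limit_is_linear_pk(self, qss_params):
        weak = QSSParams(CL=0.344, V1=5.83, Q=0.136, V2=3.17,
                         Kss=1e9, kout=0.116, BM0=0.0137)
        doses = [DoseEvent(14.0 * i, 372.5) for i in range(3)]
        t = np.array([1.0, 7.0, 13.9, 20.0, 35.0])
        drug, _ = qss_simulate(t, doses, weak)
        ref = pk2_conc(t, doses, PKParams(0.344, 5.83, 0.136, 3.17))
        assert np.max(np.abs(drug - ref) / ref) < 0.01

    def test_single_dose_suppresses_ligand_then_recovers(self, qss_params):
        t = np.array([0.0, 0.0625, 7.0, 60.0, 300.0, 700.0])
        drug, ligand = qss_simulate(t, [DoseEvent(0.0, 350.0)], qss_params)
        assert ligand[1] < 616.5          # suppressed at end of infusion
        assert ligand[2] < 616.5
        assert ligand[-1] > ligand[2]     # returns toward baseline
        assert ligand[-1] == pytest.approx(616.5, rel=0.05)
        assert np.all(ligand >= 0) and np.all(drug >= 0)

    def test_conservation_free_plus_complex(self, qss_params):
        """Free drug from the quadratic plus bound complex equals the total."""
        from bevpkpd.units import drug_mg_per_l_to_nm
        doses = [DoseEvent(0.0, 350.0)]
        t = np.linspace(0.1, 30, 40)
        drug, ligand = qss_simulate(t, doses, qss_params)
        c_nm = drug_mg_per_l_to_nm(drug)
        r_nm = ligand / 45000.0
        # from the QSS relations: complex = Rtot - R = R*C/Kss
        complex_nm = r_nm * c_nm / qss_params.Kss
        rtot = r_nm + complex_nm
        np.testing.assert_allclose(
            qss_free_target(rtot, c_nm, qss_params.Kss), r_nm, rtol=1e-9)


class TestImaxPD:
    def test_identities(self):
        pd_ = PDParams(E0=684.0, Imax=0.951, IC50=29.1)
        assert imax_effect(0.0, pd_) == pytest.approx(684.0)
        assert imax_effect(29.1, pd_) == pytest.approx(358.8, abs=0.1)
        assert imax_effect(1e9, pd_) == pytest.approx(684.0 * (1 - 0.951), rel=1e-5)

    def test_monotone_nonincreasing(self):
        pd_ = PDParams(E0=684.0, Imax=0.951, IC50=29.1)
        c = np.linspace(0, 500, 100)
        e = imax_effect(c, pd_)
        assert np.all(np.diff(e) <= 0)
        assert np.all((e > 684.0 * (1 - 0.951) - 1e-9) & (e <= 684.0))

    def test_pkpd_is_pointwise_composition(self):
        pk = PKParams(0.388, 5.48, 0.315, 8.81)
        pd_ = PDParams(E0=684.0, Imax=0.951, IC50=29.1)
        doses = [DoseEvent(0.0, 372.5), DoseEvent(14.0, 372.5)]
        t = np.linspace(0.0, 28, 30)
        drug, ligand = pkpd_simulate(t, doses, pk, pd_)
        np.testing.assert_allclose(ligand, imax_effect(drug, pd_), rtol=1e-12)
        assert ligand[0] == pytest.approx(684.0)  # no drug at t=0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PDParams(E0=684.0, Imax=1.2, IC50=29.1)
        with pytest.raises(ValueError):
            PKParams(0.0, 3.0, 0.3, 2.0)
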