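"""Deterministic kinetic cores.

Three structural models share the same disposition backbone, a two-compartment
model with linear elimination and zero-order (infusion) input:

* ``pk2_conc`` — closed-form bi-exponential solution with superposition over
  infusions; drug alone.
* ``qss_simulate`` — target-mediated drug disposition under the quasi-steady
  -state (QSS) reduction: binding of drug (bevacizumab) to its soluble target
  (VEGF-A) is collapsed into the algebraic constant ``Kss``, the drug-target
  complex is eliminated at ``kint = CL/V1`` (cleared like free drug), and the
  free target turns over with zero-order production ``kin = BM0*kout`` and
  first-order loss ``kout``. Integrated in nM, reported on the assay scale.
* ``pkpd_simulate`` — linear PK plus an immediate-response Imax transform of
  the drug concentration into free-ligand suppression (no sigmoidicity, no
  effect compartment, constant baseline).

Time unit is days throughout; all rate constants and clearances are per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .units import (
    drug_mg_to_nmol,
    drug_nm_to_mg_per_l,
    ligand_nm_to_ng_per_l,
)

#: default infusion duration (days) when a dose event does not carry one: 90 min
DEFAULT_TINF = 0.0625


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order infusion: start time (days), amount (mg), duration (days)."""

    time: float
    amount: float
    tinf: float = DEFAULT_TINF

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.tinf <= 0:
            raise ValueError("infusion duration must be positive")


@dataclass(frozen=True)
class PKParams:
    """Two-compartment disposition: CL, Q in L/day; V1, V2 in L."""

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self):
        for name in ("CL", "V1", "Q", "V2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class QSSParams:
    """QSS binding model parameters.

    Kss (nM) is the quasi-steady-state constant KD + kint/kon; BM0 (nM) the
    pre-treatment free-target level; kout (1/day) its turnover rate.
    Derived, never free: kint = CL/V1 (complex cleared like free drug) and
    kin = BM0*kout (production balancing baseline turnover).
    """

    CL: float
    V1: float
    Q: float
    V2: float
    Kss: float
    kout: float
    BM0: float

    def __post_init__(self):
        for name in ("CL", "V1", "Q", "V2", "Kss", "kout", "BM0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kint(self) -> float:
        return self.CL / self.V1

    @property
    def kin(self) -> float:
        return self.BM0 * self.kout


@dataclass(frozen=True)
class PDParams:
    """Immediate Imax inhibition: E = E0*(1 - Imax*C/(IC50 + C)).

    E0 in ng/L (baseline free ligand), Imax dimensionless in (0,1),
    IC50 in mg/L (same scale as the drug observable).
    """

    E0: float
    Imax: float
    IC50: float

    def __post_init__(self):
        if not 0 < self.Imax < 1:
            raise ValueError("Imax must lie in (0, 1)")
        if self.E0 <= 0 or self.IC50 <= 0:
            raise ValueError("E0 and IC50 must be positive")


def _as_dose_list(dose_events: Iterable) -> list[DoseEvent]:
    out = []
    for d in dose_events:
        if isinstance(d, DoseEvent):
            out.append(d)
        else:
            out.append(DoseEvent(*d))
    return out


def macro_constants(p: PKParams | QSSParams):
    """(alpha, beta, A, B): exponents and unit-bolus central-compartment
    coefficients of the bi-exponential two-compartment solution."""
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    if alpha == beta:  # repeated root: nudge apart (measure-zero in practice)
        alpha *= 1.0 + 1e-9
    A = (alpha - k21) / ((alpha - beta) * p.V1)
    B = (k21 - beta) / ((alpha - beta) * p.V1)
    return alpha, beta, A, B


def pk2_conc(times: Sequence[float], dose_events: Iterable, pk_params: PKParams) -> np.ndarray:
    """Central-compartment drug concentration (mg/L) at ``times`` (days).

    Closed-form solution for repeated zero-order infusions by superposition.
    ``times`` must be sorted ascending; values before the first dose are 0.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("times must be a 1-D sorted array")
    doses = _as_dose_list(dose_events)
    alpha, beta, A, B = macro_constants(pk_params)
    conc = np.zeros_like(t)
    for d in doses:
        rate = d.amount / d.tinf  # mg/day
        dt = t - d.time
        during = (dt > 0) & (dt <= d.tinf)
        after = dt > d.tinf
        for lam, coef in ((alpha, A), (beta, B)):
            conc[during] += rate * coef / lam * (1.0 - np.exp(-lam * dt[during]))
            conc[after] += (rate * coef / lam * (1.0 - np.exp(-lam * d.tinf))
                            * np.exp(-lam * (dt[after] - d.tinf)))
    return np.maximum(conc, 0.0)


def qss_free_drug(Ctot, Rtot, Kss):
    """Free drug concentration (nM) from totals under the QSS binding quadratic.

    Solves C^2 + (Rtot + Kss - Ctot) C - Kss Ctot = 0 for its positive root,
    i.e. C = ((Ctot-Rtot-Kss) + sqrt((Ctot-Rtot-Kss)^2 + 4 Kss Ctot))/2,
    evaluated in the cancellation-free form when the linear term dominates.
    """
    Ctot = np.maximum(np.asarray(Ctot, dtype=float), 0.0)
    Rtot = np.maximum(np.asarray(Rtot, dtype=float), 0.0)
    b = Ctot - Rtot - Kss
    disc = np.sqrt(b * b + 4.0 * Kss * Ctot)
    # root via the conjugate form where b < 0 to avoid catastrophic cancellation
    with np.errstate(divide="ignore", invalid="ignore"):
        conj = np.where(disc - b > 0, 2.0 * Kss * Ctot / (disc - b), 0.0)
    C = np.where(b >= 0, 0.5 * (b + disc), conj)
    return np.minimum(np.maximum(C, 0.0), Ctot)


def qss_free_target(Rtot, C, Kss):
    """Free target (nM): R = Rtot * Kss / (Kss + C); decreasing in drug C."""
    Rtot = np.maximum(np.asarray(Rtot, dtype=float), 0.0)
    C = np.maximum(np.asarray(C, dtype=float), 0.0)
    return Rtot * Kss / (Kss + C)


def _infusion_rate_nmol(doses: list[DoseEvent], t: float) -> float:
    rate = 0.0
    for d in doses:
        if d.time < t <= d.time + d.tinf:
            rate += drug_mg_to_nmol(d.amount) / d.tinf
    return rate


def qss_rhs(t, y, p: QSSParams, doses: list[DoseEvent]):
    """ODE right-hand side of the QSS system.

    States: y = [Atot_c (nmol total drug, central), Ap (nmol drug, peripheral),
    Rtot (nM total target, central)]. Only free drug distributes peripherally;
    the complex is eliminated from the central compartment at kint.
    """
    Atot, Ap, Rtot = y
    Ctot = Atot / p.V1
    C = float(qss_free_drug(Ctot, Rtot, p.Kss))
    complex_conc = max(Ctot - C, 0.0)
    inp = _infusion_rate_nmol(doses, t)
    dAtot = inp - p.CL * C - p.Q * C + (p.Q / p.V2) * Ap - p.kint * complex_conc * p.V1
    dAp = p.Q * C - (p.Q / p.V2) * Ap
    dRtot = p.kin - p.kout * Rtot - (p.kint - p.kout) * complex_conc
    return [dAtot, dAp, dRtot]


def qss_simulate(times: Sequence[float], dose_events: Iterable, qss_params: QSSParams,
                 rtol: float = 1e-8, atol: float = 1e-10):
    """Simulate the QSS system; returns (drug mg/L, free ligand ng/L) at ``times``.

    Initial condition: no drug on board, target at its pre-treatment steady
    state Rtot(0) = BM0. The integrator is restarted at every infusion start
    and end so the discontinuous input is never stepped over.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("times must be a 1-D sorted array")
    doses = _as_dose_list(dose_events)
    breaks = sorted({0.0} | {d.time for d in doses} | {d.time + d.tinf for d in doses})
    t_end = max(t[-1] if len(t) else 0.0, breaks[-1])
    breaks = [b for b in breaks if b <= t_end] + [t_end]
    breaks = sorted(set(breaks))

    y = np.array([0.0, 0.0, qss_params.BM0])
    out_t, out_y = [0.0], [y.copy()]
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        interior = np.unique(t[(t > a) & (t < b)])
        sol = solve_ivp(qss_rhs, (a, b), y, args=(qss_params, doses),
                        method="LSODA", rtol=rtol, atol=atol,
                        t_eval=np.concatenate([interior, [b]]),
                        max_step=max((b - a) / 4.0, 1e-6))
        if not sol.success:
            raise RuntimeError(
                f"QSS integration failed on [{a}, {b}] with state {y}: {sol.message}")
        out_t.extend(sol.t.tolist())
        out_y.extend(sol.y.T.tolist())
        y = sol.y[:, -1]
    out_t = np.asarray(out_t)
    out_y = np.asarray(out_y)
    # interpolate states onto requested times (breakpoints are exact nodes)
    Atot = np.interp(t, out_t, out_y[:, 0])
    Rtot = np.interp(t, out_t, out_y[:, 2])
    Ctot = Atot / qss_params.V1
    C = qss_free_drug(Ctot, Rtot, qss_params.Kss)
    R = qss_free_target(Rtot, C, qss_params.Kss)
    return drug_nm_to_mg_per_l(C), ligand_nm_to_ng_per_l(R)


def imax_effect(C, pd_params: PDParams):
    """Free-ligand level (ng/L) under immediate Imax inhibition by drug C (mg/L)."""
    C = np.maximum(np.asarray(C, dtype=float), 0.0)
    return pd_params.E0 * (1.0 - pd_params.Imax * C / (pd_params.IC50 + C))


def pkpd_simulate(times: Sequence[float], dose_events: Iterable,
                  pk_params: PKParams, pd_params: PDParams):
    """Joint PK/PD prediction: (drug mg/L, ligand ng/L) at ``times``.

    The ligand series is the pointwise Imax transform of the drug series —
    an immediate-response model with no effect compartment.
    """
    conc = pk2_conc(times, dose_events, pk_params)
    return conc, imax_effect(conc, pd_params)
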