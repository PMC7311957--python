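"""Compiled dataset designs and vectorized structural predictors.

`saem_fit` evaluates the structural model for every subject thousands of
times (once per MCMC proposal), so the per-subject event lists are compiled
once into flat index arrays:

* the closed-form models (pk2, pkpd) are evaluated over a flattened
  (observation, dose) pair table with one `bincount` reduction;
* the QSS ODE system is integrated by a fixed-step classical Runge-Kutta
  scheme vectorized across all subjects that share a dosing/sampling time
  template (subjects are grouped automatically; per-subject amounts and
  parameters stay free). The grid contains every infusion start/end and
  every observation time, so the piecewise-constant input is never stepped
  over and no interpolation is needed.

Predictions are returned on the assay scale, aligned with the dataset's
observation rows (drug rows in mg/L, ligand rows in ng/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset
from .structural import DEFAULT_TINF
from .units import drug_mg_to_nmol, drug_nm_to_mg_per_l, ligand_nm_to_ng_per_l

#: RK4 step ceilings (days): within an infusion window / between doses.
#: the QSS states evolve on the slow (per-day) antibody/target time scales —
#: the fast binding dynamics are algebraic — so coarse steps keep full accuracy
_H_INFUSION_FRAC = 0.34
_H_COAST = 1.0


@dataclass
class SubjectDesign:
    sid: object
    dose_times: np.ndarray
    dose_amounts: np.ndarray  # mg
    dose_tinf: np.ndarray     # days
    obs_times: np.ndarray
    obs_dvid: np.ndarray
    obs_y: np.ndarray
    obs_rows: np.ndarray      # global observation-row indices


@dataclass
class QSSGroup:
    """Subjects sharing one dose/observation time template."""

    members: np.ndarray            # subject indices into the dataset order
    grid: np.ndarray               # integration nodes (days), starts at 0
    rates_nmol: np.ndarray         # (n_intervals, m) infusion input nmol/day
    n_sub: np.ndarray              # substeps per interval
    store_nodes: np.ndarray        # node indices whose state must be kept
    obs_store_row: np.ndarray      # per group obs: row into stored states
    obs_member_col: np.ndarray     # per group obs: member column
    obs_global_rows: np.ndarray    # per group obs: global observation row
    obs_dvid: np.ndarray


class CompiledDesign:
    """All index structures required for batched prediction on one dataset."""

    def __init__(self, dataset: Dataset):
        df = dataset.df
        self.covariates = dataset.covariates()
        self.subject_order = list(self.covariates.index)
        sid_to_idx = {s: i for i, s in enumerate(self.subject_order)}

        obs = df[(df["EVID"] == 0) & (df["MDV"] == 0)].reset_index(drop=True)
        self.obs_subject_idx = obs["ID"].map(sid_to_idx).to_numpy()
        self.obs_times = obs["TIME"].to_numpy(float)
        self.obs_dvid = obs["DVID"].to_numpy(int)
        self.obs_y = obs["DV"].to_numpy(float)
        self.obs_predose = obs["PREDOSE"].to_numpy(int)
        self.n_obs = len(obs)
        self.n_subjects = len(self.subject_order)

        self.subjects: list[SubjectDesign] = []
        doses = df[df["EVID"] == 1]
        for sid in self.subject_order:
            d = doses[doses["ID"] == sid]
            rows = np.flatnonzero(obs["ID"].to_numpy() == sid)
            self.subjects.append(SubjectDesign(
                sid=sid,
                dose_times=d["TIME"].to_numpy(float),
                dose_amounts=d["AMT"].to_numpy(float),
                dose_tinf=np.where(np.isnan(d["TINF"].to_numpy(float)),
                                   DEFAULT_TINF, d["TINF"].to_numpy(float)),
                obs_times=self.obs_times[rows],
                obs_dvid=self.obs_dvid[rows],
                obs_y=self.obs_y[rows],
                obs_rows=rows,
            ))
        self._build_pairs()
        self._qss_groups: list[QSSGroup] | None = None

    # ------------------------------------------------------------------
    # closed-form path: flattened (observation, dose) pairs
    def _build_pairs(self) -> None:
        po, ps, pdt, prate, ptinf = [], [], [], [], []
        for i, sub in enumerate(self.subjects):
            for dt_, amt, tinf in zip(sub.dose_times, sub.dose_amounts, sub.dose_tinf):
                rel = sub.obs_times - dt_
                keep = rel > 0
                po.append(sub.obs_rows[keep])
                ps.append(np.full(keep.sum(), i))
                pdt.append(rel[keep])
                prate.append(np.full(keep.sum(), amt / tinf))
                ptinf.append(np.full(keep.sum(), tinf))
        conc = np.concatenate
        self.pair_obs = conc(po) if po else np.empty(0, int)
        self.pair_subj = conc(ps).astype(int) if ps else np.empty(0, int)
        self.pair_dt = conc(pdt) if pdt else np.empty(0)
        self.pair_rate = conc(prate) if prate else np.empty(0)
        self.pair_tinf = conc(ptinf) if ptinf else np.empty(0)

    def _macro(self, CL, V1, Q, V2):
        k10, k12, k21 = CL / V1, Q / V1, Q / V2
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        denom = np.where(alpha == beta, 1e-12, alpha - beta)
        A = (alpha - k21) / (denom * V1)
        B = (k21 - beta) / (denom * V1)
        return alpha, beta, A, B

    def predict_pk2(self, params: dict[str, np.ndarray]) -> np.ndarray:
        """Drug concentration (mg/L) at every observation row."""
        alpha, beta, A, B = self._macro(params["CL"], params["V1"], params["Q"], params["V2"])
        j = self.pair_subj
        te = np.minimum(self.pair_dt, self.pair_tinf)
        tail = np.maximum(self.pair_dt - self.pair_tinf, 0.0)
        contrib = np.zeros_like(self.pair_dt)
        for lam, coef in ((alpha, A), (beta, B)):
            lj, cj = lam[j], coef[j]
            contrib += self.pair_rate * cj / lj * (1.0 - np.exp(-lj * te)) * np.exp(-lj * tail)
        return np.maximum(np.bincount(self.pair_obs, weights=contrib,
                                      minlength=self.n_obs), 0.0)

    def predict_pkpd(self, params: dict[str, np.ndarray]) -> np.ndarray:
        """Drug rows: pk2 concentration; ligand rows: immediate Imax transform."""
        conc = self.predict_pk2(params)
        pred = conc.copy()
        lig = self.obs_dvid == 2
        if lig.any():
            i = self.obs_subject_idx[lig]
            E0, Imax, IC50 = params["E0"][i], params["Imax"][i], params["IC50"][i]
            c = conc[lig]
            pred[lig] = E0 * (1.0 - Imax * c / (IC50 + c))
        return pred

    # ------------------------------------------------------------------
    # QSS path: grouped fixed-step RK4
    def _build_qss_groups(self) -> list[QSSGroup]:
        # group by dosing template only; observation times may differ per
        # subject (e.g. thinned sampling) — the group stores states at the
        # union of its members' observation times
        keys: dict[tuple, list[int]] = {}
        for i, sub in enumerate(self.subjects):
            key = (tuple(np.round(sub.dose_times, 9)), tuple(np.round(sub.dose_tinf, 9)))
            keys.setdefault(key, []).append(i)
        groups = []
        for (dtimes, dtinf), members in keys.items():
            dtimes = np.array(dtimes)
            dtinf = np.array(dtinf)
            otimes = np.unique(np.round(np.concatenate(
                [self.subjects[i].obs_times for i in members]), 9))
            starts, ends = dtimes, dtimes + dtinf
            horizon = max(float(otimes.max(initial=0.0)), float(ends.max(initial=0.0)))
            nodes = {0.0, horizon}
            nodes.update(starts[starts <= horizon])
            nodes.update(ends[ends <= horizon])
            nodes.update(otimes)
            # filler nodes so every interval respects the step ceiling
            base = np.array(sorted(nodes))
            filled = [base[0]]
            for a, b in zip(base[:-1], base[1:]):
                infusing = np.any((starts < b) & (ends > a))
                h = min(dtinf.min(initial=DEFAULT_TINF) * _H_INFUSION_FRAC, _H_COAST) \
                    if infusing else _H_COAST
                n = max(int(np.ceil((b - a) / h)), 1)
                filled.extend(np.linspace(a, b, n + 1)[1:])
            grid = np.array(filled)
            mids = 0.5 * (grid[:-1] + grid[1:])
            dose_idx = np.full(len(mids), -1)
            for k, (s, e) in enumerate(zip(starts, ends)):
                dose_idx[(mids > s) & (mids < e)] = k
            m = len(members)
            amounts = np.stack([drug_mg_to_nmol(self.subjects[i].dose_amounts)
                                for i in members], axis=1)  # (d, m)
            rates = np.zeros((len(mids), m))
            live = dose_idx >= 0
            if live.any():
                rates[live] = amounts[dose_idx[live]] / dtinf[dose_idx[live]][:, None]
            store_mask = np.isin(np.round(grid, 9), np.round(otimes, 9))
            store_nodes = np.flatnonzero(store_mask)
            node_of_time = {round(float(grid[k]), 9): r for r, k in enumerate(store_nodes)}
            osr, omc, ogr, odv = [], [], [], []
            for col, i in enumerate(members):
                sub = self.subjects[i]
                for t, dv, row in zip(sub.obs_times, sub.obs_dvid, sub.obs_rows):
                    osr.append(node_of_time[round(float(t), 9)])
                    omc.append(col)
                    ogr.append(row)
                    odv.append(dv)
            groups.append(QSSGroup(
                members=np.array(members), grid=grid, rates_nmol=rates,
                n_sub=np.ones(len(mids), int),
                store_nodes=store_nodes,
                obs_store_row=np.array(osr, int), obs_member_col=np.array(omc, int),
                obs_global_rows=np.array(ogr, int), obs_dvid=np.array(odv, int),
            ))
        return groups

    @property
    def qss_groups(self) -> list[QSSGroup]:
        if self._qss_groups is None:
            self._qss_groups = self._build_qss_groups()
        return self._qss_groups

    def predict_qss(self, params: dict[str, np.ndarray]) -> np.ndarray:
        """QSS predictions at every observation row (drug mg/L, ligand ng/L)."""
        pred = np.zeros(self.n_obs)
        for g in self.qss_groups:
            mem = g.members
            CL, V1 = params["CL"][mem], params["V1"][mem]
            Q, V2 = params["Q"][mem], params["V2"][mem]
            Kss, kout, BM0 = params["Kss"][mem], params["kout"][mem], params["BM0"][mem]
            kint = CL / V1
            kin = BM0 * kout
            m = len(mem)
            inv_V1 = 1.0 / V1
            k_per = Q / V2
            cl_eff = CL + Q
            cx_coef = kint * V1
            dk = kint - kout
            four_kss = 4.0 * Kss
            two_kss = 2.0 * Kss

            def rhs(y, rate):
                # y: (3, m) = Atot_c (nmol), Ap (nmol), Rtot (nM)
                Ctot = y[0] * inv_V1
                b = Ctot - y[2] - Kss
                disc = np.sqrt(b * b + four_kss * Ctot)
                C = np.where(b >= 0, 0.5 * (b + disc),
                             two_kss * Ctot / np.maximum(disc - b, 1e-300))
                np.clip(C, 0.0, Ctot, out=C)
                cx = Ctot - C
                per = k_per * y[1]
                out = np.empty_like(y)
                out[0] = rate - cl_eff * C + per - cx_coef * cx
                out[1] = Q * C - per
                out[2] = kin - kout * y[2] - dk * cx
                return out

            state = np.zeros((3, m))
            state[2] = BM0
            stored = np.empty((len(g.store_nodes), 2, m))
            store_ptr = 0
            if len(g.store_nodes) and g.store_nodes[0] == 0:
                stored[0, 0] = 0.0
                stored[0, 1] = BM0
                store_ptr = 1
            hs = np.diff(g.grid)
            # extreme MCMC proposals can push the states toward overflow;
            # the clip keeps the arithmetic finite (such proposals are then
            # rejected by their likelihood, never accepted)
            with np.errstate(over="ignore", invalid="ignore"):
                for k in range(len(hs)):
                    h = hs[k]
                    rate = g.rates_nmol[k]
                    k1 = rhs(state, rate)
                    k2 = rhs(state + (0.5 * h) * k1, rate)
                    k3 = rhs(state + (0.5 * h) * k2, rate)
                    k4 = rhs(state + h * k3, rate)
                    state = state + (h / 6.0) * (k1 + 2.0 * (k2 + k3) + k4)
                    state = np.clip(state, 0.0, 1e12)
                    if (store_ptr < len(g.store_nodes)
                            and g.store_nodes[store_ptr] == k + 1):
                        stored[store_ptr, 0] = state[0] * inv_V1  # Ctot (nM)
                        stored[store_ptr, 1] = state[2]           # Rtot (nM)
                        store_ptr += 1

            Ctot = stored[g.obs_store_row, 0, g.obs_member_col]
            Rtot = stored[g.obs_store_row, 1, g.obs_member_col]
            KssO = Kss[g.obs_member_col]
            with np.errstate(over="ignore", invalid="ignore"):
                b = Ctot - Rtot - KssO
                disc = np.sqrt(b * b + 4.0 * KssO * Ctot)
                C = np.where(b >= 0, 0.5 * (b + disc),
                             2.0 * KssO * Ctot / np.maximum(disc - b, 1e-300))
                C = np.clip(C, 0.0, Ctot)
            vals = np.where(g.obs_dvid == 1,
                            drug_nm_to_mg_per_l(C),
                            ligand_nm_to_ng_per_l(Rtot * KssO / (KssO + C)))
            pred[g.obs_global_rows] = vals
        return pred

    # ------------------------------------------------------------------
    def predict(self, structural: str, params: dict[str, np.ndarray]) -> np.ndarray:
        if structural == "pk2":
            return self.predict_pk2(params)
        if structural == "pkpd":
            return self.predict_pkpd(params)
        if structural == "qss":
            return self.predict_qss(params)
        raise ValueError(f"unknown structural model {structural!r}")


def compile_design(dataset: Dataset) -> CompiledDesign:
    return CompiledDesign(dataset)
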