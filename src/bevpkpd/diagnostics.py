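"""Model-evaluation machinery: pcVPC, NPDE and goodness-of-fit tables.

All diagnostics simulate replicate datasets under the fitted model at the
observed design (same subjects, doses and sampling times), so they share
one simulator built on the compiled-design batch predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CompiledDesign, compile_design
from .io import Dataset
from .popmodel import ModelSpec, natural_matrix
from .saem import FitResult, _ErrorState, _observable_of_dvid


def _error_states(fit: FitResult, cd: CompiledDesign) -> dict[int, _ErrorState]:
    return {dvid: _ErrorState(**fit.sigmas[_observable_of_dvid(dvid)])
            for dvid in np.unique(cd.obs_dvid)}


def simulate_replicates(cd: CompiledDesign, spec: ModelSpec, fit: FitResult,
                        n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """(n_sim, n_obs) matrix of datasets simulated under the fitted model."""
    X = spec.design_tensor(cd.covariates)
    phi_pop = X @ fit.coeffs
    # only genuine BSV: pseudo components of omega_full are an estimation
    # device, not population variability
    omega = fit.omega_full.copy()
    bsv = np.array([p.bsv and p.omega_init > 0 for p in spec.parameters])
    omega[~bsv, :] = 0.0
    omega[:, ~bsv] = 0.0
    L = np.linalg.cholesky(omega + 1e-12 * np.eye(omega.shape[0]))
    err = _error_states(fit, cd)
    rows_of = {dvid: np.flatnonzero(cd.obs_dvid == dvid) for dvid in err}
    out = np.empty((n_sim, cd.n_obs))
    for s in range(n_sim):
        etas = rng.standard_normal(phi_pop.shape) @ L.T
        pred = cd.predict(spec.structural, natural_matrix(spec, phi_pop + etas))
        ysim = pred.copy()
        for dvid, rows in rows_of.items():
            f = np.maximum(pred[rows], 1e-12)
            ysim[rows] = f + err[dvid].sd(f) * rng.standard_normal(len(rows))
        out[s] = ysim
    return out


def population_prediction(cd: CompiledDesign, spec: ModelSpec,
                          fit: FitResult) -> np.ndarray:
    """PRED: predictions at the population parameters (eta = 0)."""
    X = spec.design_tensor(cd.covariates)
    return cd.predict(spec.structural, natural_matrix(spec, X @ fit.coeffs))


# ---------------------------------------------------------------------------
# prediction-corrected VPC


@dataclass
class VPCResult:
    observable: dict[int, pd.DataFrame]   # DVID -> band table per bin
    n_sim: int
    seed: int
    notes: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        frames = []
        for dvid, df in self.observable.items():
            d = df.copy()
            d.insert(0, "DVID", dvid)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def _quantile_bins(times: np.ndarray, n_bins: int, min_per_bin: int,
                   notes: list[str]) -> np.ndarray:
    """Assign a bin index per observation; merge bins thinner than the floor."""
    qs = np.quantile(times, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1,
                  0, len(edges) - 2)
    # merge sparse bins with their left neighbour
    changed = True
    while changed:
        changed = False
        for b in np.unique(idx):
            if (idx == b).sum() < min_per_bin and len(np.unique(idx)) > 1:
                tgt = b - 1 if b > 0 else np.unique(idx)[1]
                notes.append(f"bin {b} (<{min_per_bin} obs) merged into {tgt}")
                idx[idx == b] = tgt
                changed = True
                break
    # re-index densely
    remap = {b: i for i, b in enumerate(np.unique(idx))}
    return np.array([remap[b] for b in idx])


def pc_vpc(dataset: Dataset, spec: ModelSpec, fit: FitResult,
           n_sim: int = 1000, seed: int = 0, n_bins: int = 8,
           pi: float = 0.90, min_per_bin: int = 5) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observations and simulations are rescaled within each time bin by
    (bin-median PRED)/PRED before percentile computation, removing the
    covariate- and dose-driven spread; the simulated 90% prediction
    intervals around the 5th/50th/95th percentiles come from ``n_sim``
    replicate datasets at the observed design.
    """
    rng = np.random.default_rng(seed)
    cd = compile_design(dataset)
    pred = np.maximum(population_prediction(cd, spec, fit), 1e-12)
    sims = simulate_replicates(cd, spec, fit, n_sim, rng)
    lo_q, hi_q = (1 - pi) / 2, 1 - (1 - pi) / 2
    pcts = (5, 50, 95)
    notes: list[str] = []
    out = {}
    for dvid in np.unique(cd.obs_dvid):
        rows = np.flatnonzero(cd.obs_dvid == dvid)
        t = cd.obs_times[rows]
        bins = _quantile_bins(t, n_bins, min_per_bin, notes)
        rec = []
        for b in np.unique(bins):
            sel = rows[bins == b]
            pc = np.median(pred[sel]) / pred[sel]
            obs_pc = cd.obs_y[sel] * pc
            sim_pc = sims[:, sel] * pc          # (n_sim, bin size)
            row = {"bin": int(b), "t_mid": float(np.median(t[bins == b])),
                   "n": len(sel),
                   "pred_median": float(np.median(pred[sel]))}
            for q in pcts:
                row[f"obs_p{q}"] = float(np.percentile(obs_pc, q))
                sim_q = np.percentile(sim_pc, q, axis=1)
                row[f"sim_p{q}_lo"] = float(np.quantile(sim_q, lo_q))
                row[f"sim_p{q}_hi"] = float(np.quantile(sim_q, hi_q))
            rec.append(row)
        out[int(dvid)] = pd.DataFrame(rec)
    return VPCResult(observable=out, n_sim=n_sim, seed=seed, notes=notes)


def vpc_coverage(vpc: VPCResult) -> float:
    """Fraction of (bin, percentile) points whose observed percentile lies
    inside the simulated interval — the numerical predictive check."""
    inside = total = 0
    for df in vpc.observable.values():
        for q in (5, 50, 95):
            inside += int(((df[f"obs_p{q}"] >= df[f"sim_p{q}_lo"])
                           & (df[f"obs_p{q}"] <= df[f"sim_p{q}_hi"])).sum())
            total += len(df)
    return inside / total


# ---------------------------------------------------------------------------
# NPDE


@dataclass
class NPDEResult:
    npde: np.ndarray
    global_p: float
    mean_p: float
    var_p: float
    normality_p: float
    n_sim: int
    seed: int
    notes: list[str] = field(default_factory=list)


def npde(dataset: Dataset, spec: ModelSpec, fit: FitResult,
         n_sim: int = 1000, seed: int = 0) -> NPDEResult:
    """Normalized prediction distribution errors.

    Per subject, observations and simulations are decorrelated with the
    empirical mean/covariance of the simulated vectors (Cholesky), the
    prediction distribution error is the rank of the decorrelated
    observation among its simulations, and the inverse normal CDF maps it
    to N(0,1) under a correct model. The global test combines the mean
    (t-test), variance (chi-square) and normality (Shapiro-Wilk) components
    with a Bonferroni factor of 3.
    """
    if n_sim < 100:
        raise ValueError("npde needs n_sim >= 100")
    rng = np.random.default_rng(seed)
    cd = compile_design(dataset)
    sims = simulate_replicates(cd, spec, fit, n_sim, rng)
    notes: list[str] = []
    values = np.empty(cd.n_obs)
    for i in range(cd.n_subjects):
        rows = np.flatnonzero(cd.obs_subject_idx == i)
        Y = sims[:, rows]                       # (n_sim, q)
        mu = Y.mean(axis=0)
        V = np.cov(Y, rowvar=False)
        if V.ndim == 0:
            V = V.reshape(1, 1)
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(V) / len(rows)
            notes.append(f"subject index {i}: singular simulated covariance; "
                         f"ridge {ridge:.2e} added")
            Lc = np.linalg.cholesky(V + ridge * np.eye(len(rows)))
        y_dec = np.linalg.solve(Lc, cd.obs_y[rows] - mu)
        s_dec = np.linalg.solve(Lc, (Y - mu).T)  # (q, n_sim)
        # tie-break by an infinitesimal seeded jitter of the ranks
        jitter = 1e-9 * rng.standard_normal(s_dec.shape)
        pde = (np.sum(s_dec + jitter < y_dec[:, None], axis=1) + 0.5) / (n_sim + 1)
        values[rows] = sps.norm.ppf(pde)
    t_p = float(sps.ttest_1samp(values, 0.0).pvalue)
    nobs = len(values)
    var_stat = (nobs - 1) * np.var(values, ddof=1)
    var_p = float(2 * min(sps.chi2.cdf(var_stat, nobs - 1),
                          sps.chi2.sf(var_stat, nobs - 1)))
    sw_p = float(sps.shapiro(values[:5000]).pvalue)
    global_p = float(min(1.0, 3.0 * min(t_p, var_p, sw_p)))
    return NPDEResult(npde=values, global_p=global_p, mean_p=t_p,
                      var_p=var_p, normality_p=sw_p, n_sim=n_sim, seed=seed,
                      notes=notes)


# ---------------------------------------------------------------------------
# goodness of fit


def gof_tables(dataset: Dataset, spec: ModelSpec, fit: FitResult) -> pd.DataFrame:
    """Per-observation table: OBS, PRED, IPRED, PWRES, IWRES."""
    cd = compile_design(dataset)
    pred = population_prediction(cd, spec, fit)
    ipred = cd.predict(spec.structural, natural_matrix(spec, fit.cond_mean_phi))
    err = _error_states(fit, cd)
    sd_pred = np.empty(cd.n_obs)
    sd_ipred = np.empty(cd.n_obs)
    for dvid in err:
        rows = np.flatnonzero(cd.obs_dvid == dvid)
        sd_pred[rows] = err[dvid].sd(np.maximum(pred[rows], 1e-12))
        sd_ipred[rows] = err[dvid].sd(np.maximum(ipred[rows], 1e-12))
    return pd.DataFrame({
        "ID": cd.covariates.index.to_numpy()[cd.obs_subject_idx],
        "TIME": cd.obs_times,
        "DVID": cd.obs_dvid,
        "OBS": cd.obs_y,
        "PRED": pred,
        "IPRED": ipred,
        "PWRES": (cd.obs_y - pred) / sd_pred,
        "IWRES": (cd.obs_y - ipred) / sd_ipred,
    })
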