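"""Stochastic Approximation EM (SAEM) for the population models.

The estimation model on the transformed scale is linear-Gaussian given the
individual parameters: phi_i = X_i b + eta_i, eta_i ~ N(0, Omega), with the
observation likelihood supplied by the structural model and residual-error
model. SAEM alternates

* an E-step: a few transitions of a componentwise random-walk Metropolis
  sampler on the standardized effects u_i (eta_i = L u_i, L = chol(Omega)),
  with per-component proposal scales adapted toward a 0.3-0.5 acceptance
  rate; sampling in u-space keeps the chain well conditioned even when the
  eta(CL, Q) correlation sits near its -0.999 boundary;
* a stochastic-approximation update of the sufficient statistics of the
  linear-Gaussian layer (step size 1 during the K1 exploratory iterations,
  1/(k-K1) during the K2 smoothing iterations);
* an exact M-step: GLS for the coefficient vector b (optionally penalized by
  Gaussian priors), the structured covariance Omega (diagonal plus the
  declared correlation pairs), and closed-form residual-error updates.

Parameters declared without between-subject variability (Kss, kout, Imax,
IC50) are estimated with the standard decreasing-variability device: they
receive an artificial omega annealed geometrically from 0.3 down to a 0.05
floor across K1, which turns their individual sampling into a simulated-
annealing search for the population value. Omega and sigma are kept from
collapsing early by a geometrically decaying floor during K1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import CompiledDesign, compile_design
from .io import Dataset
from .popmodel import ModelSpec, back_transform, natural_matrix, transform
from .units import DRUG, LIGAND

_LOG_2PI = float(np.log(2.0 * np.pi))

REQUIRED_PARAMS = {
    "pk2": {"CL", "V1", "Q", "V2"},
    "qss": {"CL", "V1", "Q", "V2", "Kss", "kout", "BM0"},
    "pkpd": {"CL", "V1", "Q", "V2", "E0", "Imax", "IC50"},
}


@dataclass
class SAEMConfig:
    """Algorithm settings; defaults suit the desk-scale synthetic studies."""

    k1: int = 300                 # exploratory iterations (step size 1)
    k2: int = 100                 # smoothing iterations (step size 1/(k-K1))
    n_transitions: int = 2        # MH sweeps per iteration
    seed: int = 1
    target_accept: float = 0.4
    pseudo_omega_init: float = 0.3
    pseudo_omega_floor: float = 0.05
    annealing: float = 0.97       # geometric variance floor decay during K1

    def __post_init__(self):
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("k1 and k2 must be >= 1")


@dataclass
class FitResult:
    """Population estimates plus everything needed downstream."""

    spec: ModelSpec
    coeffs: np.ndarray                    # transformed-scale coefficient vector
    fixed_effects: dict[str, float]       # natural scale
    covariate_coeffs: dict[str, float]
    omegas: dict[str, float]
    correlations: dict[str, float]        # "CL,Q" -> rho
    sigmas: dict[str, dict]               # observable -> {kind, a, b}
    omega_full: np.ndarray
    cond_mean_phi: np.ndarray             # (n, p) conditional means of phi
    cond_cov_phi: np.ndarray              # (n, p, p)
    ebes: pd.DataFrame                    # conditional-mean etas per subject
    traces: dict[str, np.ndarray]
    accept_rates: np.ndarray
    seed: int
    config: SAEMConfig
    n_subjects: int
    n_obs: int
    minus2ll: float | None = None
    minus2ll_se: float | None = None
    se: dict[str, float] | None = None
    rse: dict[str, float] | None = None
    wald_p: dict[str, float] | None = None

    @property
    def n_parameters(self) -> int:
        """Count of estimated population parameters (for AIC/BIC)."""
        k = len(self.coeffs) + len(self.omegas) + len(self.correlations)
        k += sum(2 if s["kind"] == "combined" else 1 for s in self.sigmas.values())
        return k

    def estimates_table(self) -> pd.DataFrame:
        rows = []
        for name, val in {**self.fixed_effects, **self.covariate_coeffs}.items():
            rows.append({"parameter": name, "estimate": val,
                         "se": (self.se or {}).get(name, np.nan),
                         "rse_pct": (self.rse or {}).get(name, np.nan),
                         "wald_p": (self.wald_p or {}).get(name, np.nan)})
        for name, val in self.omegas.items():
            rows.append({"parameter": f"omega_{name}", "estimate": val,
                         "se": (self.se or {}).get(f"omega_{name}", np.nan),
                         "rse_pct": (self.rse or {}).get(f"omega_{name}", np.nan),
                         "wald_p": np.nan})
        for pair, rho in self.correlations.items():
            rows.append({"parameter": f"corr_{pair}", "estimate": rho,
                         "se": (self.se or {}).get(f"corr_{pair}", np.nan),
                         "rse_pct": (self.rse or {}).get(f"corr_{pair}", np.nan),
                         "wald_p": np.nan})
        for obs, s in self.sigmas.items():
            if s["kind"] in ("constant", "combined"):
                rows.append({"parameter": f"sigma_a_{obs}", "estimate": s["a"],
                             "se": np.nan, "rse_pct": np.nan, "wald_p": np.nan})
            if s["kind"] in ("proportional", "combined"):
                rows.append({"parameter": f"sigma_b_{obs}", "estimate": s["b"],
                             "se": np.nan, "rse_pct": np.nan, "wald_p": np.nan})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        doc = {
            "model": self.spec.name or self.spec.structural,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "fixed_effects": self.fixed_effects,
            "covariate_coeffs": self.covariate_coeffs,
            "omegas": self.omegas,
            "correlations": self.correlations,
            "sigmas": self.sigmas,
            "minus2ll": self.minus2ll,
            "se": self.se,
            "rse": self.rse,
            "wald_p": self.wald_p,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)


def saem_fit_multistart(dataset: Dataset, model_spec: ModelSpec,
                        config: SAEMConfig | None = None,
                        n_runs: int = 5, perturb: float = 0.4,
                        init_coeffs: np.ndarray | None = None,
                        priors: Mapping[str, tuple[float, float]] | None = None
                        ) -> FitResult:
    """Multi-start SAEM: independent runs from perturbed initial values,
    estimates averaged across runs.

    The marginal likelihood of sparsely sampled designs can be nearly flat
    along directions such as (clearance intercept, weight exponent) under
    per-kg dosing; a single SAEM trajectory then settles anywhere within the
    flat region. Averaging the transformed-scale estimates of ``n_runs``
    independent chains (each started from its own uniform +-``perturb``
    perturbation of the initial coefficients, roughly +-50% on the natural
    scale at the default) removes most of that algorithmic scatter.
    Deterministic given ``config.seed``.
    """
    config = config or SAEMConfig()
    rng = np.random.default_rng(config.seed)
    b_base = np.array(init_coeffs if init_coeffs is not None
                      else model_spec.init_coeffs(), dtype=float)
    fits = []
    for run in range(n_runs):
        b0 = b_base + rng.uniform(-perturb, perturb, b_base.shape)
        cfg = SAEMConfig(**{**config.__dict__,
                            "seed": int(rng.integers(0, 2 ** 31 - 1))})
        fits.append(saem_fit(dataset, model_spec, cfg, priors=priors,
                             init_coeffs=b0))
    out = fits[-1]
    out.coeffs = np.mean([f.coeffs for f in fits], axis=0)
    out.fixed_effects = model_spec.fixed_effects_from_coeffs(out.coeffs)
    out.covariate_coeffs = model_spec.covariate_coeffs_from_coeffs(out.coeffs)
    out.omegas = {nm: float(np.sqrt(np.mean([f.omegas[nm] ** 2 for f in fits])))
                  for nm in out.omegas}
    out.correlations = {key: float(np.mean([f.correlations[key] for f in fits]))
                        for key in out.correlations}
    for obs in out.sigmas:
        for wkey in ("a", "b"):
            out.sigmas[obs][wkey] = float(np.mean(
                [f.sigmas[obs][wkey] for f in fits]))
    # rebuild the full covariance from the averaged components
    spec = model_spec
    p = len(spec.parameters)
    sd = np.full(p, config.pseudo_omega_floor)
    pidx = {prm.name: i for i, prm in enumerate(spec.parameters)}
    for nm, s in out.omegas.items():
        sd[pidx[nm]] = s
    om = np.diag(sd ** 2)
    for key, r in out.correlations.items():
        p1, p2 = key.split(",")
        i, j = pidx[p1], pidx[p2]
        om[i, j] = om[j, i] = np.clip(r, -0.999, 0.999) * sd[i] * sd[j]
    out.omega_full = om
    out.cond_mean_phi = np.mean([f.cond_mean_phi for f in fits], axis=0)
    out.cond_cov_phi = np.mean([f.cond_cov_phi for f in fits], axis=0)
    X = spec.design_tensor(compile_design(dataset).covariates)
    etas = out.cond_mean_phi - X @ out.coeffs
    out.ebes.iloc[:, :] = etas
    return out


def _fixed_effects_nls(spec, cd, X, y, obs_rows_of_dvid, err, b0, config):
    """Weighted NLS for the degenerate no-BSV model, with the residual SDs
    re-estimated from the weighted residuals (two reweighting rounds)."""
    from scipy.optimize import least_squares

    def weighted_residuals(b):
        pred = cd.predict(spec.structural, natural_matrix(spec, X @ b))
        f = np.maximum(pred, 1e-12)
        r = np.empty_like(f)
        for dvid, rows in obs_rows_of_dvid.items():
            st = err[dvid]
            if st.kind == "proportional":
                r[rows] = (y[rows] - f[rows]) / f[rows]
            elif st.kind == "constant":
                r[rows] = y[rows] - f[rows]
            else:
                r[rows] = (y[rows] - f[rows]) / np.sqrt(
                    st.a ** 2 + (st.b * f[rows]) ** 2)
        return r

    b = b0.copy()
    for _ in range(2):
        sol = least_squares(weighted_residuals, b, method="lm",
                            xtol=1e-12, ftol=1e-12)
        b = sol.x
        res = weighted_residuals(b)
        for dvid, rows in obs_rows_of_dvid.items():
            st = err[dvid]
            rms = float(np.sqrt(np.mean(res[rows] ** 2)))
            if st.kind == "proportional":
                st.b = max(rms, 1e-9)
            elif st.kind == "constant":
                st.a = max(rms, 1e-9)

    n, p = cd.n_subjects, len(spec.parameters)
    phi = X @ b
    ebes = pd.DataFrame(np.zeros((n, p)), index=cd.covariates.index,
                        columns=[f"eta_{nm}" for nm in spec.param_names])
    return FitResult(
        spec=spec, coeffs=b,
        fixed_effects=spec.fixed_effects_from_coeffs(b),
        covariate_coeffs=spec.covariate_coeffs_from_coeffs(b),
        omegas={}, correlations={},
        sigmas={_observable_of_dvid(d): err[d].as_dict() for d in err},
        omega_full=1e-6 * np.eye(p), cond_mean_phi=phi,
        cond_cov_phi=np.broadcast_to(1e-8 * np.eye(p), (n, p, p)).copy(),
        ebes=ebes, traces={"coeffs": b[None, :]},
        accept_rates=np.zeros((1, p)), seed=config.seed, config=config,
        n_subjects=n, n_obs=cd.n_obs,
    )


class _ErrorState:
    """Mutable residual-error parameters for one observable during SAEM."""

    def __init__(self, kind: str, a: float, b: float):
        self.kind = kind
        self.a = max(a, 1e-3) if kind in ("constant", "combined") else 0.0
        self.b = max(b, 1e-3) if kind in ("proportional", "combined") else 0.0

    def sd(self, pred):
        if self.kind == "constant":
            return np.full_like(pred, self.a)
        if self.kind == "proportional":
            return self.b * pred
        return np.sqrt(self.a ** 2 + (self.b * pred) ** 2)

    def as_dict(self):
        return {"kind": self.kind, "a": float(self.a), "b": float(self.b)}


def _observable_of_dvid(dvid: int) -> str:
    return DRUG if dvid == 1 else LIGAND


def saem_fit(dataset: Dataset, model_spec: ModelSpec,
             config: SAEMConfig | None = None,
             priors: Mapping[str, tuple[float, float]] | None = None,
             init_coeffs: np.ndarray | None = None) -> FitResult:
    """Fit ``model_spec`` to ``dataset`` by SAEM.

    ``priors`` maps parameter names to (natural-scale center, transformed-scale
    SD) Gaussian penalties on the corresponding intercept coefficients.
    ``init_coeffs`` overrides ``model_spec``'s initial coefficient vector.
    Deterministic given (dataset, spec, config.seed).
    """
    config = config or SAEMConfig()
    spec = model_spec
    required = REQUIRED_PARAMS[spec.structural]
    have = set(spec.param_names)
    if have != required:
        raise ValueError(
            f"structural model {spec.structural!r} needs parameters {sorted(required)}, "
            f"got {sorted(have)}")
    if len(dataset.df) == 0:
        raise ValueError("empty dataset")

    rng = np.random.default_rng(config.seed)
    cd = compile_design(dataset)
    n, p = cd.n_subjects, len(spec.parameters)
    X = spec.design_tensor(cd.covariates)              # (n, p, k)
    k = X.shape[2]
    laws = [prm.law for prm in spec.parameters]
    # a declared-BSV parameter with omega fixed at 0 degenerates to a point
    # parameter and is estimated through the annealing device instead
    bsv = np.array([prm.bsv and prm.omega_init > 0 for prm in spec.parameters])
    pseudo = ~bsv
    pidx = {prm.name: i for i, prm in enumerate(spec.parameters)}

    # observation bookkeeping
    obs_subj = cd.obs_subject_idx
    y = cd.obs_y
    dvids = np.unique(cd.obs_dvid)
    err: dict[int, _ErrorState] = {}
    obs_rows_of_dvid: dict[int, np.ndarray] = {}
    for dvid in dvids:
        name = _observable_of_dvid(dvid)
        em = spec.error_models.get(name)
        if em is None:
            raise ValueError(f"no error model declared for observable {name!r}")
        err[dvid] = _ErrorState(em.kind, em.a or 0.3 * np.median(y[cd.obs_dvid == dvid]),
                                em.b or 0.3)
        obs_rows_of_dvid[dvid] = np.flatnonzero(cd.obs_dvid == dvid)

    if not bsv.any():
        # no between-subject variability anywhere: the marginal likelihood
        # degenerates to weighted nonlinear least squares on the coefficients
        return _fixed_effects_nls(spec, cd, X, y, obs_rows_of_dvid, err,
                                  np.array(init_coeffs if init_coeffs is not None
                                           else spec.init_coeffs(), dtype=float),
                                  config)

    def loglik_rows(pred):
        ll = np.empty_like(pred)
        for dvid, rows in obs_rows_of_dvid.items():
            f = np.maximum(pred[rows], 1e-12)
            sd = np.maximum(err[dvid].sd(f), 1e-12)
            z = (y[rows] - f) / sd
            ll[rows] = -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI
        return ll

    def subject_loglik(pred):
        return np.bincount(obs_subj, weights=loglik_rows(pred), minlength=n)

    # state
    b = np.array(init_coeffs if init_coeffs is not None else spec.init_coeffs(),
                 dtype=float)
    omega_var = np.array([prm.omega_init ** 2 if prm.bsv else 0.0
                          for prm in spec.parameters])
    # correlations start at 0: their sign/size is estimated, not assumed
    rho = {(c[0], c[1]): 0.0 for c in spec.correlations}
    prior_prec = np.zeros(k)
    prior_center = np.zeros(k)
    if priors:
        for name, (center, sd) in priors.items():
            j = spec.coeff_labels.index(name)
            law = laws[j] if j < p else "identity"
            c = float(transform(center, law)) if j < p else float(center)
            prior_prec[j] = 1.0 / sd ** 2
            prior_center[j] = c

    def omega_full_matrix(it: int) -> np.ndarray:
        om = np.diag(np.where(bsv, omega_var, _pseudo_var(it)))
        sd = np.sqrt(np.diag(om))
        for (p1, p2), r in rho.items():
            i, j = pidx[p1], pidx[p2]
            om[i, j] = om[j, i] = np.clip(r, -0.999, 0.999) * sd[i] * sd[j]
        return om

    def _pseudo_var(it: int) -> float:
        o0, fl = config.pseudo_omega_init, config.pseudo_omega_floor
        r = (fl / o0) ** (1.0 / max(config.k1, 1))
        return max(o0 * r ** it, fl) ** 2

    # MCMC state
    u = np.zeros((n, p))
    scales = np.full(p, 1.0)
    phi_pop = X @ b
    L = np.linalg.cholesky(omega_full_matrix(0) + 1e-12 * np.eye(p))
    phi = phi_pop + u @ L.T
    pred = cd.predict(spec.structural, natural_matrix(spec, phi))
    ll = subject_loglik(pred)
    lp = -0.5 * np.sum(u * u, axis=1)

    # sufficient statistics
    phi_bar = phi.copy()
    s_phiphi = np.einsum("ip,iq->pq", phi, phi)
    err_stats = {dvid: None for dvid in dvids}
    k2_m1 = np.zeros((n, p))
    k2_m2 = np.zeros((n, p, p))
    k2_count = 0

    n_iter = config.k1 + config.k2
    traces = {"coeffs": np.empty((n_iter, k)),
              "omega": np.empty((n_iter, p)),
              "sigma": np.empty((n_iter, len(dvids), 2)),
              "rho": np.empty((n_iter, len(rho)))}
    acc_hist = np.empty((n_iter, p))

    for it in range(n_iter):
        gamma = 1.0 if it < config.k1 else 1.0 / (it - config.k1 + 1)
        omega_full = omega_full_matrix(it)
        L = np.linalg.cholesky(omega_full + 1e-12 * np.eye(p))
        phi_pop = X @ b
        phi = phi_pop + u @ L.T
        pred = cd.predict(spec.structural, natural_matrix(spec, phi))
        ll = subject_loglik(pred)
        lp = -0.5 * np.sum(u * u, axis=1)

        # --- E-step: componentwise random-walk Metropolis on u ---
        acc = np.zeros(p)
        for _ in range(config.n_transitions):
            for c in range(p):
                u_new = u.copy()
                u_new[:, c] = u[:, c] + scales[c] * rng.standard_normal(n)
                phi_new = phi_pop + u_new @ L.T
                pred_new = cd.predict(spec.structural, natural_matrix(spec, phi_new))
                ll_new = subject_loglik(pred_new)
                lp_new = -0.5 * np.sum(u_new * u_new, axis=1)
                log_alpha = (ll_new + lp_new) - (ll + lp)
                accept = np.log(rng.random(n)) < log_alpha
                u[accept] = u_new[accept]
                phi[accept] = phi_new[accept]
                row_acc = accept[obs_subj]
                pred[row_acc] = pred_new[row_acc]
                ll[accept] = ll_new[accept]
                lp[accept] = lp_new[accept]
                acc[c] += accept.mean()
        acc /= config.n_transitions
        gain = 0.5 / (1.0 + 0.1 * it) ** 0.5
        scales *= np.exp(gain * (acc - config.target_accept))
        scales = np.clip(scales, 1e-3, 50.0)
        acc_hist[it] = acc

        # --- SA update of sufficient statistics ---
        phi_bar += gamma * (phi - phi_bar)
        s_phiphi += gamma * (np.einsum("ip,iq->pq", phi, phi) - s_phiphi)
        for dvid, rows in obs_rows_of_dvid.items():
            f = np.maximum(pred[rows], 1e-12)
            r2 = (y[rows] - f) ** 2
            stat = np.stack([r2, f])
            if err_stats[dvid] is None:
                err_stats[dvid] = stat
            else:
                err_stats[dvid] += gamma * (stat - err_stats[dvid])
        if it >= config.k1:
            k2_m1 += phi
            k2_m2 += np.einsum("ip,iq->ipq", phi, phi)
            k2_count += 1

        # --- M-step ---
        w = np.linalg.inv(omega_full + 1e-12 * np.eye(p))
        xtwx = np.einsum("ipk,pq,iql->kl", X, w, X)
        xtwy = np.einsum("ipk,pq,iq->k", X, w, phi_bar)
        A = xtwx + np.diag(prior_prec)
        rhs_v = xtwy + prior_prec * prior_center
        try:
            b = np.linalg.solve(A, rhs_v)
        except np.linalg.LinAlgError:
            # collinear coefficient columns (e.g. duplicated covariate):
            # minimum-norm solution keeps the fit going; the FIM step will
            # flag the non-identifiable coefficients
            b = np.linalg.pinv(A, rcond=1e-10) @ rhs_v

        xb = X @ b                                    # (n, p)
        cross = np.einsum("ip,iq->pq", xb, phi_bar)
        omega_hat = (s_phiphi - cross - cross.T
                     + np.einsum("ip,iq->pq", xb, xb)) / n
        floor = (np.array([prm.omega_init ** 2 for prm in spec.parameters])
                 * config.annealing ** it) if it < config.k1 else 0.0
        new_var = np.maximum(np.diag(omega_hat), 1e-10)
        if it < config.k1:
            new_var = np.maximum(new_var, floor)
        omega_var = np.where(bsv, new_var, omega_var)
        for (p1, p2) in list(rho):
            i, j = pidx[p1], pidx[p2]
            denom = np.sqrt(omega_hat[i, i] * omega_hat[j, j])
            rho[(p1, p2)] = float(np.clip(omega_hat[i, j] / max(denom, 1e-12),
                                          -0.999, 0.999))
        for dvid in dvids:
            r2_bar, f_bar = err_stats[dvid]
            st = err[dvid]
            if st.kind == "proportional":
                s2 = float(np.mean(r2_bar / f_bar ** 2))
                if it < config.k1:
                    s2 = max(s2, (st.b ** 2) * config.annealing)
                st.b = np.sqrt(s2)
            elif st.kind == "constant":
                s2 = float(np.mean(r2_bar))
                if it < config.k1:
                    s2 = max(s2, (st.a ** 2) * config.annealing)
                st.a = np.sqrt(s2)
            else:  # combined: profile the conditional normal likelihood
                from scipy.optimize import minimize
                def nll(x):
                    a2, b2 = np.exp(x)
                    v = a2 + b2 * f_bar ** 2
                    return float(np.sum(np.log(v) + r2_bar / v))
                res = minimize(nll, np.log([st.a ** 2, st.b ** 2]),
                               method="Nelder-Mead",
                               options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
                st.a, st.b = np.sqrt(np.exp(res.x))

        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(omega_var))):
            raise RuntimeError(
                f"SAEM diverged at iteration {it}: non-finite statistics; "
                f"b={b}, omega={omega_var}")
        traces["coeffs"][it] = b
        traces["omega"][it] = np.sqrt(np.where(bsv, omega_var, _pseudo_var(it)))
        traces["sigma"][it] = [[err[d].a, err[d].b] for d in dvids]
        traces["rho"][it] = list(rho.values())

    # --- assemble results ---
    omega_full = omega_full_matrix(n_iter)
    cond_mean = k2_m1 / max(k2_count, 1)
    cond_cov = k2_m2 / max(k2_count, 1) - np.einsum(
        "ip,iq->ipq", cond_mean, cond_mean)
    cond_cov += 1e-10 * np.eye(p)
    etas = cond_mean - X @ b
    ebes = pd.DataFrame(etas, index=cd.covariates.index,
                        columns=[f"eta_{nm}" for nm in spec.param_names])
    fixed = spec.fixed_effects_from_coeffs(b)
    covc = spec.covariate_coeffs_from_coeffs(b)
    return FitResult(
        spec=spec, coeffs=b, fixed_effects=fixed, covariate_coeffs=covc,
        omegas={prm.name: float(np.sqrt(omega_var[i]))
                for i, prm in enumerate(spec.parameters) if bsv[i]},
        correlations={f"{p1},{p2}": r for (p1, p2), r in rho.items()},
        sigmas={_observable_of_dvid(d): err[d].as_dict() for d in dvids},
        omega_full=omega_full, cond_mean_phi=cond_mean, cond_cov_phi=cond_cov,
        ebes=ebes, traces=traces, accept_rates=acc_hist,
        seed=config.seed, config=config, n_subjects=n, n_obs=cd.n_obs,
    )
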