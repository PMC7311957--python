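"""Standard errors and %RSE from the Fisher information matrix.

Two estimators of the information matrix are provided:

* ``linearized`` (default): the structural model is linearized around each
  subject's conditional-mean parameters, giving a Gaussian marginal for
  which per-subject score vectors are computed by central finite
  differences; the information matrix is the sum of score outer products.
  Fast and deterministic.
* ``is_fd``: central finite differences of the importance-sampling
  log-likelihood with common random numbers across perturbations. Closer to
  the exact observed information but Monte-Carlo noisy and far slower; use
  for spot checks.

SEs of natural-scale fixed effects follow by the delta method from the
transformed-scale coefficients.
"""

from __future__ import annotations

import numpy as np

from .design import compile_design
from .io import Dataset
from .popmodel import ModelSpec, natural_matrix
from .saem import FitResult, _ErrorState, _observable_of_dvid
from .stats import relative_standard_error, wald_test

_LOG_2PI = float(np.log(2.0 * np.pi))


class _Psi:
    """Packing/unpacking of the full population-parameter vector."""

    def __init__(self, spec: ModelSpec, fit: FitResult):
        self.spec = spec
        self.k = len(fit.coeffs)
        self.p = len(spec.parameters)
        self.bsv_names = [prm.name for prm in spec.parameters if prm.bsv]
        self.pidx = {prm.name: i for i, prm in enumerate(spec.parameters)}
        self.corr_pairs = [tuple(c[:2]) for c in spec.correlations]
        self.sigma_slots = []
        for obs, s in fit.sigmas.items():
            if s["kind"] in ("constant", "combined"):
                self.sigma_slots.append((obs, "a"))
            if s["kind"] in ("proportional", "combined"):
                self.sigma_slots.append((obs, "b"))
        self.names = (list(spec.coeff_labels)
                      + [f"omega_{nm}" for nm in self.bsv_names]
                      + [f"corr_{p1},{p2}" for p1, p2 in self.corr_pairs]
                      + [f"sigma_{w}_{obs}" for obs, w in self.sigma_slots])

    def pack(self, fit: FitResult) -> np.ndarray:
        psi = list(fit.coeffs)
        psi += [fit.omegas[nm] for nm in self.bsv_names]
        psi += [fit.correlations[f"{p1},{p2}"] for p1, p2 in self.corr_pairs]
        psi += [fit.sigmas[obs][w] for obs, w in self.sigma_slots]
        return np.asarray(psi, dtype=float)

    def split(self, psi: np.ndarray):
        k, nb = self.k, len(self.bsv_names)
        nc = len(self.corr_pairs)
        b = psi[:k]
        om_sd = psi[k:k + nb]
        rho = psi[k + nb:k + nb + nc]
        sig = psi[k + nb + nc:]
        return b, om_sd, rho, sig

    def omega_matrix(self, psi: np.ndarray) -> np.ndarray:
        _, om_sd, rho, _ = self.split(psi)
        sd = np.zeros(self.p)
        for nm, s in zip(self.bsv_names, om_sd):
            sd[self.pidx[nm]] = s
        om = np.diag(sd ** 2)
        for (p1, p2), r in zip(self.corr_pairs, rho):
            i, j = self.pidx[p1], self.pidx[p2]
            om[i, j] = om[j, i] = np.clip(r, -0.9995, 0.9995) * sd[i] * sd[j]
        return om

    def error_states(self, psi: np.ndarray, fit: FitResult) -> dict[str, _ErrorState]:
        _, _, _, sig = self.split(psi)
        states = {obs: _ErrorState(s["kind"], s["a"], s["b"])
                  for obs, s in fit.sigmas.items()}
        for (obs, w), v in zip(self.sigma_slots, sig):
            setattr(states[obs], w, float(v))
        return states


def _subject_ll_linearized(psi: _Psi, theta: np.ndarray, fit: FitResult,
                           blocks) -> np.ndarray:
    """Per-subject Gaussian log-likelihood of the linearized marginal model."""
    b, _, _, _ = psi.split(theta)
    omega = psi.omega_matrix(theta) + 1e-10 * np.eye(psi.p)
    err = psi.error_states(theta, fit)
    out = np.empty(len(blocks))
    for i, blk in enumerate(blocks):
        yb, pred0, F, Xi, phi_hat, obs_names = blk
        m = pred0 + F @ (Xi @ b - phi_hat)
        m = np.maximum(m, 1e-9)
        sd = np.array([err[o].sd(np.array([mv]))[0] for o, mv in zip(obs_names, m)])
        V = F @ omega @ F.T + np.diag(sd ** 2)
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            V += 1e-8 * np.eye(len(m)) * max(np.trace(V) / len(m), 1.0)
            Lc = np.linalg.cholesky(V)
        z = np.linalg.solve(Lc, yb - m)
        out[i] = (-0.5 * z @ z - np.sum(np.log(np.diag(Lc)))
                  - 0.5 * len(m) * _LOG_2PI)
    return out


def _build_blocks(cd, spec, fit):
    """Per-subject (y, pred0, F, X, phi_hat, observable names) at the EBEs."""
    phi_hat = fit.cond_mean_phi
    pred0 = cd.predict(spec.structural, natural_matrix(spec, phi_hat))
    p = phi_hat.shape[1]
    F = np.empty((cd.n_obs, p))
    for j in range(p):
        h = 1e-4 * np.maximum(np.abs(phi_hat[:, j]), 1.0)
        up, dn = phi_hat.copy(), phi_hat.copy()
        up[:, j] += h
        dn[:, j] -= h
        fu = cd.predict(spec.structural, natural_matrix(spec, up))
        fd = cd.predict(spec.structural, natural_matrix(spec, dn))
        F[:, j] = (fu - fd) / (2.0 * h[cd.obs_subject_idx])
    X = spec.design_tensor(cd.covariates)
    blocks = []
    for i in range(cd.n_subjects):
        rows = np.flatnonzero(cd.obs_subject_idx == i)
        names = [_observable_of_dvid(d) for d in cd.obs_dvid[rows]]
        blocks.append((cd.obs_y[rows], pred0[rows], F[rows], X[i],
                       phi_hat[i], names))
    return blocks


def linearized_fim(dataset: Dataset, spec: ModelSpec, fit: FitResult) -> tuple[np.ndarray, _Psi]:
    """Sum-of-scores information matrix of the linearized marginal model."""
    cd = compile_design(dataset)
    psi = _Psi(spec, fit)
    theta0 = psi.pack(fit)
    blocks = _build_blocks(cd, spec, fit)
    d = len(theta0)
    G = np.empty((cd.n_subjects, d))
    for j in range(d):
        h = 1e-4 * max(abs(theta0[j]), 0.05)
        up, dn = theta0.copy(), theta0.copy()
        up[j] += h
        dn[j] -= h
        G[:, j] = (_subject_ll_linearized(psi, up, fit, blocks)
                   - _subject_ll_linearized(psi, dn, fit, blocks)) / (2 * h)
    return G.T @ G, psi


def is_fd_fim(dataset: Dataset, spec: ModelSpec, fit: FitResult,
              n_samples: int = 300, seed: int = 0) -> tuple[np.ndarray, _Psi]:
    """Observed information by central FD of the IS log-likelihood (CRN)."""
    from .likelihood import importance_sampling_core

    cd = compile_design(dataset)
    psi = _Psi(spec, fit)
    theta0 = psi.pack(fit)
    d = len(theta0)
    rng = np.random.default_rng(seed)
    n, p = fit.cond_mean_phi.shape
    zn = rng.standard_normal((n_samples, n, p))
    ch = rng.chisquare(5.0, size=(n_samples, n)) / 5.0
    cov = fit.cond_cov_phi * 1.5 + 1e-6 * np.eye(p)
    L = np.linalg.cholesky(cov)
    X = spec.design_tensor(cd.covariates)
    rows_of = {dvid: np.flatnonzero(cd.obs_dvid == dvid)
               for dvid in np.unique(cd.obs_dvid)}

    def m2ll(theta):
        b, _, _, _ = psi.split(theta)
        omega = psi.omega_matrix(theta)
        err = psi.error_states(theta, fit)
        err_d = {dvid: err[_observable_of_dvid(dvid)] for dvid in rows_of}

        def sd_of_pred(pred):
            sd = np.empty_like(pred)
            for dvid, rows in rows_of.items():
                sd[rows] = err_d[dvid].sd(np.maximum(pred[rows], 1e-12))
            return sd

        class _FrozenRng:  # replay the common random numbers
            def __init__(self):
                self.m = 0

            def standard_normal(self, shape):
                z = zn[self.m]
                return z

            def chisquare(self, df, size):
                c = ch[self.m] * df  # core divides by df again
                self.m += 1
                return c

        ll, _ = importance_sampling_core(
            lambda phi: cd.predict(spec.structural, natural_matrix(spec, phi)),
            cd.obs_y, cd.obs_subject_idx, sd_of_pred, n,
            X, b, omega, fit.cond_mean_phi, cov, n_samples, _FrozenRng())
        return -2.0 * np.sum(ll)

    H = np.empty((d, d))
    h = np.array([1e-3 * max(abs(t), 0.05) for t in theta0])
    f0 = m2ll(theta0)
    fp = np.array([m2ll(theta0 + h * e) for e in np.eye(d)])
    fm = np.array([m2ll(theta0 - h * e) for e in np.eye(d)])
    for i in range(d):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for j in range(i + 1, d):
            e_i, e_j = np.eye(d)[i], np.eye(d)[j]
            fpp = m2ll(theta0 + h * (e_i + e_j))
            fmm = m2ll(theta0 - h * (e_i + e_j))
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j]
                                 + fmm) / (2 * h[i] * h[j])
    return 0.5 * H, psi  # -2LL Hessian / 2 = observed information


def compute_se_rse(dataset: Dataset, spec: ModelSpec, fit: FitResult,
                   method: str = "linearized", **kw) -> FitResult:
    """Attach SE, %RSE and Wald p-values to ``fit`` (modified in place).

    Raises on a singular information matrix, naming the parameters whose
    SEs could not be computed.
    """
    if method == "linearized":
        fim, psi = linearized_fim(dataset, spec, fit)
    elif method == "is_fd":
        fim, psi = is_fd_fim(dataset, spec, fit, **kw)
    else:
        raise ValueError(f"unknown FIM method {method!r}")
    d = fim.shape[0]
    evals, evecs = np.linalg.eigh(fim)
    if evals[-1] <= 0 or evals[0] <= 1e-10 * evals[-1]:
        null = evecs[:, evals <= 1e-10 * max(evals[-1], 1e-300)]
        loadings = np.max(np.abs(null), axis=1) if null.size else np.zeros(d)
        bad = [psi.names[i] for i in range(d) if loadings[i] > 0.1]
        raise np.linalg.LinAlgError(
            f"singular information matrix; non-identifiable: {bad}")
    cov = np.linalg.inv(fim)
    var = np.diag(cov)
    bad = [psi.names[i] for i in range(d) if not np.isfinite(var[i]) or var[i] <= 0]
    if bad:
        raise np.linalg.LinAlgError(
            f"singular information matrix; no SE for: {bad}")
    se_t = np.sqrt(var)

    se, rse, wp = {}, {}, {}
    p = len(spec.parameters)
    for i, name in enumerate(psi.names):
        if i < p:  # intercept coefficients -> natural scale by delta method
            prm = spec.parameters[i]
            val = fit.fixed_effects[prm.name]
            deriv = val if prm.law == "lognormal" else val * (1 - val)
            se[prm.name] = abs(deriv) * se_t[i]
            rse[prm.name] = relative_standard_error(val, se[prm.name])
        elif i < psi.k:  # covariate coefficients
            lab = psi.names[i]
            val = fit.covariate_coeffs[lab]
            se[lab] = se_t[i]
            rse[lab] = relative_standard_error(val, se_t[i]) if val else np.inf
            wp[lab] = wald_test(val, se_t[i])[1]
        else:
            lab = psi.names[i]
            vals = {**{f"omega_{k_}": v for k_, v in fit.omegas.items()},
                    **{f"corr_{k_}": v for k_, v in fit.correlations.items()},
                    **{f"sigma_a_{o}": s["a"] for o, s in fit.sigmas.items()},
                    **{f"sigma_b_{o}": s["b"] for o, s in fit.sigmas.items()}}
            val = vals.get(lab, np.nan)
            se[lab] = se_t[i]
            rse[lab] = relative_standard_error(val, se_t[i]) if val else np.inf
    fit.se, fit.rse, fit.wald_p = se, rse, wp
    return fit
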