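"""Marginal log-likelihood by importance sampling.

The observed-data likelihood of a nonlinear mixed-effects model integrates
the individual random effects out of the joint density. Here that integral
is estimated per subject by importance sampling with a multivariate t(5 df)
proposal centered at the subject's conditional mean of phi with the
conditional covariance accumulated during the SAEM smoothing phase — the
standard estimator evaluated at the final population values.

The core routine is written against plain arrays and a ``predict`` callable
so that closed-form special cases (e.g. a linear-Gaussian model, where the
marginal likelihood is available exactly) can exercise the same code path
in tests.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .design import compile_design
from .io import Dataset
from .popmodel import ModelSpec, natural_matrix
from .saem import FitResult, _ErrorState, _observable_of_dvid

_LOG_2PI = float(np.log(2.0 * np.pi))


def _mvt_logpdf(z2: np.ndarray, logdet: float, dim: int, df: float) -> np.ndarray:
    """log density of a multivariate t given squared Mahalanobis distances."""
    return (gammaln(0.5 * (df + dim)) - gammaln(0.5 * df)
            - 0.5 * dim * np.log(df * np.pi) - 0.5 * logdet
            - 0.5 * (df + dim) * np.log1p(z2 / df))


def importance_sampling_core(predict, y, obs_subj, sd_of_pred, n_subjects,
                             X, b, omega, mu, cov, n_samples, rng,
                             df: float = 5.0):
    """Per-subject marginal log-likelihoods by importance sampling.

    predict(phi) -> predictions for all observation rows, phi (n, p);
    sd_of_pred(pred) -> residual SD per observation row.
    mu/cov: proposal centers (n, p) and covariances (n, p, p).
    Returns (ll per subject, Monte-Carlo SE of total -2LL).
    """
    n, p = mu.shape
    phi_pop = X @ b
    om = omega + 1e-12 * np.eye(p)
    om_inv = np.linalg.inv(om)
    _, om_logdet = np.linalg.slogdet(om)

    cov = cov + 1e-12 * np.eye(p)
    L = np.linalg.cholesky(cov)                      # (n, p, p)
    prop_logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)

    log_w = np.empty((n_samples, n))
    for m in range(n_samples):
        zn = rng.standard_normal((n, p))
        g = rng.chisquare(df, size=n) / df
        z = zn / np.sqrt(g)[:, None]                  # t(df) in whitened space
        phi = mu + np.einsum("ipq,iq->ip", L, z)
        pred = predict(phi)
        sd = np.maximum(sd_of_pred(pred), 1e-12)
        f = np.maximum(pred, 1e-12)
        ll_rows = -0.5 * ((y - f) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI
        ll_i = np.bincount(obs_subj, weights=ll_rows, minlength=n)
        d = phi - phi_pop
        prior = (-0.5 * np.einsum("ip,pq,iq->i", d, om_inv, d)
                 - 0.5 * om_logdet - 0.5 * p * _LOG_2PI)
        z2 = np.sum(z * z, axis=1)
        prop = _mvt_logpdf(z2, 0.0, p, df) - 0.5 * prop_logdet
        log_w[m] = ll_i + prior - prop

    ll = logsumexp(log_w, axis=0) - np.log(n_samples)
    # delta-method Monte-Carlo SE of each subject's log-mean-weight
    w = np.exp(log_w - ll)                            # normalized weights
    var_ll = np.var(w, axis=0, ddof=1) / n_samples
    se_m2ll = 2.0 * np.sqrt(np.sum(var_ll))
    return ll, se_m2ll


def importance_sampling_ll(dataset: Dataset, model_spec: ModelSpec,
                           fit: FitResult, n_samples: int = 1000,
                           seed: int = 0, inflate: float = 1.5) -> tuple[float, float]:
    """-2 log-likelihood of ``fit`` on ``dataset`` and its Monte-Carlo SE.

    The proposal covariance is the SAEM conditional covariance inflated by
    ``inflate`` (heavier than the posterior, on top of the t tails).
    """
    rng = np.random.default_rng(seed)
    cd = compile_design(dataset)
    spec = model_spec
    err = {dvid: _ErrorState(**fit.sigmas[_observable_of_dvid(dvid)])
           for dvid in np.unique(cd.obs_dvid)}
    rows_of = {dvid: np.flatnonzero(cd.obs_dvid == dvid) for dvid in err}

    def sd_of_pred(pred):
        sd = np.empty_like(pred)
        for dvid, rows in rows_of.items():
            sd[rows] = err[dvid].sd(np.maximum(pred[rows], 1e-12))
        return sd

    def predict(phi):
        return cd.predict(spec.structural, natural_matrix(spec, phi))

    X = spec.design_tensor(cd.covariates)
    cov = fit.cond_cov_phi * inflate
    # guard against degenerate proposal components
    diag = np.diagonal(cov, axis1=1, axis2=2)
    if np.any(diag <= 0) or not np.all(np.isfinite(cov)):
        raise ValueError("degenerate importance-sampling proposal covariance")
    floor = 1e-6
    cov = cov + floor * np.eye(cov.shape[1])
    ll, se = importance_sampling_core(
        predict, cd.obs_y, cd.obs_subject_idx, sd_of_pred, cd.n_subjects,
        X, fit.coeffs, fit.omega_full, fit.cond_mean_phi, cov,
        n_samples, rng)
    return float(-2.0 * np.sum(ll)), float(se)
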