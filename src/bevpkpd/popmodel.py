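"""Population layer: fixed effects, covariate equations, random effects, residual error.

Individual parameters follow the exponential (lognormal) law

    P_i = P_pop * prod (cov/ref)^theta * prod exp(beta)^cat * exp(eta_P)

except Imax, which is logit-normal so that it stays in (0, 1):

    logit(Imax_i) = logit(Imax_pop) + eta.

On the transformed scale every parameter is linear in the coefficient vector:
phi_i = X_i b + eta_i with eta_i ~ N(0, Omega). The estimation engine works
entirely on that scale; this module owns the mapping in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .units import DRUG, LIGAND

# ---------------------------------------------------------------------------
# transforms


def transform(value, law: str):
    value = np.asarray(value, dtype=float)
    if law == "lognormal":
        return np.log(value)
    if law == "logitnormal":
        return np.log(value / (1.0 - value))
    raise ValueError(f"unknown law {law!r}")


def back_transform(phi, law: str):
    phi = np.asarray(phi, dtype=float)
    if law == "lognormal":
        return np.exp(phi)
    if law == "logitnormal":
        return 1.0 / (1.0 + np.exp(-phi))
    raise ValueError(f"unknown law {law!r}")


# ---------------------------------------------------------------------------
# specification types


@dataclass
class ParameterSpec:
    """One structural parameter: its distribution law and variability.

    ``bsv=False`` parameters carry no between-subject variability in the final
    model (their omega is handled internally by the estimator's annealing
    device and is not reported).
    """

    name: str
    init: float
    law: str = "lognormal"
    bsv: bool = True
    omega_init: float = 0.3
    unit: str = ""


@dataclass
class CovariateEffect:
    """A single covariate-parameter relation on the transformed scale.

    kind="power": continuous, adds coefficient * log(cov/reference)
    kind="categorical": adds coefficient * indicator (exp(beta)^cat natural scale)
    """

    parameter: str
    covariate: str
    kind: str
    coefficient: float = 0.0
    reference: float | None = None

    def design_value(self, covariates: Mapping[str, float]) -> float:
        if self.covariate not in covariates or pd.isna(covariates[self.covariate]):
            raise KeyError(f"missing covariate {self.covariate!r}")
        x = float(covariates[self.covariate])
        if self.kind == "power":
            if self.reference is None or self.reference <= 0:
                raise ValueError(f"power effect on {self.covariate} needs a positive reference")
            if x <= 0:
                raise ValueError(f"non-positive continuous covariate {self.covariate}={x}")
            return float(np.log(x / self.reference))
        if self.kind == "categorical":
            return x
        raise ValueError(f"unknown covariate-effect kind {self.kind!r}")

    @property
    def label(self) -> str:
        return f"beta_{self.parameter}_{self.covariate}"


@dataclass
class RandomEffectsSpec:
    """Per-parameter SDs (transformed scale) and estimated eta-eta correlations."""

    omegas: dict[str, float]
    correlations: list[tuple[str, str, float]] = field(default_factory=list)

    def omega_matrix(self, order: Sequence[str]) -> np.ndarray:
        sd = np.array([self.omegas.get(p, 0.0) for p in order])
        omega = np.diag(sd ** 2)
        idx = {p: i for i, p in enumerate(order)}
        for p1, p2, rho in self.correlations:
            if abs(rho) > 0.999:
                rho = np.sign(rho) * 0.999
            i, j = idx[p1], idx[p2]
            omega[i, j] = omega[j, i] = rho * sd[i] * sd[j]
        # positive definiteness check (only meaningful on the bsv block)
        live = sd > 0
        if live.any():
            block = omega[np.ix_(live, live)]
            if np.linalg.eigvalsh(block).min() <= 0:
                raise ValueError("random-effect covariance is not positive definite")
        return omega


@dataclass
class ErrorModel:
    """Residual error for one observable: constant, proportional or combined.

    constant:      obs = pred + a*eps,                 sd = a
    proportional:  obs = pred*(1 + b*eps),             sd = b*pred
    combined:      obs = pred + sqrt(a^2+(b*pred)^2)*eps
    """

    kind: str = "proportional"
    a: float = 0.0
    b: float = 0.0

    def sd(self, pred):
        pred = np.asarray(pred, dtype=float)
        if self.kind == "constant":
            return np.full_like(pred, self.a)
        if self.kind == "proportional":
            if np.any(pred <= 0):
                raise ValueError("proportional error undefined for non-positive predictions")
            return self.b * pred
        if self.kind == "combined":
            return np.sqrt(self.a ** 2 + (self.b * pred) ** 2)
        raise ValueError(f"unknown error-model kind {self.kind!r}")


_LOG_2PI = float(np.log(2.0 * np.pi))


def observation_likelihood(pred, obs, error_model: ErrorModel):
    """Elementwise Gaussian log-density of ``obs`` given ``pred``."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    sd = error_model.sd(pred)
    z = (obs - pred) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def apply_error(pred, error_model: ErrorModel, seed_or_rng):
    """Draw noisy observations around ``pred`` under the error model."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    pred = np.asarray(pred, dtype=float)
    return pred + error_model.sd(pred) * rng.standard_normal(pred.shape)


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Complete population-model specification driving the shared engine."""

    structural: str  # "pk2" | "qss" | "pkpd"
    parameters: list[ParameterSpec]
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    correlations: list[tuple[str, str, float]] = field(default_factory=list)
    error_models: dict[str, ErrorModel] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.structural not in ("pk2", "qss", "pkpd"):
            raise ValueError(f"unknown structural model {self.structural!r}")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        for eff in self.covariate_effects:
            if eff.parameter not in names:
                raise ValueError(f"covariate effect targets unknown parameter {eff.parameter}")

    # -- bookkeeping -------------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def laws(self) -> dict[str, str]:
        return {p.name: p.law for p in self.parameters}

    def param(self, name: str) -> ParameterSpec:
        return next(p for p in self.parameters if p.name == name)

    @property
    def coeff_labels(self) -> list[str]:
        """Order of the fixed-effect coefficient vector b: one intercept per
        parameter followed by the covariate coefficients."""
        return [p.name for p in self.parameters] + [e.label for e in self.covariate_effects]

    @property
    def n_coeffs(self) -> int:
        return len(self.parameters) + len(self.covariate_effects)

    @property
    def observables(self) -> list[str]:
        return [LIGAND] if self.structural == "ligand" else (
            [DRUG] if self.structural == "pk2" else [DRUG, LIGAND])

    # -- coefficient vector <-> natural-scale values -------------------------
    def init_coeffs(self) -> np.ndarray:
        b = [transform(p.init, p.law) for p in self.parameters]
        b += [e.coefficient for e in self.covariate_effects]
        return np.asarray(b, dtype=float)

    def fixed_effects_from_coeffs(self, b: np.ndarray) -> dict[str, float]:
        return {p.name: float(back_transform(b[i], p.law))
                for i, p in enumerate(self.parameters)}

    def covariate_coeffs_from_coeffs(self, b: np.ndarray) -> dict[str, float]:
        k = len(self.parameters)
        return {e.label: float(b[k + i]) for i, e in enumerate(self.covariate_effects)}

    # -- design matrices ----------------------------------------------------
    def design_matrix(self, covariates: Mapping[str, float]) -> np.ndarray:
        """X_i mapping the coefficient vector b to the subject's phi vector."""
        p, k = len(self.parameters), self.n_coeffs
        X = np.zeros((p, k))
        idx = {name: i for i, name in enumerate(self.param_names)}
        X[np.arange(p), np.arange(p)] = 1.0
        for j, eff in enumerate(self.covariate_effects):
            X[idx[eff.parameter], p + j] = eff.design_value(covariates)
        return X

    def design_tensor(self, covariates: pd.DataFrame) -> np.ndarray:
        """Stacked X_i for every subject row of ``covariates`` (n, p, k)."""
        return np.stack([self.design_matrix(row) for _, row in covariates.iterrows()])

    def random_effects_spec(self) -> RandomEffectsSpec:
        return RandomEffectsSpec(
            omegas={p.name: (p.omega_init if p.bsv else 0.0) for p in self.parameters},
            correlations=list(self.correlations),
        )

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "structural": self.structural,
            "parameters": [asdict(p) for p in self.parameters],
            "covariate_effects": [asdict(e) for e in self.covariate_effects],
            "correlations": [list(c) for c in self.correlations],
            "error_models": {k: asdict(v) for k, v in self.error_models.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            structural=doc["structural"],
            parameters=[ParameterSpec(**p) for p in doc["parameters"]],
            covariate_effects=[CovariateEffect(**e) for e in doc.get("covariate_effects", [])],
            correlations=[tuple(c) for c in doc.get("correlations", [])],
            error_models={k: ErrorModel(**v) for k, v in doc.get("error_models", {}).items()},
            name=doc.get("name", ""),
        )


# ---------------------------------------------------------------------------
# operations


def individual_params(spec: ModelSpec, b: np.ndarray,
                      covariates: Mapping[str, float],
                      eta: Mapping[str, float] | np.ndarray | None = None) -> dict[str, float]:
    """Natural-scale individual parameters for one subject.

    ``b`` is the transformed coefficient vector (intercepts + covariate
    coefficients); ``eta`` maps parameter names to random-effect values
    (or is a vector in parameter order; None means all zero).
    """
    X = spec.design_matrix(covariates)
    phi = X @ np.asarray(b, dtype=float)
    if eta is not None:
        if isinstance(eta, Mapping):
            eta = np.array([eta.get(p, 0.0) for p in spec.param_names])
        phi = phi + np.asarray(eta, dtype=float)
    return {p.name: float(back_transform(phi[i], p.law))
            for i, p in enumerate(spec.parameters)}


def phi_matrix(spec: ModelSpec, b: np.ndarray, covariates: pd.DataFrame,
               etas: np.ndarray | None = None) -> np.ndarray:
    """Transformed individual parameters for all subjects: (n, p)."""
    X = spec.design_tensor(covariates)
    phi = X @ np.asarray(b, dtype=float)
    if etas is not None:
        phi = phi + etas
    return phi


def natural_matrix(spec: ModelSpec, phi: np.ndarray) -> dict[str, np.ndarray]:
    """Columns of phi back-transformed to natural scale, keyed by parameter."""
    return {p.name: back_transform(phi[:, i], p.law)
            for i, p in enumerate(spec.parameters)}


def sample_etas(random_spec: RandomEffectsSpec, order: Sequence[str],
                n: int, seed) -> np.ndarray:
    """Draw n random-effect vectors ~ N(0, Omega); reproducible under seed."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    omega = random_spec.omega_matrix(order)
    sd = np.sqrt(np.diag(omega))
    live = sd > 0
    etas = np.zeros((n, len(order)))
    if live.any():
        block = omega[np.ix_(live, live)]
        L = np.linalg.cholesky(block)
        etas[:, live] = rng.standard_normal((n, int(live.sum()))) @ L.T
    return etas
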