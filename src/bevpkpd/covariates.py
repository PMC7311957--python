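"""Pharmacogenetic covariate machinery.

Mirrors the two-stage strategy of the analysis: (1) screening of empirical
Bayes estimates (EBEs) of the random effects against candidate covariates —
Pearson correlation for continuous, one-way ANOVA for categorical — and
(2) stepwise forward-addition / backward-elimination on the full mixed-
effects fit, where a covariate is retained only if its Wald test is
significant at 5% AND the -2LL drop it buys exceeds the chi-square(1)
5% critical value 3.84. Random-effect correlations are admitted by the
joint rule: Pearson p < 0.05, |r| > 0.5 and %RSE of the estimate < 35%.
Independence between the categorical covariates themselves is checked by
chi-square (with and without Yates continuity correction) and Fisher's
exact test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Dataset
from .popmodel import CovariateEffect, ModelSpec
from .saem import FitResult, SAEMConfig, saem_fit
from .stats import LRT_CRITICAL_1DF, lrt

CONTINUOUS_COVARIATES = {"WT", "AGE"}


# ---------------------------------------------------------------------------
# screening


def screen_covariates(ebes: pd.DataFrame, covariates: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Test every (random effect, covariate) pair on the EBE scale.

    ``ebes``: columns ``eta_<param>`` per subject. Continuous covariates get
    a Pearson correlation test, categorical a one-way ANOVA. Constant
    covariates are skipped with a note. Returns a long table with columns
    eta, covariate, kind, statistic, p, candidate, note.
    """
    rows = []
    for eta_col in ebes.columns:
        e = ebes[eta_col].to_numpy(float)
        for cov in covariates.columns:
            x = covariates[cov].to_numpy(float)
            note = ""
            if np.all(x == x[0]):
                rows.append({"eta": eta_col, "covariate": cov, "kind": "-",
                             "statistic": np.nan, "p": np.nan,
                             "candidate": False, "note": "constant covariate; skipped"})
                continue
            if cov in CONTINUOUS_COVARIATES:
                r, p = sps.pearsonr(x, e)
                kind, stat = "pearson", r
            else:
                groups = [e[x == v] for v in np.unique(x)]
                if any(len(g) < 2 for g in groups):
                    note = "group with <2 subjects"
                f, p = sps.f_oneway(*groups)
                kind, stat = "anova", f
            rows.append({"eta": eta_col, "covariate": cov, "kind": kind,
                         "statistic": float(stat), "p": float(p),
                         "candidate": bool(p < alpha), "note": note})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stepwise selection


@dataclass
class SelectionStep:
    action: str              # "add" | "remove" | "reject" | "skip"
    effect: str              # covariate-effect label
    wald_p: float | None
    lrt_drop: float | None
    minus2ll: float | None
    note: str = ""


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FitResult | None = None

    def to_json(self, path) -> None:
        doc = {"steps": [asdict(s) for s in self.steps], "retained": self.retained}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)

    def log(self) -> str:
        lines = []
        for s in self.steps:
            lines.append(f"{s.action:7s} {s.effect:28s} "
                         f"wald_p={s.wald_p if s.wald_p is not None else '-'} "
                         f"lrt_drop={s.lrt_drop if s.lrt_drop is not None else '-'} "
                         f"{s.note}")
        lines.append("retained: " + (", ".join(self.retained) or "(none)"))
        return "\n".join(lines)


def passes_inclusion(wald_p: float, lrt_drop: float, alpha: float = 0.05) -> bool:
    """Both criteria must hold: Wald p < alpha AND -2LL drop > 3.84."""
    return (wald_p < alpha) and (lrt_drop > LRT_CRITICAL_1DF)


def _with_effects(base: ModelSpec, effects: list[CovariateEffect]) -> ModelSpec:
    import copy
    spec = copy.deepcopy(base)
    spec.covariate_effects = list(base.covariate_effects) + [
        copy.deepcopy(e) for e in effects]
    return spec


def stepwise_select(dataset: Dataset, base_spec: ModelSpec,
                    candidates: list[CovariateEffect],
                    config: SAEMConfig | None = None,
                    alpha: float = 0.05,
                    ll_samples: int = 500,
                    fim_method: str = "linearized") -> SelectionTrace:
    """Forward addition then backward elimination over ``candidates``.

    Forward: at each round, every not-yet-included candidate is fitted on
    top of the current model; the one with the smallest Wald p among those
    passing both inclusion tests is added. Backward: each retained effect is
    removed in turn and dropped for good if the removal costs less than the
    chi-square criterion. Ties are broken by larger |Wald z|, then
    lexicographically. Deterministic given the config seed.
    """
    from .likelihood import importance_sampling_ll
    from .uncertainty import compute_se_rse

    config = config or SAEMConfig()
    trace = SelectionTrace()
    included: list[CovariateEffect] = []
    step_seed = config.seed

    def fit_spec(spec: ModelSpec, seed: int):
        cfg = SAEMConfig(**{**config.__dict__, "seed": seed})
        fit = saem_fit(dataset, spec, cfg)
        m2ll, _ = importance_sampling_ll(dataset, spec, fit,
                                         n_samples=ll_samples, seed=seed)
        return fit, m2ll

    base_fit, base_m2ll = fit_spec(base_spec, step_seed)
    current_spec, current_m2ll = base_spec, base_m2ll

    # ---- forward addition
    remaining = list(candidates)
    while remaining:
        results = []
        for cand in sorted(remaining, key=lambda c: c.label):
            step_seed += 1
            spec_c = _with_effects(base_spec, included + [cand])
            try:
                fit_c, m2ll_c = fit_spec(spec_c, step_seed)
                compute_se_rse(dataset, spec_c, fit_c, method=fim_method)
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                trace.steps.append(SelectionStep(
                    "skip", cand.label, None, None, None,
                    note=f"fit failed: {exc}"))
                continue
            wp = fit_c.wald_p.get(cand.label, 1.0)
            drop, _ = lrt(current_m2ll, m2ll_c)
            se = fit_c.se.get(cand.label, np.inf)
            z = abs(fit_c.covariate_coeffs[cand.label]) / se if se > 0 else 0.0
            results.append((cand, fit_c, m2ll_c, wp, drop, z))
        accepted = [r for r in results if passes_inclusion(r[3], r[4], alpha)]
        for cand, _, m2ll_c, wp, drop, _ in results:
            if not passes_inclusion(wp, drop, alpha):
                trace.steps.append(SelectionStep(
                    "reject", cand.label, wp, drop, m2ll_c,
                    note="fails Wald and/or LRT criterion"))
        if not accepted:
            break
        accepted.sort(key=lambda r: (r[3], -r[5], r[0].label))
        best = accepted[0]
        included.append(best[0])
        remaining = [c for c in remaining if c.label != best[0].label]
        current_spec, current_m2ll = _with_effects(base_spec, included), best[2]
        trace.steps.append(SelectionStep(
            "add", best[0].label, best[3], best[4], best[2]))

    # ---- backward elimination
    changed = True
    while changed and included:
        changed = False
        for eff in sorted(included, key=lambda c: c.label):
            step_seed += 1
            reduced = [c for c in included if c.label != eff.label]
            spec_r = _with_effects(base_spec, reduced)
            try:
                _, m2ll_r = fit_spec(spec_r, step_seed)
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                trace.steps.append(SelectionStep(
                    "skip", eff.label, None, None, None,
                    note=f"removal refit failed: {exc}"))
                continue
            drop, _ = lrt(m2ll_r, current_m2ll)
            if drop < LRT_CRITICAL_1DF:  # effect not worth its df
                included = reduced
                current_m2ll = m2ll_r
                trace.steps.append(SelectionStep(
                    "remove", eff.label, None, drop, m2ll_r,
                    note="removal costs < 3.84"))
                changed = True
                break

    final_spec = _with_effects(base_spec, included)
    step_seed += 1
    final_fit, final_m2ll = fit_spec(final_spec, step_seed)
    trace.retained = [e.label for e in included]
    trace.final_spec = final_spec
    trace.final_fit = final_fit
    return trace


# ---------------------------------------------------------------------------
# random-effect correlation rule


def correlation_rule(r: float, p: float, rse_pct: float,
                     alpha: float = 0.05) -> bool:
    """Admit an eta-eta correlation iff p < alpha, |r| > 0.5 and %RSE < 35."""
    return (p < alpha) and (abs(r) > 0.5) and (rse_pct < 35.0)


def correlation_inclusion(fit: FitResult, pair: tuple[str, str] = ("CL", "Q")) -> dict:
    """Apply the correlation rule to a fitted model's EBEs and estimate."""
    e1 = fit.ebes[f"eta_{pair[0]}"].to_numpy()
    e2 = fit.ebes[f"eta_{pair[1]}"].to_numpy()
    r, p = sps.pearsonr(e1, e2)
    key = f"corr_{pair[0]},{pair[1]}"
    rse = (fit.rse or {}).get(key, np.inf)
    return {"pair": pair, "r": float(r), "p": float(p), "rse_pct": float(rse),
            "include": correlation_rule(r, p, rse)}


# ---------------------------------------------------------------------------
# covariate-covariate independence


def independence_tests(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray,
                       alpha: float = 0.05) -> dict:
    """Chi-square (with and without Yates), plus Fisher exact for 2x2 tables.

    Returns the three p-values and a dependence flag at ``alpha``; when the
    table has an empty row/column the chi-square tests are marked invalid
    and only Fisher is used.
    """
    table = pd.crosstab(pd.Series(np.asarray(a)), pd.Series(np.asarray(b))).to_numpy()
    out = {"table": table.tolist()}
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any() \
        or table.shape[0] < 2 or table.shape[1] < 2
    if degenerate:
        out["chi2_p"] = out["chi2_yates_p"] = None
        out["chi2_valid"] = False
    else:
        out["chi2_p"] = float(sps.chi2_contingency(table, correction=False)[1])
        out["chi2_yates_p"] = float(sps.chi2_contingency(table, correction=True)[1])
        out["chi2_valid"] = True
    if table.shape == (2, 2):
        out["fisher_p"] = float(sps.fisher_exact(table)[1])
    else:
        out["fisher_p"] = None
    ps = [p for p in (out["chi2_p"], out["chi2_yates_p"], out["fisher_p"])
          if p is not None]
    out["dependent"] = bool(ps and min(ps) < alpha)
    return out


def independence_table(covariates: pd.DataFrame,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """All pairwise independence tests among categorical covariate columns."""
    cols = columns or [c for c in covariates.columns
                       if c not in CONTINUOUS_COVARIATES]
    rows = []
    for i, c1 in enumerate(cols):
        for c2 in cols[i + 1:]:
            res = independence_tests(covariates[c1], covariates[c2])
            rows.append({"covariate_1": c1, "covariate_2": c2,
                         "chi2_p": res["chi2_p"],
                         "chi2_yates_p": res["chi2_yates_p"],
                         "fisher_p": res["fisher_p"],
                         "dependent": res["dependent"]})
    return pd.DataFrame(rows)
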