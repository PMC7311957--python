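"""Parameter-recovery experiments on synthetic cohorts.

Each experiment simulates a cohort under one of the reference models (the
published estimates acting as simulation truth), then re-estimates the model
by multi-start SAEM from initial values perturbed by roughly +-50% around
the truth. They are the package's end-to-end exercise of the estimation
stack and are invoked both by the acceptance script and the test suite.

Problem sizes: the drug-only PK experiment uses 200 subjects on the 5 mg/kg
q2w regimen with trough+peak sampling over six cycles; the joint PK/PD and
binding QSS experiments use 100 subjects on the study's regimen mix with
reduced SAEM iteration counts (K1=150, K2=50) — rich enough for stable
recovery while keeping each experiment in the minutes range on one core.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec, dense_plan, generate_cohort, simulate_dataset
from .models import pk_reference, pkpd_reference, qss_reference
from .saem import SAEMConfig, saem_fit_multistart


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31 - 1) for s in ss.generate_state(n)]


def pk_recovery_experiment(seed: int, n_subjects: int = 200,
                           n_runs: int = 8) -> dict:
    """Two-compartment PK recovery: report CLpop and the rs1799969 effect."""
    s_coh, s_sim, s_fit = _child_seeds(seed, 3)
    spec = pk_reference()
    cohort = generate_cohort(CohortSpec(n_subjects=n_subjects, p_q2w=1.0), s_coh)
    dataset, truth = simulate_dataset(cohort, spec, s_sim,
                                      plan=dense_plan(6, observables=(1,)))
    cfg = SAEMConfig(k1=400, k2=300, n_transitions=4, seed=s_fit)
    fit = saem_fit_multistart(dataset, pk_reference(), cfg, n_runs=n_runs)
    return {
        "n_subjects": n_subjects,
        "n_obs": int(len(dataset.observations())),
        "CL_pop": fit.fixed_effects["CL"],
        "beta_CL_RS1799969": fit.covariate_coeffs["beta_CL_RS1799969"],
        "fit": fit, "dataset": dataset, "truth": truth,
    }


def pkpd_recovery_experiment(seed: int, n_subjects: int = 100,
                             n_runs: int = 3) -> dict:
    """Joint PK/Imax recovery: report Imax and IC50."""
    s_coh, s_sim, s_fit = _child_seeds(seed, 3)
    spec = pkpd_reference()
    cohort = generate_cohort(CohortSpec(n_subjects=n_subjects), s_coh)
    dataset, truth = simulate_dataset(cohort, spec, s_sim, plan=dense_plan(6))
    cfg = SAEMConfig(k1=150, k2=50, seed=s_fit)
    fit = saem_fit_multistart(dataset, pkpd_reference(), cfg, n_runs=n_runs)
    return {
        "n_subjects": n_subjects,
        "n_obs": int(len(dataset.observations())),
        "Imax": fit.fixed_effects["Imax"],
        "IC50": fit.fixed_effects["IC50"],
        "fit": fit, "dataset": dataset, "truth": truth,
    }


def qss_recovery_experiment(seed: int, n_subjects: int = 100,
                            n_runs: int = 3) -> dict:
    """Binding QSS recovery (complex clearance tied to CL): report Kss."""
    s_coh, s_sim, s_fit = _child_seeds(seed, 3)
    spec = qss_reference()
    cohort = generate_cohort(CohortSpec(n_subjects=n_subjects), s_coh)
    dataset, truth = simulate_dataset(cohort, spec, s_sim, plan=dense_plan(6))
    cfg = SAEMConfig(k1=150, k2=50, seed=s_fit)
    fit = saem_fit_multistart(dataset, qss_reference(), cfg, n_runs=n_runs)
    return {
        "n_subjects": n_subjects,
        "n_obs": int(len(dataset.observations())),
        "Kss": fit.fixed_effects["Kss"],
        "fit": fit, "dataset": dataset, "truth": truth,
    }
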