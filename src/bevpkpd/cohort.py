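"""Synthetic cohort, dosing design and dataset simulation.

The generator emulates the observed-study design this package analyses:
46 metastatic colorectal cancer patients on bevacizumab, dosed 5 mg/kg every
2 weeks (76%) or 7.5 mg/kg every 3 weeks, with trough (pre-dose) and peak
(end-of-infusion) serum samples of drug and free VEGF-A over a handful of
treatment cycles, and five angiogenesis-gene SNPs coded wild-type vs mutant
carrier. Demographics and genotype frequencies follow the study population;
per-slot retention probabilities thin the sampling grid to the study's
observation counts (156 drug / 169 ligand at n=46).

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import Dataset, COVARIATE_COLUMNS
from .popmodel import ModelSpec, apply_error, natural_matrix, phi_matrix, sample_etas
from .structural import (
    DEFAULT_TINF, DoseEvent, PKParams, PDParams, QSSParams,
    pk2_conc, pkpd_simulate, qss_simulate,
)

#: assay lower limits of quantification (drug mg/L, ligand ng/L)
LLOQ = {1: 0.033, 2: 9.0}


@dataclass
class CohortSpec:
    """Marginal laws of the study covariates.

    Weight and age are lognormal matched to the reported medians and
    interquartile ranges; SNP fields are mutant-carrier probabilities
    (one minus the reported wild-type fractions).
    """

    n_subjects: int = 46
    weight_median: float = 74.5
    weight_log_sd: float = 0.18     # compromise of the asymmetric IQR half-widths
    age_median: float = 63.0
    age_log_sd: float = 0.153
    p_male: float = 0.61
    p_mutant: dict[str, float] = field(default_factory=lambda: {
        "RS699947": 0.52, "RS1570360": 0.33, "RS2010963": 0.41,
        "RS5498": 0.70, "RS1799969": 0.20,
    })
    p_q2w: float = 0.76
    p_irinotecan: float = 0.52

    def __post_init__(self):
        probs = [self.p_male, self.p_q2w, self.p_irinotecan, *self.p_mutant.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SamplingPlan:
    """Which cycles are sampled and how trough/peak draws are placed.

    Trough 15 min before the infusion, peak 5 min after its end. The pre-dose
    drug slot of cycle 1 is skipped (no drug on board yet); the pre-dose
    ligand slot of cycle 1 is the baseline draw at t=0. ``retention`` thins
    slots by (DVID, PREDOSE) to emulate the study's observation counts; the
    dense recovery designs use retention 1.
    """

    cycles: tuple[int, ...] = (1, 3, 6, 9)
    tinf: float = DEFAULT_TINF
    peak_offset: float = 5.0 / 1440.0
    trough_offset: float = 15.0 / 1440.0
    retention: dict[tuple[int, int], float] = field(default_factory=lambda: {
        (1, 1): 76 / 138, (1, 0): 80 / 184,   # drug trough / peak
        (2, 1): 87 / 184, (2, 0): 82 / 184,   # ligand trough / peak
    })
    observables: tuple[int, ...] = (1, 2)


def dense_plan(n_cycles: int = 6, observables: tuple[int, ...] = (1, 2)) -> SamplingPlan:
    """Fully-sampled trough+peak plan over cycles 1..n_cycles (no thinning)."""
    return SamplingPlan(
        cycles=tuple(range(1, n_cycles + 1)),
        retention={(d, p): 1.0 for d in (1, 2) for p in (0, 1)},
        observables=observables,
    )


def generate_cohort(spec: CohortSpec, seed) -> pd.DataFrame:
    """Draw a covariate table (one row per subject, indexed by ID).

    Genotypes are drawn independently across SNPs, consistent with the
    absence of cross-SNP association in the study population.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = spec.n_subjects
    df = pd.DataFrame({
        "WT": np.round(spec.weight_median * np.exp(
            spec.weight_log_sd * rng.standard_normal(n)), 1),
        "AGE": np.round(spec.age_median * np.exp(
            spec.age_log_sd * rng.standard_normal(n))).astype(int),
        "SEX": (rng.random(n) < spec.p_male).astype(int),
    })
    for snp, p in spec.p_mutant.items():
        df[snp] = (rng.random(n) < p).astype(int)
    df["REG"] = np.where(rng.random(n) < spec.p_q2w, 1, 2)
    df["COTX"] = (rng.random(n) < spec.p_irinotecan).astype(int)
    df.index = pd.RangeIndex(1, n + 1, name="ID")
    return df


def generate_design(subject: pd.Series, plan: SamplingPlan):
    """Dose events and observation slots for one subject.

    Returns ``(doses, slots)`` where doses are :class:`DoseEvent` and slots
    are (time, dvid, predose) tuples before retention thinning.
    """
    q2w = int(subject["REG"]) == 1
    interval = 14.0 if q2w else 21.0
    mg_per_kg = 5.0 if q2w else 7.5
    amount = mg_per_kg * float(subject["WT"])
    n_doses = max(plan.cycles)
    doses = [DoseEvent(interval * c, amount, plan.tinf) for c in range(n_doses)]
    slots = []
    for c in plan.cycles:
        t_dose = interval * (c - 1)
        for dvid in plan.observables:
            if c == 1:
                if dvid == 2:
                    slots.append((0.0, 2, 1))  # baseline ligand draw
            else:
                slots.append((t_dose - plan.trough_offset, dvid, 1))
            slots.append((t_dose + plan.tinf + plan.peak_offset, dvid, 0))
    slots.sort()
    return doses, slots


def _structural_predict(spec: ModelSpec, params: dict[str, float],
                        doses, times: np.ndarray, dvids: np.ndarray) -> np.ndarray:
    if spec.structural == "pk2":
        return pk2_conc(times, doses, PKParams(
            CL=params["CL"], V1=params["V1"], Q=params["Q"], V2=params["V2"]))
    if spec.structural == "pkpd":
        drug, lig = pkpd_simulate(
            times, doses,
            PKParams(CL=params["CL"], V1=params["V1"], Q=params["Q"], V2=params["V2"]),
            PDParams(E0=params["E0"], Imax=params["Imax"], IC50=params["IC50"]))
        return np.where(dvids == 1, drug, lig)
    if spec.structural == "qss":
        drug, lig = qss_simulate(times, doses, QSSParams(
            CL=params["CL"], V1=params["V1"], Q=params["Q"], V2=params["V2"],
            Kss=params["Kss"], kout=params["kout"], BM0=params["BM0"]))
        return np.where(dvids == 1, drug, lig)
    raise ValueError(spec.structural)


def simulate_dataset(subjects: pd.DataFrame, model_spec: ModelSpec, seed,
                     plan: SamplingPlan | None = None,
                     etas: np.ndarray | None = None) -> tuple[Dataset, dict]:
    """Simulate a complete dataset under ``model_spec`` (its inits are the truth).

    Observations that would fall below the assay quantification limits are
    redrawn once and dropped if still unquantifiable, preserving the no-BLQ
    property of the study data. Returns the dataset and a JSON-able truth
    record (coefficients, omegas, sigmas, etas, seed).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    plan = plan or SamplingPlan()
    b = model_spec.init_coeffs()
    respec = model_spec.random_effects_spec()
    if etas is None:
        etas = sample_etas(respec, model_spec.param_names, len(subjects), rng)
    phi = phi_matrix(model_spec, b, subjects, etas)
    nat = natural_matrix(model_spec, phi)

    model_dvids = (1,) if model_spec.structural == "pk2" else (1, 2)
    rows = []
    for i, (sid, sub) in enumerate(subjects.iterrows()):
        doses, slots = generate_design(sub, plan)
        kept = [s for s in slots
                if s[1] in plan.observables and s[1] in model_dvids
                and rng.random() < plan.retention.get((s[1], s[2]), 1.0)]
        cov = {c: sub[c] for c in COVARIATE_COLUMNS if c in sub.index}
        for d in doses:
            rows.append({"ID": sid, "TIME": d.time, "EVID": 1, "AMT": d.amount,
                         "TINF": d.tinf, "DV": np.nan, "DVID": 0, "MDV": 1,
                         "PREDOSE": 0, **cov})
        if not kept:
            continue
        times = np.array([s[0] for s in kept])
        dvids = np.array([s[1] for s in kept])
        pre = np.array([s[2] for s in kept])
        params = {k: float(v[i]) for k, v in nat.items()}
        pred = _structural_predict(model_spec, params, doses, times, dvids)
        dv = np.empty_like(pred)
        for dvid, obs_name in ((1, "drug"), (2, "ligand")):
            m = dvids == dvid
            if not m.any():
                continue
            em = model_spec.error_models[obs_name]
            y = apply_error(pred[m], em, rng)
            redo = y < LLOQ[dvid]
            if redo.any():  # one redraw, then drop
                y[redo] = apply_error(pred[m][redo], em, rng)
            dv[m] = y
        ok = dv >= np.array([LLOQ[d] for d in dvids])
        for t, dvid, p_, v in zip(times[ok], dvids[ok], pre[ok], dv[ok]):
            rows.append({"ID": sid, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "TINF": np.nan, "DV": v, "DVID": int(dvid), "MDV": 0,
                         "PREDOSE": int(p_), **cov})

    dataset = Dataset(pd.DataFrame(rows))
    truth = {
        "model": model_spec.name or model_spec.structural,
        "coeffs": {k: float(v) for k, v in
                   zip(model_spec.coeff_labels, b)},
        "omegas": {p.name: p.omega_init for p in model_spec.parameters if p.bsv},
        "correlations": [list(c) for c in model_spec.correlations],
        "error_models": {k: asdict(v) for k, v in model_spec.error_models.items()},
        "etas": etas.tolist(),
    }
    return dataset, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
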