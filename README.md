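# bevpkpd

Population pharmacokinetic/pharmacodynamic modelling of **bevacizumab** and
**free VEGF-A** in metastatic colorectal cancer, with pharmacogenetic
covariates. The package implements, end to end:

* three structural models sharing a two-compartment disposition backbone —
  drug-only **PK**, a **quasi-steady-state (QSS) target-mediated** binding
  model of the drug and its soluble target, and a joint **PK/Imax** model of
  free-ligand suppression;
* a **SAEM** (stochastic approximation EM) nonlinear mixed-effects estimator
  with importance-sampling likelihood, Fisher-information standard errors,
  and Gaussian priors;
* the **covariate machinery**: EBE screening (Pearson/ANOVA), stepwise
  forward/backward selection under a joint Wald + likelihood-ratio rule,
  random-effect correlation admission, and covariate independence tests;
* model evaluation by **prediction-corrected VPC** and **NPDE**;
* a **synthetic cohort generator** emulating the study design (46 mCRC
  patients, 5 mg/kg q2w or 7.5 mg/kg q3w, trough/peak sampling, five
  *VEGF-A*/*ICAM-1* SNPs coded wild-type vs mutant carrier), since the
  original patient data are not public.

## The models

Individual parameters follow exponential covariate/random-effect laws, e.g.
for clearance

```
CL_i = CL_pop · (WT_i/70)^θ_WT · exp(β)^[rs1799969 mutant] · exp(η_CL,i),   η ~ N(0, ω²)
```

with a logit-normal law for Imax. The QSS binding model collapses the
drug–target association into the constant `Kss` with free drug the positive
root of

```
C² + (Rtot + Kss − Ctot)·C − Kss·Ctot = 0,      R = Rtot·Kss/(Kss + C)
```

target turnover `dRtot/dt = kin − kout·Rtot − (kint − kout)·(Ctot − C)`,
`kin = BM0·kout`, and the complex cleared like free drug (`kint = CL/V1`).
The PD model is an immediate-response Imax law without sigmoidicity,
`E = E0·(1 − Imax·C/(IC50 + C))`. Concentrations are carried in assay units
(drug mg/L, ligand ng/L) and converted to nM inside the binding model
(149 kDa / 45 kDa, 1:1 stoichiometry).

## Worked example

```python
from bevpkpd import CohortSpec, SAEMConfig, dense_plan
from bevpkpd.cohort import generate_cohort, simulate_dataset
from bevpkpd.models import pk_reference
from bevpkpd.saem import saem_fit_multistart

cohort = generate_cohort(CohortSpec(n_subjects=100, p_q2w=1.0), seed=11)
dataset, truth = simulate_dataset(cohort, pk_reference(), seed=12,
                                  plan=dense_plan(6, observables=(1,)))
fit = saem_fit_multistart(dataset, pk_reference(),
                          SAEMConfig(k1=300, k2=100, seed=13), n_runs=3)
print({k: round(v, 3) for k, v in fit.fixed_effects.items()})
print({k: round(v, 3) for k, v in fit.covariate_coeffs.items()})
```

prints (seeds as above)

```
{'CL': 0.214, 'V1': 3.145, 'Q': 0.361, 'V2': 2.331}
{'beta_CL_WT': 1.085, 'beta_CL_RS1799969': -0.617, 'beta_Q_RS1570360': 0.594, 'beta_Q_RS699947': -0.442}
```

i.e. the simulation truth (CL 0.200 L/day, V1 3.09 L, weight exponent 1.04,
a −0.423 mutant-carrier effect on CL) is recovered from 100 synthetic
subjects to within the precision such a cohort supports; the SNP and weight
coefficients are the noisiest because only ~20 subjects carry the mutant
allele and every dose is itself weight-proportional. The 200-subject
acceptance experiment (below) tightens all of them.

The numbered drivers under `analysis/` run the full study-shaped workflow —
cohort simulation, the three model fits, covariate selection, diagnostics —
and write their tables under `results/`. A `bevpkpd` console script exposes
the same pipeline (`bevpkpd simulate|fit|select|vpc|npde|report --help`).

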