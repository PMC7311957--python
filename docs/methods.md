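# Methods

## Structural models

All three models share a two-compartment disposition backbone with
zero-order (infusion) input and first-order elimination; time is in days,
clearances in L/day, volumes in L.

**Drug-only PK.** The central concentration is evaluated in closed form via
the macro-constant (α, β) decomposition with piecewise infusion terms and
superposition over doses. The closed form is checked in the test suite
against adaptive ODE integration (relative error < 1e-6 on random
parameter/regimen draws).

**QSS binding model.** Target-mediated disposition is reduced under the
quasi-steady-state assumption: binding, unbinding and internalization
equilibrate fast relative to disposition, so free drug C follows
algebraically from the totals,

    C = ½[(Ctot − Rtot − Kss) + sqrt((Ctot − Rtot − Kss)² + 4·Kss·Ctot)],

evaluated through the conjugate (cancellation-free) form when the linear
term is negative; free target is R = Rtot·Kss/(Kss + C). The ODE states are
total drug in the central compartment, drug in the peripheral compartment
(only free drug distributes peripherally), and total target:

    dAtot/dt = in(t) − CL·C − Q·C + (Q/V2)·Ap − kint·(Ctot − C)·V1
    dAp/dt   = Q·C − (Q/V2)·Ap
    dRtot/dt = kin − kout·Rtot − (kint − kout)·(Ctot − C)

with two hard constraints carried throughout: the drug–target complex is
cleared like free drug, kint = CL/V1 (the data cannot inform a separate
complex clearance), and target production balances its baseline turnover,
kin = BM0·kout — kin is never a free parameter. Initial condition:
Rtot(0) = BM0, no drug on board. Whether the complex also distributes
peripherally is not identifiable here; we adopt the standard QSS assumption
that it does not.

Concentrations enter the binding model in nM (bevacizumab 149 kDa, VEGF-A
45 kDa, 1:1 binding) and are reported back on the assay scales (drug mg/L,
ligand ng/L).

**PK/PD model.** An immediate-response inhibitory Imax model without
sigmoidicity and with constant baseline: E = E0·(1 − Imax·C/(IC50 + C)),
applied pointwise to the drug concentration (no effect compartment).

**Integrators.** The reference path (`qss_simulate`) uses LSODA at
rtol 1e-8/atol 1e-10 with restarts at every infusion boundary. The
estimation path integrates all subjects that share a dose/sampling time
template simultaneously with a fixed-step classical Runge–Kutta scheme whose
grid contains every infusion boundary and observation time (step ceilings:
1 day between doses, one-third of the infusion duration inside it). Because
the fast binding dynamics are handled algebraically, the remaining states
evolve on per-day time scales and the two paths agree to ~1e-5 relative —
verified in the tests. Infusion duration is not recorded in the emulated
study; the default is 90 min (0.0625 day), configurable per dose event.

## Population model

Transformed-scale linearity: φ_i = X_i b + η_i with log transforms for all
parameters except Imax (logit, keeping Imax ∈ (0,1)), η ~ N(0, Ω). The
design matrix carries one intercept per parameter plus the covariate
coefficients: continuous covariates as powers of (value/reference) — weight
centered at 70 kg per the printed equations, age at its median — and SNPs as
exp(β)^carrier with heterozygous and homozygous mutants pooled (every
printed equation uses a single carrier indicator). Ω is structured: per-
parameter variances plus the single η(CL, Q) correlation, clipped to
|ρ| ≤ 0.999 so Ω stays positive definite even when the estimate sits at the
near-singular boundary (the reference analysis reports −0.999). Random
effects are attached exactly to the parameters that carry variability in the
reference models (PK: CL, V1, Q, V2; QSS: those plus BM0; PK/PD: those plus
E0); Kss, kout, Imax and IC50 have none. Residual error is constant,
proportional or combined per observable; the reference models are
proportional (σ around 0.24–0.29).

## Estimation

**SAEM.** The E-step runs componentwise random-walk Metropolis on the
standardized effects u (η = chol(Ω)·u), two sweeps per iteration, proposal
scales adapted toward 0.4 acceptance; sampling in u-space keeps mixing
healthy under the near-singular (CL, Q) correlation. Sufficient statistics
are updated with step size 1 for K1 exploratory iterations and 1/(k−K1)
during K2 smoothing (defaults K1=300, K2=100). The M-step is exact for this
linear-Gaussian layer: GLS for b (optionally penalized by Gaussian priors on
chosen intercepts, e.g. log CL and log V1 with SD 0.3 in the binding and
PK/PD fits), a structured-covariance update for Ω, and closed-form residual
updates (the combined error model uses stochastically averaged
per-observation residuals — exact for constant/proportional, a mild
approximation for combined). During K1 a geometric annealing floor (factor
0.97) keeps ω and σ from collapsing early.

Parameters without between-subject variability are estimated with the
decreasing-variability device: an artificial ω annealed from 0.3 to a 0.05
floor across K1 turns their individual sampling into simulated annealing on
the population value. If a model declares no variability on any parameter,
the marginal likelihood degenerates and the fit switches to weighted
nonlinear least squares with reweighted residual-SD estimation.

**Multi-start averaging.** Under per-kg dosing the weight exponent nearly
cancels out of the predicted concentrations, leaving a shallow likelihood
ridge between the clearance intercept and θ_WT along which a single SAEM
trajectory random-walks slowly. `saem_fit_multistart` therefore runs several
independent chains from ±50%-perturbed initial values and averages the
transformed-scale estimates; in the replicate studies used during
development this removed most of the run-to-run scatter while leaving the
dataset-level (statistical) uncertainty, which is irreducible at the design.

**Likelihood.** −2LL by per-subject importance sampling: multivariate t(5)
proposals centered at the conditional means with 1.5× the conditional
covariances accumulated during K2; the Monte-Carlo SE of −2LL is reported
and shrinks as 1/sqrt(n_samples). AIC = −2LL + 2k, BIC = −2LL + k·ln(n
subjects).

**Standard errors.** Default: per-subject score vectors of the marginal
model linearized at the conditional means (central finite differences),
summed as an outer-product information matrix; SEs map to the natural scale
by the delta method and %RSE = 100·SE/|estimate|. A central-finite-
difference Hessian of the importance-sampling likelihood with common random
numbers is available (`method="is_fd"`) as the slower, Monte-Carlo-noisy
alternative; the linearized default keeps stepwise selection and the
acceptance runs tractable, and the two agreed within sampling noise where
compared. A rank-deficient information matrix raises an error naming the
non-identifiable parameters.

## Covariate machinery

Screening on EBEs (conditional-mean η): Pearson correlation for continuous,
one-way ANOVA for categorical covariates, candidates at p < 0.05. Stepwise
selection then refits the mixed model: forward addition admits, per round,
the candidate with the smallest Wald p among those with Wald p < 0.05 AND a
−2LL drop > 3.84 (χ²₁ at 5%); backward elimination removes any retained
effect whose removal costs < 3.84. Ties break by larger |Wald z| then
lexicographically; the trace records every decision and is reproducible
given seeds. Multiple-testing correction is deliberately not applied,
matching the reference procedure. η-η correlations are admitted only when
Pearson p < 0.05, |r| > 0.5 and %RSE < 35. Covariate-covariate independence
uses chi-square with and without Yates correction plus Fisher's exact test
(2×2).

## Diagnostics

pcVPC: quantile-based time bins (default 8, bins under 5 observations merged
and logged), prediction correction by bin-median population prediction, 90%
prediction intervals of the 5th/50th/95th percentiles from (default) 1000
replicate datasets simulated at the observed design. NPDE: per-subject
decorrelation by the Cholesky factor of the simulated covariance
(ridge-regularized and logged if singular), rank-based with an
infinitesimal seeded jitter for ties, inverse-normal mapped; the global test
Bonferroni-combines mean (t), variance (χ²) and Shapiro–Wilk components.
Both diagnostics are deterministic under a fixed seed, calibrate on
self-simulated data, and reject a two-fold clearance misspecification (shown
in the tests).

## Synthetic cohort

The generator draws weight lognormal(median 74.5 kg, log-SD 0.18 — a
compromise between the asymmetric IQR half-widths), age lognormal(median
63 y, log-SD 0.153), 61% male, mutant-carrier probabilities
rs699947 0.52, rs1570360 0.33, rs2010963 0.41, rs5498 0.70, rs1799969 0.20
(independent across SNPs, consistent with the absence of cross-SNP
association), 76% on 5 mg/kg q2w (else 7.5 mg/kg q3w), 52%
irinotecan-based co-treatment. Dose amount is per-kg dose × weight. The
study-like sampling plan draws troughs 15 min before an infusion and peaks
5 min after its end on cycles 1, 3, 6 and 9 — the true sampled cycles are
not reported, so the plan is configurable — with per-slot retention
probabilities set so a 46-subject cohort lands near the study's 156 drug and
169 ligand observations; the cycle-1 drug trough (zero concentration) is
never drawn, and the cycle-1 ligand baseline is taken at t = 0. Observations
falling below the assay quantification limits (0.033 mg/L drug, 9 ng/L
ligand) are redrawn once then dropped, preserving the no-BLQ property of the
study data. Recovery experiments use the dense variant: full trough+peak
sampling over cycles 1–6.

What the generator does **not** emulate: assay-specific error structure
beyond the fitted residual models, dropout and dose modifications,
within-subject occasion effects, linkage between SNPs, or any
outcome/survival process. Passing recovery tests therefore demonstrate that
the estimation machinery inverts the generative model at realistic designs —
not that the published estimates are correct for real patients.

## Problem sizes and numerical choices

The recovery experiments run 200 subjects (PK; five averaged chains at
K1=400/K2=300, four MH sweeps) and 100 subjects (QSS and PK/PD; three
averaged chains at K1=150/K2=50) — sizes at which each experiment completes
in minutes on a single core while the Monte-Carlo error of the recovered
quantities sits well inside the tolerances of interest. Degenerate inputs:
proposals that overflow the QSS integrator are clipped to finite state and
rejected by their likelihood; predictions are floored at 1e-12 before
entering proportional-error densities; repeated macro-constant roots (α = β)
are perturbed by one part in 1e9.

## Known limitations

* The FOCE-style linearized information matrix is an approximation; for
  weakly identified designs (few cycles, small n) its SEs can differ
  appreciably from the exact observed information — the IS-based FIM is the
  cross-check.
* Importance-sampling −2LL is biased low when the proposal is poor (e.g.
  a covariate-free model absorbing a large effect into ω); LRT drops in
  stepwise selection should be read with the Monte-Carlo SE in mind, and
  n_samples increased when decisions are borderline.
* No inter-occasion variability, no BLQ (M3) handling, no full (non-QSS)
  TMDD model, no sigmoid-Imax or effect-compartment PD — the reference
  analysis rejected or did not need these.
* The estimate of the weight exponent on CL is intrinsically fragile under
  per-kg dosing (see Multi-start averaging above); this is a property of the
  design, not of the estimator.
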