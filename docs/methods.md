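# Methods

`erfesim` implements a mechanism-based PK/PD system for erythroferrone
(ERFE), red blood cells (RBC) and hemoglobin (HGB) responses to recombinant
human erythropoietin (rHuEPO) in two anemic rat models — adenine-induced
chronic-kidney-disease anemia (CKD) and carboplatin-induced chemotherapy
anemia (CIA) — together with the statistical machinery needed to exercise it:
naive-pooled maximum-likelihood estimation, prediction-corrected VPC,
biomarker statistics (correlation, ROC/Youden), an in-silico dose-titration
trial, and a virtual-cohort generator. This note records the model algebra,
the defaults and why they were chosen, the numerical strategy, and what the
synthetic experiments do and do not demonstrate.

## Drug kinetics

rHuEPO follows a two-compartment model with parallel linear and
Michaelis-Menten elimination from the central compartment:

    dA1/dt = -kel*A1 - Vmax*C/(Km + C) - kpt*A1 + ktp*A2,   C = A1/Vc
    dA2/dt =  kpt*A1 - ktp*A2

with i.v. boluses added instantaneously to `A1`. The saturable term operates
on concentration, so `Km` (mIU/mL) is directly comparable to the
ERFE-induction `EC50`. Carboplatin follows a linear three-compartment
mammillary model eliminated from the central compartment.

The PD parameter tables this package ships do not come with companion PK
estimates, so the PK constants in `config/pk_defaults.yaml` are **synthetic
placeholders**, chosen once for pharmacological plausibility and clearly
labeled as such:

- rHuEPO (`Vc` 0.06 L/kg, `kel` 0.45 /h, `Vmax` 40 IU/kg/h, `Km` 1000
  mIU/mL, `kpt` 0.08, `ktp` 0.05): a 1350 IU/kg bolus gives C0 ≈ 2.25e4
  mIU/mL that decays through both models' EC50 ranges within 24 h, so the
  ERFE sampling schedule (0–24 h) observes the full saturable-response
  range; the nonlinear pathway contributes a noticeable but not dominant
  share of clearance.
- carboplatin (`Vc` 0.25 L/kg, `kel` 0.8 /h plus shallow peripheral
  exchange): a 60 mg/kg bolus produces a brief, intense exposure whose
  proliferation-kill integral (≈2 under the CIA model, see below) depletes
  precursors to ~15% of baseline and yields an RBC nadir around two weeks
  post-dose with recovery within a month — the qualitative clinical course
  of carboplatin myelosuppression in rats.

Every simulation and fit takes the PK config as an input
(`load_pk_config(path)`), so substituting measured PK constants requires no
code change. All PD results that depend on absolute exposure (e.g. the
recovery experiments) are internally consistent because the generator and
the estimator share the same PK.

## CKD erythroid model (lifespan/amplification with delayed outflow)

Erythroid stages BFU-E (`A_P1`), CFU-E (`A_P2`), erythroblasts (`A_P3`),
reticulocytes (`A_P4`) and circulating RBC are modeled as lifespan pools:
cells leave a precursor stage exactly one lifespan `T` after entering, and
red cells survive `T_RBC`. Amplification factors `AMPN = AMPC = 2^5` scale
the flux between stages. With the production rate

    prod(t) = K_IN0 * (RBC0/RBC(t))^gamma * (1 + K_EPO*C_EPO(t))

the system is

    dA_P1/dt = prod(t) - prod(t-T)
    dA_P2/dt = AMPN*(prod(t-T) - prod(t-2T))
    dA_P3/dt = AMPN*AMPC*(prod(t-2T) - prod(t-3T))
    dA_P4/dt = AMPN*AMPC*(prod(t-3T) - prod(t-4T))
    dA_RBC/dt = AMPN*AMPC*(prod(t-4T) - prod(t-4T-T_RBC))

`K_IN0 = RBC0/(AMPN*AMPC*T_RBC)` and the compartment initials
(`A_P1(0)=K_IN0*T`, `A_P2(0)=AMPN*K_IN0*T`,
`A_P3(0)=A_P4(0)=RET0=AMPN*AMPC*K_IN0*T`, `A_RBC(0)=RBC0`) are derived, not
free: they force exact baseline stationarity, which the tests verify to
better than 1e-6 relative over 35 days. EPO stimulation acts on production
(the P1 inflow) only; the negative RBC feedback is what ends the response
once RBC rises. HGB is algebraic throughout: `HGB = RBC*MCH/10` g/dL.

History before the first dose is the constant baseline rate `K_IN0`.

## CIA erythroid model (proliferation/transit with drug kill)

Self-renewing precursors feed three transit compartments and the circulating
pool at the shared rate `k_prol = k_circ = k_tr = (N+1)/MTT`, `N = 3`:

    dA_P1/dt = k*A_P1*(1 - K_carb*C_carb)*(1 + k_epo*C_EPO)*(RBC0/A_RBC)^gamma - k*A_P1
    dA_Pi/dt = k*(A_P(i-1) - A_Pi),  i = 2..4
    dA_RBC/dt = k*A_P4 - k*A_RBC

with all initials at `RBC0`. Design choices:

- The carboplatin effect is multiplicative inhibition `(1 - K_carb*C)` and
  is **not clamped** at zero: during peak exposure the term is strongly
  negative and represents net cytotoxic kill of the proliferating pool. The
  alternative additive-kill form `-K_carb*C*A_P1` would, under any plausible
  exposure, annihilate the pool entirely (kill integral ≈ 50) and is
  inconsistent with recovery within a month.
- The feedback exponent `gamma` drives the post-nadir rebound: with
  `gamma = 0` the model neither recovers nor overshoots (verified by test).
- `k_epo` defaults to **zero** for the CIA parameter table (no direct EPO
  term is part of those estimates); rHuEPO then affects CIA observables only
  through the ERFE pathway. The parameter exists because EPO-responsive
  virtual CIA rats are needed by the hyporesponder cohort generator (below);
  any nonzero value is an explicit override.

## ERFE subsystem

Baseline ERFE is an indirect response with cosinor forcing,

    k_CINE(t) = K_out*RM + RA*(K_out*cos(w(t-t_peak)) - w*sin(w(t-t_peak))),  w = 2*pi/24
    dA_ERFEB/dt = k_CINE(t) - K_out*A_ERFEB,

constructed so that the exact solution, initialized on-curve at
`A_ERFEB(0) = RM + RA*cos(w*(0-t_peak))`, is the cosinor with mesor `RM`,
amplitude `RA` and acrophase `t_peak` — no burn-in, and the simulated 24-h
mean and argmax reproduce the table values to the reported precision.
The circadian phase is anchored to the simulation clock (t = 0); study
designs place dosing events at multiples of 24 h so the phase relative to
dosing is the conventional one.

Induction is driven by `drive(t) = E_max * A_P3(t) * C/(EC50 + C)` through a
four-stage linear chain at rate `K_tr` (induction compartment, two transit
compartments, circulating induced pool; production into and elimination out
of the circulating induced pool are tied to `K_tr`). The induced pool is
eliminated at `K_tr`, separately from the baseline pool's `K_out`; observed
ERFE is the sum of the two circulating pools. A reduced two-stage variant
(`erfe_stages=2`) omits the transit compartments and exists for nested-model
comparison; on synthetic data it degrades the OFV far beyond the 3.84
single-parameter significance drop.

## Numerical strategy

- The CIA system is a plain ODE; the CKD system is a delay system solved by
  the **method of steps**: integration proceeds in chunks no longer than the
  shortest lag `T`, and after each chunk the production rate is appended to
  a dense history table (0.25 h sampling plus chunk endpoints) from which
  the compiled right-hand side interpolates linearly. At baseline the
  history is exactly constant, so interpolation introduces no drift.
- Integrator: `scipy.integrate.solve_ivp` LSODA with dense output,
  restarted at every dose event; default tolerances rtol 1e-8 / atol 1e-10
  (fits use 1e-6/1e-8). Halving tolerances changes observables by < 0.1%
  (self-convergence test).
- PK exposure is integrated once per schedule at rtol 1e-10 and sampled on
  a fixed 0.05 h grid consumed by linear interpolation; because generation
  and fitting share the identical exposure function, no interpolation bias
  enters the recovery experiments. Profiles are cached per
  (drug, schedule, horizon, config).
- Hot right-hand sides are numba-compiled; readable reference
  implementations live in `erythroid.py`/`erfe.py` and a regression test
  pins kernel/reference agreement at random states.
- Degenerate guards: RBC is floored at 1e-12 inside feedback powers; a
  non-positive prediction at an observation contributes a 1e6 penalty to
  the objective (with a warning) instead of crashing the optimizer.

## Estimation

Naive-pooled exact -2 log-likelihood under proportional error (sigma values
are stored on the published %CV scale and used as fractions internally).
Optimization is Nelder-Mead on log-parameters (positivity by construction;
`xatol` 1e-3 on the log scale ≈ 0.1% parameter resolution, far below the
reporting precision). Multi-start via `n_starts` (log-normal perturbations,
spread 0.15); the default is a single start from the supplied initials,
which the seeded recovery experiments show is sufficient under these study
designs — flat-objective problems should raise it. RSE% is the
delta-method value from the central-difference Hessian of OFV/2 at the
optimum. Adding a free parameter never raises the minimized OFV (guarded by
returning the initial point when an optimizer run ends worse).

The pcVPC bins by nominal scheduled time per analyte, corrects each
observation by `median(PRED_bin)/PRED_ij`, and compares observed bin medians
with the simulated 95% interval of the bin median (default 200 replicates).
On self-generated data ≥ 90% of bins are covered.

## Synthetic cohorts and study designs

`make_cohort` perturbs parameters log-normally (log-SD `sqrt(ln(1+CV^2))`);
CV = 0 reproduces the population values exactly. `make_dataset` simulates
each subject under a named design and adds independent proportional error;
negative draws are truncated at zero and flagged, never resampled.

The two fitted designs mirror the studies the parameter tables describe:
CKD — saline n=5 / 450 n=6 / 1350 IU/kg n=6, t.i.w. for two weeks, ERFE at
0,1,2,4,6,8,10,12,24 h after the first dose, hematology on days
0,4,10,15,20,25,30,34; CIA — three arms n=9, carboplatin 60 mg/kg one week
before a single rHuEPO dose, same ERFE offsets, hematology days -8..24
around the rHuEPO dose. The CIA clock starts at the earliest scheduled
sample (day -8) so all event times are nonnegative; every offset is a
multiple of 24 h, leaving the circadian phase relative to dosing unchanged.
The t.i.w. pattern is realized as injections at 0/48/96 h within each week
(Mon/Wed/Fri) and is configurable.

The **hyporesponder cohort** spans a severity axis s in [0,1] that jointly
scales the carboplatin kill (0.05+0.95s of the table value), ERFE potency
(EC50 times 0.5+4.5s), the inducible erythroblast mass (P3 scaling
2.0-1.8s) and a direct EPO proliferation effect (1.2e-3*(1-s)); the
generative label is s >= 0.5. The direct EPO effect is required for any CIA
subject to gain 1 g/dL HGB within a week (the transit delay otherwise
decouples one-week HGB from EPO entirely); its magnitude was chosen by
forward simulation so that a benign subject gains ~2-6 g/dL by day 6 and
the measured-phenotype boundary (HGB gain crossing 1 g/dL) falls at
severity ≈ 0.4-0.5, aligned with the generative label.

What these cohorts do **not** emulate: real between-animal variability in
disease induction, rotation blood-sampling designs, assay drift or
autocorrelated residuals. Passing tests therefore demonstrate internal
consistency of the estimator/biomarker pipeline under the model's own
assumptions, not reproduction of the animal data; the published
animal-level correlations, AUCs, the 1.85 ng/mL cutoff and the 12%
dose-sparing figure are covered only as direction/shape assertions.

## Recovery experiments (problem sizes)

`experiments.cia_parameter_recovery` regenerates the full CIA design
(27 subjects, 1161 observations) per seed and refits EC50, K_carb and MTT
from initials perturbed by U(0.7, 1.3); `ckd_parameter_recovery` does the
same on the CKD design (17 subjects, 425 observations) for EC50 alone —
the remaining CKD structural parameters are steady-state-tied, and the
published EC50 RSE of ~70% already marks that axis as the weakly identified
one. Five replicate seeds per experiment and median reporting are the
default; with identical-subject cohorts (IIV = 0, as the estimates assume)
arm-level prediction sharing makes each fit take tens of seconds.

## Titration trial

Decision epochs follow the study protocol: the trigger after the 1st
injection sets the week-2 dose and the trigger after the 4th sets week 3.
The HGB trigger uses the 5-day window starting at the corresponding week's
first injection; the ERFE trigger is the 4-h change from the pre-injection
baseline, measured with the subject's own assay error (seeded). A trigger
exactly at threshold takes the reduction branch (documented boundary
convention). Consumption is reported as a percentage of the initiating
regimen (nine 100 IU/kg injections). With measurement noise off, trials are
bit-reproducible.

## Known limitations

- PK constants are placeholders; absolute exposure-dependent quantities
  (e.g. HGB gain per dose) are internally consistent but not calibrated to
  measured rat PK.
- The CKD model applies EPO stimulation at production only, not per stage;
  the CIA table carries no direct EPO term, so CIA hematology is
  EPO-insensitive unless `k_epo` is overridden.
- No iron/hepcidin axis, no spleen/marrow split, no subcutaneous dosing,
  no covariate or mixed-effects modeling.
- The Youden cutoff is reported without a confidence interval.
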