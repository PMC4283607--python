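# Methods

## Model structure

The system couples three one-way-linked components: a lumped-tissue
FcRn PBPK model for drug and endogenous IgG, a Michaelis–Menten TMDD
component for the drug–target interaction, and a disease-progression
model driven by target engagement. State variables are concentrations
in µM (time in hours, volumes in litres); two ledger states accumulate
eliminated drug so that mass balance is checkable at every output point.

### FcRn PBPK

For each IgG species x ∈ {drug, endogenous}, with plasma, endosomal and
interstitial concentrations C_p, C_e (total), C_i:

    V_p dC_p/dt = In(t) − L(1−σ_v)·C_p − K_up·V_e·(δ/(1+δ))·C_p
                  + FR·K_rc·V_e·C_e,bound + L(1−σ_i)·C_i  [− TMDD, drug only]
    V_e dC_e/dt = K_up·V_e·[(δ/(1+δ))·C_p + (1/(1+δ))·C_i]
                  − CL_cat·C_e,free − K_rc·V_e·C_e,bound
    V_i dC_i/dt = L(1−σ_v)·C_p − L(1−σ_i)·C_i − K_up·V_e·(1/(1+δ))·C_i
                  + (1−FR)·K_rc·V_e·C_e,bound

Endosomal binding is treated as rapid equilibrium (only dissociation
constants are known; no kinetic on/off rates): the free receptor
concentration F solves F + Σ_x Ct_x·F/(K_D,x + F) = FcRn_total, a
quadratic in the equal-K_D case and a cubic otherwise, solved in closed
form and Newton-polished so receptor and ligand conservation hold to
~1e-15 relative. Endogenous IgG enters plasma by a zero-order synthesis
rate solved at start-up so that the drug-free system is exactly at
steady state at the nominal plasma IgG level (67 µM ≈ 10 g/L); a
1000-hour drug-free simulation drifts by < 0.1% (measured ~1e-11).

TMDD applies to the drug only (the target does not bind endogenous
IgG). Elimination is k_int·R_T·C/(K_m+C) in the target compartment
(plasma by default — CD11a rides on circulating T cells; interstitial
placement is configurable), and the total target turns over as
k_syn − k_deg·R_T − (k_int−k_deg)·R_T·C/(K_m+C), with k_syn = R_max·k_deg
derived at construction so the drug-free baseline is a fixed point.
The free/bound split within the total pool is the quasi-steady-state
partition R_bound = R_T·C/(K_m+C).

### Disease progression

The score tracks an attractor interpolated between baseline and treated
asymptote by the drive E: dY/dt = (ln2/T_p)(Y_0 − (Y_0−Y_ss)E − Y).
This embedding was chosen because it reduces exactly to the printed
asymptotic decay curve under constant full drive, and to "no change"
with no drug. Two drive mappings are implemented because the coupling
to "bound CD11a" admits two readings: `free_suppression`
(E = 1 − R_free/R_max, the default) and `bound_fraction` (E = R_bound/R_T).
The default was chosen because under MM-TMDD the bound complex can
never approach R_max (the saturated total pool is only k_deg/k_int of
baseline), so a literal bound-concentration drive could never pull the
score to its observed asymptote; the literal reading remains available
by configuration. Similarly, the reported "% of baseline" target series
defaults to the total pool (the free fraction saturates near zero,
while the total-pool plateau of 18.5% sits just below the ~25% clinical
downregulation level); free-pool reporting is also provided.

## Parameters and defaults

Drug/target/disease constants are the published efalizumab set: MW
148 841 g/mol, K_D 2.96423 µM, CL_iv 0.0227 L/h, K_m 0.000573 µM
(a concentration, despite being labelled a rate constant in the
source table), k_int 0.1 h⁻¹ (units printed as L/h, interpreted as a
first-order rate), k_deg 0.0185 h⁻¹, R_max 0.01 µM, Y_0 24.8,
Y_ss 14.8, T_p 397 h.

Physiological defaults describe a 70-kg reference subject: V_p 2.6 L,
V_e 0.1 L, V_i 6.3 L, L 0.12 L/h, σ_v 0.95, σ_i 0.2, δ 1 (symmetric
uptake), FR 0.715, K_rc 1.0 h⁻¹, FcRn_total 45 µM. Two defaults
deserve explanation:

- **K_up = 1.0 h⁻¹.** The pinocytotic uptake clearance K_up·V_e is an
  absolute ceiling on achievable catabolic clearance (nothing can be
  degraded faster than it is internalized). The ceiling must comfortably
  exceed the 0.0227 L/h calibration anchor; K_up·V_e = 0.1 L/h does,
  while remaining within literature endosomal-turnover rates.
- **K_D,en = 0.5 µM.** Efalizumab's FcRn affinity was regression-derived
  from its (short) half-life, i.e. it binds FcRn more weakly than bulk
  endogenous IgG. Giving endogenous IgG a typical pH-6 affinity of
  0.5 µM reproduces, with one shared physiology, both the drug's linear
  clearance (0.0227 L/h, t½ ≈ 4.4 d without TMDD) and a normal
  endogenous-IgG phenotype (CL ≈ 0.006 L/h ≈ 2 mL/day/kg, terminal
  t½ ≈ 17 d, inside the physiological 14–28 d window). Setting
  K_D,en = K_D,ex is possible by configuration but then the endogenous
  pool inherits the drug's fast kinetics.

CL_cat is not directly observable; `calibrate_clcat` bisects it (in
log space) until a simulated 1 mg/kg no-TMDD infusion reproduces CL_iv
by NCA within 0.2%. The shipped default (0.254257 L/h) is the
calibrated value for the default physiology; recalibrate after changing
any physiological constant. Calibration reports the achievable
clearance range when the anchor is unreachable.

## Numerics

- Stiff integration (LSODA; BDF/Radau selectable) with rtol 1e-8,
  atol 1e-12 µM. Dose starts, infusion stops and sc-depot loads are
  integration breakpoints; instantaneous inputs apply at the start of
  the segment they open, so output points at a dose time show the
  post-dose state.
- Mass balance |administered − (in-system + eliminated)|/administered is
  reported per output point; simulations hold it near 1e-13, far inside
  the 1e-3 documented guarantee.
- NCA: trapezoidal AUC plus C_last/λ_z tail, λ_z from a log-linear fit
  to the last 10 points above 1e-6·C_max (points below that sit at the
  solver noise floor and would corrupt the fit).
- The FcRn equilibrium enforces conservation to ≤ 1e-10 relative
  (measured ~1e-15); negative inputs and NaNs raise immediately.
- T_p fitting exploits the one-way coupling: the PK/target system does
  not depend on T_p, so the drive E(t) is simulated once and only the
  scalar PASI ODE is re-integrated per candidate (Brent bounded
  minimization, default bounds 24–5000 h). This is exactly equivalent
  to re-simulating the full system per candidate. The objective is
  unweighted least squares by default (weights optional; the fit is
  invariant to uniform weight rescaling). Standard errors come from
  the numerical curvature of the SSE surface; estimates within 0.1% of
  a search bound are flagged as boundary solutions rather than
  converged.

## Virtual population

Inter-individual variability is modelled as independent mean-1
lognormal multipliers (σ² = ln(1+CV²)) on: clearance (CV 30%, applied
to CL_cat), target degradation rate (CV 10%, with k_syn rescaled so
baseline R_max is preserved), baseline PASI (CV 10.8%) and the PASI
asymptote (CV 22%) — the published variability set. Age (uniform on
the design range) and sex are sampled covariates but do not modify
parameters: no covariate model is published, and the full
population-physiology machinery behind the original simulator is out
of scope here. Body weight is fixed at 70 kg unless a weight CV is
requested (lognormal, typically 15%). Each subject owns a spawned
random substream and draws parameters in declared order, so identical
seeds are bit-reproducible and adding a variability spec never
perturbs earlier draws. Percentile envelopes (5/50/95) are pooled
across trials; failing subjects are excluded and counted, never fatal.

## Synthetic data

The generator emulates the study shapes: named regimens (single 1, 3,
10 mg/kg; 0.3/0.4/0.6 then 1 mg/kg weekly ×4; flat weekly 1 mg/kg —
all 1-h IV infusions), weekly PASI sampling, and dense post-dose PK
grids. Observation noise defaults to proportional lognormal with CV 5%
(no residual-error model is published); additive and combined models
are available, with truncation at zero reported. It emulates *mean*
series with homoscedastic proportional noise only — no assay
LLOQ/BQL handling, no dropout, no placebo response, no immunogenicity —
so passing recovery tests demonstrates estimator correctness under the
stated error model, not robustness to real clinical data pathologies.
The recovery study design used in tests and in the acceptance script is
weekly PASI over the 8-week treatment phase of the escalating regimen,
5% noise, 20 replicate series.

## Problem sizes

Reference runs use: 6000 h horizons at 4 h output steps for single-dose
NCA; 20 weeks of weekly dosing for the plateau check; 8-week horizons
at 1 h steps for PD; 20 replicate refits for the recovery study; 500
subjects for the baseline-sampling check and 2×25 subjects for the
population coverage test. These sizes keep every quantity's Monte-Carlo
or discretization error well inside the tolerances quoted for it.

## Known limitations

- Single lumped tissue: no organ-level plasma flows, no two-pore
  size-dependent extravasation, no pH-dependent FcRn affinity cycling.
- The MM reduction of TMDD is accurate only while free drug exceeds the
  total-target scale; in the deep terminal phase (C < R_T) it
  underpredicts plasma drug relative to the full kinetic scheme (the
  full scheme lives in the test suite as an oracle, not as a production
  mode).
- The disease model is symptomatic-only: the drive modulates the
  attractor, never T_p; no placebo response, no rebound dynamics beyond
  the same first-order relaxation, and PASI is treated as continuous.
- Subcutaneous dosing is a single first-order depot (ka, F) without
  absorption-site mechanism; all sc doses in one regimen share ka.
- No anti-drug-antibody effects, target shedding or soluble-target
  sinks.
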