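# mabsim

A mechanistic PK/PD simulation library for monoclonal antibodies, built
around three linked models:

1. **A lumped-tissue FcRn PBPK model.** Exogenous mAb and endogenous IgG
   distribute over plasma, endosomal and interstitial spaces of a single
   lumped tissue. Extravasation is convective through vascular pores
   (reflection coefficient σ_v) with lymphatic return (σ_i, lymph flow
   L). Endothelial pinocytosis (rate K_up, luminal/abluminal split δ)
   delivers both species to the acidified endosome where they compete
   for FcRn at rapid equilibrium (dissociation constants K_D). Bound IgG
   is recycled at rate K_rc — a fraction FR to plasma, the rest
   transcytosed — while unbound IgG is catabolized with intrinsic
   clearance CL_cat. This is the mechanism that gives IgG its long
   half-life and ties mAb clearance to FcRn affinity and abundance.
2. **Michaelis–Menten target-mediated drug disposition (TMDD).** The
   drug is additionally eliminated through its pharmacological target:
   elimination rate k_int·R_T·C/(K_m + C), with target turnover
   dR_T/dt = k_syn − k_deg·R_T − (k_int − k_deg)·R_T·C/(K_m + C).
   Under saturating drug the total target settles at k_syn/k_int, i.e.
   100·k_deg/k_int percent of baseline.
3. **An asymptotic disease-progression model.** A clinical severity
   score Y (PASI for psoriasis) follows
   dY/dt = (ln 2/T_p)·(Y_0 − (Y_0 − Y_ss)·E − Y), where the drive
   E ∈ [0, 1] measures target engagement. Under constant full drive this
   is exactly Y(t) = Y_ss + (Y_0 − Y_ss)·2^(−t/T_p); with no drug the
   score stays at baseline. T_p is the half-life of progression.

The shipped parameterization is **efalizumab**, an anti-CD11a IgG1
formerly used in plaque psoriasis (MW 148 841 g/mol, K_D 2.96 µM,
CL_iv 0.0227 L/h, K_m 0.000573 µM, k_int 0.1 h⁻¹, k_deg 0.0185 h⁻¹,
R_max 0.01 µM, Y_0 24.8, Y_ss 14.8, T_p 397 h). On top of the
simulation core the package provides virtual-population trials with
lognormal inter-individual variability and percentile envelopes,
bounded least-squares estimation of T_p from PASI series, a
synthetic-data generator, YAML/CSV I/O and a thin CLI (`mabsim`).

Intended users: pharmacometricians and model-informed drug-development
scientists who want a transparent, fully scriptable desk-scale
implementation of the FcRn/TMDD/disease-progression modelling chain.

## Worked example

```python
import mabsim as ms

phys, drug = ms.PhysiologyParameters(), ms.DrugParameters()
tmdd, disease = ms.TMDDParameters(), ms.DiseaseParameters()

doses = ms.make_regimen("single_1")            # 1 mg/kg, 1-h IV infusion
amount = doses[0].amount_umol(70.0, drug.mw)   # 0.4703 µmol

for label, t in (("with TMDD", tmdd), ("without TMDD", None)):
    res = ms.simulate(phys, drug, t, None, doses, 6000.0, output_step=4.0)
    nca = ms.nca_clearance(res, amount)
    print(label, round(nca["cl_ml_per_day_per_kg"], 2), "mL/day/kg")
```

prints

```
with TMDD 11.87 mL/day/kg
without TMDD 7.78 mL/day/kg
```

The no-TMDD value is the calibrated linear clearance (0.0227 L/h at
70 kg); the with-TMDD value is larger because the drug is also removed
by internalization of the drug–CD11a complex. Repeating at 3 and
10 mg/kg gives 9.37 and 8.41 mL/day/kg — clearance falls with dose as
the target saturates, the characteristic TMDD signature. The scripts in
`examples/` walk through each capability (single-dose PK, the
escalating-dose PASI response, population percentile envelopes, T_p
fitting, clearance calibration) and print the numbers they compute.

## Layout

- `src/mabsim/` — the library: `fcrn` (competitive receptor
  equilibrium), `pbpk` (ODE system, simulation driver, NCA,
  calibration), `tmdd`, `disease`, `population`, `estimation`,
  `synthetic`, `io`, `cli`, `units`, `parameters`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — model equations, assumptions, defaults and their
  rationale, numerical choices and known limitations.
- `tests/` — pytest suite, including independent oracles (brute-force
  binding equilibrium, matrix-exponential linear limit, full kinetic
  TMDD).
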