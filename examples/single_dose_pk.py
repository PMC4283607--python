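"""Single-dose PK of efalizumab with and without target-mediated clearance.

Simulates a 1 mg/kg 1-h IV infusion in the 70-kg reference subject and
reports non-compartmental clearance for the full model and for the same
model with the CD11a pathway switched off.  The gap between the two
clearances is the target-mediated (saturable) contribution, which is why
low mAb doses clear faster per kilogram than high ones.
"""

import mabsim as ms

phys = ms.PhysiologyParameters()
drug = ms.DrugParameters()
tmdd = ms.TMDDParameters()

doses = ms.make_regimen("single_1")
amount = doses[0].amount_umol(ms.REFERENCE_WEIGHT_KG, drug.mw)
print(f"administered amount: {amount:.4f} umol "
      f"({doses[0].dose} mg/kg x 70 kg / {drug.mw:.0f} g/mol)")

for label, t in (("with TMDD", tmdd), ("without TMDD", None)):
    res = ms.simulate(phys, drug, t, None, doses, 6000.0, output_step=4.0)
    nca = ms.nca_clearance(res, amount)
    print(f"{label:13s} CL = {nca['cl_ml_per_day_per_kg']:6.2f} mL/day/kg "
          f"({nca['cl_L_per_h']:.4f} L/h), "
          f"terminal t1/2 = {nca['terminal_half_life_h'] / 24:.1f} d, "
          f"Cmax = {res.cp_ex_ug_per_ml.max():.1f} ug/mL")

print("The with-TMDD clearance exceeds the linear clearance because the\n"
      "drug is also eliminated by internalization of the drug-CD11a\n"
      "complex; the linear value matches the 0.0227 L/h calibration anchor.")
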