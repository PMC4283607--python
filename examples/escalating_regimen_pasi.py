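"""Escalating weekly dosing: CD11a suppression and PASI response.

Reproduces the escalating-dose study arm (0.3/0.4/0.6 mg/kg in weeks
1-3, then 1 mg/kg weekly for four more weeks) and prints the weekly
total-CD11a level (% of baseline), the engagement drive and the PASI
score.  PASI relaxes from its baseline 24.8 toward the treated
asymptote 14.8 with the fitted progression half-life of 397 h.
"""

import numpy as np

import mabsim as ms

phys, drug = ms.PhysiologyParameters(), ms.DrugParameters()
tmdd, disease = ms.TMDDParameters(), ms.DiseaseParameters()

doses = ms.make_regimen("gottlieb_escalating")
weeks = 8
res = ms.simulate(phys, drug, tmdd, disease, doses, weeks * 168.0,
                  output_step=1.0)

times = ms.weekly_sample_times(weeks)
cd11a = np.interp(times, res.time_h, res.rtot_pct_baseline)
drive = np.interp(times, res.time_h, res.occupancy_drive)
pasi = np.interp(times, res.time_h, res.pasi)

print("week  CD11a(%baseline)  drive E   PASI")
for w, c, e, y in zip(times / 168.0, cd11a, drive, pasi):
    print(f"{w:4.0f}  {c:16.1f}  {e:7.3f}  {y:5.2f}")

print(f"\nmass-balance residual (max): {res.massbal_residual.max():.2e}")
print("Sustained dosing drives total CD11a toward the saturating plateau\n"
      f"of {ms.saturating_plateau_percent(tmdd):.1f}% of baseline "
      "(= 100*kdeg/kint), below the ~25% reported clinically,\n"
      "while the near-unity drive pulls PASI toward its treated asymptote.")
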