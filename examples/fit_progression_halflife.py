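"""Recover the progression half-life Tp from noisy synthetic PASI data.

Generates weekly PASI observations under the escalating regimen with 5%
proportional noise, then refits Tp by bounded least squares.  Because
PK and target engagement do not depend on Tp, the drive profile is
simulated once and only the scalar PASI ODE is re-integrated per
candidate, making the fit essentially instant.
"""

import numpy as np

import mabsim as ms

phys, drug = ms.PhysiologyParameters(), ms.DrugParameters()
tmdd, disease = ms.TMDDParameters(), ms.DiseaseParameters()

doses = ms.make_regimen("gottlieb_escalating")
truth = ms.simulate(phys, drug, tmdd, disease, doses, 8 * 168.0,
                    output_step=1.0)
drive = ms.DriveProfile(truth.time_h, truth.occupancy_drive)
times = ms.weekly_sample_times(8)

noise = ms.NoiseModel(kind="proportional", cv=0.05, seed=42)
observed = ms.generate_observations(truth, times, noise)[0]
print("observed weekly PASI:", np.round(observed.values, 2))

fit = ms.fit_tp(observed, drive, disease)
print(f"Tp estimate: {fit.estimate:.1f} h (SE {fit.std_error:.1f} h), "
      f"objective {fit.objective:.3f}, converged={fit.converged}")
print(f"generating value was {disease.tp_h} h; a single 5%-noise series\n"
      "identifies Tp to roughly +-10%, and averaging the estimates from\n"
      "replicate series tightens the recovery to a few percent.")
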