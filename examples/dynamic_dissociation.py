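"""Agonist-induced dimer dissociation and re-association over time.

Programs a transient 50% loss of the dual-labeled (dimer) pool — minimum
5 min after stimulation, recovery by 20 min — simulates repeated 10 s FCCS
measurements along the time course, and recovers the dip from the ratio of
cross- to green-autocorrelation amplitudes.
"""

import numpy as np

import dimerscope as ds
from dimerscope.dimer_stats import normalize_dynamic_series

geom = ds.DetectionGeometry(omega_g=0.222, omega_r=0.272, r0=0.125)
model = ds.SpeciesModel(c_g=10.0, c_r=10.0, c_gr=40.0, d_g=0.41, d_r=0.41,
                        d_gr=0.235)
schedule = ds.DissociationSchedule(t_stim=0.0, f_min=0.5, t_min=300.0,
                                   t_recover=1200.0)
time_points = [-60.0, 120.0, 300.0, 480.0, 720.0, 960.0, 1200.0]

measurements = ds.simulate_dynamic_experiment(
    model, geom, schedule, time_points, segment_length=10.0,
    n_segments_per_point=3, dt=1e-3, box_size=2.5, seed=3)
series = ds.analyze_dynamic_experiment(measurements)
norm = normalize_dynamic_series(series)  # 1.0 at the pre-stimulation point

print("time (min)  programmed c_gr   N_gr/N_r (normalized)")
for m, value in zip(measurements, norm.bound_fraction):
    print(f"{m.time_s/60.0:8.0f}    {m.c_gr_fraction:12.2f}   {value:10.2f}")
print("The normalized bound fraction dips toward the programmed minimum "
      "(0.5 at 5 min) and returns to baseline — dissociation followed by "
      "re-association, with total green and red label conserved "
      "throughout.")
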