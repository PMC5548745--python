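"""Two-step FCCS analysis of a simulated dimerizing membrane receptor.

Simulates a batch of ten control cells (two non-interacting constructs,
used to calibrate the spectral crosstalk K as the batch median — the
per-cell estimate is noise-limited, which is why the calibration uses a
batch) and three measurement cells in which all receptors are dimers
assembled binomially from green- and red-tagged protomers, then runs the
two-step global fit and the random-pairing dimer statistics.

Runs in a few minutes on one CPU.
"""

import numpy as np

import dimerscope as ds
from dimerscope.fccs_fit import median_k
from dimerscope.dimer_stats import dimer_estimate, model_agreement_rms

geom = ds.DetectionGeometry(omega_g=0.222, omega_r=0.272, r0=0.125)
PAIRS = ("GG", "RR", "GR")


def curves_for(model, seed, duration=60.0):
    trace = ds.simulate_membrane_traces(model, geom, duration, dt=5e-4,
                                        box_size=3.0, seed=seed)
    report = ds.screen_segments(trace, segment_length=10.0)
    return {p: ds.correlate_segments(trace, p, 10.0, report, max_lag=1.0)
            for p in PAIRS}


# --- step 1: crosstalk calibration on control cells -----------------------
print("control cells (c_g=80, c_r=60 µm⁻², no dimers, true K=0.05):")
control = ds.SpeciesModel(c_g=80.0, c_r=60.0, d_g=0.41, d_r=0.41,
                          k_crosstalk=0.05)
ctrl_fits = []
rng = np.random.default_rng(0)
for i in range(10):
    seed = int(rng.integers(0, 2**31 - 1))
    fit = ds.fit_control(curves_for(control, seed), geom,
                         x_choices=[(1, 1)],
                         check_misspecification=False)[0]
    ctrl_fits.append(fit)
    print(f"  cell {i}: K = {fit.k_crosstalk:.3f}")
k_med = median_k(ctrl_fits)[(1, 1)]
print(f"  median K = {k_med:.3f}  (fixed in all dimerization fits)")

# --- step 2: dimerization fits with K fixed -------------------------------
print("measurement cells (binomial all-dimer: c_gg=12.5, c_gr=25, "
      "c_rr=12.5 µm⁻²):")
dimers = ds.SpeciesModel(c_g=12.5, c_r=12.5, c_gr=25.0, d_g=0.235,
                         d_r=0.235, d_gr=0.235, x_g=2, x_r=2,
                         k_crosstalk=0.05)
counts = []
for seed in (11, 12, 13):
    fit = ds.fit_dimerization(curves_for(dimers, seed), geom, k_fixed=k_med,
                              x=2)
    s = fit.species
    counts.append(ds.PairingCount(s.c_g, s.c_gr, s.c_r))
    est = dimer_estimate(counts[-1])
    print(f"  cell seed {seed}: gg={s.c_g:5.1f} gr={s.c_gr:5.1f} "
          f"rr={s.c_r:5.1f} µm⁻²  mixed fraction={fit.dimer_fraction():.2f} "
          f"(truth 0.50)  c_gr/c'_gr={est.ratio:.2f}")

rms = model_agreement_rms(counts, "all-dimer")
print(f"RMS deviation from the all-dimer (random-pairing) model: {rms:.3f}")
print("A small RMS and per-cell ratios near 1 mean the measured mixed-dimer "
      "concentrations match a fully dimerized receptor population.")
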