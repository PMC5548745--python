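# Methods

`dimerscope` quantifies homodimerization of a membrane receptor carried by
two spectrally separated fluorescent tags (a "green" GFP-like and a "red"
mCherry-like label) from two complementary live-cell readouts: two-color
fluorescence (cross-)correlation spectroscopy of photon-count fluctuation
traces, and dual-color FRAP of bleach-ROI intensity time series. A
Brownian-dynamics generator produces synthetic data with exactly the
statistical structure the analyses assume, so every estimator in the
package can be validated against known ground truth.

## The correlation model

Three diffusing species live on a 2D membrane: green-only units at surface
concentration c_g, red-only units at c_r, and dual-labeled complexes
(dimers carrying one label of each color) at c_gr, with diffusion
coefficients D_g, D_r, D_gr (µm²/s). They are observed through two
Gaussian detection areas with 1/e² radii ω_G and ω_R whose centers are
laterally displaced by r₀. The effective areas are A_G = πω_G²,
A_R = πω_R², and A_GR = π(ω_G² + ω_R²)/2 for the cross-correlation.

The model curves (implemented in `fccs_fit.model_correlations`) are

    G_G(τ)−1  = A_G (x_g² c_g Diff_g^G + c_gr Diff_gr^G)
                / (A_G (x_g c_g + c_gr) + BG_G)²
    G_R(τ)−1  = [A_R (x_r² c_r Diff_r^R + c_gr Diff_gr^R)
                 + 2 (A_G A_R/A_GR) K c_gr Displ·Diff_gr^GR
                 + A_G K² (x_g² c_g Diff_g^G + c_gr Diff_gr^G)]
                / (A_R (x_r c_r + c_gr) + A_G K (x_g c_g + c_gr) + BG_R)²
    G_GR(τ)−1 = [(A_G A_R/A_GR) c_gr Displ·Diff_gr^GR
                 + A_G K (x_g² c_g Diff_g^G + c_gr Diff_gr^G)]
                / [(A_G (x_g c_g + c_gr) + BG_G)
                   · (A_R (x_r c_r + c_gr) + A_G K (x_g c_g + c_gr) + BG_R)]

with the 2D diffusion factors Diff_u^X(τ) = (1 + 4 D_u τ/ω_X²)⁻¹ (the
cross term uses the mean square radius (ω_G²+ω_R²)/2) and the displacement
function Displ(τ) = exp(−2r₀²/(ω_G² + ω_R² + 8 D_gr τ)), which accounts
for the imperfect overlap of the two laser foci: at τ = 0 the co-diffusing
signal is attenuated by exp(−2r₀²/(ω_G²+ω_R²)), and diffusion during the
lag progressively bridges the displacement, so Displ is non-decreasing
in τ.

Model conventions worth spelling out:

- **x_g, x_r ∈ {1, 2}** are absorption cross-section ratios of the
  single-color species relative to the dual-labeled complex. x = 2
  describes a homodimer carrying two identical labels (twice the
  brightness, quadruple the fluctuation weight); x = 1 a monomeric label.
- **K** is the spectral crosstalk parameter: the fraction of green-label
  emission detected in the red channel. Crosstalk creates a spurious
  cross-correlation with the *shape of the green autocorrelation*, which is
  how the global fit separates it from genuine co-diffusion.
- **BG_G, BG_R** enter the model in area×concentration units. All
  brightness factors q cancel in G(τ); a background *count rate* R maps to
  the model parameter as BG = 2R/q, where q is the per-label peak
  brightness. Backgrounds suppress amplitudes quadratically but add no
  correlated signal.
- The red-channel denominator is the squared total red intensity
  (signal + crosstalk + background). The factor-2 cross term in the G_R
  numerator is the middle term of the expansion of (S_r + K·S_g)², which
  fixes the denominator's exponent unambiguously.

Useful limits, all enforced by tests: with c_gr = 0, K = 0 and no
background the model collapses to two independent one-species 2D curves
with amplitude 1/(A·c) and transit time τ_D = ω²/(4D), and G_GR ≡ 0;
Diff = 1/2 exactly at τ = τ_D; Displ ≡ 1 for r₀ = 0.

## Correlation estimation

`correlate` implements a multiple-tau estimator: m = 16 lags per octave;
at each coarser level the trace is binned by 2 (averaging, so values are
scale-free) and lags m/2+1 … m of that level are evaluated. Every lag uses
symmetric normalization — ⟨F(t)F(t+τ)⟩ over the overlap window divided by
the product of the two overlap-window means — which makes each reported
value *identical* to the direct O(n²) estimate on the (binned) trace; the
test suite verifies this equality to 1e−12 against an independent
brute-force implementation. The zero-lag bin is excluded everywhere (shot
noise); amplitudes are always obtained by model fits, never by reading the
first lag.

Acquisition screening (`screen_segments`) divides a trace into 10 s
segments and discards segments with (i) a count spike above
mean + 10 sd (bright aggregates; the threshold is high because a single
receptor crossing the focus center legitimately produces ~7 sd
excursions at these particle numbers), (ii) a fitted linear intensity
loss exceeding 100% of the segment mean per segment length (gross focal
drift or whole-ROI decay; focal-intensity fluctuation alone produces
relative slopes of ±0.3–0.5 at ~10 molecules in the focus, so only
gross decays are flagged), or (iii) variance-based molecular brightness
(var−mean)/(mean·dt) at or below 0.2 kHz per molecule. Kept segments are
correlated individually and averaged; the lag-wise standard deviation
across ≥3 segments provides fit weights (uniform weights otherwise).

## Two-step global fitting

Following the calibration-first design, fitting proceeds in two steps, in
both of which ω_G and ω_R are fixed to their solution-calibration values
(0.222 and 0.272 µm here):

1. **Controls** (cells co-expressing two *non-interacting* constructs,
   c_gr ≡ 0): global least squares of the three curves with c_g, c_r,
   D_g, D_r and K free, one fit per x_g/x_r combination. With c_gr pinned
   at zero, r₀ and D_gr do not appear in any surviving model term and are
   held fixed rather than left as free, gradient-less parameters. The
   per-cell K estimate is noise-limited by the sampling covariance of the
   cross-correlation (sd ≈ 0.03–0.05 per 60 s cell at the default
   concentrations), so the calibration constant is the **median K across
   the control batch**. An optional likelihood-ratio diagnostic refits
   each control with c_gr free and flags `control_misspecified` when
   freeing it removes >30% of the residual sum of squares while assigning
   >5% of the population to the dual-labeled species.
2. **Dimerization measurements**: K fixed to the control median, r₀
   restricted to the 100–150 nm calibration band, c_g, c_r, c_gr and all
   D free; x_g = x_r set to 1 (monomeric single-color species) or 2
   (homodimeric). The optimizer is scipy's trust-region reflective least
   squares (via lmfit) with five deterministic multi-starts spanning
   concentration scale, diffusion scale and initial dimer fraction —
   amplitude/width-based starting values plus perturbations — because the
   model's parameters (notably c_gr vs r₀, and K vs c_r) are correlated
   and single starts occasionally land in a c_gr = 0 basin. The three
   curves enter the objective with equal weight.

R² is computed per curve as 1 − SS_res/SS_tot on the G(τ)−1 values.
Derived per-fit quantities: τ_D = ω²/(4D) per species and channel,
particle numbers N = A·c, and counts per molecule
CPM = (mean rate − background) × (fitted amplitude) in kHz.

**Quality control** (`apply_qc`): a measurement enters downstream
statistics only if total screened time ∈ [20, 80] s, single-species
transit times ∈ [1, 150] ms, R² ∈ [0.9, 1], CPM ∈ [0.2, 2.5] kHz/molecule
and the green/red brightness ratio ∈ [0.5, 2.5]. The transit-time and R²
checks are evaluated on one-component fits of the autocorrelation curves
(the same single-species normal-diffusion screen the thresholds were
defined for); every failure carries a machine-readable reason code.

## Dimer combinatorics

If M green and N red protomers pair at random into (M+N)/2 dimers, the
probability that a given dimer is mixed is exactly
2MN/((M+N)(M+N−1)) — verified in the package by exhaustive enumeration of
all perfect pairings up to 12 molecules — and approximately
2MN/(M+N)² = (2c_gg+c_gr)(2c_rr+c_gr)/(2(c_gg+c_gr+c_rr)²) in
concentration variables, with an error of at most 1/(M+N). The expected
mixed-dimer concentration under random pairing is
c′_gr = (2c_gg+c_gr)(2c_rr+c_gr)/(2(c_gg+c_gr+c_rr)), and the ratio
c_gr/c′_gr equals 1 identically for any binomially assembled population —
the fixed point that defines "all receptors are dimers". The
"percentage of dimerization" reported by the pipeline is 100·c_gr/c′_gr.
`model_agreement_rms` summarizes a batch of cells as the RMS difference
between measured mixed-dimer fractions and a model prediction: p_gr for
the all-dimer model, 0 for the zero-dimer model.

## Dynamic dissociation analysis

Stimulation time courses are analyzed per time point from 3–6 segments of
10 s: the fraction of red diffusing units also carrying green is the
amplitude ratio (G_cc(0)−1)/(G_g(0)−1), with both amplitudes from
one-component fits. Focus displacement is deliberately left uncorrected
here — the readout is a *relative* time course and the attenuation factor
cancels in the normalization to the pre-stimulation point. Cells with
green/red intensity ratio above 1 are deselected. Particle-number series
N = 1/(G(0)−1) are reported normalized to 100 at the first time point.

Spurious cross-correlation from spectral bleed-through is removed at the
amplitude level with the intensity-bleed model I_r^meas = I_r^true + κ·I_g:

    G_x,corr − 1 = [(G_x(0)−1)·I_r^meas − κ·I_g·(G_g(0)−1)]
                   / (I_r^meas − κ·I_g)

The defining (and tested) property is that data from a cell with no true
red signal beyond bleed-through and background corrects to zero within
sampling error. The formula requires I_r^meas > κ·I_g; a red channel
consisting purely of crosstalk has no information about true red species
and is rejected.

## FRAP analysis

Raw bleach-ROI traces are double-normalized: background-subtracted,
divided by the background-subtracted reference ROI (which cancels
whole-field acquisition bleaching exactly), and scaled so the pre-bleach
mean is 1. The mobile fraction is F_m = (I_P − I_0)/(I_I − I_0) with I_I
the pre-bleach mean, I_0 the *first* post-bleach frame (single frame, not
averaged — the immediate post-bleach value), and I_P the mean within the
85–101 s window of an acquisition that starts with 15 s of pre-bleach
frames (window boundaries configurable). F_m is invariant under affine
rescaling of the raw intensities. Recovery kinetics use a two-phase
association fit I_0 + A·[s(1−e^(−k₁t)) + (1−s)(1−e^(−k₂t))] with k₁ ≥ k₂
enforced by parametrization; a collapse to a single phase (s → 0/1 or
k₁ ≈ k₂) is flagged as degenerate rather than treated as an error.

Two screens gate dual-color FRAP statistics: the crosslinked anchor
population must show at least a 40% reduction in mobile fraction relative
to its uncrosslinked baseline (insufficient immobilization otherwise), and
the GFP/mCherry intensity ratio must stay below 1.6 (the crosslinked
population must be in excess for interaction to register). Both screens
are pure predicates evaluated per ROI, with per-experiment aggregates
reported by `summarize_condition` (mean ± s.e.m., sample-sd convention).

## The synthetic-data generator

`ffs_sim` emulates exactly the ingredients the model assumes, and nothing
more:

- Particles of the three species are placed uniformly in a periodic
  square box (default 20 × 20 µm; analyses in the test suite use
  2.5–4 µm patches, always ≥ 10 detection radii, to keep runtimes at
  desk scale) with per-species counts drawn once from
  Poisson(c × area), then propagated by per-axis Gaussian steps of sd
  √(2D·dt) each photon bin (dt default 0.5 ms, well below the shortest
  fitted lag of 1 ms).
- Expected channel intensities per bin are brightness-weighted Gaussian
  profile sums over all particles (green focus at the box center, red
  focus displaced by r₀ along x); the dual-labeled species contributes
  one label to each channel, single-color species x·q to theirs. Photon
  counts are Poisson draws around expectation, with K-scaled green signal
  and a constant background rate added to the red channel.
- Default brightness q = 2000 counts/s gives 1 kHz CPM, mid-range of the
  0.2–2.5 kHz inclusion window; default diffusion coefficients 0.41 µm²/s
  (monomer-like, 30 ms transit) and 0.235 µm²/s (dimer-like, 52 ms
  transit) are receptor-scale values consistent with the transit times the
  single-color analysis targets, and are configurable — the theoretical
  dimer model itself does not pin them down.
- Not simulated (by design): triplet blinking, photobleaching during
  acquisition, detector afterpulsing, 3D confocal profiles, flow.
  Passing tests therefore demonstrate estimator correctness under the
  model's own assumptions, not robustness to these real-data artifacts.

The dynamic experiment draws baseline counts once and converts every
dissociated complex into one green-only plus one red-only particle
following a piecewise-linear schedule, so green and red label totals are
conserved exactly across the time course. The FRAP generator evaluates
the two-phase law analytically, multiplies ROI and reference by a common
acquisition-bleaching decay, and adds Gaussian noise; with zero noise it
reproduces its generating curve to float precision.

All randomness in a simulation flows from a single integer seed;
identical seeds give bit-identical traces. The Brownian kernel is
numba-compiled with fastmath, so sums over particles are reassociated:
cross-checks against a straightforward vectorized evaluation of the same
positions use rtol 1e−10 rather than bit equality.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run entirely on synthetic data
at desk scale: 2.5–3 µm membrane patches, 10–100 molecules/µm², 20–60 s
per simulated cell (within the 20–80 s inclusion window), 10–20 seeds per
recovery experiment, and n = 50–100 records per FRAP grid cell. At these
sizes the dominant uncertainty is the genuine sampling noise of the
correlation amplitudes; recovery tolerances in the tests (15% for
single-species amplitude/transit time, 0.15 for dimer fractions and
model-agreement RMS, ±0.02 for the control-median crosstalk and FRAP
bias) reflect that noise level, not the estimators' asymptotic accuracy.
Ties and degenerate inputs: an empty control set raises; an all-zero
channel cannot be correlation-normalized and raises; segment screens on
constant traces treat zero variance as "no spike".

## Known limitations

- Eq.-style backgrounds are model-unit parameters; fitting real traces
  with strong backgrounds requires the BG = 2R/q conversion and a
  brightness estimate.
- Per-cell crosstalk estimates are wide (±0.05); downstream dimer
  fractions are robust to K errors of this size, but the control batch
  median — not per-cell K — is the calibration quantity.
- The dynamic bound-fraction series is relative; absolute dimer fractions
  over time would require the displacement correction and x-factor
  assumptions of the full two-step fit.
- The simulator's periodic box fixes the particle number per realization;
  number fluctuations in the focus remain effectively Poissonian only
  while the detection area is a small fraction of the box (all defaults
  respect this by two orders of magnitude).
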