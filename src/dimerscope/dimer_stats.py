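"""Combinatorial dimer statistics and dynamic bound-fraction analysis.

Under random pairing of M green and N red protomers into (M+N)/2 dimers,
the probability that a given dimer is mixed (one green, one red) is
p = 2MN/((M+N)(M+N−1)) ≈ 2MN/(M+N)², which in dimer-concentration variables
(c_gg, c_gr, c_rr) reads (2c_gg+c_gr)(2c_rr+c_gr)/(2(c_gg+c_gr+c_rr)²).
Comparing the measured mixed-dimer concentration c_gr with the
random-pairing expectation c′_gr tests an all-dimer model against the data:
c_gr/c′_gr = 1 when every protomer is paired and labels mix binomially.

The dynamic analysis estimates the fraction of red diffusing units that
also carry a green label from the amplitude ratio (G_cc(0)−1)/(G_g(0)−1),
corrects spurious cross-correlation caused by spectral bleed-through, and
applies the normalizations used for stimulation time-course reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ffs_sim import PairingCount, DynamicMeasurement
from . import correlate as _corr
from . import fccs_fit as _fit

__all__ = [
    "DimerEstimate",
    "DynamicSeries",
    "pair_probability",
    "expected_crossdimer",
    "dimer_estimate",
    "model_agreement_rms",
    "bound_fraction",
    "correct_crosstalk_amplitude",
    "intensity_ratio_screen",
    "normalize_dynamic_series",
    "analyze_dynamic_experiment",
]


@dataclass(frozen=True)
class DimerEstimate:
    """Random-pairing expectation for one cell's dimer concentrations."""

    p_gr: float
    c_prime_gr: float
    ratio: float
    counts: PairingCount


def pair_probability(counts: PairingCount) -> float:
    """Probability that a dimer is mixed under random pairing,
    (2c_gg+c_gr)(2c_rr+c_gr)/(2(c_gg+c_gr+c_rr)²).

    This is the large-population approximation of the exact pairing
    probability 2MN/((M+N)(M+N−1)); the gap is at most 1/(M+N).
    """
    if counts.total <= 0:
        raise ValueError("total dimer concentration must be positive")
    return counts.m_green * counts.n_red / (2.0 * counts.total**2)


def expected_crossdimer(counts: PairingCount) -> float:
    """Expected mixed-dimer concentration under random pairing,
    c′_gr = (2c_gg+c_gr)(2c_rr+c_gr)/(2(c_gg+c_gr+c_rr))."""
    if counts.total <= 0:
        raise ValueError("total dimer concentration must be positive")
    return counts.m_green * counts.n_red / (2.0 * counts.total)


def dimer_estimate(counts: PairingCount) -> DimerEstimate:
    """Bundle p_gr, c′_gr and the measured-to-expected ratio c_gr/c′_gr.

    ratio = 1 signals agreement with the all-dimer random-pairing model;
    the paper-style "percentage of dimerization" is 100·ratio.
    """
    p = pair_probability(counts)
    c_prime = expected_crossdimer(counts)
    ratio = counts.c_gr / c_prime if c_prime > 0 else math.nan
    return DimerEstimate(p, c_prime, ratio, counts)


def model_agreement_rms(cells: Sequence[PairingCount],
                        model: str = "all-dimer") -> float:
    """RMS deviation between measured and model-predicted mixed fractions.

    Per cell the measured mixed-dimer fraction c_gr/(c_gg+c_gr+c_rr) is
    compared with the model prediction: the "all-dimer" model predicts the
    random-pairing probability p_gr (every protomer paired, labels mixing
    binomially); the "zero-dimer" model predicts 0 (no genuine co-diffusing
    species, any residual c_gr is artifact).
    """
    if not cells:
        raise ValueError("need at least one cell")
    if model not in ("all-dimer", "zero-dimer"):
        raise ValueError("model must be 'all-dimer' or 'zero-dimer'")
    devs = []
    for c in cells:
        measured = c.c_gr / c.total if c.total > 0 else math.nan
        predicted = pair_probability(c) if model == "all-dimer" else 0.0
        devs.append(measured - predicted)
    return float(np.sqrt(np.mean(np.square(devs))))


def bound_fraction(gcc0_minus1: float, gg0_minus1: float) -> float:
    """Fraction of red diffusing units also carrying green,
    N_gr/N_r = (G_cc(0)−1)/(G_g(0)−1)."""
    if gg0_minus1 <= 0:
        raise ValueError("green autocorrelation amplitude must be positive")
    if gcc0_minus1 < 0:
        gcc0_minus1 = 0.0
    return gcc0_minus1 / gg0_minus1


def correct_crosstalk_amplitude(gx0_minus1: float, gg0_minus1: float,
                                i_g: float, i_r: float,
                                kappa: float) -> float:
    """Remove the spurious cross-correlation amplitude caused by green
    emission bleeding into the red channel.

    With measured red intensity I_r^meas = I_r^true + κ·I_g, the
    crosstalk-free amplitude is

        G_x,corr − 1 = [(G_x(0)−1)·I_r^meas − κ·I_g·(G_g(0)−1)]
                       / (I_r^meas − κ·I_g).

    The defining property: applied to data from a cell with no red species
    beyond bleed-through (plus background), the corrected amplitude is zero
    within sampling error.
    """
    if not 0.0 <= kappa < 1.0:
        raise ValueError("kappa must be in [0, 1)")
    true_red = i_r - kappa * i_g
    if true_red <= 0:
        raise ValueError("red channel intensity does not exceed crosstalk; "
                         "correction undefined")
    return (gx0_minus1 * i_r - kappa * i_g * gg0_minus1) / true_red


def intensity_ratio_screen(i_g: float, i_r: float,
                           max_ratio: float = 1.0) -> bool:
    """Deselect cells with green/red intensity ratio above `max_ratio`
    (excess green makes the bound-fraction estimate unreliable)."""
    if i_r <= 0:
        raise ValueError("red intensity must be positive")
    return (i_g / i_r) <= max_ratio


# ---------------------------------------------------------------------------
# Stimulation time-course series
# ---------------------------------------------------------------------------

@dataclass
class DynamicSeries:
    """Bound-fraction and particle-number readouts over a stimulation
    time course."""

    time_min: np.ndarray
    bound_fraction: np.ndarray
    n_g: np.ndarray
    n_r: np.ndarray
    normalized: str = "none"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.bound_fraction = np.asarray(self.bound_fraction, dtype=float)
        self.n_g = np.asarray(self.n_g, dtype=float)
        self.n_r = np.asarray(self.n_r, dtype=float)


def normalize_dynamic_series(series: DynamicSeries,
                             mode: str = "fraction-to-reference",
                             reference_index: int = 0) -> DynamicSeries:
    """Normalize a time course for cross-cell comparison.

    "fraction-to-reference" divides the bound-fraction series by its value
    at the reference (pre-stimulation) point, so the series is 1 there;
    "particles-to-100" rescales N_g and N_r so the first point is 100.
    """
    if mode == "fraction-to-reference":
        ref = series.bound_fraction[reference_index]
        if ref == 0:
            raise ValueError("zero reference bound fraction")
        return replace(series, bound_fraction=series.bound_fraction / ref,
                       normalized="fraction-to-reference")
    if mode == "particles-to-100":
        if series.n_g[0] == 0 or series.n_r[0] == 0:
            raise ValueError("zero first-point particle number")
        return replace(series, n_g=100.0 * series.n_g / series.n_g[0],
                       n_r=100.0 * series.n_r / series.n_r[0],
                       normalized="particles-to-100")
    raise ValueError("mode must be 'fraction-to-reference' or "
                     "'particles-to-100'")


def analyze_dynamic_experiment(measurements: Sequence[DynamicMeasurement],
                               kappa: float = 0.0,
                               max_lag: float = 1.0,
                               min_lag: float = 1e-3) -> DynamicSeries:
    """Amplitude-ratio bound-fraction series from a dynamic experiment.

    Per time point the segments are correlated individually and averaged;
    one-component fits of the green autocorrelation and the
    cross-correlation give G_g(0)−1 and G_cc(0)−1 (the focus-displacement
    loss is left uncorrected — the readout is a relative time course). The
    cross amplitude is crosstalk-corrected when κ > 0. Particle numbers are
    reported as N = 1/(G(0)−1) per channel.
    """
    times, fractions, n_gs, n_rs = [], [], [], []
    for meas in measurements:
        gg = _corr.average_curves(
            [_corr.autocorrelate(t, "G", max_lag=max_lag)
             for t in meas.traces])
        rr = _corr.average_curves(
            [_corr.autocorrelate(t, "R", max_lag=max_lag)
             for t in meas.traces])
        gx = _corr.average_curves(
            [_corr.crosscorrelate(t, max_lag=max_lag) for t in meas.traces])
        g_fit = _fit.fit_fcs_tauD(gg, min_lag=min_lag)
        r_fit = _fit.fit_fcs_tauD(rr, min_lag=min_lag)
        x_fit = _fit.fit_fcs_tauD(gx, min_lag=min_lag)
        gcc0 = max(x_fit.g0, 0.0)
        if kappa > 0:
            rates = [t.mean_rates() for t in meas.traces]
            i_g = float(np.mean([r[0] for r in rates]))
            i_r = float(np.mean([r[1] for r in rates]))
            gcc0 = max(correct_crosstalk_amplitude(gcc0, g_fit.g0, i_g, i_r,
                                                   kappa), 0.0)
        times.append(meas.time_s / 60.0)
        fractions.append(bound_fraction(gcc0, g_fit.g0))
        n_gs.append(1.0 / g_fit.g0 if g_fit.g0 > 0 else math.nan)
        n_rs.append(1.0 / r_fit.g0 if r_fit.g0 > 0 else math.nan)
    return DynamicSeries(np.array(times), np.array(fractions),
                         np.array(n_gs), np.array(n_rs),
                         metadata={"kappa": kappa})
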