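"""Synthetic fluorescence-fluctuation and FRAP data generation.

Simulates the physical situation assumed by the two-color membrane FCCS
model: three fluorescent species (green-only, red-only, and dual-labeled
green/red complex) diffusing by 2D Brownian motion in a periodic square
membrane patch, observed through two laterally displaced Gaussian detection
areas. Photon counts per sampling bin are Poisson draws around the summed
Gaussian-profile intensity of all particles, with green-to-red spectral
crosstalk and per-channel backgrounds.

Also provides a schedule-driven dynamic dissociation experiment (transient
loss of the dual-labeled species with label conservation), an analytic
two-phase FRAP recovery generator, and an exhaustive perfect-pairing
enumerator used as the combinatorial oracle for dimer statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from numba import njit

from .frap_analysis import FrapChannel, FrapRecord

__all__ = [
    "DetectionGeometry",
    "SpeciesModel",
    "IntensityTrace",
    "DissociationSchedule",
    "PairingCount",
    "DynamicMeasurement",
    "simulate_membrane_traces",
    "simulate_dynamic_experiment",
    "simulate_frap_record",
    "enumerate_pairings",
]


@dataclass(frozen=True)
class DetectionGeometry:
    """Lateral geometry of the two confocal detection areas.

    Parameters
    ----------
    omega_g, omega_r : float
        1/e² lateral radii of the green and red detection profiles (µm).
        Calibration values for a 488/543 nm setup are 0.222 and 0.272 µm.
    r0 : float
        Lateral displacement between the centers of the two foci (µm).
    """

    omega_g: float = 0.222
    omega_r: float = 0.272
    r0: float = 0.125

    def __post_init__(self):
        if self.omega_g <= 0 or self.omega_r <= 0:
            raise ValueError("detection radii must be positive")
        if self.r0 < 0:
            raise ValueError("focus displacement r0 must be >= 0")

    @property
    def area_g(self) -> float:
        """Effective green detection area A_G = π·ω_G² (µm²)."""
        return math.pi * self.omega_g**2

    @property
    def area_r(self) -> float:
        """Effective red detection area A_R = π·ω_R² (µm²)."""
        return math.pi * self.omega_r**2

    @property
    def area_gr(self) -> float:
        """Effective cross-correlation area A_GR = π·(ω_G²+ω_R²)/2 (µm²)."""
        return math.pi * (self.omega_g**2 + self.omega_r**2) / 2.0


@dataclass(frozen=True)
class SpeciesModel:
    """Concentrations, mobilities and photophysics of the three-species system.

    Parameters
    ----------
    c_g, c_r, c_gr : float
        Surface concentrations of green-only, red-only and dual-labeled
        diffusing units (molecules/µm²).
    d_g, d_r, d_gr : float
        Lateral diffusion coefficients (µm²/s). Defaults correspond to
        transit times of roughly 30 ms (single units) and 52 ms (complex)
        through a 222 nm radius focus, typical for a membrane receptor.
    q_g, q_r : float
        Molecular brightness of one green / red label at the focus center
        (counts/s); 2000 counts/s gives 1 kHz counts-per-molecule.
    x_g, x_r : int
        Absorption cross-section ratios of the single-color species relative
        to the dual-labeled one (1 for monomeric labels, 2 when the
        single-color species is itself a double-labeled homodimer).
    k_crosstalk : float
        Brightness ratio of green emission detected in the red channel.
    bg_g, bg_r : float
        Background count rates per channel (counts/s).
    """

    c_g: float = 0.0
    c_r: float = 0.0
    c_gr: float = 0.0
    d_g: float = 0.41
    d_r: float = 0.41
    d_gr: float = 0.235
    q_g: float = 2000.0
    q_r: float = 2000.0
    x_g: int = 1
    x_r: int = 1
    k_crosstalk: float = 0.0
    bg_g: float = 0.0
    bg_r: float = 0.0

    def __post_init__(self):
        if min(self.c_g, self.c_r, self.c_gr) < 0:
            raise ValueError("concentrations must be >= 0")
        if min(self.d_g, self.d_r, self.d_gr) <= 0:
            raise ValueError("diffusion coefficients must be > 0")
        if self.x_g not in (1, 2) or self.x_r not in (1, 2):
            raise ValueError("x_g and x_r must be 1 or 2")
        if not 0.0 <= self.k_crosstalk < 1.0:
            raise ValueError("crosstalk parameter must be in [0, 1)")
        if self.bg_g < 0 or self.bg_r < 0:
            raise ValueError("backgrounds must be >= 0")


@dataclass
class IntensityTrace:
    """Two-channel photon-count time series with sampling metadata."""

    dt: float
    counts_green: np.ndarray
    counts_red: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts_green = np.asarray(self.counts_green)
        self.counts_red = np.asarray(self.counts_red)
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be > 0")
        if self.counts_green.shape != self.counts_red.shape:
            raise ValueError("channel arrays must have equal length")
        if np.issubdtype(self.counts_green.dtype, np.integer):
            if (self.counts_green < 0).any() or (self.counts_red < 0).any():
                raise ValueError("photon counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts_green)

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt

    def mean_rates(self) -> tuple[float, float]:
        """Mean count rates (counts/s) of the green and red channel."""
        return (
            float(self.counts_green.mean() / self.dt),
            float(self.counts_red.mean() / self.dt),
        )


@dataclass(frozen=True)
class DissociationSchedule:
    """Piecewise-linear transient loss of the dual-labeled species.

    The instantaneous dual-label concentration is ``f(t)·c_gr(baseline)``
    with f = 1 before ``t_stim``, falling linearly to ``f_min`` at ``t_min``
    and returning linearly to 1 at ``t_recover`` (all times in seconds).
    """

    t_stim: float
    f_min: float
    t_min: float
    t_recover: float

    def __post_init__(self):
        if not 0.0 <= self.f_min <= 1.0:
            raise ValueError("f_min must be in [0, 1]")
        if not self.t_stim < self.t_min < self.t_recover:
            raise ValueError("schedule requires t_stim < t_min < t_recover")

    def fraction_at(self, t: float) -> float:
        if t <= self.t_stim or t >= self.t_recover:
            return 1.0
        if t <= self.t_min:
            w = (t - self.t_stim) / (self.t_min - self.t_stim)
        else:
            w = (self.t_recover - t) / (self.t_recover - self.t_min)
        return 1.0 + w * (self.f_min - 1.0)


@dataclass(frozen=True)
class PairingCount:
    """Concentrations (or counts) of green-green, green-red, red-red dimers."""

    c_gg: float
    c_gr: float
    c_rr: float

    def __post_init__(self):
        if min(self.c_gg, self.c_gr, self.c_rr) < 0:
            raise ValueError("pairing counts must be >= 0")

    @property
    def m_green(self) -> float:
        """Total green molecules M = 2·c_gg + c_gr."""
        return 2.0 * self.c_gg + self.c_gr

    @property
    def n_red(self) -> float:
        """Total red molecules N = 2·c_rr + c_gr."""
        return 2.0 * self.c_rr + self.c_gr

    @property
    def total(self) -> float:
        return self.c_gg + self.c_gr + self.c_rr


# ---------------------------------------------------------------------------
# Brownian-dynamics photon trace simulation
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _propagate_and_project(pos, step_sd, b_green, b_red, n_bins, box,
                           omega_g2, omega_r2, r0, seed):
    """Advance all particles one Brownian step per bin and accumulate the
    per-bin Gaussian-profile intensity sums for both foci.

    Green focus at the box center; red focus displaced by r0 along x.
    Returns expected signal (brightness-weighted profile sums) per bin,
    in counts/s units.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    lam_g = np.zeros(n_bins)
    lam_r = np.zeros(n_bins)
    half = box / 2.0
    ag = -2.0 / omega_g2
    ar = -2.0 / omega_r2
    for t in range(n_bins):
        sg = 0.0
        sr = 0.0
        for i in range(n):
            x = pos[i, 0] + step_sd[i] * np.random.normal()
            y = pos[i, 1] + step_sd[i] * np.random.normal()
            x -= box * math.floor(x / box)
            y -= box * math.floor(y / box)
            pos[i, 0] = x
            pos[i, 1] = y
            dx = x - half
            dy = y - half
            if b_green[i] > 0.0:
                sg += b_green[i] * math.exp(ag * (dx * dx + dy * dy))
            if b_red[i] > 0.0:
                dxr = dx - r0
                sr += b_red[i] * math.exp(ar * (dxr * dxr + dy * dy))
        lam_g[t] = sg
        lam_r[t] = sr
    return lam_g, lam_r


@njit(cache=True, fastmath=True)
def _propagate_and_project_recorded(pos, step_sd, b_green, b_red, n_bins, box,
                                    omega_g2, omega_r2, r0, seed):
    """As `_propagate_and_project` but also records particle positions per bin
    (small systems only; used for direct profile-sum verification)."""
    np.random.seed(seed)
    n = pos.shape[0]
    lam_g = np.zeros(n_bins)
    lam_r = np.zeros(n_bins)
    hist = np.zeros((n_bins, n, 2))
    half = box / 2.0
    ag = -2.0 / omega_g2
    ar = -2.0 / omega_r2
    for t in range(n_bins):
        sg = 0.0
        sr = 0.0
        for i in range(n):
            x = pos[i, 0] + step_sd[i] * np.random.normal()
            y = pos[i, 1] + step_sd[i] * np.random.normal()
            x -= box * math.floor(x / box)
            y -= box * math.floor(y / box)
            pos[i, 0] = x
            pos[i, 1] = y
            hist[t, i, 0] = x
            hist[t, i, 1] = y
            dx = x - half
            dy = y - half
            if b_green[i] > 0.0:
                sg += b_green[i] * math.exp(ag * (dx * dx + dy * dy))
            if b_red[i] > 0.0:
                dxr = dx - r0
                sr += b_red[i] * math.exp(ar * (dxr * dxr + dy * dy))
        lam_g[t] = sg
        lam_r[t] = sr
    return lam_g, lam_r, hist


def _assemble_particles(model: SpeciesModel, counts: tuple[int, int, int]):
    """Per-particle diffusion step sd and channel brightnesses.

    Green-only units carry x_g green labels (brightness x_g·q_g), red-only
    units x_r red labels, dual-labeled units one label of each color.
    """
    n_g, n_r, n_gr = counts
    n = n_g + n_r + n_gr
    step_sd = np.empty(n)
    b_green = np.zeros(n)
    b_red = np.zeros(n)
    sl_g = slice(0, n_g)
    sl_r = slice(n_g, n_g + n_r)
    sl_gr = slice(n_g + n_r, n)
    step_sd[sl_g] = math.sqrt(2.0 * model.d_g)
    step_sd[sl_r] = math.sqrt(2.0 * model.d_r)
    step_sd[sl_gr] = math.sqrt(2.0 * model.d_gr)
    b_green[sl_g] = model.x_g * model.q_g
    b_red[sl_r] = model.x_r * model.q_r
    b_green[sl_gr] = model.q_g
    b_red[sl_gr] = model.q_r
    return step_sd, b_green, b_red


def _simulate_with_counts(model, geom, duration, dt, box_size, seed, counts,
                          return_internals=False):
    n_bins = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    n = sum(counts)
    pos = rng.uniform(0.0, box_size, size=(n, 2))
    step_sd, b_green, b_red = _assemble_particles(model, counts)
    step_sd = step_sd * math.sqrt(dt)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    args = (pos, step_sd, b_green, b_red, n_bins, box_size,
            geom.omega_g**2, geom.omega_r**2, geom.r0, kernel_seed)
    if return_internals:
        sig_g, sig_r, hist = _propagate_and_project_recorded(*args)
    else:
        sig_g, sig_r = _propagate_and_project(*args)
        hist = None
    lam_green = (sig_g + model.bg_g) * dt
    lam_red = (sig_r + model.k_crosstalk * sig_g + model.bg_r) * dt
    counts_green = rng.poisson(lam_green)
    counts_red = rng.poisson(lam_red)
    trace = IntensityTrace(
        dt=dt,
        counts_green=counts_green,
        counts_red=counts_red,
        metadata={
            "seed": seed,
            "box_size_um": box_size,
            "n_particles": {"g": counts[0], "r": counts[1], "gr": counts[2]},
            "model": model,
            "geometry": geom,
            "synthetic": True,
        },
    )
    if return_internals:
        internals = {
            "positions": hist,
            "signal_green": sig_g,
            "signal_red": sig_r,
            "brightness_green": b_green,
            "brightness_red": b_red,
        }
        return trace, internals
    return trace


def simulate_membrane_traces(model: SpeciesModel, geom: DetectionGeometry,
                             duration: float, dt: float = 5e-4,
                             box_size: float = 20.0, seed: int = 0,
                             return_internals: bool = False):
    """Simulate a two-channel photon-count trace from membrane diffusion.

    Particle numbers for each species are Poisson draws around
    concentration × box area and stay fixed for the realization (periodic
    boundaries conserve the in-box concentration). Each sampling bin the
    particles take one Brownian step (per-axis sd = sqrt(2·D·dt)) and the
    expected channel intensities are the brightness-weighted Gaussian
    profile sums over all particles; photon counts are Poisson draws around
    those expectations, with green→red crosstalk and backgrounds added.

    Parameters
    ----------
    duration, dt : float
        Trace length and sampling interval (s); `dt` should stay well below
        the shortest lag used in fitting (1 ms).
    box_size : float
        Side of the periodic membrane patch (µm); must be at least
        10 detection radii so the focus never feels the boundary.
    seed : int
        Single source of randomness for the whole realization.
    return_internals : bool
        Also return per-bin particle positions and noiseless intensity sums
        (memory heavy; small systems only).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if round(duration / dt) < 2:
        raise ValueError("trace must contain at least 2 bins")
    if box_size < 10.0 * geom.omega_g:
        raise ValueError(
            f"box_size {box_size} µm too small relative to the detection "
            f"radius (need >= {10 * geom.omega_g:.2f} µm)")
    area = box_size**2
    rng = np.random.default_rng(seed)
    counts = (
        int(rng.poisson(model.c_g * area)),
        int(rng.poisson(model.c_r * area)),
        int(rng.poisson(model.c_gr * area)),
    )
    # the realization is fully determined by (seed, counts);
    # _simulate_with_counts derives its own generator from the same seed
    return _simulate_with_counts(model, geom, duration, dt, box_size,
                                 seed, counts, return_internals)


@dataclass
class DynamicMeasurement:
    """Traces acquired at one time point of a dynamic experiment."""

    time_s: float
    traces: list
    counts: tuple[int, int, int]
    c_gr_fraction: float


def simulate_dynamic_experiment(model: SpeciesModel, geom: DetectionGeometry,
                                schedule: DissociationSchedule,
                                time_points: Sequence[float],
                                segment_length: float = 10.0,
                                n_segments_per_point: int = 3,
                                dt: float = 5e-4, box_size: float = 20.0,
                                seed: int = 0) -> list[DynamicMeasurement]:
    """Simulate a stimulation time course of transient dimer dissociation.

    At each requested time point the dual-labeled particle count follows the
    schedule; every dissociated complex is converted into one extra
    green-only and one extra red-only particle, so the total number of green
    and of red labels is conserved exactly across the series.
    """
    time_points = np.asarray(time_points, dtype=float)
    if time_points.size == 0:
        raise ValueError("need at least one time point")
    if schedule.t_stim < time_points.min() - 1e-9 or \
            schedule.t_recover > time_points.max() + 1e-9:
        raise ValueError("schedule times must lie within the sampled span")
    rng = np.random.default_rng(seed)
    area = box_size**2
    n_g0 = int(rng.poisson(model.c_g * area))
    n_r0 = int(rng.poisson(model.c_r * area))
    n_gr0 = int(rng.poisson(model.c_gr * area))
    out = []
    for t in time_points:
        f = schedule.fraction_at(float(t))
        n_gr = int(round(f * n_gr0))
        released = n_gr0 - n_gr
        counts = (n_g0 + released, n_r0 + released, n_gr)
        traces = []
        for k in range(n_segments_per_point):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            traces.append(_simulate_with_counts(
                model, geom, segment_length, dt, box_size, sub_seed, counts))
        out.append(DynamicMeasurement(float(t), traces, counts, f))
    return out


# ---------------------------------------------------------------------------
# FRAP recovery generator
# ---------------------------------------------------------------------------

def simulate_frap_record(f_m: float, k_fast: float = 0.2, k_slow: float = 0.06,
                         amp_split: float = 0.6, i_pre: float = 100.0,
                         bleach_depth: float = 0.8, noise_sd: float = 0.0,
                         acq_bleach_rate: float = 0.0, duration: float = 101.0,
                         frame_interval: float = 1.0, bleach_time: float = 15.0,
                         background: float = 5.0, channel: str = "GFP",
                         condition: str = "", seed: int = 0) -> FrapRecord:
    """Generate a bleach-ROI recovery record with reference and background ROIs.

    The post-bleach ROI trace follows a two-phase association law
    ``I(t') = I_0 + F_m·(I_pre − I_0)·[s·(1−e^(−k_fast·t')) +
    (1−s)·(1−e^(−k_slow·t'))]`` with ``I_0 = I_pre·(1−bleach_depth)``,
    multiplied by a whole-field acquisition-bleaching decay
    ``e^(−acq_bleach_rate·t)`` that also affects the (unbleached) reference
    ROI, plus additive Gaussian noise on all ROIs.
    """
    if not 0.0 <= f_m <= 1.0:
        raise ValueError("mobile fraction must be in [0, 1]")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    if k_fast <= 0 or k_slow <= 0:
        raise ValueError("recovery rates must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= amp_split <= 1.0:
        raise ValueError("amp_split must be in [0, 1]")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration + 0.5 * frame_interval, frame_interval)
    bleach_index = int(np.searchsorted(time, bleach_time, side="left"))
    if bleach_index == 0 or bleach_index >= len(time):
        raise ValueError("bleach_time must fall inside the acquisition")
    i_0 = i_pre * (1.0 - bleach_depth)
    roi = np.empty_like(time)
    roi[:bleach_index] = i_pre
    tp = time[bleach_index:] - time[bleach_index]
    recovery = amp_split * (1.0 - np.exp(-k_fast * tp)) + \
        (1.0 - amp_split) * (1.0 - np.exp(-k_slow * tp))
    roi[bleach_index:] = i_0 + f_m * (i_pre - i_0) * recovery
    decay = np.exp(-acq_bleach_rate * time)
    roi = roi * decay + background
    reference = i_pre * decay + background
    bg = np.full_like(time, background)
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd, roi.shape)
        reference = reference + rng.normal(0.0, noise_sd, reference.shape)
        bg = bg + rng.normal(0.0, noise_sd, bg.shape)
    rec = FrapRecord(
        time_s=time,
        channels={channel: FrapChannel(roi=roi, reference=reference,
                                       background=bg)},
        bleach_index=bleach_index,
        condition=condition,
        metadata={
            "seed": seed, "f_m": f_m, "k_fast": k_fast, "k_slow": k_slow,
            "amp_split": amp_split, "i_pre": i_pre,
            "bleach_depth": bleach_depth, "noise_sd": noise_sd,
            "acq_bleach_rate": acq_bleach_rate, "background": background,
            "synthetic": True,
        },
    )
    return rec


# ---------------------------------------------------------------------------
# Exhaustive dimer-pairing oracle
# ---------------------------------------------------------------------------

def _enumerate_matchings(labels: tuple[int, ...]):
    """Yield the mixed-pair count of every perfect matching of `labels`."""
    if not labels:
        yield 0
        return
    first, rest = labels[0], labels[1:]
    for j in range(len(rest)):
        partner = rest[j]
        remaining = rest[:j] + rest[j + 1:]
        mixed = 1 if first != partner else 0
        for sub in _enumerate_matchings(remaining):
            yield mixed + sub


@lru_cache(maxsize=None)
def _mean_mixed_fraction(m: int, n: int) -> float:
    labels = (0,) * m + (1,) * n
    n_pairs = (m + n) // 2
    total = 0
    count = 0
    for mixed in _enumerate_matchings(labels):
        total += mixed
        count += 1
    return total / (count * n_pairs)


def enumerate_pairings(m: int, n: int, exhaustive_limit: int = 12) -> float:
    """Expected fraction of mixed (green-red) pairs under random pairing.

    For ``m + n <= exhaustive_limit`` the value is obtained by exhaustive
    enumeration of all perfect pairings of m green and n red molecules;
    beyond that the exact closed form ``2mn/((m+n)(m+n−1))`` is used (the
    two coincide; the enumeration is retained as an independent oracle).
    """
    if m < 0 or n < 0 or m != int(m) or n != int(n):
        raise ValueError("molecule counts must be non-negative integers")
    m, n = int(m), int(n)
    if (m + n) % 2 != 0:
        raise ValueError("total number of molecules must be even")
    if m + n < 2:
        raise ValueError("need at least one pair")
    if m + n <= exhaustive_limit:
        return _mean_mixed_fraction(m, n)
    return 2.0 * m * n / ((m + n) * (m + n - 1.0))
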