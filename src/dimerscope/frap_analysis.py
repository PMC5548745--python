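"""Dual-color FRAP normalization, mobile-fraction estimation and screens.

The mobile fraction of a membrane protein is F_m = (I_P − I_0)/(I_I − I_0),
where I_I is the pre-bleach intensity, I_0 the intensity immediately after
photobleaching and I_P the late-recovery plateau (here the average within a
fixed window late in the acquisition). In the dual-color assay one receptor
population (mCherry-tagged) is immobilized by antibody crosslinking;
interaction with the co-expressed GFP-tagged population shows up as a
crosslinking-induced drop in the GFP mobile fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "FrapChannel",
    "FrapRecord",
    "NormalizedRecovery",
    "MobileFractionResult",
    "ScreenVerdict",
    "TwoPhaseFit",
    "ConditionSummary",
    "normalize_recovery",
    "mobile_fraction",
    "crosslink_screen",
    "fit_two_phase",
    "summarize_condition",
]

DEFAULT_WINDOW = (85.0, 101.0)


@dataclass
class FrapChannel:
    """Raw ROI intensity traces of one channel (arbitrary units)."""

    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        self.roi = np.asarray(self.roi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not (len(self.roi) == len(self.reference) == len(self.background)):
            raise ValueError("ROI, reference and background must align")


@dataclass
class FrapRecord:
    """Pre/post-bleach ROI intensities for one or two channels.

    `bleach_index` is the index of the first post-bleach frame. The bleach
    ROI is 1.80 × 1.80 µm by default, matching the acquisition protocol.
    """

    time_s: np.ndarray
    channels: dict[str, FrapChannel]
    bleach_index: int
    condition: str = ""
    roi_size_um: float = 1.8
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not 0 < self.bleach_index < len(self.time_s):
            raise ValueError("bleach index must fall inside the time grid")
        for name, ch in self.channels.items():
            if len(ch.roi) != len(self.time_s):
                raise ValueError(f"channel {name!r} length mismatch")


@dataclass
class NormalizedRecovery:
    """Double-normalized recovery curve (pre-bleach mean ≡ 1)."""

    time_s: np.ndarray
    values: np.ndarray
    bleach_index: int
    channel: str


def normalize_recovery(record: FrapRecord,
                       channel: str | None = None) -> dict[str, NormalizedRecovery]:
    """Background-subtract, divide by the reference-ROI drift, and scale the
    pre-bleach mean to 1 (standard double normalization).

    The reference ROI tracks whole-field acquisition bleaching, so any
    multiplicative drift common to ROI and reference cancels exactly.
    """
    names = [channel] if channel is not None else list(record.channels)
    out = {}
    for name in names:
        ch = record.channels[name]
        ref = ch.reference - ch.background
        if np.any(ref <= 0):
            raise ValueError(
                f"channel {name!r}: reference does not exceed background "
                "everywhere; normalization undefined")
        norm = (ch.roi - ch.background) / ref
        pre = norm[:record.bleach_index].mean()
        if pre == 0:
            raise ValueError(f"channel {name!r}: zero pre-bleach intensity")
        out[name] = NormalizedRecovery(record.time_s, norm / pre,
                                       record.bleach_index, name)
    return out


@dataclass
class MobileFractionResult:
    f_m: float
    i_initial: float
    i_post_bleach: float
    i_plateau: float
    window: tuple[float, float]
    channel: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def in_physical_range(self) -> bool:
        return 0.0 <= self.f_m <= 1.0


def mobile_fraction(curve: NormalizedRecovery,
                    window: tuple[float, float] = DEFAULT_WINDOW) -> MobileFractionResult:
    """Window-average mobile fraction F_m = (I_P − I_0)/(I_I − I_0).

    I_I is the pre-bleach mean, I_0 the first post-bleach frame, and I_P the
    mean within `window` on the experiment clock (the default 85–101 s window
    sits late in a 101 s acquisition that starts with 15 s of pre-bleach
    frames).
    """
    t = curve.time_s
    if t[-1] < window[0]:
        raise ValueError("curve ends before the plateau window starts")
    i_i = float(curve.values[:curve.bleach_index].mean())
    i_0 = float(curve.values[curve.bleach_index])
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError("no frames inside the plateau window")
    i_p = float(curve.values[sel].mean())
    if i_i == i_0:
        raise ValueError("no bleach detected (I_I equals I_0)")
    f_m = (i_p - i_0) / (i_i - i_0)
    flags = []
    if not -0.1 <= f_m <= 1.1:
        flags.append("out_of_physical_range")
    elif not 0.0 <= f_m <= 1.0:
        flags.append("outside_unit_interval")
    return MobileFractionResult(f_m, i_i, i_0, i_p, tuple(window),
                                curve.channel, flags)


@dataclass
class ScreenVerdict:
    included: bool
    reasons: list[str] = field(default_factory=list)


def crosslink_screen(fm_crosslinked: float, fm_baseline: float,
                     intensity_ratio: float,
                     reduction_cutoff: float = 0.40,
                     ratio_cutoff: float = 1.6) -> ScreenVerdict:
    """Inclusion screen for dual-color FRAP measurements.

    A measurement is analyzable only if (i) crosslinking immobilized the
    anchor (mCherry) population sufficiently — its mobile fraction dropped by
    at least `reduction_cutoff` (40%) relative to the uncrosslinked baseline —
    and (ii) the GFP/mCherry intensity ratio stays below `ratio_cutoff` (1.6
    for a fixed 488/543 laser ratio), ensuring the crosslinked population is
    in excess.
    """
    if fm_baseline <= 0:
        raise ValueError("baseline mobile fraction must be positive")
    reasons = []
    reduction = 1.0 - fm_crosslinked / fm_baseline
    if reduction < reduction_cutoff:
        reasons.append("insufficient_immobilization")
    if intensity_ratio >= ratio_cutoff:
        reasons.append("stoichiometry")
    return ScreenVerdict(not reasons, reasons)


@dataclass
class TwoPhaseFit:
    i_0: float
    amplitude: float
    k_fast: float
    k_slow: float
    split: float
    plateau: float
    success: bool
    degenerate: bool
    message: str = ""

    def mobile_fraction_from_plateau(self, i_initial: float = 1.0) -> float:
        """F_m implied by the fitted plateau, (plateau − I_0)/(I_I − I_0)."""
        return (self.plateau - self.i_0) / (i_initial - self.i_0)


def fit_two_phase(curve: NormalizedRecovery) -> TwoPhaseFit:
    """Least-squares two-phase association fit of the post-bleach recovery.

    Model: I(t') = I_0 + A·[s·(1 − e^(−k₁t')) + (1 − s)·(1 − e^(−k₂t'))]
    with k₁ ≥ k₂ enforced by parametrizing k₂ = k₁·ratio, ratio ∈ (0, 1].
    Returns a degenerate flag when the two phases collapse (s → 0/1 or
    k₁ ≈ k₂), in which case the curve is effectively single-exponential.
    """
    post = curve.values[curve.bleach_index:]
    tp = curve.time_s[curve.bleach_index:] - curve.time_s[curve.bleach_index]
    if len(post) < 10:
        raise ValueError("need at least 10 post-bleach points")
    i0_guess = float(post[0])
    amp_guess = max(float(post[-5:].mean() - post[0]), 1e-6)
    span = float(tp[-1])

    params = lmfit.Parameters()
    params.add("i_0", value=i0_guess)
    params.add("amplitude", value=amp_guess, min=0.0)
    params.add("split", value=0.6, min=0.0, max=1.0)
    params.add("k_fast", value=5.0 / span, min=1e-6 / span, max=1e4 / span)
    params.add("k_ratio", value=0.2, min=1e-6, max=1.0)

    def residual(p):
        k1 = p["k_fast"].value
        k2 = k1 * p["k_ratio"].value
        s = p["split"].value
        model = p["i_0"].value + p["amplitude"].value * (
            s * (1.0 - np.exp(-k1 * tp)) + (1.0 - s) * (1.0 - np.exp(-k2 * tp)))
        return model - post

    best = None
    for k_start in (1.0 / span, 5.0 / span, 30.0 / span):
        p = params.copy()
        p["k_fast"].value = k_start
        res = lmfit.minimize(residual, p, method="least_squares")
        if best is None or res.chisqr < best.chisqr:
            best = res
    p = best.params
    k1 = float(p["k_fast"].value)
    k2 = k1 * float(p["k_ratio"].value)
    s = float(p["split"].value)
    amp = float(p["amplitude"].value)
    i0 = float(p["i_0"].value)
    degenerate = s > 0.97 or s < 0.03 or (k2 > 0 and k1 / k2 < 1.2)
    return TwoPhaseFit(i_0=i0, amplitude=amp, k_fast=k1, k_slow=k2, split=s,
                       plateau=i0 + amp, success=bool(best.success),
                       degenerate=degenerate, message=best.message or "")


@dataclass
class ConditionSummary:
    mean: float
    sem: float
    n: int
    flags: list[str] = field(default_factory=list)


def summarize_condition(results) -> ConditionSummary:
    """Arithmetic mean ± s.e.m. of mobile fractions across included ROIs."""
    values = np.asarray(
        [r.f_m if isinstance(r, MobileFractionResult) else float(r)
         for r in results])
    if values.size < 1:
        raise ValueError("need at least one result")
    mean = float(values.mean())
    if values.size == 1:
        return ConditionSummary(mean, 0.0, 1, flags=["sem_undefined_n1"])
    sem = float(values.std(ddof=1) / math.sqrt(values.size))
    return ConditionSummary(mean, sem, int(values.size))
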