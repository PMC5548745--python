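"""Correlation-curve estimation and acquisition-segment screening.

Auto- and cross-correlation of two-channel photon-count traces on a
multiple-tau lag grid (m points per octave, the trace binned by 2 at each
coarser level) with symmetric normalization: for every lag the numerator
mean ⟨F(t)·F(t+τ)⟩ is divided by the product of the channel means computed
over the two overlapping sub-windows, so slow drifts bias the estimate as
little as possible. Values are reported as G(τ) − 1; the zero-lag bin is
never included (shot noise dominated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ffs_sim import IntensityTrace

__all__ = [
    "CorrelationCurve",
    "SegmentVerdict",
    "SegmentScreenReport",
    "autocorrelate",
    "crosscorrelate",
    "screen_segments",
    "correlate_segments",
    "average_curves",
]


@dataclass
class CorrelationCurve:
    """Lag grid and G(τ)−1 estimates for one channel pair (GG, RR or GR)."""

    pair: str
    lags: np.ndarray
    values: np.ndarray
    n_samples: np.ndarray
    sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_samples = np.asarray(self.n_samples)
        if self.pair not in ("GG", "RR", "GR"):
            raise ValueError("pair must be GG, RR or GR")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")

    def restrict(self, min_lag: float = 0.0, max_lag: float = math.inf):
        sel = (self.lags >= min_lag) & (self.lags <= max_lag)
        return CorrelationCurve(
            self.pair, self.lags[sel], self.values[sel], self.n_samples[sel],
            None if self.sd is None else self.sd[sel], dict(self.metadata))


def _multiple_tau_lags(n: int, m: int, max_lag_bins: int) -> list[tuple[int, int]]:
    """(level, lag-in-original-bins) pairs of the multiple-tau grid."""
    out = [(0, j) for j in range(1, m + 1)]
    level = 1
    while True:
        scale = 2**level
        n_level = n // scale
        lags = [j * scale for j in range(m // 2 + 1, m + 1)]
        lags = [lag for lag in lags
                if lag <= max_lag_bins and lag // scale < n_level // 2]
        if not lags:
            break
        out.extend((level, lag) for lag in lags)
        level += 1
        if 2**level > n:
            break
    return [(lev, lag) for lev, lag in out if lag <= max_lag_bins]


def _bin_by_two(x: np.ndarray) -> np.ndarray:
    n = len(x) // 2
    return x[: 2 * n].reshape(n, 2).mean(axis=1)


def _correlate_arrays(a: np.ndarray, b: np.ndarray, dt: float, m: int,
                      max_lag: float | None):
    """Symmetric-normalized multiple-tau estimate of ⟨δa·δb⟩/(⟨a⟩⟨b⟩)."""
    n = len(a)
    if n < 4:
        raise ValueError("trace too short to correlate")
    max_lag_bins = n // 2 if max_lag is None else int(max_lag / dt)
    max_lag_bins = min(max_lag_bins, n // 2)
    plan = _multiple_tau_lags(n, m, max_lag_bins)
    levels = {}
    cur_a, cur_b = a.astype(float), b.astype(float)
    levels[0] = (cur_a, cur_b)
    max_level = max(lev for lev, _ in plan)
    for lev in range(1, max_level + 1):
        cur_a, cur_b = _bin_by_two(cur_a), _bin_by_two(cur_b)
        levels[lev] = (cur_a, cur_b)
    lags, values, counts = [], [], []
    for lev, lag_bins in plan:
        la, lb = levels[lev]
        j = lag_bins // 2**lev
        nn = len(la) - j
        if nn < 2:
            continue
        left = la[:nn]
        right = lb[j:]
        denom = left.mean() * right.mean()
        if denom == 0:
            raise ValueError("zero mean intensity; correlation undefined")
        g = float((left * right).mean() / denom - 1.0)
        lags.append(lag_bins * dt)
        values.append(g)
        counts.append(nn)
    return np.array(lags), np.array(values), np.array(counts)


def autocorrelate(trace: IntensityTrace, channel: str = "G", m: int = 16,
                  max_lag: float | None = None) -> CorrelationCurve:
    """Autocorrelation curve G(τ)−1 of one detection channel."""
    x = trace.counts_green if channel.upper().startswith("G") \
        else trace.counts_red
    if len(x) == 0:
        raise ValueError("empty trace")
    if np.all(x == 0):
        raise ValueError("all-zero trace; normalization undefined")
    lags, values, counts = _correlate_arrays(x, x, trace.dt, m, max_lag)
    pair = "GG" if channel.upper().startswith("G") else "RR"
    return CorrelationCurve(pair, lags, values, counts,
                            metadata={"duration_s": trace.duration})


def crosscorrelate(trace: IntensityTrace, m: int = 16,
                   max_lag: float | None = None) -> CorrelationCurve:
    """Cross-correlation curve ⟨δF_G(t)δF_R(t+τ)⟩/(⟨F_G⟩⟨F_R⟩)."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    if np.all(trace.counts_green == 0) or np.all(trace.counts_red == 0):
        raise ValueError("all-zero channel; normalization undefined")
    lags, values, counts = _correlate_arrays(
        trace.counts_green, trace.counts_red, trace.dt, m, max_lag)
    return CorrelationCurve("GR", lags, values, counts,
                            metadata={"duration_s": trace.duration})


# ---------------------------------------------------------------------------
# Segment screening
# ---------------------------------------------------------------------------

@dataclass
class SegmentVerdict:
    index: int
    t_start: float
    t_stop: float
    kept: bool
    reasons: list[str] = field(default_factory=list)
    cpm_khz: float = math.nan
    rel_slope: float = math.nan
    max_z: float = math.nan


@dataclass
class SegmentScreenReport:
    segments: list[SegmentVerdict]
    segment_length: float

    @property
    def included_time(self) -> float:
        return sum(s.t_stop - s.t_start for s in self.segments if s.kept)

    @property
    def kept_indices(self) -> list[int]:
        return [s.index for s in self.segments if s.kept]


def _segment_cpm_khz(counts: np.ndarray, dt: float) -> float:
    """Molecular brightness estimate (kHz) from the excess variance.

    For fluctuations on top of shot noise, var − mean = mean²·(G(0)−1) per
    bin, so (var − mean)/(mean·dt) estimates rate/N — the counts per
    molecule. Returns NaN for an empty or constant segment.
    """
    mean = counts.mean()
    if mean <= 0:
        return math.nan
    excess = counts.var() - mean
    if excess <= 0:
        return 0.0
    return float(excess / (mean * dt) / 1000.0)


def screen_segments(trace: IntensityTrace, segment_length: float = 10.0,
                    spike_z: float = 10.0, decay_slope: float = 1.0,
                    min_cpm: float | None = None,
                    channel: str = "G") -> SegmentScreenReport:
    """Flag acquisition segments unusable for correlation analysis.

    A segment is discarded when (i) any bin exceeds mean + `spike_z`·sd
    (bright aggregates passing the focus), (ii) a linear intensity fit loses
    more than `decay_slope` of the mean over the segment (whole-ROI decay,
    e.g. membrane movement), or (iii) the variance-based molecular
    brightness falls at or below `min_cpm` (kHz per molecule). A partial
    trailing segment is dropped. Every discarded segment carries reason
    codes; an empty kept-set is a valid outcome.
    """
    x = (trace.counts_green if channel.upper().startswith("G")
         else trace.counts_red).astype(float)
    bins_per_seg = int(round(segment_length / trace.dt))
    if bins_per_seg < 2:
        raise ValueError("segment shorter than two bins")
    n_seg = len(x) // bins_per_seg
    verdicts = []
    for i in range(n_seg):
        seg = x[i * bins_per_seg:(i + 1) * bins_per_seg]
        t0 = i * segment_length
        reasons = []
        mean = seg.mean()
        sd = seg.std()
        max_z = (seg.max() - mean) / sd if sd > 0 else 0.0
        if sd > 0 and max_z > spike_z:
            reasons.append("intensity_spike")
        tt = np.arange(len(seg)) * trace.dt
        slope = np.polyfit(tt, seg, 1)[0] if mean > 0 else 0.0
        rel_slope = slope * segment_length / mean if mean > 0 else 0.0
        if rel_slope < -decay_slope:
            reasons.append("monotone_decay")
        cpm = _segment_cpm_khz(seg, trace.dt)
        if min_cpm is not None and not (cpm > min_cpm):
            reasons.append("low_brightness")
        verdicts.append(SegmentVerdict(
            index=i, t_start=t0, t_stop=t0 + segment_length,
            kept=not reasons, reasons=reasons, cpm_khz=cpm,
            rel_slope=float(rel_slope), max_z=float(max_z)))
    return SegmentScreenReport(verdicts, segment_length)


def correlate_segments(trace: IntensityTrace, pair: str,
                       segment_length: float = 10.0,
                       report: SegmentScreenReport | None = None,
                       m: int = 16,
                       max_lag: float | None = None) -> CorrelationCurve:
    """Per-kept-segment correlation averaged into one curve with per-lag sd.

    Correlating segments independently and averaging (rather than
    concatenating, which would create artificial seams) also yields the
    lag-wise standard deviation used for weighting in model fits.
    """
    bins_per_seg = int(round(segment_length / trace.dt))
    n_seg = len(trace) // bins_per_seg
    indices = range(n_seg) if report is None else report.kept_indices
    curves = []
    for i in indices:
        sl = slice(i * bins_per_seg, (i + 1) * bins_per_seg)
        sub = IntensityTrace(trace.dt, trace.counts_green[sl],
                             trace.counts_red[sl])
        if pair == "GR":
            curves.append(crosscorrelate(sub, m=m, max_lag=max_lag))
        else:
            curves.append(autocorrelate(sub, channel=pair[0], m=m,
                                        max_lag=max_lag))
    if not curves:
        raise ValueError("no kept segments to correlate")
    return average_curves(curves)


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Average correlation curves sharing a lag grid; attach per-lag sd."""
    ref = curves[0]
    for c in curves[1:]:
        if c.pair != ref.pair or len(c.lags) != len(ref.lags) or \
                not np.allclose(c.lags, ref.lags):
            raise ValueError("curves must share pair and lag grid")
    stack = np.vstack([c.values for c in curves])
    sd = stack.std(axis=0, ddof=1) if len(curves) >= 2 else None
    total_time = sum(c.metadata.get("duration_s", 0.0) for c in curves)
    return CorrelationCurve(
        ref.pair, ref.lags.copy(), stack.mean(axis=0),
        np.sum([c.n_samples for c in curves], axis=0), sd,
        metadata={"n_segments": len(curves), "duration_s": total_time})
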