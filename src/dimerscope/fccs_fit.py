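"""Two-color membrane FCCS correlation model and global fitting.

The model describes three species (green-only g, red-only r, dual-labeled
gr) diffusing in 2D, observed through two laterally displaced Gaussian
detection areas, with green→red spectral crosstalk K, per-channel
backgrounds, and absorption cross-section ratios x_g/x_r that account for
single-color species carrying one or two labels:

    G_G(τ)−1  = A_G (x_g² c_g Diff_g^G + c_gr Diff_gr^G)
                / (A_G (x_g c_g + c_gr) + BG_G)²
    G_R(τ)−1  = [A_R (x_r² c_r Diff_r^R + c_gr Diff_gr^R)
                 + 2 (A_G A_R / A_GR) K c_gr Displ·Diff_gr^GR
                 + A_G K² (x_g² c_g Diff_g^G + c_gr Diff_gr^G)]
                / (A_R (x_r c_r + c_gr) + A_G K (x_g c_g + c_gr) + BG_R)²
    G_GR(τ)−1 = [(A_G A_R / A_GR) c_gr Displ·Diff_gr^GR
                 + A_G K (x_g² c_g Diff_g^G + c_gr Diff_gr^G)]
                / [(A_G (x_g c_g + c_gr) + BG_G)
                   · (A_R (x_r c_r + c_gr) + A_G K (x_g c_g + c_gr) + BG_R)]

with 2D diffusion factors Diff_u^G = (1 + 4 D_u τ/ω_G²)⁻¹ (ω_R² for the red
channel, (ω_G²+ω_R²)/2 for the cross term) and the focus-displacement
function Displ(τ) = exp(−2 r₀²/(ω_G² + ω_R² + 8 D_gr τ)). All brightness
factors cancel in these ratios; the background parameters are therefore
expressed in area×concentration equivalents (BG = 2·rate/q for a background
count rate and per-label peak brightness q).

Fitting follows a two-step procedure: control measurements (no dual-labeled
species) determine the crosstalk parameter K for each x_g/x_r combination;
dimerization measurements are then fitted with K fixed to the control
median and r₀ restricted to its calibration band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .ffs_sim import DetectionGeometry, SpeciesModel
from .correlate import CorrelationCurve

__all__ = [
    "FccsFit",
    "TauDFit",
    "QcVerdict",
    "diffusion_factor",
    "displacement_factor",
    "model_correlations",
    "fit_control",
    "fit_dimerization",
    "fit_fcs_tauD",
    "apply_qc",
    "qc_verdict",
    "median_k",
]

PAIRS = ("GG", "RR", "GR")


def diffusion_factor(tau, d: float, omega_sq: float):
    """2D diffusion factor Diff(τ) = (1 + 4·D·τ/ω²)⁻¹; equals 1/2 at the
    transit time τ = ω²/(4D)."""
    return 1.0 / (1.0 + 4.0 * d * np.asarray(tau) / omega_sq)


def displacement_factor(tau, geom: DetectionGeometry, d_gr: float):
    """Focus-displacement function Displ(τ) = exp(−2r₀²/(ω_G²+ω_R²+8·D·τ));
    identically 1 for perfectly overlapping foci (r₀ = 0), and
    non-decreasing in τ (diffusion bridges the displacement)."""
    wg2, wr2 = geom.omega_g**2, geom.omega_r**2
    return np.exp(-2.0 * geom.r0**2 /
                  (wg2 + wr2 + 8.0 * d_gr * np.asarray(tau)))


def model_correlations(species: SpeciesModel, geom: DetectionGeometry,
                       lags: np.ndarray) -> dict[str, np.ndarray]:
    """Evaluate the three model curves G(τ)−1 on a lag grid (seconds)."""
    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0):
        raise ValueError("lags must be positive")
    if species.c_g == 0 and species.c_r == 0 and species.c_gr == 0:
        raise ValueError("all species concentrations are zero; "
                         "amplitudes undefined")
    a_g, a_r, a_gr = geom.area_g, geom.area_r, geom.area_gr
    wg2, wr2 = geom.omega_g**2, geom.omega_r**2
    c_g, c_r, c_gr = species.c_g, species.c_r, species.c_gr
    x_g, x_r = species.x_g, species.x_r
    k = species.k_crosstalk
    bg_g, bg_r = species.bg_g, species.bg_r

    diff_g_G = diffusion_factor(lags, species.d_g, wg2)
    diff_gr_G = diffusion_factor(lags, species.d_gr, wg2)
    diff_r_R = diffusion_factor(lags, species.d_r, wr2)
    diff_gr_R = diffusion_factor(lags, species.d_gr, wr2)
    diff_gr_GR = diffusion_factor(lags, species.d_gr, (wg2 + wr2) / 2.0)
    displ = displacement_factor(lags, geom, species.d_gr)

    green_fluct = x_g**2 * c_g * diff_g_G + c_gr * diff_gr_G
    i_green = a_g * (x_g * c_g + c_gr) + bg_g
    i_red = a_r * (x_r * c_r + c_gr) + a_g * k * (x_g * c_g + c_gr) + bg_r

    # a channel with no signal at all carries no correlation
    zeros = np.zeros_like(lags)
    cross_codiff = (a_g * a_r / a_gr) * c_gr * displ * diff_gr_GR
    gg = a_g * green_fluct / i_green**2 if i_green > 0 else zeros
    rr = (a_r * (x_r**2 * c_r * diff_r_R + c_gr * diff_gr_R)
          + 2.0 * k * cross_codiff + a_g * k**2 * green_fluct) / i_red**2 \
        if i_red > 0 else zeros
    gr = (cross_codiff + a_g * k * green_fluct) / (i_green * i_red) \
        if i_green > 0 and i_red > 0 else zeros
    return {"GG": gg, "RR": rr, "GR": gr}


# ---------------------------------------------------------------------------
# Global least-squares machinery
# ---------------------------------------------------------------------------

def _species_from_params(p, x_g: int, x_r: int) -> SpeciesModel:
    return SpeciesModel(
        c_g=p["c_g"].value, c_r=p["c_r"].value, c_gr=p["c_gr"].value,
        d_g=p["d_g"].value, d_r=p["d_r"].value, d_gr=p["d_gr"].value,
        x_g=x_g, x_r=x_r, k_crosstalk=p["k"].value,
        bg_g=p["bg_g"].value, bg_r=p["bg_r"].value)


def _geom_from_params(p, geom: DetectionGeometry) -> DetectionGeometry:
    return DetectionGeometry(geom.omega_g, geom.omega_r, p["r0"].value)


def _as_curve_dict(curves) -> dict[str, CorrelationCurve]:
    if isinstance(curves, dict):
        d = dict(curves)
    else:
        d = {c.pair: c for c in curves}
    missing = [p for p in PAIRS if p not in d]
    if missing:
        raise ValueError(f"missing correlation curves: {missing}")
    return d


def _curve_weights(curve: CorrelationCurve) -> np.ndarray:
    """1/sd weights when segment scatter is available (>= 3 segments),
    uniform otherwise."""
    if curve.sd is not None and curve.metadata.get("n_segments", 0) >= 3:
        sd = np.where(curve.sd > 0, curve.sd, np.nan)
        floor = np.nanmedian(sd)
        if np.isfinite(floor) and floor > 0:
            return 1.0 / np.where(np.isnan(sd), floor, np.maximum(sd, 0.1 * floor))
    return np.ones_like(curve.values)


def _amplitude_guess(curve: CorrelationCurve) -> tuple[float, float]:
    """Crude (amplitude, half-decay lag) read from a curve for starting
    values; smoothing over the first lags suppresses shot noise."""
    v = curve.values
    head = float(np.median(v[: min(8, len(v))]))
    amp = max(head, 1e-4)
    below = np.nonzero(v < amp / 2.0)[0]
    tau_half = curve.lags[below[0]] if below.size else curve.lags[-1] / 4.0
    return amp, float(tau_half)


@dataclass
class FccsFit:
    """Result of a global three-curve fit."""

    species: SpeciesModel
    geom: DetectionGeometry
    stderr: dict[str, float]
    r_squared: dict[str, float]
    residuals: dict[str, np.ndarray]
    chisqr: float
    success: bool
    message: str = ""
    x_combination: tuple[int, int] = (1, 1)
    cpm_khz: dict[str, float] = field(default_factory=dict)
    qc: "QcVerdict | None" = None
    flags: list[str] = field(default_factory=list)

    @property
    def k_crosstalk(self) -> float:
        return self.species.k_crosstalk

    def tau_d_ms(self, species: str = "gr", channel: str = "G") -> float:
        """Transit time ω²/(4D) of one species through one focus (ms)."""
        d = getattr(self.species, f"d_{species}")
        w = self.geom.omega_g if channel.upper() == "G" else self.geom.omega_r
        return 1e3 * w**2 / (4.0 * d)

    def particle_numbers(self) -> dict[str, float]:
        """Mean particle numbers in the effective detection areas."""
        return {
            "N_g": self.geom.area_g * self.species.c_g,
            "N_r": self.geom.area_r * self.species.c_r,
            "N_gr": self.geom.area_gr * self.species.c_gr,
        }

    def dimer_fraction(self) -> float:
        """Fitted c_gr as a fraction of all diffusing units."""
        s = self.species
        total = s.c_g + s.c_r + s.c_gr
        return s.c_gr / total if total > 0 else math.nan

    def amplitudes(self) -> dict[str, float]:
        """Model amplitudes G(0⁺)−1 (evaluated at a 1 µs lag)."""
        m = model_correlations(self.species, self.geom, np.array([1e-6]))
        return {p: float(m[p][0]) for p in PAIRS}

    def compute_cpm(self, mean_rates: tuple[float, float],
                    bg_rates: tuple[float, float] = (0.0, 0.0)) -> dict[str, float]:
        """Counts per molecule (kHz) per channel: (rate − background)
        divided by the particle number implied by the fitted amplitude."""
        amps = self.amplitudes()
        out = {}
        for ch, rate, bg, pair in (("G", mean_rates[0], bg_rates[0], "GG"),
                                   ("R", mean_rates[1], bg_rates[1], "RR")):
            n_eff = 1.0 / amps[pair] if amps[pair] > 0 else math.inf
            out[ch] = (rate - bg) / n_eff / 1000.0 if math.isfinite(n_eff) else 0.0
        self.cpm_khz = out
        return out


def _global_fit(curve_dict, geom, x_g, x_r, vary, fixed, r0_bounds,
                n_starts=5):
    """Multi-start global least-squares fit of the model to three curves."""
    data = {p: curve_dict[p] for p in PAIRS}
    weights = {p: _curve_weights(data[p]) for p in PAIRS}

    amp_gg, tau_g = _amplitude_guess(data["GG"])
    amp_rr, tau_r = _amplitude_guess(data["RR"])
    c_tot_g = max(1.0 / (geom.area_g * amp_gg), 1e-3)
    c_tot_r = max(1.0 / (geom.area_r * amp_rr), 1e-3)
    d_g0 = geom.omega_g**2 / (4.0 * max(tau_g, 1e-4))
    d_r0 = geom.omega_r**2 / (4.0 * max(tau_r, 1e-4))

    def make_params(c_scale, d_scale, gr_frac, k_start):
        p = lmfit.Parameters()
        c_gr0 = fixed.get("c_gr", gr_frac * min(c_tot_g, c_tot_r))
        p.add("c_g", value=max((c_tot_g - c_gr0) * c_scale / x_g, 1e-4),
              min=0.0, vary="c_g" in vary)
        p.add("c_r", value=max((c_tot_r - c_gr0) * c_scale / x_r, 1e-4),
              min=0.0, vary="c_r" in vary)
        p.add("c_gr", value=c_gr0, min=0.0, vary="c_gr" in vary)
        p.add("d_g", value=d_g0 * d_scale, min=1e-4, max=100.0,
              vary="d_g" in vary)
        p.add("d_r", value=d_r0 * d_scale, min=1e-4, max=100.0,
              vary="d_r" in vary)
        p.add("d_gr", value=fixed.get("d_gr", min(d_g0, d_r0) * d_scale),
              min=1e-4, max=100.0, vary="d_gr" in vary)
        p.add("r0", value=fixed.get("r0", np.mean(r0_bounds)),
              min=r0_bounds[0], max=r0_bounds[1], vary="r0" in vary)
        p.add("k", value=fixed.get("k", k_start), min=0.0, max=0.999,
              vary="k" in vary)
        p.add("bg_g", value=fixed.get("bg_g", 0.0), min=0.0,
              vary="bg_g" in vary)
        p.add("bg_r", value=fixed.get("bg_r", 0.0), min=0.0,
              vary="bg_r" in vary)
        return p

    def residual(p):
        species = _species_from_params(p, x_g, x_r)
        g = _geom_from_params(p, geom)
        if species.c_g == species.c_r == species.c_gr == 0:
            return np.full(sum(len(data[q].lags) for q in PAIRS), 1e6)
        parts = []
        for q in PAIRS:
            model = model_correlations(species, g, data[q].lags)[q]
            parts.append((model - data[q].values) * weights[q])
        return np.concatenate(parts)

    starts = [(1.0, 1.0, 0.3, 0.05), (1.0, 0.3, 0.3, 0.0),
              (1.0, 3.0, 0.3, 0.15), (0.5, 1.0, 0.8, 0.05),
              (2.0, 1.0, 0.05, 0.02)][:max(n_starts, 1)]
    best = None
    for c_scale, d_scale, gr_frac, k_start in starts:
        try:
            with warnings.catch_warnings():
                # singular covariance on boundary solutions is expected
                warnings.simplefilter("ignore", RuntimeWarning)
                res = lmfit.minimize(
                    residual, make_params(c_scale, d_scale, gr_frac, k_start),
                    method="least_squares", x_scale="jac")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    flags = []
    if best is None:
        raise RuntimeError("all fit starts failed")
    if not best.success:
        flags.append("non_convergence")

    p = best.params
    species = _species_from_params(p, x_g, x_r)
    g = _geom_from_params(p, geom)
    r2 = {}
    resid = {}
    for q in PAIRS:
        mq = model_correlations(species, g, data[q].lags)[q]
        rq = data[q].values - mq
        resid[q] = rq
        ss_tot = float(((data[q].values - data[q].values.mean())**2).sum())
        r2[q] = 1.0 - float((rq**2).sum()) / ss_tot if ss_tot > 0 else math.nan
    stderr = {name: (p[name].stderr if p[name].stderr is not None else math.nan)
              for name in p if p[name].vary}
    return FccsFit(species=species, geom=g, stderr=stderr, r_squared=r2,
                   residuals=resid, chisqr=float(best.chisqr),
                   success=bool(best.success), message=best.message or "",
                   x_combination=(x_g, x_r), flags=flags)


def fit_control(curves, geom: DetectionGeometry,
                x_choices=((1, 1), (1, 2), (2, 1), (2, 2)),
                backgrounds: tuple[float, float] = (0.0, 0.0),
                n_starts: int = 5,
                check_misspecification: bool = True) -> list[FccsFit]:
    """Step 1 of the two-step procedure: control fits with c_gr ≡ 0.

    Control measurements come from cells expressing two non-interacting
    constructs (no dual-labeled complex), so the cross-correlation is pure
    crosstalk and identifies K. The detection radii are fixed to their
    solution-calibration values; c_g, c_r, D_g, D_r and K vary. One fit per
    x_g/x_r combination is returned (the combinations correspond to the
    single-color species being monomeric or homodimeric). With c_gr fixed
    at zero, r₀ and D_gr do not enter the model and are held fixed.

    If the control cross-correlation shows structure beyond crosstalk (a
    dual-labeled species leaked into the control), the fit is flagged with
    ``control_misspecified``. Detection refits with c_gr free: a large
    relative drop in the residual sum of squares together with a
    non-negligible fitted dual-labeled fraction indicates that the
    c_gr ≡ 0 restriction is inconsistent with the data.
    """
    curve_dict = _as_curve_dict(curves)
    fits = []
    for x_g, x_r in x_choices:
        fit = _global_fit(
            curve_dict, geom, x_g, x_r,
            vary={"c_g", "c_r", "d_g", "d_r", "k"},
            fixed={"c_gr": 0.0, "r0": geom.r0, "d_gr": 0.235,
                   "bg_g": backgrounds[0], "bg_r": backgrounds[1]},
            r0_bounds=(0.0, 0.5), n_starts=n_starts)
        if check_misspecification and fit.chisqr > 1e-12:
            alt = _global_fit(
                curve_dict, geom, x_g, x_r,
                vary={"c_g", "c_r", "c_gr", "d_g", "d_r", "d_gr", "k", "r0"},
                fixed={"bg_g": backgrounds[0], "bg_r": backgrounds[1]},
                r0_bounds=(0.05, 0.3), n_starts=3)
            s = alt.species
            total = s.c_g + s.c_r + s.c_gr
            improvement = (fit.chisqr - alt.chisqr) / fit.chisqr
            if improvement > 0.3 and total > 0 and s.c_gr / total > 0.05:
                fit.flags.append("control_misspecified")
        fits.append(fit)
    return fits


def median_k(control_fits: list[FccsFit]) -> dict[tuple[int, int], float]:
    """Median crosstalk parameter across control cells per x-combination."""
    if not control_fits:
        raise ValueError("no control fits provided")
    by_x: dict[tuple[int, int], list[float]] = {}
    for f in control_fits:
        by_x.setdefault(f.x_combination, []).append(f.k_crosstalk)
    return {x: float(np.median(v)) for x, v in by_x.items()}


def fit_dimerization(curves, geom: DetectionGeometry, k_fixed: float,
                     x: int = 2, r0_bounds: tuple[float, float] = (0.100, 0.150),
                     backgrounds: tuple[float, float] = (0.0, 0.0),
                     n_starts: int = 5) -> FccsFit:
    """Step 2: dimerization fit with K fixed to the control median.

    Concentrations of all three species and their diffusion coefficients
    vary; the focus displacement r₀ is restricted to its calibration band
    (100–150 nm by default, in µm units here). For a homodimerization
    experiment x_g = x_r = x: 1 treats single-color species as monomers,
    2 as double-labeled homodimers.
    """
    if not 0.0 <= k_fixed < 1.0:
        raise ValueError("fixed crosstalk parameter must be in [0, 1)")
    curve_dict = _as_curve_dict(curves)
    return _global_fit(
        curve_dict, geom, x, x,
        vary={"c_g", "c_r", "c_gr", "d_g", "d_r", "d_gr", "r0"},
        fixed={"k": k_fixed, "bg_g": backgrounds[0], "bg_r": backgrounds[1]},
        r0_bounds=r0_bounds, n_starts=n_starts)


# ---------------------------------------------------------------------------
# Single-component FCS transit-time fit
# ---------------------------------------------------------------------------

@dataclass
class TauDFit:
    tau_d: float
    g0: float
    tau_d_stderr: float
    g0_stderr: float
    success: bool
    r_squared: float
    message: str = ""

    @property
    def tau_d_ms(self) -> float:
        return 1e3 * self.tau_d


def fit_fcs_tauD(curve: CorrelationCurve, min_lag: float = 1e-3) -> TauDFit:
    """One-component 2D diffusion fit G(τ)−1 = G₀·(1 + τ/τ_D)⁻¹.

    Lags shorter than `min_lag` (default 1 ms, where afterpulsing and fast
    photophysics may contaminate the estimate) are excluded from the fit.
    """
    sub = curve.restrict(min_lag=min_lag)
    if len(sub.lags) < 5:
        raise ValueError("need at least 5 lags above min_lag")
    amp, tau_half = _amplitude_guess(sub)
    weights = _curve_weights(sub)

    params = lmfit.Parameters()
    params.add("g0", value=amp, min=0.0)
    params.add("tau_d", value=max(tau_half, sub.lags[0]), min=sub.lags[0] / 100,
               max=sub.lags[-1] * 100)

    def residual(p):
        model = p["g0"].value / (1.0 + sub.lags / p["tau_d"].value)
        return (model - sub.values) * weights

    res = lmfit.minimize(residual, params, method="least_squares")
    p = res.params
    model = p["g0"].value / (1.0 + sub.lags / p["tau_d"].value)
    ss_tot = float(((sub.values - sub.values.mean())**2).sum())
    r2 = 1.0 - float(((sub.values - model)**2).sum()) / ss_tot \
        if ss_tot > 0 else math.nan
    return TauDFit(
        tau_d=float(p["tau_d"].value), g0=float(p["g0"].value),
        tau_d_stderr=float(p["tau_d"].stderr) if p["tau_d"].stderr else math.nan,
        g0_stderr=float(p["g0"].stderr) if p["g0"].stderr else math.nan,
        success=bool(res.success), r_squared=r2, message=res.message or "")


# ---------------------------------------------------------------------------
# Quality-control screen
# ---------------------------------------------------------------------------

@dataclass
class QcVerdict:
    included: bool
    reasons: list[str] = field(default_factory=list)


def qc_verdict(total_time_s: float, tau_d_ms, r_squared, cpm_g_khz: float,
               cpm_r_khz: float,
               time_range: tuple[float, float] = (20.0, 80.0),
               tau_range_ms: tuple[float, float] = (1.0, 150.0),
               r2_range: tuple[float, float] = (0.9, 1.0),
               cpm_range_khz: tuple[float, float] = (0.2, 2.5),
               ratio_range: tuple[float, float] = (0.5, 2.5)) -> QcVerdict:
    """Measurement-level inclusion screen.

    Included iff the total screened acquisition time lies in 20–80 s, every
    single-species transit time in 1–150 ms, every per-curve R² in 0.9–1,
    both channel brightnesses in 0.2–2.5 kHz/molecule, and the green/red
    brightness ratio in 0.5–2.5. Each failing criterion contributes a
    reason code.
    """
    reasons = []
    if not time_range[0] <= total_time_s <= time_range[1]:
        reasons.append("measurement_time")
    taus = np.atleast_1d(np.asarray(tau_d_ms, dtype=float))
    if np.any(taus < tau_range_ms[0]) or np.any(taus > tau_range_ms[1]):
        reasons.append("transit_time")
    r2s = np.asarray(list(r_squared.values()) if isinstance(r_squared, dict)
                     else np.atleast_1d(r_squared), dtype=float)
    if np.any(r2s < r2_range[0]) or np.any(r2s > r2_range[1]):
        reasons.append("goodness_of_fit")
    for cpm in (cpm_g_khz, cpm_r_khz):
        if not cpm_range_khz[0] <= cpm <= cpm_range_khz[1]:
            reasons.append("brightness")
            break
    ratio = cpm_g_khz / cpm_r_khz if cpm_r_khz > 0 else math.inf
    if not ratio_range[0] <= ratio <= ratio_range[1]:
        reasons.append("brightness_ratio")
    return QcVerdict(not reasons, reasons)


def apply_qc(fit: FccsFit, total_time_s: float, curves=None,
             **kwargs) -> QcVerdict:
    """Attach the inclusion verdict for a fitted measurement to the fit.

    The exclusion criteria are evaluated on single-species fits of the
    autocorrelation curves: when `curves` (the measurement's GG/RR curves)
    is given, τ_D and R² come from one-component fits of those curves; when
    omitted they fall back to the global fit's diffusion coefficients
    (ω²/4D for species actually present) and per-curve R². Brightness
    values must have been set via `FccsFit.compute_cpm`.
    """
    if curves is not None:
        curve_dict = _as_curve_dict(curves) if not isinstance(curves, dict) \
            else curves
        taus, r2 = [], {}
        for pair in ("GG", "RR"):
            single = fit_fcs_tauD(curve_dict[pair])
            taus.append(single.tau_d_ms)
            r2[pair] = single.r_squared
    else:
        taus = []
        if fit.species.c_g > 0:
            taus.append(fit.tau_d_ms("g", "G"))
        if fit.species.c_r > 0:
            taus.append(fit.tau_d_ms("r", "R"))
        if fit.species.c_gr > 0:
            taus.append(fit.tau_d_ms("gr", "G"))
        r2 = fit.r_squared
    cpm_g = fit.cpm_khz.get("G", math.nan)
    cpm_r = fit.cpm_khz.get("R", math.nan)
    verdict = qc_verdict(total_time_s, taus, r2, cpm_g, cpm_r, **kwargs)
    fit.qc = verdict
    return verdict
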