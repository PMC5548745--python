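"""Unit tests of the correlation model and the two-step fitting procedure."""

import numpy as np
import pytest

import dimerscope as ds
from dimerscope.correlate import CorrelationCurve
from dimerscope.fccs_fit import (diffusion_factor, displacement_factor,
                                 model_correlations, fit_control,
                                 fit_dimerization, fit_fcs_tauD, median_k,
                                 qc_verdict)

LAGS = np.geomspace(5e-4, 1.0, 100)


def _noiseless_curves(species, geom, lags=LAGS):
    m = model_correlations(species, geom, lags)
    return {p: CorrelationCurve(p, lags, m[p], np.ones(len(lags)))
            for p in ("GG", "RR", "GR")}


class TestModelIdentities:
    def test_displacement_is_unity_for_overlapping_foci(self, geom_overlap):
        assert np.all(displacement_factor(LAGS, geom_overlap, 0.3) == 1.0)

    def test_displacement_nondecreasing_in_lag(self, geom):
        d = displacement_factor(LAGS, geom, 0.3)
        assert np.all(np.diff(d) >= 0)
        assert np.all(d <= 1.0)

    def test_diffusion_factor_half_at_transit_time(self):
        omega_sq = 0.222**2
        tau_d = omega_sq / (4.0 * 0.3)
        assert diffusion_factor(tau_d, 0.3, omega_sq) == pytest.approx(0.5)

    def test_diffusion_factor_strictly_decreasing(self):
        d = diffusion_factor(LAGS, 0.3, 0.222**2)
        assert np.all(np.diff(d) < 0)

    def test_single_species_amplitude_and_null_cross(self, geom_overlap):
        """100 molecules/µm² seen through a 222 nm focus: amplitude
        1/(π·0.222²·100) ≈ 0.0646; no dual-labeled species, no crosstalk ⇒
        cross-correlation identically zero."""
        species = ds.SpeciesModel(c_g=100.0, c_r=1e-9, d_g=0.3)
        m = model_correlations(species, geom_overlap, np.array([1e-9, 1e-3]))
        assert m["GG"][0] == pytest.approx(1.0 / (np.pi * 0.222**2 * 100.0),
                                           rel=1e-6)
        np.testing.assert_allclose(m["GR"], 0.0, atol=1e-18)

    def test_gg_curve_strictly_decreasing(self, geom):
        species = ds.SpeciesModel(c_g=50.0, d_g=0.41)
        m = model_correlations(species, geom, LAGS)
        assert np.all(np.diff(m["GG"]) < 0)

    def test_background_strictly_suppresses_amplitude(self, geom):
        amps = []
        for bg in (0.0, 5.0, 10.0):
            species = ds.SpeciesModel(c_g=50.0, d_g=0.41, bg_g=bg)
            amps.append(model_correlations(species, geom,
                                           np.array([1e-6]))["GG"][0])
        assert amps[0] > amps[1] > amps[2]

    def test_displacement_scales_cross_amplitude(self, geom, geom_overlap):
        species = ds.SpeciesModel(c_gr=40.0, d_gr=0.235)
        tiny = np.array([1e-9])
        with_displ = model_correlations(species, geom, tiny)["GR"][0]
        no_displ = model_correlations(species, geom_overlap, tiny)["GR"][0]
        expected = np.exp(-2.0 * geom.r0**2 /
                          (geom.omega_g**2 + geom.omega_r**2))
        assert with_displ / no_displ == pytest.approx(expected, rel=1e-6)

    def test_all_zero_concentrations_rejected(self, geom):
        with pytest.raises(ValueError, match="zero"):
            model_correlations(ds.SpeciesModel(), geom, LAGS)

    def test_nonpositive_lags_rejected(self, geom):
        with pytest.raises(ValueError, match="positive"):
            model_correlations(ds.SpeciesModel(c_g=1.0), geom,
                               np.array([0.0, 1e-3]))


class TestLocalOptimality:
    def test_truth_beats_perturbed_parameters_on_noiseless_curves(self, geom):
        truth = ds.SpeciesModel(c_g=30.0, c_r=25.0, c_gr=40.0, d_g=0.41,
                                d_r=0.41, d_gr=0.235, k_crosstalk=0.05)
        curves = _noiseless_curves(truth, geom)

        def objective(species):
            m = model_correlations(species, geom, LAGS)
            return sum(float(((m[p] - curves[p].values)**2).sum())
                       for p in ("GG", "RR", "GR"))

        base = objective(truth)
        import dataclasses
        for field, delta in [("c_g", 3.0), ("c_gr", -4.0), ("d_gr", 0.05),
                             ("k_crosstalk", 0.02)]:
            perturbed = dataclasses.replace(
                truth, **{field: getattr(truth, field) + delta})
            assert objective(perturbed) > base


class TestControlFit:
    def test_noiseless_control_recovers_crosstalk_exactly(self, geom):
        truth = ds.SpeciesModel(c_g=80.0, c_r=60.0, d_g=0.41, d_r=0.41,
                                k_crosstalk=0.05)
        fit = fit_control(_noiseless_curves(truth, geom), geom,
                          x_choices=[(1, 1)])[0]
        assert fit.k_crosstalk == pytest.approx(0.05, abs=1e-4)
        assert fit.species.c_g == pytest.approx(80.0, rel=1e-3)
        assert fit.species.c_r == pytest.approx(60.0, rel=1e-3)
        assert not fit.flags

    def test_zero_crosstalk_not_inflated(self, geom):
        truth = ds.SpeciesModel(c_g=80.0, c_r=60.0, d_g=0.41, d_r=0.41)
        fit = fit_control(_noiseless_curves(truth, geom), geom,
                          x_choices=[(1, 1)])[0]
        assert fit.k_crosstalk < 1e-3

    def test_injected_dimer_species_raises_diagnostic_flag(self, geom):
        truth = ds.SpeciesModel(c_g=60.0, c_r=50.0, c_gr=30.0, d_g=0.41,
                                d_r=0.41, d_gr=0.235, k_crosstalk=0.05)
        fit = fit_control(_noiseless_curves(truth, geom), geom,
                          x_choices=[(1, 1)])[0]
        assert "control_misspecified" in fit.flags

    def test_one_fit_per_x_combination(self, geom):
        truth = ds.SpeciesModel(c_g=40.0, c_r=40.0, d_g=0.41, d_r=0.41,
                                k_crosstalk=0.05)
        fits = fit_control(_noiseless_curves(truth, geom), geom,
                           check_misspecification=False)
        assert [f.x_combination for f in fits] == [(1, 1), (1, 2), (2, 1),
                                                   (2, 2)]


class TestDimerizationFit:
    def test_noiseless_mixture_recovered(self, geom):
        truth = ds.SpeciesModel(c_g=12.5, c_r=12.5, c_gr=25.0, d_g=0.235,
                                d_r=0.235, d_gr=0.235, x_g=2, x_r=2,
                                k_crosstalk=0.05)
        fit = fit_dimerization(_noiseless_curves(truth, geom), geom,
                               k_fixed=0.05, x=2)
        assert fit.dimer_fraction() == pytest.approx(0.5, abs=0.01)
        assert fit.species.c_gr == pytest.approx(25.0, rel=0.05)

    def test_invalid_fixed_crosstalk_rejected(self, geom):
        truth = ds.SpeciesModel(c_gr=30.0, d_gr=0.235)
        with pytest.raises(ValueError, match="crosstalk"):
            fit_dimerization(_noiseless_curves(truth, geom), geom,
                             k_fixed=1.5)

    def test_missing_curve_rejected(self, geom):
        truth = ds.SpeciesModel(c_gr=30.0, d_gr=0.235)
        curves = _noiseless_curves(truth, geom)
        del curves["GR"]
        with pytest.raises(ValueError, match="GR"):
            fit_dimerization(curves, geom, k_fixed=0.05)


class TestMedianK:
    def test_median_per_combination(self, geom):
        truth = ds.SpeciesModel(c_g=40.0, c_r=40.0, d_g=0.41, d_r=0.41,
                                k_crosstalk=0.05)
        curves = _noiseless_curves(truth, geom)
        fits = fit_control(curves, geom, x_choices=[(1, 1)],
                           check_misspecification=False) * 3
        med = median_k(fits)
        assert set(med) == {(1, 1)}
        assert med[(1, 1)] == pytest.approx(0.05, abs=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_k([])


class TestSingleComponentFit:
    def _curve(self, tau_d=0.030, g0=0.05, lags=None):
        lags = LAGS if lags is None else lags
        return CorrelationCurve("GG", lags, g0 / (1.0 + lags / tau_d),
                                np.ones(len(lags)))

    def test_noiseless_transit_time_recovered(self):
        fit = fit_fcs_tauD(self._curve())
        assert fit.tau_d_ms == pytest.approx(30.0, rel=1e-3)
        assert fit.g0 == pytest.approx(0.05, rel=1e-3)

    def test_short_lag_contamination_excluded(self):
        clean = self._curve()
        contaminated = CorrelationCurve(
            "GG", clean.lags,
            clean.values + 0.5 * (clean.lags < 1e-3), clean.n_samples)
        fit_clean = fit_fcs_tauD(clean, min_lag=1e-3)
        fit_dirty = fit_fcs_tauD(contaminated, min_lag=1e-3)
        assert fit_dirty.tau_d == pytest.approx(fit_clean.tau_d, rel=1e-9)

    def test_too_few_lags_rejected(self):
        short = self._curve(lags=np.array([2e-3, 3e-3, 4e-3]))
        with pytest.raises(ValueError, match="5 lags"):
            fit_fcs_tauD(short)


class TestQualityControl:
    BASE = dict(total_time_s=40.0, tau_d_ms=50.0, r_squared=0.95,
                cpm_g_khz=1.0, cpm_r_khz=1.0)

    def test_all_criteria_inside_ranges_included(self):
        verdict = qc_verdict(**self.BASE)
        assert verdict.included and not verdict.reasons

    @pytest.mark.parametrize("override,reason", [
        (dict(tau_d_ms=0.5), "transit_time"),
        (dict(tau_d_ms=200.0), "transit_time"),
        (dict(cpm_g_khz=0.1), "brightness"),
        (dict(cpm_g_khz=3.0), "brightness"),
        (dict(total_time_s=10.0), "measurement_time"),
        (dict(total_time_s=90.0), "measurement_time"),
        (dict(r_squared=0.8), "goodness_of_fit"),
        (dict(cpm_g_khz=0.4), "brightness_ratio"),
    ])
    def test_each_violation_carries_reason_code(self, override, reason):
        params = dict(self.BASE)
        params.update(override)
        verdict = qc_verdict(**params)
        assert not verdict.included
        assert reason in verdict.reasons

    def test_screen_is_deterministic(self):
        a = qc_verdict(**self.BASE)
        b = qc_verdict(**self.BASE)
        assert a.included == b.included and a.reasons == b.reasons

    def test_multiple_transit_times_all_checked(self):
        params = dict(self.BASE)
        params["tau_d_ms"] = [50.0, 0.5]
        assert "transit_time" in qc_verdict(**params).reasons
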