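"""Unit tests of the synthetic-data generator."""

import numpy as np
import pytest

import dimerscope as ds
from dimerscope.ffs_sim import _simulate_with_counts


class TestMembraneTraces:
    def test_background_only_trace_is_poisson(self, geom):
        model = ds.SpeciesModel(bg_g=1000.0, bg_r=400.0)
        tr = ds.simulate_membrane_traces(model, geom, duration=10.0, dt=1e-3,
                                         box_size=4.0, seed=3)
        assert len(tr) == 10000
        assert abs(tr.counts_green.mean() - 1.0) < 0.05
        assert abs(tr.counts_red.mean() - 0.4) < 0.03
        for counts in (tr.counts_green, tr.counts_red):
            ratio = counts.var() / counts.mean()
            assert 0.9 < ratio < 1.1

    def test_same_seed_bitwise_identical(self, geom):
        model = ds.SpeciesModel(c_g=20.0, c_gr=10.0, bg_g=100.0)
        a = ds.simulate_membrane_traces(model, geom, 2.0, 1e-3, 3.0, seed=9)
        b = ds.simulate_membrane_traces(model, geom, 2.0, 1e-3, 3.0, seed=9)
        c = ds.simulate_membrane_traces(model, geom, 2.0, 1e-3, 3.0, seed=10)
        assert np.array_equal(a.counts_green, b.counts_green)
        assert np.array_equal(a.counts_red, b.counts_red)
        assert not np.array_equal(a.counts_green, c.counts_green)

    def test_intensity_matches_direct_profile_sum(self, geom):
        """The kernel's per-bin intensity equals the brightness-weighted
        Gaussian profile sum over the recorded particle positions."""
        model = ds.SpeciesModel(c_g=3.0, c_r=2.0, c_gr=2.0,
                                k_crosstalk=0.05)
        box = 2.5
        tr, internals = ds.simulate_membrane_traces(
            model, geom, duration=0.1, dt=5e-4, box_size=box, seed=21,
            return_internals=True)
        pos = internals["positions"]
        bg_, br_ = internals["brightness_green"], internals["brightness_red"]
        half = box / 2.0
        dx = pos[:, :, 0] - half
        dy = pos[:, :, 1] - half
        expect_g = (bg_ * np.exp(-2.0 * (dx**2 + dy**2) / geom.omega_g**2)
                    ).sum(axis=1)
        dxr = dx - geom.r0
        expect_r = (br_ * np.exp(-2.0 * (dxr**2 + dy**2) / geom.omega_r**2)
                    ).sum(axis=1)
        np.testing.assert_allclose(internals["signal_green"], expect_g,
                                   rtol=1e-10)
        np.testing.assert_allclose(internals["signal_red"], expect_r,
                                   rtol=1e-10)

    @pytest.mark.parametrize("kwargs,match", [
        (dict(duration=-1.0), "positive"),
        (dict(dt=0.0), "positive"),
        (dict(dt=2.0, duration=2.0), "2 bins"),
        (dict(box_size=1.0), "too small"),
    ])
    def test_invalid_inputs_rejected(self, geom, kwargs, match):
        params = dict(duration=1.0, dt=1e-3, box_size=4.0, seed=0)
        params.update(kwargs)
        with pytest.raises(ValueError, match=match):
            ds.simulate_membrane_traces(ds.SpeciesModel(c_g=1.0), geom,
                                        **params)

    def test_fixed_counts_override(self, geom):
        tr = _simulate_with_counts(ds.SpeciesModel(c_g=1.0), geom, 0.5, 1e-3,
                                   3.0, 0, (5, 2, 3))
        assert tr.metadata["n_particles"] == {"g": 5, "r": 2, "gr": 3}


class TestSpeciesModelValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(c_g=-1.0), dict(d_g=0.0), dict(x_g=3), dict(k_crosstalk=1.0),
        dict(bg_r=-5.0),
    ])
    def test_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ds.SpeciesModel(**kwargs)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            ds.DetectionGeometry(omega_g=0.0)
        with pytest.raises(ValueError):
            ds.DetectionGeometry(r0=-0.1)
        g = ds.DetectionGeometry()
        assert g.area_gr >= min(g.area_g, g.area_r)


class TestDissociationSchedule:
    def test_piecewise_fraction(self):
        s = ds.DissociationSchedule(t_stim=0.0, f_min=0.4, t_min=100.0,
                                    t_recover=300.0)
        assert s.fraction_at(-10.0) == 1.0
        assert s.fraction_at(50.0) == pytest.approx(0.7)
        assert s.fraction_at(100.0) == pytest.approx(0.4)
        assert s.fraction_at(200.0) == pytest.approx(0.7)
        assert s.fraction_at(400.0) == 1.0

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            ds.DissociationSchedule(0.0, 1.5, 10.0, 20.0)
        with pytest.raises(ValueError):
            ds.DissociationSchedule(10.0, 0.5, 5.0, 20.0)


class TestDynamicExperiment:
    MODEL = ds.SpeciesModel(c_g=5.0, c_r=5.0, c_gr=20.0, d_gr=0.235)
    SCHED = ds.DissociationSchedule(t_stim=0.0, f_min=0.5, t_min=60.0,
                                    t_recover=240.0)

    def _run(self, geom, f_min=0.5, seed=4):
        sched = ds.DissociationSchedule(0.0, f_min, 60.0, 240.0)
        return ds.simulate_dynamic_experiment(
            self.MODEL, geom, sched, [-10.0, 30.0, 60.0, 120.0, 240.0],
            segment_length=0.5, n_segments_per_point=2, dt=1e-3,
            box_size=2.5, seed=seed)

    def test_label_conservation_exact(self, geom):
        meas = self._run(geom)
        greens = {m.counts[0] + m.counts[2] for m in meas}
        reds = {m.counts[1] + m.counts[2] for m in meas}
        assert len(greens) == 1 and len(reds) == 1

    def test_full_dissociation_empties_gr_pool(self, geom):
        meas = self._run(geom, f_min=0.0)
        at_min = [m for m in meas if m.time_s == 60.0][0]
        assert at_min.counts[2] == 0

    def test_noop_schedule_keeps_counts_constant(self, geom):
        meas = self._run(geom, f_min=1.0)
        assert len({m.counts for m in meas}) == 1

    def test_schedule_outside_span_rejected(self, geom):
        with pytest.raises(ValueError, match="span"):
            ds.simulate_dynamic_experiment(self.MODEL, geom, self.SCHED,
                                           [0.0, 10.0], box_size=2.5, seed=0)


class TestFrapGenerator:
    def test_full_recovery_reaches_prebleach(self):
        rec = ds.simulate_frap_record(1.0, k_fast=5.0, k_slow=1.0,
                                      noise_sd=0.0, acq_bleach_rate=0.0)
        ch = rec.channels["GFP"]
        assert ch.roi[-1] - ch.background[-1] == pytest.approx(100.0, rel=1e-6)

    def test_immobile_pool_stays_at_floor(self):
        rec = ds.simulate_frap_record(0.0, noise_sd=0.0, acq_bleach_rate=0.0)
        ch = rec.channels["GFP"]
        post = ch.roi[rec.bleach_index:] - ch.background[rec.bleach_index:]
        np.testing.assert_allclose(post, 20.0, rtol=1e-12)

    def test_half_recovery_plateau_is_midpoint(self):
        rec = ds.simulate_frap_record(0.5, k_fast=5.0, k_slow=2.0,
                                      noise_sd=0.0, acq_bleach_rate=0.0)
        ch = rec.channels["GFP"]
        plateau = ch.roi[-1] - ch.background[-1]
        assert plateau == pytest.approx((100.0 + 20.0) / 2.0, rel=1e-4)

    @pytest.mark.parametrize("kwargs", [
        dict(f_m=1.5), dict(bleach_depth=0.0), dict(noise_sd=-1.0),
        dict(k_fast=-0.1), dict(amp_split=2.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        params = dict(f_m=0.5)
        params.update(kwargs)
        with pytest.raises(ValueError):
            ds.simulate_frap_record(**params)


class TestEnumeratePairings:
    def test_small_exhaustive_cases(self):
        assert ds.enumerate_pairings(2, 2) == pytest.approx(2.0 / 3.0)
        assert ds.enumerate_pairings(2, 0) == 0.0
        assert ds.enumerate_pairings(6, 2) == pytest.approx(24.0 / 56.0)

    def test_enumeration_equals_closed_form_up_to_ten(self):
        for total in range(2, 11, 2):
            for m in range(total + 1):
                n = total - m
                exact = 2.0 * m * n / (total * (total - 1))
                assert ds.enumerate_pairings(m, n) == pytest.approx(
                    exact, abs=1e-12)

    def test_large_inputs_use_closed_form(self):
        assert ds.enumerate_pairings(100, 100) == pytest.approx(
            2 * 100 * 100 / (200 * 199))

    def test_odd_total_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ds.enumerate_pairings(3, 2)
        with pytest.raises(ValueError):
            ds.enumerate_pairings(0, 0)


class TestPairingCount:
    def test_molecule_totals(self):
        c = ds.PairingCount(c_gg=3.0, c_gr=2.0, c_rr=1.0)
        assert c.m_green == 8.0
        assert c.n_red == 4.0
        assert c.m_green + c.n_red == 2.0 * c.total

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ds.PairingCount(-1.0, 0.0, 0.0)
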