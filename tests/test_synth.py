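"""Generator behaviour: kinetics, determinism, wash-in shape, spike statistics."""

import numpy as np
import pytest

from lmotools import (
    LMOPreset,
    MEAPresetRates,
    NoiseModel,
    PerfusionModel,
    make_mea_recording,
    make_patch_cohort,
    make_patch_sweeps,
    make_plate_readings,
)
from lmotools.presets import PresetError
from lmotools.synth import washin_fraction, _refractory_poisson_times
from lmotools.patch import analyze_cell


class TestPatchSweeps:
    def test_same_seed_bit_identical(self, simple_preset):
        a = make_patch_sweeps(simple_preset, seed=7, post_perfusion_s=10.0)
        b = make_patch_sweeps(simple_preset, seed=7, post_perfusion_s=10.0)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert np.array_equal(a[1].samples, b[1].samples)

    def test_zero_coupling_gives_flat_luciferin_sweep(self, noiseless):
        preset = LMOPreset(name="zero", peak_photocurrent=-500.0, true_ce=0.0,
                           expression_cv=0.0)
        _, luc = make_patch_sweeps(preset, noise=noiseless, seed=0,
                                   post_perfusion_s=10.0)
        assert np.all(luc.samples == 0.0)

    def test_noiseless_steady_state_matches_closed_form(self, noiseless):
        # plateau = A * r since desensitization is essentially complete by
        # the last 100 ms of a 1 s pulse (tau_desens = 150 ms << 900 ms)
        preset = LMOPreset(name="p", peak_photocurrent=-500.0, true_ce=0.5,
                           desensitization_ratio=0.8, expression_cv=0.0)
        photo, _ = make_patch_sweeps(preset, noise=noiseless, seed=0,
                                     post_perfusion_s=2.0)
        illum = photo.epoch("illumination")
        i0 = photo.sample_index(illum.end_s - 0.1)
        i1 = photo.sample_index(illum.end_s)
        mean_last_100ms = photo.samples[i0:i1].mean()
        assert mean_last_100ms == pytest.approx(-400.0, rel=0.01)

    def test_washin_magnitude_nondecreasing_and_step_levels(self, perfusion):
        t = np.linspace(0.0, 200.0, 20001)
        for k in (0, 1, 4, 6):
            g = washin_fraction(t, perfusion, step_count=k)
            assert np.all(np.diff(g) >= 0)
            if k > 0:
                levels = np.unique(g)
                assert levels.size == k + 1
                assert levels[0] == 0.0 and levels[-1] == 1.0

    def test_invalid_preset_rejected(self):
        with pytest.raises(PresetError):
            LMOPreset(name="bad", peak_photocurrent=-100.0, true_ce=1.5)
        with pytest.raises(PresetError):
            LMOPreset(name="bad", peak_photocurrent=-100.0, true_ce=0.5,
                      desensitization_ratio=0.0)
        with pytest.raises(PresetError):
            LMOPreset(name="bad", peak_photocurrent=-100.0, true_ce=0.5,
                      tau_rise=-1.0)


class TestPatchCohort:
    def test_zero_expression_cv_identical_signals(self, noiseless):
        preset = LMOPreset(name="p", peak_photocurrent=-300.0, true_ce=0.4,
                           expression_cv=0.0)
        pairs = make_patch_cohort(preset, 3, seed=0, noise=noiseless,
                                  post_perfusion_s=10.0)
        for photo, luc in pairs[1:]:
            assert np.array_equal(photo.samples, pairs[0][0].samples)
            assert np.array_equal(luc.samples, pairs[0][1].samples)

    def test_expression_scale_cancels_in_ce(self, noiseless, short_sweeps_kwargs):
        # noiseless cohort with wide expression spread: every cell's CE ratio
        # equals the same value because the scale multiplies both sweeps
        preset = LMOPreset(name="p", peak_photocurrent=-500.0, true_ce=0.4,
                           expression_cv=0.5)
        pairs = make_patch_cohort(preset, 4, seed=3, noise=noiseless,
                                  **short_sweeps_kwargs)
        ces = [analyze_cell(p, l).coupling_efficiency for p, l in pairs]
        assert np.allclose(ces, ces[0], rtol=1e-9)

    def test_rejects_empty_cohort(self, simple_preset):
        with pytest.raises(PresetError):
            make_patch_cohort(simple_preset, 0, seed=0)


class TestMEAGeneration:
    def test_zero_rates_zero_spikes(self):
        rates = MEAPresetRates("x", "vehicle", 0.0, 0.0, event_time=5.0)
        _, truth = make_mea_recording(rates, n_channels=3, duration=12.0, seed=0)
        assert all(len(t) == 0 for t in truth)

    def test_total_count_matches_poisson_expectation(self):
        # 10 Hz x 60 s x 8 channels = 4800 expected ground-truth spikes
        rates = MEAPresetRates("x", "vehicle", 10.0, 10.0, event_time=30.0)
        _, truth = make_mea_recording(rates, n_channels=8, duration=60.0, seed=42)
        total = sum(len(t) for t in truth)
        assert abs(total - 4800) < 3 * np.sqrt(4800)

    def test_same_seed_identical(self):
        rates = MEAPresetRates("x", "CTZ", 5.0, 15.0, event_time=5.0,
                               ctz_concentration=10.0)
        rec1, tr1 = make_mea_recording(rates, n_channels=2, duration=12.0, seed=9)
        rec2, tr2 = make_mea_recording(rates, n_channels=2, duration=12.0, seed=9)
        assert np.array_equal(rec1.samples, rec2.samples)
        for a, b in zip(tr1, tr2):
            assert np.array_equal(a.times_s, b.times_s)

    def test_renewal_rate_calibration(self):
        # empirical rate over many independent channels within 5% of nominal
        rng = np.random.default_rng(0)
        total = sum(
            _refractory_poisson_times(rng, 8.0, 0.0, 60.0, 0.002).size
            for _ in range(200)
        )
        nominal = 8.0 * 60.0 * 200
        assert abs(total / nominal - 1.0) < 0.05

    def test_rejects_bad_geometry(self):
        rates = MEAPresetRates("x", "vehicle", 1.0, 1.0, event_time=5.0)
        with pytest.raises(PresetError):
            make_mea_recording(rates, n_channels=0, duration=10.0)
        with pytest.raises(PresetError):
            make_mea_recording(rates, n_channels=2, duration=-1.0)
        with pytest.raises(PresetError):
            make_mea_recording(rates, n_channels=2, duration=4.0)  # event outside


class TestPlateReadings:
    def test_quenching_lowers_normalized_luminescence(self):
        lo = LMOPreset(name="lo", peak_photocurrent=-500.0, true_ce=0.1)
        hi = LMOPreset(name="hi", peak_photocurrent=-500.0, true_ce=0.6)
        df = make_plate_readings([lo, hi], n_wells=8, seed=1)
        norm = df.assign(r=df.luminescence_au / df.fluorescence_au)
        means = norm.groupby("construct")["r"].mean()
        assert means["hi"] < means["lo"]

    def test_zero_radiance_zero_luminescence(self):
        dark = LMOPreset(name="dark", peak_photocurrent=-500.0, true_ce=0.3,
                         radiance_au=0.0)
        df = make_plate_readings([dark], n_wells=4, seed=0)
        assert np.all(df.luminescence_au == 0.0)

    def test_default_replication_is_eight_wells(self, simple_preset):
        df = make_plate_readings([simple_preset], seed=0)
        assert len(df) == 8

    def test_rejects_empty_inputs(self, simple_preset):
        with pytest.raises(PresetError):
            make_plate_readings([], n_wells=8)
        with pytest.raises(PresetError):
            make_plate_readings([simple_preset], n_wells=1)
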