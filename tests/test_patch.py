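"""Sweep measurements: filtering, baselines, amplitudes, coupling efficiency."""

import numpy as np
import pytest

from lmotools import (
    EpochAnnotation,
    LMOPreset,
    SweepTrace,
    analyze_cell,
    analyze_cohort,
    baseline_current,
    coupling_efficiency,
    gaussian_lowpass,
    luciferin_plateau,
    make_patch_sweeps,
    photocurrent_amplitude,
)
from lmotools.patch import CurrentMeasurement, MeasurementError

FS = 10_000.0


def _tone_attenuation(freq_hz: float, cutoff_hz: float = 250.0) -> float:
    """FFT amplitude oracle: output/input ratio for a pure sinusoid."""
    t = np.arange(int(10 * FS)) / FS
    x = np.sin(2 * np.pi * freq_hz * t)
    y = gaussian_lowpass(SweepTrace(x, sampling_rate=FS), cutoff_hz).samples
    # amplitude at the probe bin, ignoring edge effects
    core = slice(int(FS), int(9 * FS))
    fx = np.fft.rfft(x[core])
    fy = np.fft.rfft(y[core])
    k = int(np.argmax(np.abs(fx)))
    return float(np.abs(fy[k]) / np.abs(fx[k]))


class TestGaussianLowpass:
    def test_dc_gain_unity(self):
        trace = SweepTrace(np.full(1000, 5.0), sampling_rate=FS)
        out = gaussian_lowpass(trace)
        assert np.allclose(out.samples, 5.0)

    def test_half_power_at_cutoff(self):
        assert _tone_attenuation(250.0) == pytest.approx(10 ** (-3 / 20), abs=0.01)

    def test_passband_essentially_flat(self):
        assert _tone_attenuation(10.0) > 0.99

    def test_rejects_cutoff_at_nyquist(self):
        trace = SweepTrace(np.zeros(100), sampling_rate=FS)
        with pytest.raises(MeasurementError):
            gaussian_lowpass(trace, cutoff_hz=5000.0)


class TestBaseline:
    def test_flat_trace(self, cfg):
        epoch = EpochAnnotation("illumination", 1.0, 2.0)
        trace = SweepTrace(np.full(30_000, -20.0), sampling_rate=FS,
                           annotations=[epoch])
        assert baseline_current(trace, epoch, cfg) == pytest.approx(-20.0)

    def test_ramp_mean_equals_value_at_window_center(self, cfg):
        # 1 pA/s drift: analytic mean of a linear ramp over the window is its
        # value at the window center (0.49 - 0.51 s gap excluded -> center 0.74 s... )
        epoch = EpochAnnotation("illumination", 1.0, 2.0)
        t = np.arange(30_000) / FS
        trace = SweepTrace(t * 1.0, sampling_rate=FS, annotations=[epoch])
        # window: [epoch - 10 ms - 500 ms, epoch - 10 ms) -> center 0.745 s
        expected = (0.49 + 0.99) / 2.0 * 1.0
        assert baseline_current(trace, epoch, cfg) == pytest.approx(expected, abs=1e-3)

    def test_epoch_at_zero_errors(self, cfg):
        epoch = EpochAnnotation("illumination", 0.0, 1.0)
        trace = SweepTrace(np.zeros(20_000), sampling_rate=FS, annotations=[epoch])
        with pytest.raises(MeasurementError):
            baseline_current(trace, epoch, cfg)


class TestPhotocurrentAmplitude:
    def test_flat_plateau(self, cfg):
        epoch = EpochAnnotation("illumination", 1.0, 2.0)
        x = np.zeros(30_000)
        x[10_000:20_000] = -200.0
        trace = SweepTrace(x, sampling_rate=FS, annotations=[epoch])
        m = photocurrent_amplitude(trace, epoch, cfg)
        assert m.amplitude_pA == pytest.approx(-200.0, abs=1.0)

    def test_all_zero_trace(self, cfg):
        epoch = EpochAnnotation("illumination", 1.0, 2.0)
        trace = SweepTrace(np.zeros(30_000), sampling_rate=FS, annotations=[epoch])
        assert photocurrent_amplitude(trace, epoch, cfg).amplitude_pA == 0.0

    def test_matches_brute_force_window_means_exactly(self, cfg):
        from lmotools import get_preset

        photo, _ = make_patch_sweeps(get_preset("lmo3"), seed=4,
                                     post_perfusion_s=2.0)
        illum = photo.epoch("illumination")
        m = photocurrent_amplitude(photo, illum, cfg)
        # independent brute-force: mean of last 1000 samples of the epoch
        # minus mean of the 5000-sample baseline window ending 100 samples
        # before epoch start
        end = int(round(illum.end_s * FS))
        e0 = int(round(illum.start_s * FS))
        brute = photo.samples[end - 1000:end].mean() - photo.samples[
            e0 - 100 - 5000:e0 - 100].mean()
        assert m.amplitude_pA == brute

    def test_epoch_shorter_than_window_errors(self, cfg):
        epoch = EpochAnnotation("illumination", 1.0, 1.05)
        trace = SweepTrace(np.zeros(30_000), sampling_rate=FS, annotations=[epoch])
        with pytest.raises(MeasurementError):
            photocurrent_amplitude(trace, epoch, cfg)


class TestLuciferinPlateau:
    def _trace(self, x):
        onset = EpochAnnotation("perfusion_onset", 1.0, 1.0)
        return SweepTrace(x, sampling_rate=FS, annotations=[onset]), onset

    def test_held_washin_level(self, cfg):
        x = np.zeros(60_000)
        x[10_000:20_000] = np.linspace(0, -150.0, 10_000)  # rising phase
        x[20_000:] = -150.0
        trace, onset = self._trace(x)
        m = luciferin_plateau(trace, onset, cfg)
        assert m.amplitude_pA == pytest.approx(-150.0, abs=1.0)
        assert not m.plateau_fallback

    def test_flat_zero_after_onset(self, cfg):
        trace, onset = self._trace(np.zeros(60_000))
        assert luciferin_plateau(trace, onset, cfg).amplitude_pA == 0.0

    def test_stepped_trace_selects_deepest_level(self, cfg):
        # levels 0, -50, -100 pA held >= window; deepest qualifying window wins
        x = np.zeros(80_000)
        x[20_000:40_000] = -50.0
        x[40_000:] = -100.0
        trace, onset = self._trace(x)
        m = luciferin_plateau(trace, onset, cfg)
        # enumeration oracle over a coarse grid of fully-contained windows
        w = 10_000
        best = 0.0
        for start in range(10_000, 80_000 - w + 1, 100):
            seg = x[start:start + w]
            mean = seg.mean()
            slope = np.polyfit(np.arange(w) / FS, seg, 1)[0]
            if abs(slope) < cfg.plateau_slope_tol * abs(mean):
                if abs(mean) > abs(best):
                    best = mean
        assert best == pytest.approx(-100.0)
        assert m.amplitude_pA == pytest.approx(best, abs=1.0)

    def test_too_short_post_onset_errors(self, cfg):
        trace, onset = self._trace(np.zeros(15_000))
        with pytest.raises(MeasurementError):
            luciferin_plateau(trace, onset, cfg)


class TestCouplingEfficiency:
    def _m(self, amp):
        return CurrentMeasurement(0.0, amp, (0.0, 1.0))

    def test_simple_ratio(self, cfg):
        res = coupling_efficiency(self._m(-130.0), self._m(-200.0), 5.0, cfg)
        assert res.coupling_efficiency == pytest.approx(0.65)

    def test_zero_luciferin_current(self, cfg):
        res = coupling_efficiency(self._m(0.0), self._m(-200.0), 5.0, cfg)
        assert res.coupling_efficiency == 0.0

    def test_below_floor_flagged_nonfunctional(self, cfg):
        res = coupling_efficiency(self._m(-10.0), self._m(-2.0), 5.0, cfg)
        assert res.nonfunctional
        assert res.coupling_efficiency is None
        assert res.display_ce == "n.f."

    def test_zero_photocurrent_with_floor_disabled_raises(self, cfg):
        with pytest.raises(ZeroDivisionError):
            coupling_efficiency(self._m(0.0), self._m(0.0), 0.0, cfg)


class TestCohort:
    def _pairs(self, n, noiseless, kwargs):
        preset = LMOPreset(name="p", peak_photocurrent=-500.0, true_ce=0.31,
                           expression_cv=0.0)
        from lmotools import make_patch_cohort
        return make_patch_cohort(preset, n, seed=0, noise=noiseless, **kwargs)

    def test_identical_noiseless_cells_mean(self, noiseless):
        # wash-in long enough (90 s) that the plateau sits at ~98% occupancy
        kwargs = dict(pre_perfusion_s=2.0, post_perfusion_s=90.0)
        _, summary = analyze_cohort(self._pairs(5, noiseless, kwargs))
        assert summary.mean_ce == pytest.approx(0.31, abs=0.02)
        assert summary.n_functional == 5

    def test_single_cell_mean_is_that_cell(self, noiseless, short_sweeps_kwargs):
        results, summary = analyze_cohort(self._pairs(1, noiseless, short_sweeps_kwargs))
        assert summary.mean_ce == results[0].coupling_efficiency

    def test_all_nonfunctional_cohort_flagged(self, noiseless, short_sweeps_kwargs):
        dead = LMOPreset(name="dead", peak_photocurrent=-3.0, true_ce=0.0,
                         nonfunctional=True, expression_cv=0.0)
        from lmotools import make_patch_cohort
        # with zero noise the floor is zero, so add noise to exercise the flag
        from lmotools import NoiseModel
        pairs = make_patch_cohort(dead, 3, seed=0, noise=NoiseModel(),
                                  **short_sweeps_kwargs)
        _, summary = analyze_cohort(pairs)
        assert summary.nonfunctional
        assert summary.mean_ce is None

    def test_empty_cohort_errors(self):
        with pytest.raises(MeasurementError):
            analyze_cohort([])


class TestInvariants:
    @pytest.mark.parametrize("scale", [0.1, 1.0, 10.0])
    def test_gain_invariance(self, noiseless, short_sweeps_kwargs, scale, simple_preset):
        photo, luc = make_patch_sweeps(simple_preset, noise=noiseless, seed=0,
                                       **short_sweeps_kwargs)
        base = analyze_cell(photo, luc).coupling_efficiency
        photo2 = SweepTrace(photo.samples * scale, sampling_rate=FS,
                            annotations=photo.annotations)
        luc2 = SweepTrace(luc.samples * scale, sampling_rate=FS,
                          annotations=luc.annotations)
        scaled = analyze_cell(photo2, luc2).coupling_efficiency
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_display_filter_does_not_bias_ce(self, noiseless, short_sweeps_kwargs,
                                             simple_preset):
        photo, luc = make_patch_sweeps(simple_preset, noise=noiseless, seed=0,
                                       **short_sweeps_kwargs)
        raw = analyze_cell(photo, luc).coupling_efficiency
        filt = analyze_cell(gaussian_lowpass(photo), gaussian_lowpass(luc))
        assert filt.coupling_efficiency == pytest.approx(raw, rel=1e-3)
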