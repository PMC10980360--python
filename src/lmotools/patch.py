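"""Coupling-efficiency quantification from voltage-clamp sweeps.

The coupling efficiency (CE) of a luminopsin is the magnitude of the
luciferin-induced current divided by the magnitude of the maximal
lamp-evoked photocurrent in the same cell:

    CE = |I_luciferin| / |I_photo|

Photocurrents are measured at steady state over the last 100 ms of the
illumination epoch (avoiding the pre-adaptation peak); luciferin-induced
currents are measured where the amplitude plateaus during wash-in, found by
sliding a window over the post-onset region and keeping the flattest,
deepest one.  Both measurements are baseline-subtracted.  Cells whose
photocurrent does not exceed a noise floor are flagged nonfunctional (n.f.)
rather than contributing an ill-defined ratio.

A zero-phase Gaussian low-pass (250 Hz half-power cutoff) is provided for
display; amplitude measurements always use the raw trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .traces import EpochAnnotation, SweepTrace

__all__ = [
    "MeasurementConfig",
    "CurrentMeasurement",
    "CouplingResult",
    "CohortSummary",
    "gaussian_lowpass",
    "baseline_current",
    "estimate_patch_noise_sd",
    "photocurrent_amplitude",
    "luciferin_plateau",
    "coupling_efficiency",
    "analyze_cohort",
]


class MeasurementError(ValueError):
    """Raised when a trace cannot support the requested measurement."""


@dataclass(frozen=True)
class MeasurementConfig:
    """Windows and thresholds for sweep measurements.

    steady_state_window_ms:
        Length of the terminal illumination window averaged for the
        photocurrent (default 100 ms).
    baseline_window_ms / baseline_gap_ms:
        Baseline mean is taken over ``baseline_window_ms`` ending
        ``baseline_gap_ms`` before the reference epoch.
    plateau_window_s / plateau_slope_tol:
        Plateau search window length and flatness criterion: a window
        qualifies if its fitted |slope| is below ``plateau_slope_tol`` x
        |window mean - baseline| per second.
    functional_floor_sd:
        Cells whose |photocurrent| is below this multiple of the baseline
        noise SD are flagged nonfunctional.
    """

    steady_state_window_ms: float = 100.0
    baseline_window_ms: float = 500.0
    baseline_gap_ms: float = 10.0
    plateau_window_s: float = 1.0
    plateau_slope_tol: float = 0.05
    functional_floor_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "steady_state_window_ms",
            "baseline_window_ms",
            "baseline_gap_ms",
            "plateau_window_s",
            "plateau_slope_tol",
            "functional_floor_sd",
        ):
            if getattr(self, name) <= 0 and name != "baseline_gap_ms":
                raise MeasurementError(f"{name} must be positive")
        if self.baseline_gap_ms < 0:
            raise MeasurementError("baseline_gap_ms must be >= 0")


@dataclass(frozen=True)
class CurrentMeasurement:
    """A baseline-subtracted current amplitude and the window it came from."""

    baseline_pA: float
    amplitude_pA: float  # signed; inward currents negative
    window_used: tuple[float, float]  # [start_s, end_s)
    plateau_fallback: bool = False  # True if no flat window qualified


@dataclass(frozen=True)
class CouplingResult:
    """Per-cell coupling-efficiency result."""

    photocurrent: CurrentMeasurement
    luciferin_current: CurrentMeasurement
    coupling_efficiency: float | None  # None when nonfunctional
    nonfunctional: bool = False

    @property
    def display_ce(self) -> str:
        return "n.f." if self.nonfunctional else f"{self.coupling_efficiency:.2f}"


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level CE summary (functional cells only enter the mean)."""

    mean_ce: float | None
    sd_ce: float | None
    n_cells: int
    n_functional: int
    nonfunctional: bool  # True when no functional cell remains


def gaussian_lowpass(trace: SweepTrace, cutoff_hz: float = 250.0) -> SweepTrace:
    """Zero-phase Gaussian smoothing with half-power point at ``cutoff_hz``.

    The Gaussian magnitude response is exp(-f^2 / (2 sigma_f^2)); choosing
    sigma_f = cutoff / sqrt(ln 2) puts the response at 1/sqrt(2) (-3 dB) at
    the cutoff.  DC gain is 1.  For display/reporting only.
    """
    nyquist = trace.sampling_rate / 2.0
    if not (0.0 < cutoff_hz < nyquist):
        raise MeasurementError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    sigma_f = cutoff_hz / math.sqrt(math.log(2.0))
    sigma_samples = trace.sampling_rate / (2.0 * math.pi * sigma_f)
    smoothed = ndimage.gaussian_filter1d(trace.samples, sigma_samples, mode="nearest")
    return SweepTrace(
        smoothed,
        sampling_rate=trace.sampling_rate,
        holding_potential=trace.holding_potential,
        annotations=list(trace.annotations),
    )


def _baseline_slice(
    trace: SweepTrace, reference_epoch: EpochAnnotation, cfg: MeasurementConfig
) -> slice:
    fs = trace.sampling_rate
    end = trace.sample_index(reference_epoch.start_s - cfg.baseline_gap_ms / 1000.0)
    start = end - int(round(cfg.baseline_window_ms / 1000.0 * fs))
    if start < 0:
        raise MeasurementError(
            f"need {cfg.baseline_window_ms + cfg.baseline_gap_ms} ms of pre-epoch "
            f"baseline, epoch starts at {reference_epoch.start_s} s"
        )
    return slice(start, end)


def baseline_current(
    trace: SweepTrace, reference_epoch: EpochAnnotation, cfg: MeasurementConfig
) -> float:
    """Mean current over the baseline window preceding ``reference_epoch``."""
    return float(np.mean(trace.samples[_baseline_slice(trace, reference_epoch, cfg)]))


def estimate_patch_noise_sd(
    trace: SweepTrace, reference_epoch: EpochAnnotation, cfg: MeasurementConfig
) -> float:
    """Robust noise SD (1.4826 x MAD) over the pre-epoch baseline window."""
    seg = trace.samples[_baseline_slice(trace, reference_epoch, cfg)]
    return float(1.4826 * np.median(np.abs(seg - np.median(seg))))


def photocurrent_amplitude(
    trace: SweepTrace,
    illum: EpochAnnotation | None = None,
    cfg: MeasurementConfig | None = None,
) -> CurrentMeasurement:
    """Steady-state photocurrent: mean over the last 100 ms of illumination.

    The terminal window avoids the transient peak before light adaptation.
    Sign is preserved (inward currents negative).
    """
    cfg = cfg or MeasurementConfig()
    illum = illum or trace.epoch("illumination")
    win_s = cfg.steady_state_window_ms / 1000.0
    if illum.duration_s < win_s:
        raise MeasurementError(
            f"illumination epoch of {illum.duration_s*1e3:.0f} ms shorter than "
            f"steady-state window of {cfg.steady_state_window_ms:.0f} ms"
        )
    end = trace.sample_index(illum.end_s)
    start = trace.sample_index(illum.end_s - win_s)
    mean = float(np.mean(trace.samples[start:end]))
    base = baseline_current(trace, illum, cfg)
    return CurrentMeasurement(
        baseline_pA=base,
        amplitude_pA=mean - base,
        window_used=(start / trace.sampling_rate, end / trace.sampling_rate),
    )


def _window_means_and_slopes(
    x: np.ndarray, w: int, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and fitted slope (per second) of every length-w window of x.

    O(n) via cumulative sums; windows indexed by their start sample.
    """
    n = x.size
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    j = np.arange(n, dtype=float)
    cj = np.concatenate(([0.0], np.cumsum(j * x)))
    starts = np.arange(n - w + 1)
    sums = c1[starts + w] - c1[starts]
    means = sums / w
    # slope of OLS fit against local sample index k = 0..w-1
    sum_jx = cj[starts + w] - cj[starts]
    sum_kx = sum_jx - starts * sums
    kbar = (w - 1) / 2.0
    denom = w * (w * w - 1.0) / 12.0  # sum (k - kbar)^2
    slope_per_sample = (sum_kx - kbar * sums) / denom
    return means, slope_per_sample * fs


def luciferin_plateau(
    trace: SweepTrace,
    onset: EpochAnnotation | None = None,
    cfg: MeasurementConfig | None = None,
) -> CurrentMeasurement:
    """Luciferin-induced current where the amplitude plateaus after wash-in.

    Slides a ``plateau_window_s`` window over the post-onset region; among
    windows whose fitted |slope| is below ``plateau_slope_tol`` x
    |mean - baseline| per second, returns the one maximizing
    |mean - baseline| (earliest on ties).  If no window qualifies — e.g. a
    still-rising or flat-zero response — falls back to the window of maximal
    |mean - baseline| and sets ``plateau_fallback``.
    """
    cfg = cfg or MeasurementConfig()
    onset = onset or trace.epoch("perfusion_onset")
    fs = trace.sampling_rate
    w = int(round(cfg.plateau_window_s * fs))
    i0 = trace.sample_index(onset.start_s)
    post = trace.samples[i0:]
    if post.size < w:
        raise MeasurementError(
            f"trace extends only {post.size / fs:.3f} s past perfusion onset; "
            f"plateau window is {cfg.plateau_window_s} s"
        )
    base = baseline_current(trace, onset, cfg)
    means, slopes = _window_means_and_slopes(post, w, fs)
    depth = np.abs(means - base)
    ok = np.abs(slopes) < cfg.plateau_slope_tol * depth
    fallback = not bool(ok.any())
    if fallback:
        best = int(np.argmax(depth))
    else:
        masked = np.where(ok, depth, -np.inf)
        best = int(np.argmax(masked))  # argmax returns the earliest maximum
    start_s = (i0 + best) / fs
    return CurrentMeasurement(
        baseline_pA=base,
        amplitude_pA=float(means[best] - base),
        window_used=(start_s, start_s + w / fs),
        plateau_fallback=fallback,
    )


def coupling_efficiency(
    luc: CurrentMeasurement,
    photo: CurrentMeasurement,
    noise_sd: float,
    cfg: MeasurementConfig | None = None,
) -> CouplingResult:
    """CE = |luciferin amplitude| / |photocurrent amplitude| for one cell.

    When the photocurrent magnitude is below ``functional_floor_sd`` x
    ``noise_sd`` the cell is flagged nonfunctional instead of dividing by a
    noise-level denominator.  With the floor disabled (``noise_sd = 0``) a
    zero photocurrent raises.
    """
    cfg = cfg or MeasurementConfig()
    floor = cfg.functional_floor_sd * noise_sd
    p = abs(photo.amplitude_pA)
    if p < floor:
        return CouplingResult(photo, luc, None, nonfunctional=True)
    if p == 0.0:
        raise ZeroDivisionError(
            "photocurrent amplitude is exactly zero and the noise floor is disabled"
        )
    return CouplingResult(photo, luc, abs(luc.amplitude_pA) / p)


def analyze_cell(
    photo_trace: SweepTrace,
    luc_trace: SweepTrace,
    cfg: MeasurementConfig | None = None,
) -> CouplingResult:
    """Measure both sweeps of one cell and form its coupling efficiency."""
    cfg = cfg or MeasurementConfig()
    illum = photo_trace.epoch("illumination")
    onset = luc_trace.epoch("perfusion_onset")
    photo = photocurrent_amplitude(photo_trace, illum, cfg)
    luc = luciferin_plateau(luc_trace, onset, cfg)
    noise_sd = estimate_patch_noise_sd(photo_trace, illum, cfg)
    return coupling_efficiency(luc, photo, noise_sd, cfg)


def analyze_cohort(
    sweep_pairs: list[tuple[SweepTrace, SweepTrace]],
    cfg: MeasurementConfig | None = None,
) -> tuple[list[CouplingResult], CohortSummary]:
    """Per-cell CE for a cohort plus the functional-cell mean.

    Nonfunctional cells are excluded from the mean but counted; a cohort
    with no functional cell is itself flagged nonfunctional (mean
    undefined), mirroring an "n.f." construct call.
    """
    if not sweep_pairs:
        raise MeasurementError("cohort is empty")
    results = [analyze_cell(p, l, cfg) for p, l in sweep_pairs]
    ces = [r.coupling_efficiency for r in results if not r.nonfunctional]
    if ces:
        summary = CohortSummary(
            mean_ce=float(np.mean(ces)),
            sd_ce=float(np.std(ces, ddof=1)) if len(ces) > 1 else 0.0,
            n_cells=len(results),
            n_functional=len(ces),
            nonfunctional=False,
        )
    else:
        summary = CohortSummary(
            mean_ce=None, sd_ce=None, n_cells=len(results), n_functional=0,
            nonfunctional=True,
        )
    return results, summary
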