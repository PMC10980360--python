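"""Extracellular spike detection and pre/post treatment firing rates.

Spikes are counted where the signal exceeds nine standard deviations of the
baseline noise (negative-going threshold, the usual extracellular trough
polarity).  The noise SD is a robust estimate (1.4826 x median absolute
deviation) so that the spikes themselves do not inflate the threshold.
Firing rates are spike counts over half-open windows before the treatment
event and immediately after it (after a short blanking period covering the
time-locked application artifact).  For luciferin treatments, analysis is
restricted to responder electrodes — channels whose firing increases under
a blue-LED probe, evidence of opsin-expressing neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import MEARecording, SpikeTrain, TreatmentEvent

__all__ = [
    "SpikeDetectorConfig",
    "RateSummary",
    "estimate_noise_sd",
    "detect_spikes",
    "firing_rate",
    "responder_filter",
    "pre_post_rates",
]


class DetectionError(ValueError):
    """Raised for invalid detection or windowing parameters."""


@dataclass(frozen=True)
class SpikeDetectorConfig:
    """Threshold-crossing detector parameters.

    threshold_sd:
        Detection threshold as a multiple of the baseline noise SD (9).
    dead_time_ms:
        Minimum separation between detected spikes; later crossings within
        this of an accepted spike are merged into it.
    noise_window_s:
        Length of the quiet window used for noise estimation.
    artifact_blank_s:
        Samples within this interval after any treatment event are ignored.
    """

    threshold_sd: float = 9.0
    dead_time_ms: float = 1.0
    polarity: str = "negative"
    noise_window_s: float = 10.0
    artifact_blank_s: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise DetectionError("threshold_sd must be positive")
        if self.dead_time_ms < 0:
            raise DetectionError("dead_time_ms must be >= 0")
        if self.polarity != "negative":
            raise DetectionError("only negative-polarity detection is supported")
        if self.noise_window_s < 0.5:
            raise DetectionError("noise_window_s must be >= 0.5 s")
        if self.artifact_blank_s < 0:
            raise DetectionError("artifact_blank_s must be >= 0")


@dataclass(frozen=True)
class RateSummary:
    """Pre/post firing rates for one channel around one treatment event."""

    channel: str
    pre_rate: float  # Hz
    post_rate: float  # Hz
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    responder: bool | None = None


def estimate_noise_sd(
    x: np.ndarray,
    sampling_rate: float,
    quiet_window: tuple[float, float],
) -> float:
    """Robust baseline noise SD over ``quiet_window`` = (start_s, end_s).

    Uses 1.4826 x median absolute deviation, which tolerates a small
    fraction of spike samples without the inflation a plain SD suffers.
    """
    start_s, end_s = quiet_window
    if end_s - start_s < 0.5:
        raise DetectionError("quiet window must be at least 0.5 s")
    i0 = int(round(start_s * sampling_rate))
    i1 = int(round(end_s * sampling_rate))
    seg = np.asarray(x, dtype=float)[i0:i1]
    if seg.size == 0:
        raise DetectionError("quiet window outside trace")
    return float(1.4826 * np.median(np.abs(seg - np.median(seg))))


def detect_spikes(
    x: np.ndarray,
    noise_sd: float,
    cfg: SpikeDetectorConfig | None = None,
    sampling_rate: float = 10_000.0,
    channel: str = "ch01",
    events: list[TreatmentEvent] | None = None,
) -> SpikeTrain:
    """Threshold-crossing spike detection on one channel.

    The threshold is ``-threshold_sd * noise_sd``; each maximal
    below-threshold excursion yields one spike at its trough sample, troughs
    closer than ``dead_time_ms`` are merged (first kept), and spikes inside
    ``artifact_blank_s`` after any treatment event are discarded.
    """
    cfg = cfg or SpikeDetectorConfig()
    if noise_sd <= 0:
        raise DetectionError("noise_sd must be positive")
    x = np.asarray(x, dtype=float)
    threshold = -cfg.threshold_sd * noise_sd
    below = x < threshold
    if not below.any():
        return SpikeTrain(channel, np.empty(0))
    # run boundaries of contiguous below-threshold excursions
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [x.size]))
    troughs = np.array(
        [s + int(np.argmin(x[s:e])) for s, e in zip(starts, ends)], dtype=float
    )
    times = troughs / sampling_rate
    # dead-time merge: keep a spike only if >= dead_time after the last kept
    dead = cfg.dead_time_ms / 1000.0
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= dead:
            kept.append(t)
            last = t
    times = np.asarray(kept)
    if events:
        mask = np.ones(times.size, dtype=bool)
        for ev in events:
            mask &= ~(
                (times >= ev.time_s) & (times < ev.time_s + cfg.artifact_blank_s)
            )
        times = times[mask]
    return SpikeTrain(channel, times)


def firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in the half-open window [start, end) divided by its length."""
    start, end = window
    if end <= start:
        raise DetectionError("window must have positive length")
    count = int(np.count_nonzero((train.times_s >= start) & (train.times_s < end)))
    return count / (end - start)


def responder_filter(
    summaries: list[RateSummary], min_ratio: float = 1.2
) -> list[str]:
    """Channels whose firing increases under the LED probe.

    ``summaries`` must come from an LED probe event (pre = baseline, post =
    during LED).  A channel is kept when its LED rate is at least
    ``min_ratio`` times its baseline rate; silent-baseline channels are kept
    iff they fire at all under the LED.
    """
    if not summaries:
        raise DetectionError("no LED-probe rate summaries supplied")
    kept = []
    for s in summaries:
        if s.pre_rate == 0.0:
            if s.post_rate > 0.0:
                kept.append(s.channel)
        elif s.post_rate >= min_ratio * s.pre_rate:
            kept.append(s.channel)
    return kept


def pre_post_rates(
    recording: MEARecording,
    event: TreatmentEvent | None = None,
    window_len: float = 60.0,
    cfg: SpikeDetectorConfig | None = None,
) -> list[RateSummary]:
    """Per-channel firing rates before and immediately after a treatment.

    Pre window: [event - window_len, event).  Post window starts after the
    artifact blanking: [event + blank, event + blank + window_len).  The
    noise SD is estimated per channel from the start of the pre window.
    """
    cfg = cfg or SpikeDetectorConfig()
    if event is None:
        if not recording.events:
            raise DetectionError("recording carries no treatment event")
        event = recording.events[0]
    t_ev = event.time_s
    pre_win = (t_ev - window_len, t_ev)
    post_win = (
        t_ev + cfg.artifact_blank_s,
        t_ev + cfg.artifact_blank_s + window_len,
    )
    if pre_win[0] < 0 or post_win[1] > recording.duration_s:
        raise DetectionError(
            f"windows [{pre_win[0]:.1f}, {post_win[1]:.1f}) s exceed recording "
            f"of {recording.duration_s:.1f} s"
        )
    quiet = (pre_win[0], min(pre_win[0] + cfg.noise_window_s, t_ev))
    out = []
    for label, x in zip(recording.channels, recording.samples):
        sd = estimate_noise_sd(x, recording.sampling_rate, quiet)
        train = detect_spikes(
            x, sd, cfg, recording.sampling_rate, channel=label, events=[event]
        )
        out.append(
            RateSummary(
                channel=label,
                pre_rate=firing_rate(train, pre_win),
                post_rate=firing_rate(train, post_win),
                pre_window=pre_win,
                post_window=post_win,
            )
        )
    return out
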