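"""In-memory containers for patch-clamp sweeps and MEA recordings.

Conventions: time in seconds from sweep start, sample 0 at t = 0, half-open
epochs [start, end), currents in pA (inward negative), extracellular
voltages in µV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SAMPLING_RATE = 10_000.0  # Hz


class AnnotationError(ValueError):
    """Raised for epoch/event annotations inconsistent with their trace."""


@dataclass(frozen=True)
class EpochAnnotation:
    """A labelled interval (or point event) within a sweep.

    ``illumination`` epochs are proper intervals; ``perfusion_onset`` is a
    point event with ``end_s == start_s``.
    """

    kind: str  # illumination | perfusion_onset
    start_s: float
    end_s: float
    wavelength_nm: float | None = None
    luciferin: str | None = None
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "illumination":
            if not self.end_s > self.start_s:
                raise AnnotationError("illumination epoch must have end_s > start_s")
        elif self.kind == "perfusion_onset":
            if self.end_s != self.start_s:
                raise AnnotationError("perfusion_onset is a point event (end_s == start_s)")
        else:
            raise AnnotationError(f"unknown epoch kind {self.kind!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SweepTrace:
    """One voltage-clamp current sweep with its epoch annotations."""

    samples: np.ndarray  # pA
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    holding_potential: float = -60.0  # mV
    annotations: list[EpochAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration_s
        for ann in self.annotations:
            if ann.start_s < 0 or ann.end_s > dur + 0.5 / self.sampling_rate:
                raise AnnotationError(
                    f"annotation [{ann.start_s}, {ann.end_s}) outside trace of {dur:.6g} s"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def epoch(self, kind: str) -> EpochAnnotation:
        """Return the first annotation of the given kind."""
        for ann in self.annotations:
            if ann.kind == kind:
                return ann
        raise AnnotationError(f"trace has no {kind!r} annotation")

    def sample_index(self, t_s: float) -> int:
        return int(round(t_s * self.sampling_rate))


@dataclass(frozen=True)
class TreatmentEvent:
    """A treatment application (LED onset, vehicle or luciferin addition)."""

    treatment: str  # LED | vehicle | CTZ
    time_s: float
    wavelength_nm: float | None = None
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in ("LED", "vehicle", "CTZ"):
            raise AnnotationError(f"unknown treatment {self.treatment!r}")
        if self.time_s < 0:
            raise AnnotationError("event time must be >= 0")


@dataclass
class MEARecording:
    """Multichannel extracellular voltage recording with treatment events."""

    channels: list[str]
    samples: np.ndarray  # µV, shape (n_channels, n_samples)
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    events: list[TreatmentEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channel x time)")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.samples.shape[0]} rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for ev in self.events:
            if ev.time_s >= self.duration_s:
                raise AnnotationError(
                    f"event at {ev.time_s} s outside recording of {self.duration_s:.6g} s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channels.index(label)]


@dataclass
class SpikeTrain:
    """Sorted spike times for one channel."""

    channel: str
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be 1-D")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times_s.size)
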