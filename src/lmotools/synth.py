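"""Synthetic electrophysiology and plate-reader data generator.

Emulates the three data streams of a luminopsin characterization study:

* whole-cell voltage-clamp sweeps at 10 kHz — a 1 s lamp illumination evoking
  an inward photocurrent (fast rise, partial desensitization to a sustained
  plateau), followed in a second sweep by luciferin perfusion evoking an
  inward current that tracks chamber luciferin concentration, optionally in
  discrete "steps";
* multichannel MEA recordings at 10 kHz — Poisson-like spontaneous spiking
  whose per-channel rate switches at a treatment event, spikes rendered as
  biphasic ~1 ms extracellular templates over Gaussian noise, plus a
  time-locked square application artifact on every channel;
* plate-reader tables of per-well bioluminescence and fluorescence, with
  luminescence reduced by FRET donor quenching in efficiently coupled
  constructs.

Photocurrent model during illumination (t from light onset, A the driving
amplitude, r the desensitization ratio):

    I(t) = A * (1 - exp(-t/tau_rise)) * (r + (1 - r) * exp(-t/tau_desens))

and exponential shut-off with ``tau_off`` after light offset.  The
luciferin-induced current is ``true_ce * A * r * g(t)``, where g is the
receptor-occupancy wash-in function normalized to its value at the final
chamber concentration, so the fully washed-in current is exactly
``true_ce`` times the photocurrent plateau.  ``step_count = K`` quantizes g
to the nearest of K equal increments, giving K+1 discrete levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .presets import (
    LMOPreset,
    MEAPresetRates,
    NoiseModel,
    PerfusionModel,
    PresetError,
)
from .traces import (
    DEFAULT_SAMPLING_RATE,
    EpochAnnotation,
    MEARecording,
    SpikeTrain,
    SweepTrace,
    TreatmentEvent,
)

__all__ = [
    "make_patch_sweeps",
    "make_patch_cohort",
    "make_mea_recording",
    "make_plate_readings",
    "photocurrent_waveform",
    "washin_fraction",
    "SPIKE_TEMPLATE",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def photocurrent_waveform(
    t_s: np.ndarray,
    amplitude_pA: float,
    desensitization_ratio: float,
    tau_rise_ms: float,
    tau_desens_ms: float,
) -> np.ndarray:
    """Opsin current during illumination, t_s measured from light onset."""
    t = np.asarray(t_s, dtype=float)
    r = desensitization_ratio
    rise = 1.0 - np.exp(-t * 1000.0 / tau_rise_ms)
    desens = r + (1.0 - r) * np.exp(-t * 1000.0 / tau_desens_ms)
    return amplitude_pA * rise * desens


def washin_fraction(
    t_s: np.ndarray, perfusion: PerfusionModel, step_count: int = 0
) -> np.ndarray:
    """Normalized activation fraction g(t) in [0, 1] after perfusion onset.

    g = occupancy(C(t)) / occupancy(C_final) with single-compartment
    exchange C(t) = C_final * (1 - exp(-t/tau_wash)) and Langmuir occupancy
    C / (C + K_half).  With ``step_count`` K > 0 the fraction is quantized
    to the nearest multiple of 1/K (K+1 discrete levels including 0 and 1).
    """
    t = np.asarray(t_s, dtype=float)
    tau = perfusion.washin_tau
    c = perfusion.final_concentration * -np.expm1(-np.clip(t, 0.0, None) / tau)
    occ = c / (c + perfusion.k_half)
    occ_final = perfusion.final_concentration / (
        perfusion.final_concentration + perfusion.k_half
    )
    g = occ / occ_final
    g[t < 0] = 0.0
    if step_count > 0:
        g = np.round(g * step_count) / step_count
    return g


def make_patch_sweeps(
    preset: LMOPreset,
    perfusion: PerfusionModel | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    pre_light_s: float = 1.0,
    light_s: float = 1.0,
    post_light_s: float = 1.0,
    pre_perfusion_s: float = 5.0,
    post_perfusion_s: float = 165.0,
    expression_scale: float = 1.0,
) -> tuple[SweepTrace, SweepTrace]:
    """Generate the photocurrent and luciferin sweeps for one cell.

    Returns ``(photo, luciferin)`` sweeps.  ``expression_scale`` multiplies
    both signal amplitudes (not the noise), emulating the cell's expression
    level; the luciferin/photocurrent ratio is invariant to it.
    """
    if perfusion is None:
        perfusion = PerfusionModel()
    if noise is None:
        noise = NoiseModel()
    if expression_scale <= 0:
        raise PresetError("expression_scale must be positive")
    rng = _rng(seed)
    dt = 1.0 / sampling_rate

    amp = preset.peak_photocurrent * expression_scale

    # --- photocurrent sweep: baseline, 1 s illumination, shut-off tail
    n_pre = int(round(pre_light_s * sampling_rate))
    n_light = int(round(light_s * sampling_rate))
    n_post = int(round(post_light_s * sampling_rate))
    sig = np.zeros(n_pre + n_light + n_post)
    t_light = np.arange(n_light) * dt
    sig[n_pre : n_pre + n_light] = photocurrent_waveform(
        t_light, amp, preset.desensitization_ratio, preset.tau_rise, preset.tau_desens
    )
    i_off = sig[n_pre + n_light - 1]
    t_post = np.arange(1, n_post + 1) * dt
    sig[n_pre + n_light :] = i_off * np.exp(-t_post * 1000.0 / preset.tau_off)
    photo = sig + _patch_noise(rng, sig.size, dt, noise)
    photo_trace = SweepTrace(
        photo,
        sampling_rate=sampling_rate,
        annotations=[
            EpochAnnotation(
                "illumination",
                start_s=pre_light_s,
                end_s=pre_light_s + light_s,
                wavelength_nm=540.0,
            )
        ],
    )

    # --- luciferin sweep: baseline then wash-in driven current
    n_pre_p = int(round(pre_perfusion_s * sampling_rate))
    n_post_p = int(round(post_perfusion_s * sampling_rate))
    t_rel = (np.arange(n_pre_p + n_post_p) - n_pre_p) * dt
    plateau = amp * preset.desensitization_ratio
    ce = 0.0 if preset.nonfunctional else preset.true_ce
    luc_sig = ce * plateau * washin_fraction(t_rel, perfusion, preset.step_count)
    luc = luc_sig + _patch_noise(rng, luc_sig.size, dt, noise)
    luc_trace = SweepTrace(
        luc,
        sampling_rate=sampling_rate,
        annotations=[
            EpochAnnotation(
                "perfusion_onset",
                start_s=pre_perfusion_s,
                end_s=pre_perfusion_s,
                luciferin=preset.luciferin,
                concentration_uM=perfusion.final_concentration,
            )
        ],
    )
    return photo_trace, luc_trace


def _patch_noise(
    rng: np.random.Generator, n: int, dt: float, noise: NoiseModel
) -> np.ndarray:
    out = np.zeros(n)
    if noise.patch_sd > 0:
        out += rng.normal(0.0, noise.patch_sd, n)
    if noise.drift_slope != 0.0:
        out += noise.drift_slope * np.arange(n) * dt
    return out


def make_patch_cohort(
    preset: LMOPreset,
    n_cells: int,
    seed: int = 0,
    perfusion: PerfusionModel | None = None,
    noise: NoiseModel | None = None,
    **sweep_kwargs,
) -> list[tuple[SweepTrace, SweepTrace]]:
    """Generate sweep pairs for ``n_cells`` independent cells.

    Each cell draws a multiplicative expression scale ~ lognormal(0,
    expression_cv) applied to both of its sweeps, so the per-cell coupling
    ratio is unaffected by expression variability.
    """
    if n_cells < 1:
        raise PresetError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    scales = (
        np.exp(rng.normal(0.0, preset.expression_cv, n_cells))
        if preset.expression_cv > 0
        else np.ones(n_cells)
    )
    return [
        make_patch_sweeps(
            preset,
            perfusion=perfusion,
            noise=noise,
            seed=rng,
            expression_scale=float(s),
            **sweep_kwargs,
        )
        for s in scales
    ]


# Biphasic extracellular spike template, 1.0 ms at 10 kHz, trough normalized
# to -1 (sample 3), followed by a smaller positive overshoot.
SPIKE_TEMPLATE = np.array(
    [0.0, -0.35, -0.82, -1.0, -0.55, 0.1, 0.32, 0.25, 0.12, 0.03]
)
_TEMPLATE_TROUGH = int(np.argmin(SPIKE_TEMPLATE))


def _refractory_poisson_times(
    rng: np.random.Generator, rate_hz: float, t0: float, t1: float, refractory_s: float
) -> np.ndarray:
    """Spike times in [t0, t1) at mean rate ``rate_hz`` with a hard refractory gap.

    ISIs are refractory + Exp(rate_adj) with rate_adj chosen so the mean ISI
    equals 1/rate_hz, keeping the realized rate at its nominal value.
    """
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    if rate_hz * refractory_s >= 1.0:
        raise PresetError(
            f"rate {rate_hz} Hz incompatible with {refractory_s*1e3:.1f} ms refractory period"
        )
    rate_adj = rate_hz / (1.0 - rate_hz * refractory_s)
    span = t1 - t0
    # draw in blocks until past the end
    times: list[np.ndarray] = []
    t = t0 + rng.exponential(1.0 / rate_hz)  # first event: plain exponential delay
    while t < t1:
        n_block = max(16, int(1.5 * rate_hz * (t1 - t)) + 8)
        isis = refractory_s + rng.exponential(1.0 / rate_adj, n_block)
        block = t + np.concatenate(([0.0], np.cumsum(isis)))
        times.append(block[block < t1])
        t = block[-1]
    if not times:
        return np.empty(0)
    return np.concatenate(times)


def make_mea_recording(
    rates: MEAPresetRates,
    n_channels: int = 8,
    duration: float = 135.0,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    template_amplitude_sd: float = 12.0,
    refractory_s: float = 0.002,
    artifact_duration_s: float = 0.05,
) -> tuple[MEARecording, list[SpikeTrain]]:
    """Simulate one MEA recording plus per-channel ground-truth spike times.

    Each channel fires as an independent renewal process at ``pre_rate``
    before the treatment event and ``post_rate`` after it.  Spikes are added
    as biphasic templates with trough ``template_amplitude_sd`` x the noise
    SD; a square artifact of ``rates.artifact_amplitude`` µV (downward) is
    applied on all channels for ``artifact_duration_s`` at the event.
    """
    if n_channels < 1:
        raise PresetError("n_channels must be >= 1")
    if duration <= 0:
        raise PresetError("duration must be positive")
    if rates.event_time >= duration:
        raise PresetError("event_time must fall inside the recording")
    if noise is None:
        noise = NoiseModel()
    rng = _rng(seed)
    n_samp = int(round(duration * sampling_rate))
    template = SPIKE_TEMPLATE * template_amplitude_sd * noise.mea_sd
    tlen = template.size

    data = np.empty((n_channels, n_samp))
    truth: list[SpikeTrain] = []
    labels = [f"ch{i + 1:02d}" for i in range(n_channels)]
    ev_i0 = int(round(rates.event_time * sampling_rate))
    ev_i1 = min(n_samp, ev_i0 + int(round(artifact_duration_s * sampling_rate)))

    for ci, label in enumerate(labels):
        x = rng.normal(0.0, noise.mea_sd, n_samp) if noise.mea_sd > 0 else np.zeros(n_samp)
        pre = _refractory_poisson_times(rng, rates.pre_rate, 0.0, rates.event_time, refractory_s)
        post = _refractory_poisson_times(rng, rates.post_rate, rates.event_time, duration, refractory_s)
        spikes = np.concatenate([pre, post])
        kept = []
        for t in spikes:
            trough_i = int(round(t * sampling_rate))
            start = trough_i - _TEMPLATE_TROUGH
            if start < 0 or start + tlen > n_samp:
                continue
            x[start : start + tlen] += template
            kept.append(trough_i / sampling_rate)
        x[ev_i0:ev_i1] -= rates.artifact_amplitude
        data[ci] = x
        truth.append(SpikeTrain(label, np.array(sorted(kept))))

    event = TreatmentEvent(
        rates.treatment,
        rates.event_time,
        wavelength_nm=rates.wavelength_nm,
        concentration_uM=rates.ctz_concentration or None,
    )
    rec = MEARecording(labels, data, sampling_rate=sampling_rate, events=[event])
    return rec, truth


def make_plate_readings(
    presets: list[LMOPreset],
    n_wells: int = 8,
    seed: int | np.random.Generator = 0,
    *,
    quench_strength: float = 0.7,
    fluorescence_scale: float = 1000.0,
    luminescence_scale: float = 1e5,
    well_noise_sigma: float = 0.2,
) -> pd.DataFrame:
    """Simulate plate-reader luminescence/fluorescence for each construct.

    Per well, expression ~ lognormal(0, expression_cv) scales both readouts;
    luminescence carries an additional FRET donor-quenching factor
    ``1 - quench_strength * true_ce``, so efficiently coupled constructs emit
    fewer photons per unit expression.  Noise is multiplicative lognormal.
    """
    if not presets:
        raise PresetError("preset list must be non-empty")
    if n_wells < 2:
        raise PresetError("n_wells must be >= 2")
    if not (0.0 <= quench_strength < 1.0):
        raise PresetError("quench_strength must be in [0, 1)")
    rng = _rng(seed)
    rows = []
    for preset in presets:
        ce = 0.0 if preset.nonfunctional else preset.true_ce
        for w in range(n_wells):
            expr = np.exp(rng.normal(0.0, preset.expression_cv))
            lum = (
                luminescence_scale
                * preset.radiance_au
                * (1.0 - quench_strength * ce)
                * expr
                * np.exp(rng.normal(0.0, well_noise_sigma))
            )
            fluor = (
                fluorescence_scale * expr * np.exp(rng.normal(0.0, well_noise_sigma))
            )
            rows.append(
                {
                    "construct": preset.name,
                    "well": f"{preset.name}_w{w + 1:02d}",
                    "luminescence_au": lum,
                    "fluorescence_au": fluor,
                }
            )
    return pd.DataFrame(rows)
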