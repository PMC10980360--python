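"""Construct presets and simulation parameter models.

A luminopsin (LMO) is a luciferase-opsin fusion protein that can be driven
either optogenetically (physical light source) or chemogenetically (luciferin
substrate oxidized by the tethered luciferase).  Each :class:`LMOPreset`
parameterizes the synthetic-data generator for one construct: the maximal
lamp-evoked photocurrent, its activation/desensitization kinetics, the true
luciferase-to-opsin coupling efficiency, the qualitative "stepped" activation
behaviour seen with bright emitters, and the construct's relative emitted
radiance.

The shipped registry covers the excitatory constructs characterized in HEK293
cells: sbGLuc- and NCS2-based VChR1 fusions, the machine-learned ChRger3
pairing, GeNL_SS-based VChR1/ChRmine fusions, and a red-shifted C-terminal
ChRmine fusion.  Coupling efficiencies are the per-construct cohort means;
absolute current amplitudes are free parameters chosen at physiologically
plausible values (hundreds of pA for healthy expression at -60 mV), and
radiance values encode only the reported ordinal relationships.
"""

from __future__ import annotations

from dataclasses import dataclass


class PresetError(ValueError):
    """Raised when a generator preset fails validation."""


@dataclass(frozen=True)
class LMOPreset:
    """Generator parameterization for one luminopsin construct.

    Parameters
    ----------
    name:
        Registry label, e.g. ``"lmo11"``.
    peak_photocurrent:
        Driving amplitude of the lamp-evoked current in pA; negative values
        are inward (the convention for the excitatory opsins modelled here).
    desensitization_ratio:
        Plateau/peak magnitude ratio in (0, 1]; 1 means no desensitization.
    tau_rise, tau_desens, tau_off:
        Activation, desensitization and shut-off time constants in ms.
    true_ce:
        Ground-truth coupling efficiency (luciferin-induced current over
        maximal photocurrent), in [0, 1].
    nonfunctional:
        If True the construct expresses but produces neither usable
        photocurrent nor luciferin response (membrane trafficking failure);
        both currents are forced near zero regardless of ``true_ce``.
    step_count:
        Number of discrete activation increments during luciferin wash-in;
        0 gives a smooth saturating rise.
    luciferin:
        Substrate label: ``CTZ``, ``hCTZ`` or ``eCTZ``.
    radiance_au:
        Relative emitted radiance per unit expression (arbitrary units).
    expression_cv:
        Lognormal sigma of the cell-to-cell expression scale.
    emitter, opsin, arrangement:
        Descriptive metadata for summary tables (light emitter, opsin, and
        N-/C-terminal arrangement of the emitter).
    """

    name: str
    peak_photocurrent: float
    true_ce: float
    desensitization_ratio: float = 0.8
    tau_rise: float = 3.0
    tau_desens: float = 150.0
    tau_off: float = 20.0
    nonfunctional: bool = False
    step_count: int = 0
    luciferin: str = "hCTZ"
    radiance_au: float = 1.0
    expression_cv: float = 0.3
    emitter: str = ""
    opsin: str = ""
    arrangement: str = "N-terminal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_ce <= 1.0):
            raise PresetError(f"true_ce must be in [0, 1], got {self.true_ce}")
        if not (0.0 < self.desensitization_ratio <= 1.0):
            raise PresetError(
                f"desensitization_ratio must be in (0, 1], got {self.desensitization_ratio}"
            )
        for label in ("tau_rise", "tau_desens", "tau_off"):
            if getattr(self, label) <= 0:
                raise PresetError(f"{label} must be positive")
        if self.step_count < 0 or int(self.step_count) != self.step_count:
            raise PresetError(f"step_count must be a non-negative integer, got {self.step_count}")
        if self.luciferin not in ("CTZ", "hCTZ", "eCTZ"):
            raise PresetError(f"unknown luciferin label {self.luciferin!r}")
        if self.radiance_au < 0:
            raise PresetError("radiance_au must be >= 0")
        if self.expression_cv < 0:
            raise PresetError("expression_cv must be >= 0")

    @property
    def functional(self) -> bool:
        return not self.nonfunctional


@dataclass(frozen=True)
class PerfusionModel:
    """Single-compartment luciferin wash-in for the recording chamber.

    The chamber exchanges at ``flow_rate`` giving an exponential approach to
    ``final_concentration`` with time constant ``washin_tau`` =
    chamber_volume / flow_rate (seconds, with volume in mL and flow in
    mL/min converted internally).
    """

    flow_rate: float = 1.5  # mL/min
    chamber_volume: float = 1.0  # mL
    final_concentration: float = 100.0  # µM
    k_half: float = 20.0  # µM half-saturating luciferin concentration

    def __post_init__(self) -> None:
        if self.flow_rate <= 0 or self.chamber_volume <= 0:
            raise PresetError("flow_rate and chamber_volume must be positive")
        if self.final_concentration <= 0 or self.k_half <= 0:
            raise PresetError("final_concentration and k_half must be positive")

    @property
    def washin_tau(self) -> float:
        """Wash-in time constant in seconds."""
        return self.chamber_volume / self.flow_rate * 60.0


@dataclass(frozen=True)
class NoiseModel:
    """Recording noise floors: additive white Gaussian plus optional drift."""

    patch_sd: float = 5.0  # pA
    mea_sd: float = 5.0  # µV
    drift_slope: float = 0.0  # pA/s, patch sweeps only

    def __post_init__(self) -> None:
        if self.patch_sd < 0 or self.mea_sd < 0:
            raise PresetError("noise SDs must be >= 0")


@dataclass(frozen=True)
class MEAPresetRates:
    """Per-channel firing-rate regime for one construct x treatment condition."""

    construct: str
    treatment: str  # LED | vehicle | CTZ
    pre_rate: float  # Hz per channel
    post_rate: float  # Hz per channel
    event_time: float = 70.0  # s
    artifact_amplitude: float = 100.0  # µV, time-locked application artifact
    ctz_concentration: float = 0.0  # µM, 10 for CTZ treatments
    wavelength_nm: float | None = None  # LED probe wavelength

    def __post_init__(self) -> None:
        if self.pre_rate < 0 or self.post_rate < 0:
            raise PresetError("firing rates must be >= 0")
        if self.event_time <= 0:
            raise PresetError("event_time must be positive")
        if self.treatment not in ("LED", "vehicle", "CTZ"):
            raise PresetError(f"unknown treatment {self.treatment!r}")


def _p(**kw) -> LMOPreset:
    return LMOPreset(**kw)


#: Shipped construct registry.  Coupling efficiencies are cohort means from
#: whole-cell recordings (n=5 per construct); `lmo7` and `lmo7_alt` are the
#: two independently recorded LMO7 cohorts.  Photocurrent amplitudes are
#: plausible free choices; radiance encodes the ordinal plate-reader ranking
#: (the double-emitter nonfunctional construct is the brightest).
PRESETS: dict[str, LMOPreset] = {
    p.name: p
    for p in [
        _p(name="lmo3", peak_photocurrent=-450.0, true_ce=0.31, step_count=1,
           luciferin="CTZ", radiance_au=0.75, emitter="sbGLuc", opsin="VChR1"),
        _p(name="lmo7", peak_photocurrent=-500.0, true_ce=0.52,
           radiance_au=1.0, emitter="NCS2", opsin="VChR1"),
        _p(name="lmo7_alt", peak_photocurrent=-500.0, true_ce=0.56,
           radiance_au=1.0, emitter="NCS2", opsin="VChR1"),
        _p(name="lmo7_2", peak_photocurrent=-480.0, true_ce=0.30,
           radiance_au=1.0, emitter="NCS2", opsin="VChR1",
           arrangement="C-terminal"),
        _p(name="lmo7_3", peak_photocurrent=-4.0, true_ce=0.0,
           nonfunctional=True, radiance_au=2.0, emitter="NCS2", opsin="VChR1",
           arrangement="N- and C-terminal"),
        _p(name="lmo8", peak_photocurrent=-900.0, true_ce=0.0,
           radiance_au=1.3, emitter="NCS2", opsin="ChRger3"),
        _p(name="lmo10", peak_photocurrent=-550.0, true_ce=0.57, step_count=5,
           radiance_au=1.1, emitter="GeNL_SS", opsin="VChR1"),
        _p(name="lmo11", peak_photocurrent=-700.0, true_ce=0.65, step_count=6,
           radiance_au=1.1, emitter="GeNL_SS", opsin="ChRmine"),
        _p(name="lmo12", peak_photocurrent=-700.0, true_ce=0.16,
           luciferin="eCTZ", radiance_au=0.7, emitter="mCh22.0-RLuc8.6",
           opsin="ChRmine", arrangement="C-terminal"),
    ]
}

#: Firing-rate regimes for the MEA experiments: cortical cultures expressing
#: either the NCS2-VChR1 or GeNL_SS-ChRmine construct, probed with an LED,
#: vehicle, or 10 µM hCTZ.  Rates are the reported pooled per-electrode means.
MEA_RATE_PRESETS: dict[tuple[str, str], MEAPresetRates] = {
    (r.construct, r.treatment.lower()): r
    for r in [
        MEAPresetRates("lmo7", "LED", 6.92, 12.63, wavelength_nm=465.0),
        MEAPresetRates("lmo7", "vehicle", 5.09, 4.39),
        MEAPresetRates("lmo7", "CTZ", 8.52, 14.54, ctz_concentration=10.0),
        MEAPresetRates("lmo11", "LED", 4.48, 34.75, wavelength_nm=465.0),
        MEAPresetRates("lmo11", "vehicle", 6.75, 7.10),
        MEAPresetRates("lmo11", "CTZ", 12.91, 16.65, ctz_concentration=10.0),
    ]
}


def get_preset(name: str) -> LMOPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise PresetError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def get_mea_rates(construct: str, treatment: str) -> MEAPresetRates:
    key = (construct, treatment.lower())
    try:
        return MEA_RATE_PRESETS[key]
    except KeyError:
        raise PresetError(
            f"no MEA rate preset for {construct!r} / {treatment!r}; "
            f"available: {sorted(MEA_RATE_PRESETS)}"
        ) from None
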