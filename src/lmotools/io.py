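"""CSV + JSON sidecar file formats and run configuration.

Canonical on-disk dialect: UTF-8 CSV with a header row, '.' decimal, times
in seconds, currents in pA, voltages in µV.  Every trace CSV is accompanied
by a JSON sidecar of the same stem carrying the sampling rate, units, epoch
or event annotations (half-open [start, end) intervals, 0-based samples),
and — for simulated MEA data — the ground-truth spike times.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .traces import (
    EpochAnnotation,
    MEARecording,
    SpikeTrain,
    SweepTrace,
    TreatmentEvent,
)

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "TruncatedFileError",
    "RunConfig",
    "write_sweep_bundle",
    "write_mea_bundle",
    "read_trace_bundle",
    "write_rate_summaries",
    "write_coupling_results",
]


class SchemaError(ValueError):
    """Sidecar or table does not match the expected schema."""


class TruncatedFileError(ValueError):
    """Trace CSV has missing values / ragged rows."""


# --------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Flat, versioned key-value document echoed into every output directory."""

    seed: int = 0
    values: dict[str, Any] = dataclasses.field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    _KNOWN_KEYS = {
        "seed",
        "schema_version",
        "measurement",
        "detector",
        "permutation",
        "preset",
        "treatment",
        "n_cells",
        "n_channels",
        "duration_s",
        "window_len_s",
    }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - cls._KNOWN_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        seed = int(d.get("seed", 0))
        version = int(d.get("schema_version", SCHEMA_VERSION))
        values = {k: v for k, v in d.items() if k not in ("seed", "schema_version")}
        return cls(seed=seed, values=values, schema_version=version)

    def to_dict(self) -> dict[str, Any]:
        return {"schema_version": self.schema_version, "seed": self.seed, **self.values}

    def echo(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "run_config.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


# --------------------------------------------------------------------------
# writers


def _epoch_to_dict(ann: EpochAnnotation) -> dict[str, Any]:
    d: dict[str, Any] = {"kind": ann.kind, "start_s": ann.start_s, "end_s": ann.end_s}
    if ann.wavelength_nm is not None:
        d["wavelength_nm"] = ann.wavelength_nm
    if ann.luciferin is not None:
        d["luciferin"] = ann.luciferin
    if ann.concentration_uM is not None:
        d["concentration_uM"] = ann.concentration_uM
    return d


def write_sweep_bundle(trace: SweepTrace, base: str | Path) -> tuple[Path, Path]:
    """Write ``base.csv`` (time_s, current_pA) and ``base.json``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    pd.DataFrame(
        {"time_s": trace.times_s, "current_pA": trace.samples}
    ).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "patch_sweep",
        "sampling_rate_hz": trace.sampling_rate,
        "units": {"time": "s", "current": "pA"},
        "holding_potential_mv": trace.holding_potential,
        "epochs": [_epoch_to_dict(a) for a in trace.annotations],
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return csv_path, json_path


def write_mea_bundle(
    recording: MEARecording,
    base: str | Path,
    ground_truth: list[SpikeTrain] | None = None,
) -> tuple[Path, Path]:
    """Write ``base.csv`` (time_s, ch01..chNN in µV) and ``base.json``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    cols = {"time_s": np.arange(recording.samples.shape[1]) / recording.sampling_rate}
    for label, row in zip(recording.channels, recording.samples):
        cols[label] = row
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "kind": "mea_recording",
        "sampling_rate_hz": recording.sampling_rate,
        "units": {"time": "s", "voltage": "uV"},
        "channels": list(recording.channels),
        "events": [
            {
                "treatment": ev.treatment,
                "time_s": ev.time_s,
                "wavelength_nm": ev.wavelength_nm,
                "concentration_uM": ev.concentration_uM,
            }
            for ev in recording.events
        ],
    }
    if ground_truth is not None:
        sidecar["ground_truth_spikes"] = {
            t.channel: [float(x) for x in t.times_s] for t in ground_truth
        }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return csv_path, json_path


# --------------------------------------------------------------------------
# readers


def _load_sidecar(base: Path) -> dict[str, Any]:
    json_path = base.with_suffix(".json")
    if not json_path.exists():
        raise SchemaError(f"sidecar {json_path} not found")
    sidecar = json.loads(json_path.read_text())
    for fieldname in ("kind", "sampling_rate_hz"):
        if fieldname not in sidecar:
            raise SchemaError(f"sidecar {json_path} missing required field {fieldname!r}")
    return sidecar


def _check_complete(df: pd.DataFrame, csv_path: Path) -> None:
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise TruncatedFileError(
            f"{csv_path} has missing values starting at data row {row}"
        )


def read_trace_bundle(base: str | Path) -> SweepTrace | MEARecording:
    """Load a trace bundle; the sidecar ``kind`` selects the return type.

    ``base`` may be the CSV path, the JSON path, or the common stem.
    Returns the ground-truth spike trains alongside an MEA recording via
    :func:`read_mea_ground_truth` when needed.
    """
    base = Path(base)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    sidecar = _load_sidecar(base)
    csv_path = base.with_suffix(".csv")
    if not csv_path.exists():
        raise SchemaError(f"trace CSV {csv_path} not found")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    _check_complete(df, csv_path)
    fs = float(sidecar["sampling_rate_hz"])
    kind = sidecar["kind"]
    if kind == "patch_sweep":
        if "current_pA" not in df.columns:
            raise SchemaError(f"{csv_path} lacks a current_pA column")
        units = sidecar.get("units", {})
        if units.get("current", "pA") != "pA":
            raise SchemaError(f"unsupported current unit {units.get('current')!r}")
        annotations = [
            EpochAnnotation(
                kind=e["kind"],
                start_s=e["start_s"],
                end_s=e["end_s"],
                wavelength_nm=e.get("wavelength_nm"),
                luciferin=e.get("luciferin"),
                concentration_uM=e.get("concentration_uM"),
            )
            for e in sidecar.get("epochs", [])
        ]
        return SweepTrace(
            df["current_pA"].to_numpy(),
            sampling_rate=fs,
            holding_potential=float(sidecar.get("holding_potential_mv", -60.0)),
            annotations=annotations,
        )
    if kind == "mea_recording":
        channels = sidecar.get("channels")
        if not channels:
            raise SchemaError(f"sidecar for {csv_path} missing 'channels'")
        missing = [c for c in channels if c not in df.columns]
        if missing:
            raise SchemaError(f"{csv_path} lacks channel columns {missing}")
        units = sidecar.get("units", {})
        if units.get("voltage", "uV") != "uV":
            raise SchemaError(f"unsupported voltage unit {units.get('voltage')!r}")
        events = [
            TreatmentEvent(
                treatment=e["treatment"],
                time_s=e["time_s"],
                wavelength_nm=e.get("wavelength_nm"),
                concentration_uM=e.get("concentration_uM"),
            )
            for e in sidecar.get("events", [])
        ]
        samples = np.vstack([df[c].to_numpy() for c in channels])
        return MEARecording(list(channels), samples, sampling_rate=fs, events=events)
    raise SchemaError(f"unknown bundle kind {kind!r}")


def read_mea_ground_truth(base: str | Path) -> list[SpikeTrain] | None:
    """Ground-truth spike trains from a simulated MEA sidecar, if present."""
    base = Path(base)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    sidecar = _load_sidecar(base)
    gt = sidecar.get("ground_truth_spikes")
    if gt is None:
        return None
    return [SpikeTrain(ch, np.asarray(times, dtype=float)) for ch, times in gt.items()]


# --------------------------------------------------------------------------
# result tables


def write_coupling_results(results, summary, path: str | Path) -> Path:
    """Per-cell results CSV: cell_id, photocurrent_pA, luciferin_pA, ce, flags."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "cell_id": f"cell{i + 1:02d}",
                "photocurrent_pA": r.photocurrent.amplitude_pA,
                "luciferin_pA": r.luciferin_current.amplitude_pA,
                "ce": "" if r.nonfunctional else r.coupling_efficiency,
                "flags": ";".join(
                    f
                    for f in (
                        "nonfunctional" if r.nonfunctional else "",
                        "plateau_fallback" if r.luciferin_current.plateau_fallback else "",
                    )
                    if f
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_rate_summaries(summaries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "channel": s.channel,
                "pre_rate_hz": s.pre_rate,
                "post_rate_hz": s.post_rate,
                "pre_start_s": s.pre_window[0],
                "pre_end_s": s.pre_window[1],
                "post_start_s": s.post_window[0],
                "post_end_s": s.post_window[1],
                "responder": s.responder,
            }
            for s in summaries
        ]
    ).to_csv(path, index=False)
    return path
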