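"""Cross-construct summary tables.

Combines per-construct cohort analyses into a single table carrying the
construct's descriptive features (light emitter, opsin, arrangement,
luciferin) next to its mean coupling efficiency, rendering nonfunctional
cohorts as "n.f.".  The reference-construct CE (the sbGLuc-VChR1 fusion,
the established benchmark for a robustly functioning construct) is recorded
in the metadata so plots can draw it as a reference line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .patch import CohortSummary
from .presets import PRESETS

__all__ = ["construct_report", "write_report"]

REFERENCE_CONSTRUCT = "lmo3"

#: Display order mirroring the construct comparison figure.
REPORT_ORDER = [
    "lmo3", "lmo7", "lmo7_alt", "lmo7_2", "lmo7_3", "lmo8", "lmo10", "lmo11", "lmo12",
]


def construct_report(
    summaries: dict[str, CohortSummary],
) -> tuple[pd.DataFrame, dict]:
    """Per-construct table + metadata from cohort summaries keyed by preset name."""
    if not summaries:
        raise ValueError("no cohort summaries supplied")
    order = [n for n in REPORT_ORDER if n in summaries] + [
        n for n in sorted(summaries) if n not in REPORT_ORDER
    ]
    rows = []
    for name in order:
        s = summaries[name]
        preset = PRESETS.get(name)
        rows.append(
            {
                "construct": name,
                "emitter": preset.emitter if preset else "",
                "opsin": preset.opsin if preset else "",
                "arrangement": preset.arrangement if preset else "",
                "luciferin": preset.luciferin if preset else "",
                "mean_ce": "n.f." if s.nonfunctional else f"{s.mean_ce:.2f}",
                "n_cells": s.n_cells,
                "n_functional": s.n_functional,
            }
        )
    table = pd.DataFrame(rows)
    meta = {}
    ref = summaries.get(REFERENCE_CONSTRUCT)
    if ref is not None and not ref.nonfunctional:
        meta["reference_construct"] = REFERENCE_CONSTRUCT
        meta["reference_ce"] = ref.mean_ce
    return table, meta


def write_report(
    summaries: dict[str, CohortSummary],
    out_dir: str | Path,
    rate_table: pd.DataFrame | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, meta = construct_report(summaries)
    table.to_csv(out / "construct_summary.csv", index=False)
    (out / "report_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    if rate_table is not None:
        rate_table.to_csv(out / "rate_comparisons.csv", index=False)
    return out
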