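"""Expression-normalized bioluminescence and its relation to coupling.

Plate-reader luminescence is normalized well-by-well to the fluorescence of
the construct's reporter protein, removing expression-level differences.
Across constructs, emitted radiance is expected to vary inversely with
coupling efficiency: when luciferase-to-opsin energy transfer (FRET) is
efficient, donor photon emission is quenched, so poorly coupled constructs
are the brightest.  The summary here is the Spearman rank correlation
between per-construct coupling efficiency and mean normalized radiance,
with nonfunctional constructs entering the ranking at CE 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellReading",
    "RadianceSummary",
    "normalize_bioluminescence",
    "summarize_wells",
    "ce_vs_radiance",
]


class RadianceError(ValueError):
    """Raised for invalid plate-reader inputs."""


@dataclass(frozen=True)
class WellReading:
    construct: str
    well_id: str
    luminescence_au: float
    fluorescence_au: float

    def __post_init__(self) -> None:
        if self.luminescence_au < 0 or self.fluorescence_au < 0:
            raise RadianceError("readings must be >= 0")


@dataclass(frozen=True)
class RadianceSummary:
    construct: str
    mean_normalized_radiance: float
    ce: float | None  # None = nonfunctional
    n_wells: int

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise RadianceError("n_wells must be >= 1")


def normalize_bioluminescence(lum: float, fluor: float) -> float:
    """Luminescence per unit reporter fluorescence (scale-invariant ratio)."""
    if fluor <= 0:
        raise RadianceError(
            f"fluorescence must be positive to normalize, got {fluor}"
        )
    return lum / fluor


def summarize_wells(
    wells: pd.DataFrame, ce_by_construct: dict[str, float | None]
) -> list[RadianceSummary]:
    """Per-construct mean of well-level normalized radiance.

    ``wells`` needs columns construct, luminescence_au, fluorescence_au.
    The per-construct radiance is the mean of per-well ratios (each well is
    one biological replicate), not the ratio of summed signals.
    """
    required = {"construct", "luminescence_au", "fluorescence_au"}
    missing = required - set(wells.columns)
    if missing:
        raise RadianceError(f"wells table missing columns: {sorted(missing)}")
    out = []
    for construct, grp in wells.groupby("construct", sort=True):
        ratios = [
            normalize_bioluminescence(l, f)
            for l, f in zip(grp["luminescence_au"], grp["fluorescence_au"])
        ]
        out.append(
            RadianceSummary(
                construct=str(construct),
                mean_normalized_radiance=float(np.mean(ratios)),
                ce=ce_by_construct.get(str(construct)),
                n_wells=len(ratios),
            )
        )
    return out


def ce_vs_radiance(
    summaries: list[RadianceSummary],
) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between CE and normalized radiance.

    Nonfunctional constructs (ce None) rank at CE 0.  Returns (rho, table)
    with the table sorted by descending radiance; rho is NaN when either
    variable is constant (all-tied ranks carry no ordering information).
    """
    if len(summaries) < 3:
        raise RadianceError("need at least 3 constructs for a rank correlation")
    ce = np.array([0.0 if s.ce is None else s.ce for s in summaries])
    rad = np.array([s.mean_normalized_radiance for s in summaries])
    if np.all(ce == ce[0]) or np.all(rad == rad[0]):
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(ce, rad).statistic)
    table = pd.DataFrame(
        {
            "construct": [s.construct for s in summaries],
            "ce": [s.ce for s in summaries],
            "mean_normalized_radiance": rad,
            "n_wells": [s.n_wells for s in summaries],
        }
    ).sort_values("mean_normalized_radiance", ascending=False, ignore_index=True)
    return rho, table
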