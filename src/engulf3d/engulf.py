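"""Nested volume-overlap engulfment metrics and per-animal aggregation.

The core readouts of the assay, per section:

* microglial volume (Iba1 mask),
* lysosomal volume within microglia (CD68 AND Iba1),
* total neurite/synapse marker volume,
* engulfed marker volume (marker AND CD68 AND Iba1),
* percent engulfed = 100 x engulfed / marker volume.

Engulfment requires the triple overlap — marker colocalised with lysosomes
*inside* microglia; a secondary contact metric (marker AND Iba1, without
lysosomal localisation) is also reported.  Animals, not sections, are the
experimental unit: sections are averaged per animal (default minimum 6
sections) before any statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment3d import BinaryMask3D, mask_volume_um3

__all__ = [
    "EngulfmentResult",
    "lysosome_in_microglia",
    "engulfment_metrics",
    "aggregate_cohort",
    "group_label",
]

log = logging.getLogger(__name__)

#: CohortTable metric columns, averaged across sections per animal.
METRIC_COLUMNS = (
    "iba1_volume_um3",
    "cd68_in_iba1_volume_um3",
    "marker_volume_um3",
    "engulfed_volume_um3",
    "marker_in_iba1_volume_um3",
    "percent_engulfed",
)


@dataclass
class EngulfmentResult:
    """Per-section engulfment readouts (volumes in um^3)."""

    iba1_volume_um3: float
    cd68_in_iba1_volume_um3: float
    marker_volume_um3: float
    engulfed_volume_um3: float
    percent_engulfed: float  # NaN when marker volume is 0 (see defined flag)
    marker_in_iba1_volume_um3: float = 0.0
    percent_defined: bool = True
    marker_kind: str = "VGAT"
    section_id: str = ""
    animal_id: str = ""


def _check_compatible(*masks: BinaryMask3D) -> None:
    ref = masks[0]
    for m in masks[1:]:
        if m.grid.shape != ref.grid.shape:
            raise ValueError(
                f"mask shapes differ: {m.grid.shape} vs {ref.grid.shape}"
            )
        if m.voxel != ref.voxel:
            raise ValueError(f"voxel sizes differ: {m.voxel} vs {ref.voxel}")


def lysosome_in_microglia(
    iba1_mask: BinaryMask3D, cd68_mask: BinaryMask3D
) -> BinaryMask3D:
    """Lysosomal compartment inside microglia: CD68 AND Iba1, voxelwise."""
    _check_compatible(iba1_mask, cd68_mask)
    return BinaryMask3D(
        grid=iba1_mask.grid & cd68_mask.grid,
        voxel=iba1_mask.voxel,
        source_channel="cd68&iba1",
        method="intersection",
    )


def engulfment_metrics(
    iba1_mask: BinaryMask3D,
    cd68_mask: BinaryMask3D,
    marker_mask: BinaryMask3D,
    marker_kind: str = "VGAT",
    section_id: str = "",
    animal_id: str = "",
) -> EngulfmentResult:
    """Compute all overlap volumes and the percent of marker engulfed.

    ``engulfed = marker AND cd68 AND iba1``; the percent denominator is the
    total marker volume in the analysed field of view.  When no marker
    signal is present the percent is NaN and flagged undefined, with the
    volumes still reported.
    """
    _check_compatible(iba1_mask, cd68_mask, marker_mask)
    lyso_in = lysosome_in_microglia(iba1_mask, cd68_mask)
    engulfed = BinaryMask3D(
        grid=marker_mask.grid & lyso_in.grid,
        voxel=marker_mask.voxel,
        source_channel="marker&cd68&iba1",
        method="intersection",
    )
    contact = BinaryMask3D(
        grid=marker_mask.grid & iba1_mask.grid,
        voxel=marker_mask.voxel,
        source_channel="marker&iba1",
        method="intersection",
    )
    marker_vol = mask_volume_um3(marker_mask)
    engulfed_vol = mask_volume_um3(engulfed)
    defined = marker_vol > 0
    percent = 100.0 * engulfed_vol / marker_vol if defined else math.nan
    return EngulfmentResult(
        iba1_volume_um3=mask_volume_um3(iba1_mask),
        cd68_in_iba1_volume_um3=mask_volume_um3(lyso_in),
        marker_volume_um3=marker_vol,
        engulfed_volume_um3=engulfed_vol,
        percent_engulfed=percent,
        marker_in_iba1_volume_um3=mask_volume_um3(contact),
        percent_defined=defined,
        marker_kind=marker_kind,
        section_id=section_id,
        animal_id=animal_id,
    )


def group_label(neonatal: str, adult: str) -> str:
    """Map factor levels to the IN(neonatal, adult) group notation."""
    return f"IN({neonatal},{adult})"


def aggregate_cohort(
    results: list[EngulfmentResult],
    manifest: pd.DataFrame,
    min_sections: int = 6,
) -> pd.DataFrame:
    """Aggregate per-section results into a per-animal cohort table.

    ``manifest`` has one row per animal with columns ``animal_id``, ``sex``,
    ``neonatal_incision``, ``adult_incision``.  Each metric is the
    arithmetic mean across the animal's sections; animals with fewer than
    ``min_sections`` sections are excluded with a logged warning.  An animal
    present in the results but absent from the manifest is an error.
    """
    if not results:
        raise ValueError("no results to aggregate")
    required = {"animal_id", "sex", "neonatal_incision", "adult_incision"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    manifest = manifest.drop_duplicates("animal_id").set_index("animal_id")

    per_section = pd.DataFrame(
        [{c: getattr(r, c) for c in METRIC_COLUMNS} | {"animal_id": r.animal_id}
         for r in results]
    )
    unknown = set(per_section["animal_id"]) - set(manifest.index)
    if unknown:
        raise ValueError(f"animals missing from manifest: {sorted(unknown)}")

    rows = []
    for animal_id, sub in per_section.groupby("animal_id", sort=True):
        n = len(sub)
        if n < min_sections:
            log.warning(
                "excluding animal %s: %d sections < minimum %d",
                animal_id, n, min_sections,
            )
            continue
        info = manifest.loc[animal_id]
        row = {
            "animal_id": animal_id,
            "sex": info["sex"],
            "neonatal_incision": info["neonatal_incision"],
            "adult_incision": info["adult_incision"],
            "group": group_label(info["neonatal_incision"], info["adult_incision"]),
            "n_sections": n,
        }
        for c in METRIC_COLUMNS:
            row[c] = float(sub[c].mean())
        rows.append(row)
    if not rows:
        raise ValueError(
            f"every animal fell below the {min_sections}-section minimum"
        )
    return pd.DataFrame(rows)
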