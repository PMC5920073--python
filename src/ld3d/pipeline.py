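"""End-to-end quantification of one field: segmentation through summary tables."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import morphometrics, segment_cells, segment_droplets
from .config import default_config, merge_config
from .stack_io import IntensityStack, LabelVolume, check_compatible

__all__ = ["FieldResult", "quantify_field"]


@dataclass
class FieldResult:
    """All per-field outputs of the quantification pipeline."""

    droplet_labels: LabelVolume
    cell_labels: LabelVolume
    droplets: pd.DataFrame
    cells: pd.DataFrame
    summary: dict
    spacing_pairs: pd.DataFrame
    sizes_long: pd.DataFrame


def quantify_field(fluor: IntensityStack, cells: LabelVolume | None = None,
                   brightfield: IntensityStack | None = None,
                   config: dict | None = None) -> FieldResult:
    """Run the full pipeline on one field.

    Cell labels may be supplied directly (e.g. hand-segmented, or synthetic
    truth); otherwise they are segmented from the bright-field channel.
    Deterministic: no randomness anywhere downstream of the inputs.
    """
    cfg = merge_config(default_config(), config or {})
    droplet_labels = segment_droplets.segment_droplets(fluor, cfg)

    if cells is None:
        if brightfield is None:
            raise ValueError("either cell labels or a bright-field channel is required")
        cells = segment_cells.segment_cells(brightfield, cfg)
    check_compatible(fluor, cells)

    assignment = segment_cells.assign_droplets(droplet_labels, cells)
    integrated = segment_cells.integrated_cells(cells)

    met = cfg["metrics"]
    droplets_df = morphometrics.droplet_records(
        droplet_labels, assignment,
        large_diam_um=met["large_diam_um"], small_class_um3=met["small_class_um3"],
    )
    cells_df = morphometrics.cell_records(cells, droplets_df, integrated=integrated)
    spacing = morphometrics.cell_spacing(cells, max_gap_um=met["max_gap_um"])
    summary = morphometrics.field_summary(droplet_labels, cells, spacing=spacing,
                                          integrated=integrated)
    sizes = droplets_df[["cell_id", "volume_um3"]].reset_index(drop=True)
    return FieldResult(
        droplet_labels=droplet_labels,
        cell_labels=cells,
        droplets=droplets_df,
        cells=cells_df,
        summary=summary,
        spacing_pairs=spacing[1],
        sizes_long=sizes,
    )
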