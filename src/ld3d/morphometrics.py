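"""Morphometrics: droplet geometry, per-cell oil fractions, field totals,
size classes and inter-cell spacing.

Quantities follow the conventions of per-cell organelle volumetry:

* a droplet's volume is its voxel count times the voxel volume dx*dy*dz;
* its *equivalent diameter* is that of the equal-volume sphere,
  ``(6 V / pi) ** (1/3)``;
* ``VSC`` is a cell's labeled volume, ``VLD`` the summed volume of droplets
  assigned to it, so ``VLD/VSC`` is the per-cell lipid volume fraction;
* ``VTLD/VTSF`` is the same fraction over the whole scanning field, using
  every droplet whether or not it was assigned to a cell;
* ``CS`` (cell spacing) is the mean surface gap between adjacent cells.

Per-cell statistics downstream restrict to *integrated* cells (no contact
with any face of the stack); field totals do not.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .segment_cells import CellAssignment, integrated_cells
from .stack_io import LabelVolume, check_compatible

__all__ = [
    "field_volume_um3",
    "droplet_records",
    "cell_records",
    "cell_spacing",
    "field_summary",
    "size_distribution",
]

LARGE_DIAM_UM = 5.0        # "unusually large" droplet: equivalent diameter > 5 um
SMALL_CLASS_UM3 = 100.0    # small size class: volume < 100 um^3


def field_volume_um3(shape, calibration) -> float:
    """Physical volume of the full voxel grid (VTSF for a whole field)."""
    return float(np.prod(shape)) * calibration.voxel_volume_um3()


def _border_ids(labels: np.ndarray) -> set[int]:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1],
             labels[:, :, 0], labels[:, :, -1]]
    out: set[int] = set()
    for f in faces:
        out.update(int(v) for v in np.unique(f) if v > 0)
    return out


def droplet_records(droplets: LabelVolume, assignment: CellAssignment,
                    large_diam_um: float = LARGE_DIAM_UM,
                    small_class_um3: float = SMALL_CLASS_UM3) -> pd.DataFrame:
    """One row of physical-unit geometry per droplet label.

    ``cell_id`` is 0 for unassigned droplets. Size-class flags use strict
    inequalities: ``is_large`` iff equivalent diameter strictly exceeds
    ``large_diam_um``; ``is_small_class`` iff volume is strictly below
    ``small_class_um3``.
    """
    cal = droplets.calibration
    voxvol = cal.voxel_volume_um3()
    dz, dy, dx = cal.sampling
    lab = droplets.labels
    ids = droplets.ids()
    columns = ["droplet_id", "cell_id", "voxel_count", "volume_um3",
               "eq_diameter_um", "centroid_z_um", "centroid_y_um",
               "centroid_x_um", "is_large", "is_small_class", "touches_border"]
    if len(ids) == 0:
        return pd.DataFrame(columns=columns)

    counts = np.bincount(lab.ravel())[ids]
    centroids = np.asarray(ndi.center_of_mass(np.ones_like(lab, dtype=np.uint8), lab, ids))
    border = _border_ids(lab)
    volumes = counts * voxvol
    eq_d = (6.0 * volumes / math.pi) ** (1.0 / 3.0)
    return pd.DataFrame({
        "droplet_id": ids.astype(int),
        "cell_id": [assignment.cell_of(int(i)) for i in ids],
        "voxel_count": counts.astype(int),
        "volume_um3": volumes,
        "eq_diameter_um": eq_d,
        "centroid_z_um": (centroids[:, 0] + 0.5) * dz,
        "centroid_y_um": (centroids[:, 1] + 0.5) * dy,
        "centroid_x_um": (centroids[:, 2] + 0.5) * dx,
        "is_large": eq_d > large_diam_um,
        "is_small_class": volumes < small_class_um3,
        "touches_border": [int(i) in border for i in ids],
    }, columns=columns)


def cell_records(cells: LabelVolume, records: pd.DataFrame,
                 integrated: set[int] | None = None) -> pd.DataFrame:
    """Per-cell VSC, VLD, VLD/VSC, TNLD and large-droplet count.

    ``integrated`` defaults to :func:`ld3d.segment_cells.integrated_cells`.
    A droplet record assigned to a cell id absent from the volume is an
    error.
    """
    cal = cells.calibration
    voxvol = cal.voxel_volume_um3()
    ids = cells.ids()
    if integrated is None:
        integrated = integrated_cells(cells)

    assigned = records[records["cell_id"] > 0] if len(records) else records
    known = set(int(i) for i in ids)
    if len(assigned):
        bad = set(int(c) for c in assigned["cell_id"].unique()) - known
        if bad:
            raise ValueError(f"droplets assigned to nonexistent cell id(s): {sorted(bad)}")

    counts = np.bincount(cells.labels.ravel())
    rows = []
    for cid in ids:
        cid = int(cid)
        sub = assigned[assigned["cell_id"] == cid] if len(assigned) else assigned
        vsc = counts[cid] * voxvol
        vld = float(sub["volume_um3"].sum()) if len(sub) else 0.0
        rows.append({
            "cell_id": cid,
            "voxel_count": int(counts[cid]),
            "vsc_um3": vsc,
            "vld_um3": vld,
            "vld_vsc_ratio": vld / vsc,
            "tnld": int(len(sub)),
            "n_large": int(sub["is_large"].sum()) if len(sub) else 0,
            "is_integrated": cid in integrated,
        })
    columns = ["cell_id", "voxel_count", "vsc_um3", "vld_um3", "vld_vsc_ratio",
               "tnld", "n_large", "is_integrated"]
    return pd.DataFrame(rows, columns=columns)


def cell_spacing(cells: LabelVolume, max_gap_um: float = 15.0):
    """Mean surface gap (CS) between adjacent cells, plus the per-pair table.

    For each unordered cell pair the minimum physical distance between their
    voxel centres is found; pairs within ``max_gap_um`` are adjacent. Pair
    spacing is that minimum distance minus one mean in-plane pitch — a
    surface correction taking centre-to-centre to approximately
    edge-to-edge — floored at zero. CS is the mean over adjacent pairs.

    Returns ``(mean_spacing, pairs)``; the mean is NaN (missing, not 0) with
    fewer than two cells or no adjacent pair.
    """
    cal = cells.calibration
    columns = ["cell_i", "cell_j", "min_distance_um", "spacing_um"]
    ids = cells.ids()
    if len(ids) < 2:
        warnings.warn("cell spacing undefined with fewer than 2 cells", stacklevel=2)
        return float("nan"), pd.DataFrame(columns=columns)

    pitch = np.asarray(cal.sampling)
    correction = 0.5 * (cal.dx_um + cal.dy_um)
    objects = ndi.find_objects(cells.labels)
    surfaces: dict[int, np.ndarray] = {}
    for cid in ids:
        sl = objects[int(cid) - 1]
        mask = cells.labels[sl] == cid
        interior = ndi.binary_erosion(mask)
        coords = np.argwhere(mask & ~interior)
        offset = np.array([s.start for s in sl])
        surfaces[int(cid)] = (coords + offset + 0.5) * pitch

    rows = []
    trees = {cid: cKDTree(pts) for cid, pts in surfaces.items()}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = int(ids[a]), int(ids[b])
            small, big = (i, j) if len(surfaces[i]) <= len(surfaces[j]) else (j, i)
            dmin = float(trees[big].query(surfaces[small], k=1)[0].min())
            if dmin <= max_gap_um:
                rows.append({
                    "cell_i": i,
                    "cell_j": j,
                    "min_distance_um": dmin,
                    "spacing_um": max(dmin - correction, 0.0),
                })
    pairs = pd.DataFrame(rows, columns=columns)
    mean = float(pairs["spacing_um"].mean()) if len(pairs) else float("nan")
    return mean, pairs


def field_summary(droplets: LabelVolume, cells: LabelVolume,
                  spacing=None, integrated: set[int] | None = None) -> dict:
    """Field-level totals: VTSF, VTLD, their ratio, cell counts and CS.

    ``VTLD`` counts every positive droplet voxel, assigned or not — the
    whole-scanning-field convention. ``spacing`` is the result of
    :func:`cell_spacing` and is computed here when omitted.
    """
    check_compatible(droplets, cells)
    cal = droplets.calibration
    voxvol = cal.voxel_volume_um3()
    if spacing is None:
        spacing = cell_spacing(cells)
    mean_cs, pairs = spacing
    if integrated is None:
        integrated = integrated_cells(cells)
    vtsf = field_volume_um3(droplets.shape, cal)
    vtld = float(np.count_nonzero(droplets.labels)) * voxvol
    return {
        "vtsf_um3": vtsf,
        "vtld_um3": vtld,
        "vtld_vtsf_ratio": vtld / vtsf,
        "n_cells": int(len(cells.ids())),
        "n_integrated": int(len(integrated)),
        "mean_cell_spacing_um": mean_cs,
        "n_spacing_pairs": int(len(pairs)),
    }


def size_distribution(records: pd.DataFrame, bin_edges_um3) -> dict:
    """Droplet-volume histogram plus a long-format table for violin plots.

    Returns counts per bin, the long table ``(cell_id, volume_um3)``, and
    the percentages of large (``is_large``) and small-class
    (``is_small_class``) droplets. An empty record list yields empty but
    valid outputs.
    """
    edges = np.asarray(bin_edges_um3, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges_um3 must be strictly increasing with >= 2 edges")
    if len(records) == 0:
        return {
            "bin_edges_um3": edges,
            "counts": np.zeros(len(edges) - 1, dtype=int),
            "long": pd.DataFrame(columns=["cell_id", "volume_um3"]),
            "large_pct": float("nan"),
            "small_class_pct": float("nan"),
        }
    volumes = records["volume_um3"].to_numpy()
    counts, _ = np.histogram(volumes, bins=edges)
    return {
        "bin_edges_um3": edges,
        "counts": counts,
        "long": records[["cell_id", "volume_um3"]].reset_index(drop=True),
        "large_pct": 100.0 * float(records["is_large"].sum()) / len(records),
        "small_class_pct": 100.0 * float(records["is_small_class"].sum()) / len(records),
    }
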