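"""Cell segmentation, integrated-cell selection, and droplet-to-cell assignment.

Cells are delimited by the dark intercellular matrix in the bright-field
channel: a seeded watershed grows cell regions within the above-cutoff mask
while voxels below the wall cutoff stay background (label 0), preserving the
matrix that both excludes wall volume from VSC and carries the cell-spacing
measurement. Externally supplied cell label volumes are accepted as a
first-class alternative, since real boundary channels are often segmented
by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .config import default_config, merge_config
from .segment_droplets import _select_markers
from .stack_io import IntensityStack, LabelVolume, check_compatible

__all__ = ["CellAssignment", "segment_cells", "integrated_cells", "assign_droplets"]


@dataclass
class CellAssignment:
    """Droplet-to-cell map plus the set of droplets left unassigned."""

    assignment: dict[int, int]
    unassigned: set[int]

    def cell_of(self, droplet_id: int) -> int:
        """Cell id for a droplet, or 0 if unassigned."""
        return self.assignment.get(droplet_id, 0)


def segment_cells(boundary: IntensityStack, config: dict | None = None,
                  seeds=None) -> LabelVolume:
    """Seeded watershed on the boundary channel.

    Seeds default to distance-transform maxima of the above-cutoff mask at
    least ``cells.min_seed_sep_um`` apart; a list of (z, y, x) voxel
    coordinates may be supplied instead. The wall cutoff defaults to Otsu on
    the smoothed channel; when the channel is constant and seeds are given,
    the whole field is treated as cell interior.
    """
    cfg = merge_config(default_config(), config or {})["cells"]
    cal = boundary.calibration
    vox = boundary.voxels

    sigma_um = cfg["seed_sigma_um"]
    if sigma_um and sigma_um > 0:
        smooth = ndi.gaussian_filter(vox, sigma=tuple(sigma_um / d for d in cal.sampling))
    else:
        smooth = vox

    cutoff = cfg["wall_cutoff"]
    if cutoff is not None:
        mask = smooth > cutoff
    elif smooth.max() > smooth.min():
        mask = smooth > threshold_otsu(smooth, nbins=256)
    else:
        mask = np.ones_like(smooth, dtype=bool)

    edt = ndi.distance_transform_edt(mask, sampling=cal.sampling)
    if seeds is None:
        # Cotyledon stacks span a single cell layer, so the 3D EDT of a cell
        # plateaus at half the slab thickness and sprouts spurious maxima.
        # Seeds are therefore found on the in-plane z-projection, where each
        # cell has one clean distance peak, then dropped at the mid-depth of
        # the cell column.
        proj = mask.any(axis=0)
        edt2 = ndi.distance_transform_edt(proj, sampling=(cal.dy_um, cal.dx_um))
        peaks2 = _select_markers(edt2, proj, (cal.dy_um, cal.dx_um),
                                 cfg["min_seed_sep_um"])
        if len(peaks2) == 0:
            raise ValueError("zero seeds found in the boundary channel")
        markers = []
        for y, x in peaks2:
            zs = np.nonzero(mask[:, y, x])[0]
            z = int(zs.mean().round()) if len(zs) else vox.shape[0] // 2
            markers.append((z, int(y), int(x)))
        markers = np.asarray(markers, dtype=int)
    else:
        markers = np.atleast_2d(np.asarray(seeds, dtype=int))
        if markers.shape[0] == 0:
            raise ValueError("zero seeds supplied")

    marker_img = np.zeros(vox.shape, dtype=np.int32)
    for m, p in enumerate(markers, start=1):
        marker_img[tuple(p)] = m
    cells = watershed(-edt, markers=marker_img, mask=mask)
    return LabelVolume(cells.astype(np.int32), cal, kind="cell")


def integrated_cells(cells: LabelVolume) -> set[int]:
    """Ids of cells wholly inside the field: no voxel on any bounding face.

    All six faces count, the z faces included, so a cell clipped by the top
    or bottom of the stack is excluded just like one clipped laterally.
    """
    lab = cells.labels
    faces = [lab[0], lab[-1], lab[:, 0], lab[:, -1], lab[:, :, 0], lab[:, :, -1]]
    border = set()
    for f in faces:
        border.update(np.unique(f).tolist())
    return {int(i) for i in np.unique(lab) if i > 0} - border


def assign_droplets(droplets: LabelVolume, cells: LabelVolume) -> CellAssignment:
    """Assign each droplet to the cell holding the most of its voxels.

    Ties between cells break to the smallest cell id; a droplet whose
    background overlap strictly exceeds its best cell overlap is unassigned.
    """
    check_compatible(droplets, cells)
    d = droplets.labels.ravel()
    c = cells.labels.ravel()
    sel = d > 0
    dd = d[sel]
    cc = c[sel]

    d_ids = np.unique(dd)
    c_max = int(cells.labels.max(initial=0))
    d_index = np.searchsorted(d_ids, dd)
    counts = np.zeros((len(d_ids), c_max + 1), dtype=np.int64)
    np.add.at(counts, (d_index, cc), 1)

    assignment: dict[int, int] = {}
    unassigned: set[int] = set()
    for row, did in enumerate(d_ids):
        background = counts[row, 0]
        if c_max == 0:
            unassigned.add(int(did))
            continue
        best = int(np.argmax(counts[row, 1:])) + 1  # argmax -> smallest id on ties
        best_count = counts[row, best]
        if best_count == 0 or background > best_count:
            unassigned.add(int(did))
        else:
            assignment[int(did)] = best
    return CellAssignment(assignment=assignment, unassigned=unassigned)
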