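"""Droplet segmentation: threshold, 3D connected components, size filter,
and watershed splitting of touching droplets.

The original workflow selected droplet voxels interactively; here a global
Otsu threshold (with a fixed-level override) is the deterministic analogue.
Droplets use 26-connectivity by default so bright blobs do not fragment on
diagonal contacts. All distance computations run in physical units so that
the z-anisotropy of confocal stacks does not bias marker detection.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from . import preprocess
from .config import default_config, merge_config
from .stack_io import Calibration, IntensityStack, LabelVolume

__all__ = [
    "threshold",
    "label_components",
    "filter_small",
    "split_touching",
    "segment_droplets",
]

_CONN_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """The 3x3x3 adjacency footprint for 6-, 18- or 26-connectivity."""
    try:
        return ndi.generate_binary_structure(3, _CONN_RANK[connectivity])
    except KeyError:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")


def threshold(stack: IntensityStack, method: str = "otsu",
              value: float | None = None) -> np.ndarray:
    """Binarize a stack: voxels strictly above the level become foreground.

    Otsu's level is computed on the whole-volume histogram with 256 bins
    spanning the value range; a constant stack has no separable classes and
    raises.
    """
    vox = stack.voxels
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        level = float(value)
    elif method == "otsu":
        if vox.max() == vox.min():
            raise ValueError("Otsu threshold is undefined on a constant stack")
        level = float(threshold_otsu(vox, nbins=256))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return vox > level


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels densely from 1 in first-encounter raster order."""
    flat = labels.ravel()
    values, first = np.unique(flat, return_index=True)
    pos = values > 0
    order = np.argsort(first[pos])
    lut = np.zeros(int(values.max(initial=0)) + 1, dtype=labels.dtype)
    lut[values[pos][order]] = np.arange(1, pos.sum() + 1, dtype=labels.dtype)
    return lut[labels]


def label_components(mask: np.ndarray, calibration: Calibration,
                     connectivity: int = 26) -> LabelVolume:
    """Label maximal connected components of a binary mask.

    Labels are numbered from 1 in first-encounter (z, y, x) raster order;
    background stays 0.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, _ = ndi.label(mask, structure=connectivity_structure(connectivity))
    return LabelVolume(_relabel_raster(lab.astype(np.int32)), calibration, kind="droplet")


def filter_small(labels: LabelVolume, min_volume_um3: float) -> LabelVolume:
    """Drop components whose physical volume is below the threshold.

    Survivors are renumbered densely from 1 preserving raster order.
    """
    if min_volume_um3 < 0:
        raise ValueError("min_volume_um3 must be >= 0")
    voxvol = labels.calibration.voxel_volume_um3()
    counts = np.bincount(labels.labels.ravel())
    lut = np.zeros_like(counts, dtype=labels.labels.dtype)
    keep = np.nonzero((counts > 0) & (counts * voxvol >= min_volume_um3))[0]
    keep = keep[keep > 0]
    lut[keep] = np.arange(1, len(keep) + 1, dtype=lut.dtype)
    return LabelVolume(lut[labels.labels], labels.calibration, kind=labels.kind)


def _select_markers(edt: np.ndarray, mask: np.ndarray, sampling,
                    min_sep_um: float) -> np.ndarray:
    """Greedy physical-distance suppression of distance-transform maxima.

    Candidate markers are local maxima of the EDT; they are visited in
    decreasing EDT order and kept if at least ``min_sep_um`` (in um) from all
    already-kept markers. Maxima below half the component's EDT peak are
    discarded: a genuine droplet lobe has a core comparable to the largest
    one, whereas digitization ripples do not.
    """
    peaks = peak_local_max(edt, min_distance=1, exclude_border=False,
                           labels=mask.astype(np.uint8))
    if len(peaks) == 0:
        return peaks
    values = edt[tuple(peaks.T)]
    order = np.argsort(values)[::-1]
    peaks = peaks[order]
    values = values[order]
    floor = 0.5 * values[0]
    kept: list[np.ndarray] = []
    scale = np.asarray(sampling)
    for p, v in zip(peaks, values):
        if kept and v < floor:
            break
        phys = p * scale
        if all(np.sum((phys - k) ** 2) >= min_sep_um ** 2 for k in kept):
            kept.append(phys)
    return np.array([(k / scale).round().astype(int) for k in kept])


def split_touching(labels: LabelVolume, min_sep_um: float = 3.0) -> LabelVolume:
    """Split merged components by watershed on the negated distance transform.

    Within each component, markers are Euclidean-distance-transform maxima
    (physical units) at least ``min_sep_um`` apart; components yielding a
    single marker pass through unchanged.
    """
    cal = labels.calibration
    src = labels.labels
    out = np.zeros_like(src)
    next_id = 1
    for old_id, sl in enumerate(ndi.find_objects(src), start=1):
        if sl is None:
            continue
        sub = src[sl] == old_id
        edt = ndi.distance_transform_edt(sub, sampling=cal.sampling)
        markers = _select_markers(edt, sub, cal.sampling, min_sep_um)
        if len(markers) <= 1:
            out[sl][sub] = next_id
            next_id += 1
            continue
        marker_img = np.zeros(sub.shape, dtype=np.int32)
        for m, p in enumerate(markers, start=1):
            marker_img[tuple(p)] = m
        ws = watershed(-edt, markers=marker_img, mask=sub)
        for m in range(1, len(markers) + 1):
            out[sl][ws == m] = next_id
            next_id += 1
    return LabelVolume(_relabel_raster(out), cal, kind=labels.kind)


def segment_droplets(stack: IntensityStack, config: dict | None = None) -> LabelVolume:
    """Full droplet pipeline: preprocess, threshold, label, filter, split.

    Deterministic: the same stack and config always yield the same labels.
    Configuration keys (with defaults) live in :mod:`ld3d.config`.
    """
    cfg = merge_config(default_config(), config or {})
    pp = cfg["preprocess"]
    seg = cfg["segment"]

    x = stack
    if pp["method"] is not None and any(r > 0 for r in np.atleast_1d(pp["radius_vox"])):
        x = preprocess.denoise(x, method=pp["method"], radius_vox=pp["radius_vox"])
    if pp["sigma_um"] is not None:
        x = preprocess.correct_illumination(x, sigma_um=pp["sigma_um"])

    mask = threshold(x, method=seg["threshold"]["method"], value=seg["threshold"]["value"])
    lv = label_components(mask, stack.calibration, connectivity=seg["connectivity"])
    lv = filter_small(lv, seg["min_volume_um3"])
    if seg["split"]["enabled"]:
        lv = split_touching(lv, min_sep_um=seg["split"]["min_sep_um"])
    return lv
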