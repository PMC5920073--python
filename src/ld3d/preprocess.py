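"""Denoising and illumination flattening applied before segmentation.

Both operations are deterministic, preserve shape and calibration, and keep
values non-negative.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi

from .stack_io import IntensityStack

__all__ = ["denoise", "correct_illumination"]


def _per_axis(radius) -> tuple[float, float, float]:
    if np.isscalar(radius):
        radius = (radius, radius, radius)
    radius = tuple(float(r) for r in radius)
    if len(radius) != 3:
        raise ValueError("radius_vox must be a scalar or a (z, y, x) triple")
    if any(r < 0 for r in radius):
        raise ValueError(f"radius_vox must be >= 0 per axis, got {radius}")
    return radius


def denoise(stack: IntensityStack, method: str = "median",
            radius_vox=(1, 1, 1)) -> IntensityStack:
    """Remove speckle noise with a median or Gaussian filter.

    ``radius_vox`` is per (z, y, x) axis: the median window is ``2 r + 1``
    voxels per axis (so always odd); for the Gaussian it is the sigma in
    voxels. Radius 0 on every axis is the identity.
    """
    radius = _per_axis(radius_vox)
    vox = stack.voxels
    if all(r == 0 for r in radius):
        out = vox.copy()
    elif method == "median":
        size = tuple(2 * int(round(r)) + 1 for r in radius)
        out = ndi.median_filter(vox, size=size)
    elif method == "gaussian":
        out = ndi.gaussian_filter(vox, sigma=radius)
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return IntensityStack(np.clip(out, 0, None), stack.calibration, stack.channel)


def correct_illumination(stack: IntensityStack, sigma_um: float = 25.0) -> IntensityStack:
    """Subtract a per-slice Gaussian background estimate and clip at zero.

    The background is estimated independently on each z slice (confocal
    shading varies with depth) by 2D Gaussian smoothing at scale ``sigma_um``,
    which should sit well above droplet diameters; a warning is emitted below
    10 um.
    """
    if sigma_um <= 0:
        raise ValueError(f"sigma_um must be positive, got {sigma_um}")
    if sigma_um < 10:
        warnings.warn(
            f"illumination sigma_um={sigma_um} is below 10 um and may erode "
            "droplet-scale structure", stacklevel=2,
        )
    cal = stack.calibration
    background = ndi.gaussian_filter(
        stack.voxels, sigma=(0.0, sigma_um / cal.dy_um, sigma_um / cal.dx_um)
    )
    out = np.clip(stack.voxels - background, 0, None)
    return IntensityStack(out, cal, stack.channel)
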