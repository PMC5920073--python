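"""Calibrated 3D image stacks, label volumes, and their TIFF/CSV plumbing.

Conventions used throughout the package:

* array axis order is ``(z, y, x)``, 0-based; TIFF page order maps to
  increasing ``z``;
* voxel ``(k, j, i)`` has its centre at physical coordinates
  ``((k + 0.5) dz, (j + 0.5) dy, (i + 0.5) dx)`` in micrometres;
* label ``0`` always means background.

Calibration is carried on every volume; operations that combine two volumes
require identical shape and calibration and raise on mismatch rather than
resampling silently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Calibration",
    "DEFAULT_CALIBRATION",
    "IntensityStack",
    "LabelVolume",
    "voxel_volume",
    "read_stack",
    "read_label_volume",
    "write_stack",
    "write_label_volume",
    "check_compatible",
]

_DESC_KEY = "ld3d"

CHANNELS = ("fluorescence", "brightfield")
LABEL_KINDS = ("droplet", "cell")


@dataclass(frozen=True)
class Calibration:
    """Physical voxel pitch in micrometres along each axis.

    Parameters
    ----------
    dx_um, dy_um : float
        In-plane pixel pitch (x and y).
    dz_um : float
        Spacing between consecutive z slices.
    """

    dx_um: float
    dy_um: float
    dz_um: float

    def __post_init__(self) -> None:
        for name in ("dx_um", "dy_um", "dz_um"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    @property
    def sampling(self) -> tuple[float, float, float]:
        """Pitch in ``(z, y, x)`` array order, suitable for scipy ``sampling=``."""
        return (self.dz_um, self.dy_um, self.dx_um)

    def voxel_volume_um3(self) -> float:
        return self.dx_um * self.dy_um * self.dz_um


#: Pitch of the imaging setup this pipeline targets: 0.159 um per pixel in
#: x and y, 0.38 um between z slices.
DEFAULT_CALIBRATION = Calibration(dx_um=0.159, dy_um=0.159, dz_um=0.38)


def voxel_volume(calibration: Calibration) -> float:
    """Physical volume of one voxel, dx*dy*dz, in cubic micrometres."""
    return calibration.voxel_volume_um3()


def _check_array(arr: np.ndarray, what: str) -> None:
    if arr.ndim != 3:
        raise ValueError(f"{what} must be a 3D (z, y, x) array, got ndim={arr.ndim}")
    if min(arr.shape) < 1:
        raise ValueError(f"{what} must have every dimension >= 1, got shape {arr.shape}")


@dataclass
class IntensityStack:
    """A single-channel 3D scalar image with physical calibration."""

    voxels: np.ndarray
    calibration: Calibration
    channel: str = "fluorescence"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        _check_array(self.voxels, "IntensityStack.voxels")
        if self.voxels.min() < 0:
            raise ValueError("intensity values must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """A 3D integer segmentation map; 0 is background.

    Positive labels need not be contiguous integers.
    """

    labels: np.ndarray
    calibration: Calibration
    kind: str = "droplet"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        _check_array(self.labels, "LabelVolume.labels")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if self.kind not in LABEL_KINDS:
            raise ValueError(f"kind must be one of {LABEL_KINDS}, got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]


def check_compatible(a, b) -> None:
    """Raise ValueError unless the two volumes share shape and calibration."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.calibration != b.calibration:
        raise ValueError(f"calibration mismatch: {a.calibration} vs {b.calibration}")


# ---------------------------------------------------------------------------
# TIFF I/O


def _description(calibration: Calibration, **extra) -> str:
    payload = {"calibration": asdict(calibration)}
    payload.update(extra)
    return json.dumps({_DESC_KEY: payload})


def _calibration_from_tiff(tf: tifffile.TiffFile) -> Calibration | None:
    """Best-effort calibration recovery from TIFF metadata.

    Our own JSON description tag takes precedence; otherwise an ImageJ-style
    ``spacing`` plus resolution tags is accepted. Returns None when the
    metadata are absent or incomplete.
    """
    try:
        desc = tf.pages[0].description
        if desc:
            payload = json.loads(desc).get(_DESC_KEY)
            if payload and "calibration" in payload:
                return Calibration(**payload["calibration"])
    except (json.JSONDecodeError, TypeError, KeyError, ValueError):
        pass
    try:
        meta = tf.imagej_metadata or {}
        spacing = meta.get("spacing")
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if spacing and xres and yres:
            xn, xd = xres.value
            yn, yd = yres.value
            if xn > 0 and yn > 0:
                return Calibration(dx_um=xd / xn, dy_um=yd / yn, dz_um=float(spacing))
    except (TypeError, ValueError, ZeroDivisionError):
        pass
    return None


def _read_pages(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # empty/corrupt container
        raise ValueError(f"zero pages or unreadable TIFF: {path}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"expected multi-page grayscale TIFF (pages x rows x cols), got shape {arr.shape}"
        )
    if arr.shape[0] == 0:
        raise ValueError(f"zero pages in {path}")
    return arr


def read_stack(path, calibration: Calibration | None = None,
               channel: str = "fluorescence") -> IntensityStack:
    """Read a multi-page grayscale TIFF as an IntensityStack.

    Pages map to z in file order. Integer pixel types are widened losslessly
    to float64. Calibration stored in file metadata, when present and
    complete, overrides the ``calibration`` argument.
    """
    arr = _read_pages(path)
    with tifffile.TiffFile(path) as tf:
        meta_cal = _calibration_from_tiff(tf)
    cal = meta_cal or calibration
    if cal is None:
        raise ValueError(f"no calibration supplied and none found in {path}")
    return IntensityStack(voxels=arr.astype(np.float64), calibration=cal, channel=channel)


def read_label_volume(path, calibration: Calibration | None = None,
                      kind: str = "droplet") -> LabelVolume:
    """Read a label volume written by :func:`write_label_volume`."""
    arr = _read_pages(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label TIFF must have an integer pixel type, got {arr.dtype}")
    with tifffile.TiffFile(path) as tf:
        meta_cal = _calibration_from_tiff(tf)
    cal = meta_cal or calibration
    if cal is None:
        raise ValueError(f"no calibration supplied and none found in {path}")
    return LabelVolume(labels=arr.astype(np.int64), calibration=cal, kind=kind)


def write_stack(stack: IntensityStack, path) -> None:
    """Write an intensity stack as float TIFF; value-identical on read-back."""
    tifffile.imwrite(
        path,
        stack.voxels,
        photometric="minisblack",
        description=_description(stack.calibration, channel=stack.channel),
    )


def write_label_volume(labels: LabelVolume, path) -> None:
    """Write a label volume at the smallest unsigned depth that is lossless."""
    mx = int(labels.labels.max(initial=0))
    if mx <= np.iinfo(np.uint8).max:
        dtype = np.uint8
    elif mx <= np.iinfo(np.uint16).max:
        dtype = np.uint16
    elif mx <= np.iinfo(np.uint32).max:
        dtype = np.uint32
    else:
        raise ValueError(f"label {mx} overflows 32-bit unsigned TIFF storage")
    tifffile.imwrite(
        path,
        labels.labels.astype(dtype),
        photometric="minisblack",
        description=_description(labels.calibration, kind=labels.kind),
    )
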