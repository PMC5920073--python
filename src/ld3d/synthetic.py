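"""Synthetic confocal-like fields of oilseed cotyledon cells and lipid droplets.

The generator builds, with full ground truth, the scene the pipeline is meant
to quantify: a single layer of convex parenchyma-like cells filling a
127 x 127 um field, separated by a dark intercellular matrix a few
micrometres wide, each cell packed with spherical Nile-Red-bright lipid
droplets whose diameters follow a right-skewed (lognormal) distribution with
a tail above 5 um. Two presets emulate high-oil (HO-like: many droplets,
narrow cell gaps) and low-oil (LO-like: fewer droplets, wider gaps)
breeding-line phenotypes.

Rendering is deliberately simple: two-level intensities, an anisotropic
Gaussian point-spread blur expressed in micrometres, Poisson shot noise and
additive Gaussian read noise. One top-level seed drives all randomness
through deterministically spawned child streams.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .stack_io import Calibration, IntensityStack, LabelVolume

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "DESK_CALIBRATION",
    "generate_tessellation",
    "place_droplets",
    "render_channels",
    "generate_field",
    "voxelized_ball",
    "ho_like",
    "lo_like",
    "noise_free",
]

#: Desk-scale sampling of the target field: the physical 127 x 127 x 26.6 um
#: scan re-gridded to 256 x 256 x 40 voxels so a full field renders and
#: segments in seconds rather than minutes.
DESK_CALIBRATION = Calibration(dx_um=127.0 / 256, dy_um=127.0 / 256, dz_um=26.6 / 40)

DESK_SHAPE = (40, 256, 256)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic field; defaults are HO-like.

    ``diam_lognorm`` is (mu, sigma) of the *log* droplet diameter in um,
    truncated to ``diam_range_um`` by rejection. ``psf_sigma_um`` is the
    Gaussian blur sigma per (z, y, x) axis in micrometres, converted to
    voxels per axis so calibration anisotropy does not distort the blur.
    """

    field_shape: tuple[int, int, int] = DESK_SHAPE
    calibration: Calibration = DESK_CALIBRATION
    n_cells: int = 9
    wall_um: float = 4.0
    droplets_per_cell: float = 100.0
    diam_lognorm: tuple[float, float] = (math.log(4.4), 0.38)
    diam_range_um: tuple[float, float] = (1.5, 8.5)
    droplet_intensity: float = 150.0
    background_intensity: float = 20.0
    brightfield_intensity: float = 180.0
    matrix_intensity: float = 40.0
    psf_sigma_um: tuple[float, float, float] = (0.4, 0.25, 0.25)
    poisson_on: bool = True
    gaussian_sd: float = 3.0
    min_gap_um: float = 1.0
    allow_contact: bool = False
    #: carve the intercellular matrix along the field faces too, so that a
    #: generated field contains fully integrated cells (a single cell layer
    #: would otherwise touch the z faces everywhere)
    inset_faces: bool = True
    max_attempts: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.field_shape
        if min(nz, ny, nx) < 1:
            raise ValueError(f"field_shape must be positive, got {self.field_shape}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.wall_um < 0:
            raise ValueError("wall_um must be >= 0")
        dmin, dmax = self.diam_range_um
        if not (0 < dmin <= dmax):
            raise ValueError(f"bad diam_range_um {self.diam_range_um}")
        ext = self.extent_um
        if dmax > min(ext):
            raise ValueError("diam_range_um max exceeds the smallest field extent")
        if self.droplet_intensity <= self.background_intensity:
            raise ValueError("droplet intensity must exceed background intensity")
        if min(self.droplet_intensity, self.background_intensity,
               self.brightfield_intensity, self.matrix_intensity) < 0:
            raise ValueError("intensities must be >= 0")
        if self.droplets_per_cell < 0 or self.min_gap_um < 0 or self.gaussian_sd < 0:
            raise ValueError("droplets_per_cell, min_gap_um, gaussian_sd must be >= 0")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical field extent per (z, y, x) axis."""
        return tuple(n * d for n, d in zip(self.field_shape, self.calibration.sampling))

    def to_dict(self) -> dict:
        d = {
            "field_shape": list(self.field_shape),
            "calibration": {
                "dx_um": self.calibration.dx_um,
                "dy_um": self.calibration.dy_um,
                "dz_um": self.calibration.dz_um,
            },
        }
        for k in ("n_cells", "wall_um", "droplets_per_cell", "droplet_intensity",
                  "background_intensity", "brightfield_intensity", "matrix_intensity",
                  "poisson_on", "gaussian_sd", "min_gap_um", "allow_contact",
                  "inset_faces", "max_attempts", "seed"):
            d[k] = getattr(self, k)
        d["diam_lognorm"] = list(self.diam_lognorm)
        d["diam_range_um"] = list(self.diam_range_um)
        d["psf_sigma_um"] = list(self.psf_sigma_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "calibration" in d:
            d["calibration"] = Calibration(**d["calibration"])
        for k in ("field_shape", "diam_lognorm", "diam_range_um", "psf_sigma_um"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Truth labels and records from which every downstream metric follows."""

    cell_labels: LabelVolume
    droplet_labels: LabelVolume
    droplet_truth: pd.DataFrame
    true_field_fraction: float
    placement_shortfall: int = 0


def _voxel_centers_um(shape, calibration) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        (np.arange(n) + 0.5) * d for n, d in zip(shape, calibration.sampling)
    )


def generate_tessellation(spec: SyntheticSpec, rng: np.random.Generator) -> LabelVolume:
    """Partition the field into ``n_cells`` wall-separated convex regions.

    Seed points are laid on a jittered in-plane grid at mid depth; each voxel
    joins the nearest seed's region (a Voronoi cell in physical units) and is
    then carved back to background where it lies within ``wall_um / 2`` of a
    Voronoi bisector or of a field face. Adjacent cell surfaces therefore sit
    about ``wall_um`` apart and label 0 forms the intercellular matrix.
    """
    nz, ny, nx = spec.field_shape
    cal = spec.calibration
    ez, ey, ex = spec.extent_um
    n = spec.n_cells

    # in-plane grid roughly matching the field aspect ratio
    gx = max(1, int(math.ceil(math.sqrt(n * ex / ey))))
    gy = max(1, int(math.ceil(n / gx)))
    px, py = ex / gx, ey / gy
    sites = np.empty((n, 3))
    for idx in range(n):
        iy, ix = divmod(idx, gx)
        sites[idx] = (
            0.5 * ez + rng.uniform(-0.10, 0.10) * ez,
            (iy + 0.5) * py + rng.uniform(-0.25, 0.25) * py,
            (ix + 0.5) * px + rng.uniform(-0.25, 0.25) * px,
        )

    zc, yc, xc = _voxel_centers_um(spec.field_shape, cal)
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    points = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])

    if n == 1:
        owner = np.ones(points.shape[0], dtype=np.int32)
        half_sep = np.full(points.shape[0], np.inf)
    else:
        dist, idx = cKDTree(sites).query(points, k=2)
        owner = idx[:, 0].astype(np.int32) + 1
        half_sep = (dist[:, 1] - dist[:, 0]) / 2.0

    keep = half_sep >= spec.wall_um / 2.0
    if spec.inset_faces and spec.wall_um > 0:
        half = spec.wall_um / 2.0
        face = np.minimum.reduce([
            np.minimum(points[:, 0], ez - points[:, 0]),
            np.minimum(points[:, 1], ey - points[:, 1]),
            np.minimum(points[:, 2], ex - points[:, 2]),
        ])
        keep &= face >= half
    labels = np.where(keep, owner, 0).reshape(spec.field_shape).astype(np.int32)

    counts = np.bincount(labels.ravel(), minlength=n + 1)
    missing = [i for i in range(1, n + 1) if counts[i] == 0]
    if missing:
        raise ValueError(
            f"wall_um={spec.wall_um} erases cell region(s) {missing}; reduce the wall width"
        )
    return LabelVolume(labels=labels, calibration=cal, kind="cell")


def voxelized_ball(shape, center_um, radius_um, calibration) -> tuple[tuple, np.ndarray]:
    """Voxelize a sphere: a voxel belongs iff its centre lies within the radius.

    Returns ``(index_arrays, none)``-style output as a tuple of (z, y, x)
    integer index arrays for the voxels inside the sphere, clipped to shape.
    """
    dz, dy, dx = calibration.sampling
    cz, cy, cx = center_um
    lo = [max(0, int(math.floor((c - radius_um) / d - 0.5)))
          for c, d in zip(center_um, (dz, dy, dx))]
    hi = [min(n - 1, int(math.ceil((c + radius_um) / d)))
          for c, n, d in zip(center_um, shape, (dz, dy, dx))]
    if any(l > h for l, h in zip(lo, hi)):
        return (np.empty(0, int), np.empty(0, int), np.empty(0, int))
    zi = np.arange(lo[0], hi[0] + 1)
    yi = np.arange(lo[1], hi[1] + 1)
    xi = np.arange(lo[2], hi[2] + 1)
    Z, Y, X = np.meshgrid((zi + 0.5) * dz - cz, (yi + 0.5) * dy - cy,
                          (xi + 0.5) * dx - cx, indexing="ij")
    inside = Z * Z + Y * Y + X * X <= radius_um * radius_um
    kz, ky, kx = np.nonzero(inside)
    return (zi[kz], yi[ky], xi[kx])


def _truncated_lognormal_diameters(n, mu, sigma, dmin, dmax, rng) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(mu, sigma, size=max(16, 2 * (n - filled))))
        draw = draw[(draw >= dmin) & (draw <= dmax)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def place_droplets(cells: LabelVolume, spec: SyntheticSpec,
                   rng: np.random.Generator) -> GroundTruth:
    """Pack non-overlapping spheres into each cell by rejection sampling.

    Per-cell counts are Poisson with mean ``droplets_per_cell``; diameters
    are truncated-lognormal draws, placed largest first so the packing
    converges. Each sphere must lie wholly within its cell; unless
    ``allow_contact`` is set, sphere surfaces keep at least ``min_gap_um``
    clearance. Droplets that cannot be placed within ``max_attempts`` are
    counted in ``placement_shortfall`` and reported with a warning.
    """
    cal = spec.calibration
    shape = cells.shape
    labels = cells.labels
    droplet_labels = np.zeros(shape, dtype=np.int32)
    mu, sigma = spec.diam_lognorm
    dmin, dmax = spec.diam_range_um
    gap = 0.0 if spec.allow_contact else spec.min_gap_um

    placed_centers: list[tuple[float, float, float]] = []
    placed_radii: list[float] = []
    records = []
    shortfall = 0
    next_id = 1
    voxvol = cal.voxel_volume_um3()
    dz, dy, dx = cal.sampling

    centers_arr = np.empty((0, 3))
    radii_arr = np.empty(0)

    for cid in cells.ids():
        coords = np.argwhere(labels == cid)
        n_drops = int(rng.poisson(spec.droplets_per_cell))
        if n_drops == 0:
            continue
        radii = _truncated_lognormal_diameters(n_drops, mu, sigma, dmin, dmax, rng) / 2.0
        radii = np.sort(radii)[::-1]
        for r in radii:
            placed = False
            for _ in range(spec.max_attempts):
                k = int(rng.integers(len(coords)))
                c = (
                    (coords[k, 0] + 0.5) * dz,
                    (coords[k, 1] + 0.5) * dy,
                    (coords[k, 2] + 0.5) * dx,
                )
                if len(radii_arr):
                    d2 = np.sum((centers_arr - np.asarray(c)) ** 2, axis=1)
                    if np.any(d2 < (radii_arr + r + gap) ** 2):
                        continue
                idx = voxelized_ball(shape, c, r, cal)
                if len(idx[0]) == 0:
                    continue
                if not np.all(labels[idx] == cid):
                    continue
                droplet_labels[idx] = next_id
                vcount = len(idx[0])
                vol = vcount * voxvol
                records.append({
                    "droplet_id": next_id,
                    "cell_id": int(cid),
                    "radius_um": float(r),
                    "voxel_count": vcount,
                    "volume_um3": vol,
                    "eq_diameter_um": (6.0 * vol / math.pi) ** (1.0 / 3.0),
                    "centroid_z_um": c[0],
                    "centroid_y_um": c[1],
                    "centroid_x_um": c[2],
                })
                placed_centers.append(c)
                placed_radii.append(float(r))
                centers_arr = np.asarray(placed_centers)
                radii_arr = np.asarray(placed_radii)
                next_id += 1
                placed = True
                break
            if not placed:
                shortfall += 1

    if shortfall:
        warnings.warn(
            f"could not place {shortfall} droplet(s) within the attempt budget",
            stacklevel=2,
        )
    columns = ["droplet_id", "cell_id", "radius_um", "voxel_count", "volume_um3",
               "eq_diameter_um", "centroid_z_um", "centroid_y_um", "centroid_x_um"]
    truth = pd.DataFrame(records, columns=columns)
    frac = float(np.count_nonzero(droplet_labels)) / droplet_labels.size
    return GroundTruth(
        cell_labels=cells,
        droplet_labels=LabelVolume(droplet_labels, cal, kind="droplet"),
        droplet_truth=truth,
        true_field_fraction=frac,
        placement_shortfall=shortfall,
    )


def _blur_and_noise(img: np.ndarray, spec: SyntheticSpec,
                    rng: np.random.Generator) -> np.ndarray:
    sig_vox = tuple(s / d for s, d in zip(spec.psf_sigma_um, spec.calibration.sampling))
    if any(s > 0 for s in sig_vox):
        img = gaussian_filter(img, sigma=sig_vox)
    if spec.poisson_on:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if spec.gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_channels(truth: GroundTruth, spec: SyntheticSpec,
                    rng: np.random.Generator) -> tuple[IntensityStack, IntensityStack]:
    """Render the fluorescence (droplet) and bright-field (cell) channels."""
    cal = spec.calibration
    fg = truth.droplet_labels.labels > 0
    fluor = np.where(fg, spec.droplet_intensity + spec.background_intensity,
                     spec.background_intensity).astype(np.float64)
    fluor = _blur_and_noise(fluor, spec, rng)

    in_cell = truth.cell_labels.labels > 0
    bf = np.where(in_cell, spec.brightfield_intensity,
                  spec.matrix_intensity).astype(np.float64)
    bf = _blur_and_noise(bf, spec, rng)
    return (
        IntensityStack(fluor, cal, channel="fluorescence"),
        IntensityStack(bf, cal, channel="brightfield"),
    )


def generate_field(spec: SyntheticSpec):
    """Generate one complete field: (fluorescence, brightfield, GroundTruth).

    All randomness derives from ``spec.seed`` through spawned child streams,
    so identical specs yield identical outputs.
    """
    ss = np.random.SeedSequence(spec.seed)
    r_tess, r_drop, r_render = (np.random.default_rng(s) for s in ss.spawn(3))
    cells = generate_tessellation(spec, r_tess)
    truth = place_droplets(cells, spec, r_drop)
    fluor, bf = render_channels(truth, spec, r_render)
    return fluor, bf, truth


# ---------------------------------------------------------------------------
# Presets


def ho_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """High-oil-like preset: ~100 droplets/cell, ~4 um intercellular gaps."""
    base = dict(
        n_cells=9,
        wall_um=4.0,
        droplets_per_cell=100.0,
        diam_lognorm=(math.log(4.4), 0.38),
        diam_range_um=(1.5, 8.5),
        seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


def lo_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """Low-oil-like preset: ~40 droplets/cell, ~6 um intercellular gaps."""
    base = dict(
        n_cells=9,
        wall_um=6.0,
        droplets_per_cell=40.0,
        diam_lognorm=(math.log(4.9), 0.38),
        diam_range_um=(1.5, 9.5),
        seed=seed,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


def noise_free(spec: SyntheticSpec) -> SyntheticSpec:
    """The same scene with blur and both noise sources switched off."""
    return replace(spec, psf_sigma_um=(0.0, 0.0, 0.0), poisson_on=False, gaussian_sd=0.0)
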