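"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: flood-fill labeling by
breadth-first search, Otsu by exhaustive between-class-variance search, and
sphere voxelization by direct per-voxel distance tests.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int):
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                s = abs(dz) + abs(dy) + abs(dx)
                if s == 0:
                    continue
                if (connectivity == 6 and s == 1) or \
                   (connectivity == 18 and s <= 2) or \
                   (connectivity == 26):
                    out.append((dz, dy, dx))
    return out


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling, labels in raster first-encounter order."""
    mask = np.asarray(mask, dtype=bool)
    offsets = neighbor_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    nz, ny, nx = mask.shape
    next_label = 0
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not mask[z0, y0, x0] or labels[z0, y0, x0]:
                    continue
                next_label += 1
                queue = deque([(z0, y0, x0)])
                labels[z0, y0, x0] = next_label
                while queue:
                    z, y, x = queue.popleft()
                    for dz, dy, dx in offsets:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx \
                                and mask[zz, yy, xx] and not labels[zz, yy, xx]:
                            labels[zz, yy, xx] = next_label
                            queue.append((zz, yy, xx))
    return labels


def otsu_exhaustive(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's level by brute-force search over all histogram cut points."""
    counts, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_idx = -1.0, 0
    total = counts.sum()
    for t in range(nbins - 1):  # class 1 = bins 0..t, class 2 = t+1..
        w1 = counts[: t + 1].sum()
        w2 = total - w1
        if w1 == 0 or w2 == 0:
            continue
        mu1 = (counts[: t + 1] * centers[: t + 1]).sum() / w1
        mu2 = (counts[t + 1:] * centers[t + 1:]).sum() / w2
        var = w1 * w2 * (mu1 - mu2) ** 2
        if var > best_var:
            best_var, best_idx = var, t
    return float(centers[best_idx])


def sphere_voxel_count(radius: float, pitch=(1.0, 1.0, 1.0), center=None) -> int:
    """Count voxel centres inside a sphere by direct enumeration."""
    dz, dy, dx = pitch
    if center is None:
        center = (0.0, 0.0, 0.0)
    cz, cy, cx = center
    n = 0
    kz = int(np.ceil((radius + abs(cz)) / dz)) + 2
    ky = int(np.ceil((radius + abs(cy)) / dy)) + 2
    kx = int(np.ceil((radius + abs(cx)) / dx)) + 2
    for z in range(-kz, kz + 1):
        for y in range(-ky, ky + 1):
            for x in range(-kx, kx + 1):
                if (z * dz - cz) ** 2 + (y * dy - cy) ** 2 + (x * dx - cx) ** 2 <= radius ** 2:
                    n += 1
    return n
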