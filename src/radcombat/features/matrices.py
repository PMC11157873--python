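"""Texture-matrix builders: GLCM, GLRLM, GLSZM, GLDM.

All builders operate on a :class:`~radcombat.features.preprocessing.
DiscretizedROI` (background level 0 is excluded everywhere) and pool over
the 13 unique 3D directions where directional aggregation applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing import DiscretizedROI

__all__ = ["TextureMatrix", "DIRECTIONS_13", "glcm", "glrlm_matrix",
           "glszm_matrix", "gldm_matrix"]

#: the 13 unique (up to sign) nonzero offsets of a 3x3x3 neighborhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: all 26 neighbor offsets (Chebyshev distance 1)
_NEIGHBORS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


@dataclass
class TextureMatrix:
    kind: str                 # GLCM | GLRLM | GLSZM | GLDM
    matrix: np.ndarray        # nonnegative 2D array
    normalized: bool          # sums to one when True
    n_levels: int
    n_directions: int = 1     # directions pooled into the counts
    voxel_count: int = 0

    def normalize(self) -> "TextureMatrix":
        total = self.matrix.sum()
        if total == 0:
            raise ValueError(f"degenerate {self.kind}: no counts")
        return TextureMatrix(self.kind, self.matrix / total, True,
                             self.n_levels, self.n_directions,
                             self.voxel_count)


def _offset_slices(shape, offset):
    """Aligned slice pair (a, b) with ``A[a]`` at p and ``A[b]`` at p+offset."""
    sl_a, sl_b = [], []
    for size, d in zip(shape, offset):
        if d >= 0:
            sl_a.append(slice(0, size - d))
            sl_b.append(slice(d, size))
        else:
            sl_a.append(slice(-d, size))
            sl_b.append(slice(0, size + d))
    return tuple(sl_a), tuple(sl_b)


def glcm(
    roi: DiscretizedROI,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
    normalize: bool = True,
) -> TextureMatrix:
    """Symmetric gray-level co-occurrence counts pooled over directions.

    Each in-ROI voxel pair at the scaled offset contributes to both
    ``(i, j)`` and ``(j, i)``, so the matrix is symmetric by
    construction. Raises if no pair exists at any direction (ROI smaller
    than the distance everywhere).
    """
    L = roi.levels
    Ng = roi.n_levels
    P = np.zeros((Ng, Ng), dtype=float)
    for d in directions:
        off = tuple(int(distance) * c for c in d)
        sl_a, sl_b = _offset_slices(L.shape, off)
        a, b = L[sl_a], L[sl_b]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        np.add.at(P, (a[ok] - 1, b[ok] - 1), 1.0)
    P = P + P.T  # symmetric pairing
    if P.sum() == 0:
        raise ValueError("degenerate GLCM: ROI has no voxel pair at the "
                         "requested distance")
    m = TextureMatrix("GLCM", P, False, Ng, len(directions), roi.voxel_count)
    return m.normalize() if normalize else m


def glrlm_matrix(
    roi: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> TextureMatrix:
    """Run-length counts, runs pooled over the 13 directions.

    A run is a maximal sequence of in-ROI voxels of equal level along one
    direction; background voxels break runs.
    """
    L = roi.levels
    Ng = roi.n_levels
    max_len = max(L.shape)
    P = np.zeros((Ng, max_len), dtype=float)
    inroi = L > 0
    for d in directions:
        sl_a, sl_b = _offset_slices(L.shape, d)
        # cont[p]: the run through p continues to p + d
        cont = np.zeros(L.shape, dtype=bool)
        cont[sl_a] = inroi[sl_a] & inroi[sl_b] & (L[sl_a] == L[sl_b])
        # start[p]: no same-level in-ROI predecessor at p - d
        prev = np.zeros(L.shape, dtype=bool)
        prev[sl_b] = cont[sl_a]
        starts = np.argwhere(inroi & ~prev)
        if starts.size == 0:
            continue
        pos = starts.copy()
        length = np.ones(len(starts), dtype=int)
        active = np.ones(len(starts), dtype=bool)
        while active.any():
            idx = np.nonzero(active)[0]
            p = pos[idx]
            go = cont[p[:, 0], p[:, 1], p[:, 2]]
            stepping = idx[go]
            pos[stepping] += d
            length[stepping] += 1
            active[idx[~go]] = False
        lv = L[starts[:, 0], starts[:, 1], starts[:, 2]]
        np.add.at(P, (lv - 1, length - 1), 1.0)
    if P.sum() == 0:
        raise ValueError("degenerate GLRLM: empty ROI")
    return TextureMatrix("GLRLM", P, False, Ng, len(directions),
                         roi.voxel_count)


def glszm_matrix(roi: DiscretizedROI) -> TextureMatrix:
    """Size-zone counts; zones are 26-connected equal-level components."""
    L = roi.levels
    Ng = roi.n_levels
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for level in np.unique(L[L > 0]):
        labeled, n = ndimage.label(L == level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones.append((int(level), int(s)))
            max_size = max(max_size, int(s))
    if not zones:
        raise ValueError("degenerate GLSZM: empty ROI")
    P = np.zeros((Ng, max_size), dtype=float)
    for level, s in zones:
        P[level - 1, s - 1] += 1.0
    return TextureMatrix("GLSZM", P, False, Ng, 1, roi.voxel_count)


def gldm_matrix(roi: DiscretizedROI, alpha: int = 0) -> TextureMatrix:
    """Dependence counts: for every in-ROI voxel, the size of its
    dependence set — itself plus the 26-neighbors whose level differs by
    at most ``alpha``. Columns index dependence size starting at 1.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    L = roi.levels
    Ng = roi.n_levels
    inroi = L > 0
    dep = np.zeros(L.shape, dtype=int)
    for d in _NEIGHBORS_26:
        sl_a, sl_b = _offset_slices(L.shape, d)
        hit = inroi[sl_a] & inroi[sl_b] & (
            np.abs(L[sl_a] - L[sl_b]) <= alpha
        )
        dep[sl_a] += hit
    sizes = dep[inroi] + 1  # the voxel belongs to its own dependence set
    levels = L[inroi]
    if sizes.size == 0:
        raise ValueError("degenerate GLDM: empty ROI")
    P = np.zeros((Ng, 27), dtype=float)
    np.add.at(P, (levels - 1, sizes - 1), 1.0)
    P = P[:, : sizes.max()]
    return TextureMatrix("GLDM", P, False, Ng, 1, roi.voxel_count)
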