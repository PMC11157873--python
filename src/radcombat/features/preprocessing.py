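"""ROI intensity normalization and gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedROI", "minmax_normalize", "discretize"]


@dataclass
class DiscretizedROI:
    """A 3D ROI discretized to integer gray levels.

    ``levels`` holds 0 outside the ROI and values in ``1..n_levels``
    inside; ``voxel_count`` is the number of in-ROI voxels.
    """

    levels: np.ndarray
    n_levels: int
    voxel_count: int

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def minmax_normalize(roi_voxels: np.ndarray) -> np.ndarray:
    """Linearly map ROI intensities onto [0, 1].

    A constant ROI maps to all zeros (the documented degenerate
    convention). Raises ``ValueError`` on an empty input.
    """
    x = np.asarray(roi_voxels, dtype=float)
    if x.size == 0:
        raise ValueError("empty ROI")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def discretize(roi_voxels: np.ndarray, n_levels: int = 25,
               mask: np.ndarray | None = None) -> DiscretizedROI:
    """Equal-width binning of [0,1] values into ``n_levels`` gray levels.

    Bin ``k`` (1-based) covers ``[(k-1)/n, k/n)``; the value 1.0 is
    assigned to the top level. When ``mask`` is given, voxels outside it
    get level 0 (background) and are excluded from ``voxel_count``.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    x = np.asarray(roi_voxels, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("discretize expects values in [0, 1]")
    levels = np.minimum(np.floor(x * n_levels).astype(int) + 1, n_levels)
    if mask is not None:
        levels = np.where(mask, levels, 0)
        count = int(np.count_nonzero(mask))
    else:
        count = int(x.size)
    return DiscretizedROI(levels, int(n_levels), count)
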