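"""Whole-phantom feature extraction: volume + label map -> FeatureTable."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..datatypes import FeatureTable
from ..simulate import PhantomVolume
from .preprocessing import minmax_normalize, discretize
from .matrices import glcm
from .families import (
    FAMILY_FEATURE_NAMES,
    firstorder_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    gldm_features,
)

__all__ = ["extract_roi", "extract_all", "all_feature_names"]


def all_feature_names() -> list[str]:
    """Family-prefixed names of every extracted feature, in fixed order."""
    return [
        f"{family} {name}"
        for family, names in FAMILY_FEATURE_NAMES.items()
        for name in names
    ]


def extract_roi(
    voxels: np.ndarray,
    mask: np.ndarray | None = None,
    n_levels: int = 25,
    distance: int = 1,
    alpha: int = 0,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """Compute all five feature families for one 3D ROI.

    ``voxels`` is a 3D array; ``mask`` (same shape, default all-True)
    marks the in-ROI voxels. The in-ROI intensities are Min-Max
    normalized to [0, 1] and discretized to ``n_levels`` equal-width gray
    levels; voxels outside the mask are background for every texture
    matrix.
    """
    voxels = np.asarray(voxels, dtype=float)
    if voxels.ndim != 3:
        raise ValueError("extract_roi expects a 3D array")
    if mask is None:
        mask = np.ones(voxels.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")

    inroi = voxels[mask]
    norm_flat = minmax_normalize(inroi)
    norm = np.zeros_like(voxels)
    norm[mask] = norm_flat
    disc = discretize(norm, n_levels, mask=mask)

    out: dict[str, float] = {}
    fams = [
        ("First order", firstorder_features(norm_flat, disc, voxel_volume)),
        ("Glcm", glcm_features(glcm(disc, distance=distance))),
        ("Glrlm", glrlm_features(disc)),
        ("Glszm", glszm_features(disc)),
        ("Gldm", gldm_features(disc, alpha=alpha)),
    ]
    for family, fv in fams:
        for name, value in fv.as_dict().items():
            out[f"{family} {name}"] = value
    return out


def extract_all(
    volume: PhantomVolume,
    n_levels: int = 25,
    distance: int = 1,
    alpha: int = 0,
    batch: str = "batch0",
) -> FeatureTable:
    """One feature row per labeled cube in the volume.

    Cubes are recovered as 26-connected components of each class code
    (0 and 1) in the label map; the class code becomes the row's class
    label, so a separate background code never collides with the classes.
    """
    lab = volume.label_map
    voxel_volume = float(np.prod(volume.voxel_spacing))
    rows, classes, ids = [], [], []
    names = all_feature_names()
    for cls in (0, 1):
        comp, n = ndimage.label(lab == cls, structure=np.ones((3, 3, 3)))
        for k, box in enumerate(ndimage.find_objects(comp), start=1):
            if box is None:
                continue
            mask = comp[box] == k
            feats = extract_roi(
                volume.voxels[box], mask, n_levels, distance, alpha,
                voxel_volume,
            )
            rows.append([feats[n_] for n_ in names])
            classes.append(cls)
            ids.append(f"c{cls}_roi{k:03d}")
    if not rows:
        raise ValueError("label map contains no ROI (codes 0/1)")
    return FeatureTable(
        np.asarray(rows, dtype=float),
        names,
        np.full(len(rows), batch),
        np.asarray(classes, dtype=int),
        ids,
    )
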