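"""Radiomic feature families: first-order and the four texture-matrix sets.

Feature definitions follow the IBSI-style conventions of the standard
extraction tools. Degenerate ROIs (a single gray level) never propagate
NaN: zero-spread moments (variance, skewness, kurtosis) return 0, GLCM
Correlation returns 1 and the information-measure features return 0 by
documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import DiscretizedROI
from .matrices import TextureMatrix, glcm, glrlm_matrix, glszm_matrix, \
    gldm_matrix

__all__ = [
    "FeatureVector", "firstorder_features", "glcm_features",
    "glrlm_features", "glszm_features", "gldm_features",
    "FAMILY_FEATURE_NAMES",
]

_EPS = np.finfo(float).eps


@dataclass
class FeatureVector:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values)
                   if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite features: {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# first order

FIRSTORDER_NAMES = [
    "Percentile 10", "Percentile 90", "Energy", "Entropy",
    "Interquartile Range", "Kurtosis", "Maximum", "Mean Absolute Deviation",
    "Mean", "Median", "Minimum", "Range", "Robust Mean Absolute Deviation",
    "Root Mean Squared", "Skewness", "Total Energy", "Uniformity", "Variance",
]


def firstorder_features(
    roi_voxels: np.ndarray,
    levels: DiscretizedROI,
    voxel_volume: float = 1.0,
) -> FeatureVector:
    """Intensity-statistic features of the (normalized) ROI voxel values.

    ``Entropy`` and ``Uniformity`` are computed on the discretized
    gray-level histogram; everything else on the continuous values.
    """
    x = np.asarray(roi_voxels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    lv = levels.levels[levels.levels > 0]
    hist = np.bincount(lv, minlength=levels.n_levels + 1)[1:]
    p = hist / hist.sum()

    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    skew = float(((x - mean) ** 3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float(((x - mean) ** 4).mean() / var**2) if var > 0 else 0.0

    values = [
        p10,
        p90,
        float((x**2).sum()),
        _entropy2(p),
        p75 - p25,
        kurt,
        x.max(),
        float(np.abs(x - mean).mean()),
        mean,
        med,
        x.min(),
        x.max() - x.min(),
        float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        float(np.sqrt((x**2).mean())),
        skew,
        float((x**2).sum() * voxel_volume),
        float((p**2).sum()),
        var,
    ]
    return FeatureVector(list(FIRSTORDER_NAMES), np.array(values))


# ---------------------------------------------------------------------------
# GLCM

GLCM_NAMES = [
    "Autocorrelation", "Joint Average", "Cluster Prominence", "Cluster Shade",
    "Cluster Tendency", "Contrast", "Correlation", "Difference Average",
    "Difference Entropy", "Difference Variance", "Joint Energy",
    "Joint Entropy", "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn",
    "Inverse Variance", "Maximum Probability", "Sum Entropy", "Sum Squares",
]


def glcm_features(m: TextureMatrix) -> FeatureVector:
    """The 22 co-occurrence features from a normalized symmetric GLCM."""
    if m.kind != "GLCM":
        raise ValueError("expected a GLCM")
    P = m.matrix if m.normalized else m.matrix / m.matrix.sum()
    Ng = m.n_levels
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.array([P[(I + J) == k].sum() for k in k_sum])
    k_diff = np.arange(0, Ng)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])

    contrast = float((P * (I - J) ** 2).sum())
    if sig_x > 0 and sig_y > 0:
        corr = float(((P * I * J).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        corr = 1.0  # degenerate single-level convention

    da = float((p_diff * k_diff).sum())
    hxy = _entropy2(P.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = np.outer(px, py)
    mask = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[mask] * np.log2(pxy[mask])).sum())
    hxy2 = _entropy2(pxy.ravel())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) \
        if hxy2 >= hxy else 0.0

    off = I != J
    inv_var = float((P[off] / (I[off] - J[off]) ** 2).sum())

    values = [
        float((P * I * J).sum()),
        mu_x,
        float((P * (I + J - mu_x - mu_y) ** 4).sum()),
        float((P * (I + J - mu_x - mu_y) ** 3).sum()),
        float((P * (I + J - mu_x - mu_y) ** 2).sum()),
        contrast,
        corr,
        da,
        _entropy2(p_diff),
        float((p_diff * (k_diff - da) ** 2).sum()),
        float((P**2).sum()),
        hxy,
        imc1,
        imc2,
        float((P / (1.0 + (I - J) ** 2)).sum()),
        float((P / (1.0 + ((I - J) / Ng) ** 2)).sum()),
        float((P / (1.0 + np.abs(I - J))).sum()),
        float((P / (1.0 + np.abs(I - J) / Ng)).sum()),
        inv_var,
        float(P.max()),
        _entropy2(p_sum),
        float((P * (I - mu_x) ** 2).sum()),
    ]
    return FeatureVector(list(GLCM_NAMES), np.array(values))


# ---------------------------------------------------------------------------
# GLRLM

GLRLM_NAMES = [
    "Gray Level non uniformity", "Gray Level non uniformity Normalized",
    "Gray Level Variance", "High Gray Level Run Emphasis",
    "Long Run Emphasis", "Long Run High Gray Level Emphasis",
    "Long Run Low Gray Level Emphasis", "Low Gray Level Run Emphasis",
    "Run Entropy", "Run Length non uniformity",
    "Run Length non uniformity Normalized", "Run Percentage", "Run Variance",
    "Short Run Emphasis", "Short Run High Gray Level Emphasis",
    "Short Run Low Gray Level Emphasis",
]


def _weighted_moments(p: np.ndarray, axis_vals: np.ndarray, axis: int):
    marg = p.sum(axis=1 - axis)
    mu = float((marg * axis_vals).sum())
    var = float((marg * (axis_vals - mu) ** 2).sum())
    return mu, var


def glrlm_features(roi: DiscretizedROI) -> FeatureVector:
    """The 16 run-length features, runs pooled over the 13 directions.

    Run Percentage is the number of runs divided by ``voxels x
    directions`` (the pooled-matrix analogue of the per-direction ratio).
    """
    m = glrlm_matrix(roi)
    P = m.matrix
    Nr = P.sum()
    p = P / Nr
    Ng, Lmax = P.shape
    i = np.arange(1, Ng + 1)
    j = np.arange(1, Lmax + 1)
    Iv, Jv = np.meshgrid(i, j, indexing="ij")
    ri = P.sum(axis=1)  # per gray level
    rj = P.sum(axis=0)  # per run length
    _, glv = _weighted_moments(p, i.astype(float), 0)
    _, rv = _weighted_moments(p, j.astype(float), 1)

    values = [
        float((ri**2).sum() / Nr),
        float((ri**2).sum() / Nr**2),
        glv,
        float((p * Iv**2).sum()),
        float((p * Jv**2).sum()),
        float((p * Iv**2 * Jv**2).sum()),
        float((p * Jv**2 / Iv**2).sum()),
        float((p / Iv**2).sum()),
        _entropy2(p.ravel()),
        float((rj**2).sum() / Nr),
        float((rj**2).sum() / Nr**2),
        float(Nr / (m.voxel_count * m.n_directions)),
        rv,
        float((p / Jv**2).sum()),
        float((p * Iv**2 / Jv**2).sum()),
        float((p / (Iv**2 * Jv**2)).sum()),
    ]
    return FeatureVector(list(GLRLM_NAMES), np.array(values))


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_NAMES = [
    "Gray Level non uniformity", "Gray Level non uniformity Normalized",
    "Gray Level Variance", "High Gray Level Zone Emphasis",
    "Large Area Emphasis", "Large Area High Gray Level Emphasis",
    "Large Area Low Gray Level Emphasis", "Low Gray Level Zone Emphasis",
    "Size Zone non uniformity", "Size Zone non uniformity Normalized",
    "Small Area Emphasis", "Small Area High Gray Level Emphasis",
    "Small Area Low Gray Level Emphasis", "Zone Entropy", "Zone%",
    "Zone Variance",
]


def glszm_features(roi: DiscretizedROI) -> FeatureVector:
    """The 16 size-zone features (zones = 26-connected components)."""
    m = glszm_matrix(roi)
    P = m.matrix
    Nz = P.sum()
    p = P / Nz
    Ng, Smax = P.shape
    i = np.arange(1, Ng + 1)
    s = np.arange(1, Smax + 1)
    Iv, Sv = np.meshgrid(i, s, indexing="ij")
    zi = P.sum(axis=1)
    zs = P.sum(axis=0)
    _, glv = _weighted_moments(p, i.astype(float), 0)
    _, zv = _weighted_moments(p, s.astype(float), 1)

    values = [
        float((zi**2).sum() / Nz),
        float((zi**2).sum() / Nz**2),
        glv,
        float((p * Iv**2).sum()),
        float((p * Sv**2).sum()),
        float((p * Iv**2 * Sv**2).sum()),
        float((p * Sv**2 / Iv**2).sum()),
        float((p / Iv**2).sum()),
        float((zs**2).sum() / Nz),
        float((zs**2).sum() / Nz**2),
        float((p / Sv**2).sum()),
        float((p * Iv**2 / Sv**2).sum()),
        float((p / (Iv**2 * Sv**2)).sum()),
        _entropy2(p.ravel()),
        float(Nz / m.voxel_count),
        zv,
    ]
    return FeatureVector(list(GLSZM_NAMES), np.array(values))


# ---------------------------------------------------------------------------
# GLDM

GLDM_NAMES = [
    "Dependence Entropy", "Dependence non uniformity",
    "Dependence non uniformity Normalized", "Dependence Variance",
    "Gray Level non uniformity", "Gray Level Variance",
    "High Gray Level Emphasis", "Large Dependence Emphasis",
    "Large Dependence High Gray Level Emphasis",
    "Large Dependence Low Gray Level Emphasis", "Low Gray Level Emphasis",
    "Small Dependence Emphasis", "Small Dependence High Gray Level Emphasis",
    "Small Dependence Low Gray Level Emphasis",
]


def gldm_features(roi: DiscretizedROI, alpha: int = 0) -> FeatureVector:
    """The 14 dependence features; a voxel's dependence size counts itself
    plus 26-neighbors within gray-level tolerance ``alpha``."""
    m = gldm_matrix(roi, alpha=alpha)
    P = m.matrix
    Nd = P.sum()
    p = P / Nd
    Ng, Dmax = P.shape
    i = np.arange(1, Ng + 1)
    j = np.arange(1, Dmax + 1)
    Iv, Jv = np.meshgrid(i, j, indexing="ij")
    di = P.sum(axis=1)
    dj = P.sum(axis=0)
    _, glv = _weighted_moments(p, i.astype(float), 0)
    _, dv = _weighted_moments(p, j.astype(float), 1)

    values = [
        _entropy2(p.ravel()),
        float((dj**2).sum() / Nd),
        float((dj**2).sum() / Nd**2),
        dv,
        float((di**2).sum() / Nd),
        glv,
        float((p * Iv**2).sum()),
        float((p * Jv**2).sum()),
        float((p * Iv**2 * Jv**2).sum()),
        float((p * Jv**2 / Iv**2).sum()),
        float((p / Iv**2).sum()),
        float((p / Jv**2).sum()),
        float((p * Iv**2 / Jv**2).sum()),
        float((p / (Iv**2 * Jv**2)).sum()),
    ]
    return FeatureVector(list(GLDM_NAMES), np.array(values))


FAMILY_FEATURE_NAMES = {
    "First order": FIRSTORDER_NAMES,
    "Glcm": GLCM_NAMES,
    "Glrlm": GLRLM_NAMES,
    "Glszm": GLSZM_NAMES,
    "Gldm": GLDM_NAMES,
}
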