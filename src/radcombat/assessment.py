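"""Batch-effect assessment: per-feature one-way ANOVA across batches,
PCA of the standardized feature table, and per-group distribution
summaries. Run before and after harmonization, these quantify how much
scanner-manufacturer variability the adjustment removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import FeatureTable

__all__ = [
    "AnovaRecord", "PcaProjection", "anova_by_batch", "pca_project",
    "distribution_summary", "rejection_rate", "batch_silhouette",
]

#: underflow-safe minimum reported p-value (degenerate zero-within-variance)
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class AnovaRecord:
    feature_name: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    p_bh: float = float("nan")  # Benjamini-Hochberg adjusted, filled per set


def anova_by_batch(
    table: FeatureTable, feature_subset: list[str] | None = None
) -> list[AnovaRecord]:
    """Classical one-way fixed-effects ANOVA of each feature across batches.

    F is computed straight from the between/within sums of squares; the
    p-value comes from the F distribution. Zero within-group variance
    with distinct means reports the underflow-safe minimum p; identical
    constant groups report F=0, p=1. A Benjamini-Hochberg column is
    filled across the tested set for transparency (the per-feature
    p-values themselves are unadjusted).
    """
    levels = table.batch_levels
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 batches")
    masks = [table.batch_labels == b for b in levels]
    ns = np.array([int(m.sum()) for m in masks])
    if (ns < 2).any():
        raise ValueError("every batch needs at least 2 samples")
    names = feature_subset if feature_subset is not None else table.feature_names
    idx = [table.feature_names.index(n) for n in names]
    Y = table.values[:, idx]
    N = Y.shape[0]
    k = len(levels)
    df_b, df_w = k - 1, N - k

    grand = Y.mean(axis=0)
    ss_between = np.zeros(len(idx))
    ss_within = np.zeros(len(idx))
    for m, n_i in zip(masks, ns):
        gi = Y[m]
        mu_i = gi.mean(axis=0)
        ss_between += n_i * (mu_i - grand) ** 2
        ss_within += ((gi - mu_i) ** 2).sum(axis=0)

    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    records = []
    fs = np.empty(len(idx))
    ps = np.empty(len(idx))
    for g in range(len(idx)):
        if ms_w[g] == 0.0:
            if ms_b[g] == 0.0:
                f, p = 0.0, 1.0
            else:
                f, p = float("inf"), P_FLOOR
        else:
            f = ms_b[g] / ms_w[g]
            p = float(stats.f.sf(f, df_b, df_w))
            p = max(p, P_FLOOR)
        fs[g], ps[g] = f, p
    p_bh = _benjamini_hochberg(ps)
    for g, name in enumerate(names):
        records.append(
            AnovaRecord(name, float(fs[g]), float(ps[g]), df_b, df_w,
                        float(p_bh[g]))
        )
    return records


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        g = order[rank - 1]
        running = min(running, p[g] * n / rank)
        adj[g] = running
    return adj


def rejection_rate(records: list[AnovaRecord], alpha: float = 0.05) -> float:
    """Fraction of features whose unadjusted ANOVA p falls below alpha."""
    return float(np.mean([r.p_value < alpha for r in records]))


@dataclass
class PcaProjection:
    scores: np.ndarray                  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray                # (n_kept_features, n_components)
    feature_names: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)


def pca_project(table: FeatureTable, n_components: int = 2) -> PcaProjection:
    """Project samples on the top principal components of the
    standardized feature matrix.

    Constant features are dropped (with a warning) before
    standardization. Component signs follow the convention that each
    component's largest-magnitude loading is positive.
    """
    import warnings

    X = table.values
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [n for n, k in zip(table.feature_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant features before PCA: {dropped}",
                      RuntimeWarning)
    X = X[:, keep]
    if X.shape[1] < n_components:
        raise ValueError("fewer non-constant features than components")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T.copy()
    for c in range(n_components):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PcaProjection(
        scores,
        pca.explained_variance_ratio_.copy(),
        loadings,
        [n for n, k in zip(table.feature_names, keep) if k],
        dropped,
    )


def batch_silhouette(table: FeatureTable, n_components: int = 2) -> float:
    """Mean silhouette of the batch labels in PC score space.

    High values mean batches form separated clusters (strong batch
    effect); values near zero mean the batches are mixed.
    """
    from sklearn.metrics import silhouette_score

    proj = pca_project(table, n_components)
    return float(silhouette_score(proj.scores, table.batch_labels))


def distribution_summary(
    table: FeatureTable,
    feature_subset: list[str] | None = None,
    group_by: str = "batch",
    grid_points: int = 256,
) -> dict:
    """Quartile/whisker statistics and a Gaussian KDE per feature and group.

    Quartiles use linear interpolation; the KDE bandwidth follows
    Silverman's rule and is evaluated on a fixed common grid per feature,
    so curves are directly comparable across groups.
    """
    names = feature_subset if feature_subset is not None else table.feature_names
    if group_by == "batch":
        group_labels = table.batch_labels
    elif group_by == "class":
        group_labels = table.class_labels
    else:
        raise ValueError("group_by must be 'batch' or 'class'")
    groups = list(dict.fromkeys(group_labels.tolist()))
    out: dict = {"quartile_convention": "linear interpolation",
                 "bandwidth": "silverman", "features": {}}
    for name in names:
        g = table.feature_names.index(name)
        col = table.values[:, g]
        lo, hi = col.min(), col.max()
        # pad by 4 kernel bandwidths so the densities integrate to ~1
        bws = [
            stats.gaussian_kde(col[group_labels == b],
                               bw_method="silverman").factor
            * col[group_labels == b].std(ddof=1)
            for b in groups
            if (col[group_labels == b].size > 1
                and col[group_labels == b].std() > 0)
        ]
        pad = 4.0 * max(bws) if bws else 1.0
        grid = np.linspace(lo - pad, hi + pad, grid_points)
        per_group = {}
        for b in groups:
            v = col[group_labels == b]
            if v.size == 0:
                raise ValueError(f"empty group {b!r}")
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo_w = float(v[v >= q1 - 1.5 * iqr].min())
            hi_w = float(v[v <= q3 + 1.5 * iqr].max())
            if v.size > 1 and v.std() > 0:
                dens = stats.gaussian_kde(v, bw_method="silverman")(grid)
            else:
                dens = np.zeros_like(grid)  # point mass: no finite density
            per_group[str(b)] = {
                "n": int(v.size),
                "quartiles": [float(q1), float(med), float(q3)],
                "whiskers": [lo_w, hi_w],
                "density": dens.tolist(),
            }
        out["features"][name] = {"grid": grid.tolist(), "groups": per_group}
    return out
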