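"""Parametric empirical-Bayes ComBat harmonization.

Removes per-batch additive (location) and multiplicative (scale) effects
from a feature table while preserving protected covariates (here the
texture class). The model for feature ``g`` of sample ``j`` in batch ``i``
is

.. math:: y_{ijg} = \\alpha_g + X\\beta_g + \\gamma_{ig}
          + \\delta_{ig}\\,\\epsilon_{ijg},
          \\qquad \\epsilon_{ijg} \\sim N(0, \\sigma_g^2),

and the harmonized value is

.. math:: \\hat y_{ijg} = \\frac{y_{ijg} - \\hat\\alpha_g - X\\hat\\beta_g
          - \\gamma^*_{ig}}{\\delta^*_{ig}} + \\hat\\alpha_g + X\\hat\\beta_g.

The batch effects are estimated per feature by least squares under the
batch-size-weighted zero-sum constraint, then shrunk across features with
empirical-Bayes priors: normal on the standardized additive effects,
inverse-gamma on the squared multiplicative effects, with hyperparameters
fitted by the method of moments and the conditional posteriors iterated to
a fixed point. Conventions follow the canonical parametric ComBat: pooled
error variance with denominator N, per-batch variances with ddof=1,
posterior mean for gamma and conditional posterior mean for delta**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .datatypes import FeatureTable, require_harmonizable

__all__ = ["CombatModel", "fit_standardize", "eb_hyperpriors", "eb_adjust",
           "harmonize"]

#: floor applied to degenerate within-batch variances of standardized data
DELTA2_FLOOR = 1e-8


class ConfoundingError(ValueError):
    """The covariate design is collinear with batch; effects unidentifiable."""


@dataclass
class CombatModel:
    """All fitted parameters of the location/scale harmonization model.

    Shapes: per-feature vectors are ``(G,)``; batch-by-feature matrices are
    ``(I, G)`` with batches ordered as ``batch_levels``.
    """

    batch_levels: list
    design_columns: list[str]
    n_per_batch: np.ndarray
    alpha_hat: np.ndarray        # (G,) grand location (weighted over batches)
    beta_hat: np.ndarray         # (C, G) protected-covariate coefficients
    sigma2_hat: np.ndarray       # (G,) pooled error variance
    gamma_hat: np.ndarray        # (I, G) standardized per-batch means
    delta2_hat: np.ndarray       # (I, G) standardized per-batch variances
    hyper_gamma_mean: np.ndarray | None = None  # (I,)
    hyper_gamma_var: np.ndarray | None = None   # (I,)
    hyper_delta_lambda: np.ndarray | None = None  # (I,) inv-gamma shape
    hyper_delta_theta: np.ndarray | None = None   # (I,) inv-gamma scale
    gamma_star: np.ndarray | None = None   # (I, G) EB posterior additive
    delta2_star: np.ndarray | None = None  # (I, G) EB posterior multiplicative
    n_iter: int = 0
    converged: bool = False
    variance_floored: bool = False

    def to_dict(self) -> dict:
        """JSON-serializable dump of every fitted parameter."""
        out = {}
        for k, v in asdict(self).items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def _design_matrix(table: FeatureTable, covariates: Sequence[str]):
    """Batch one-hot block followed by covariate columns."""
    levels = table.batch_levels
    n = table.n_samples
    B = np.zeros((n, len(levels)))
    for i, b in enumerate(levels):
        B[:, i] = table.batch_labels == b
    cov_cols, cov_names = [], []
    for c in covariates:
        if c == "class":
            cov_cols.append(table.class_labels.astype(float))
        else:
            raise ValueError(f"unknown covariate {c!r}")
        cov_names.append(c)
    X = np.column_stack([B] + [c[:, None] for c in cov_cols]) if cov_cols else B
    return X, levels, cov_names


def fit_standardize(
    table: FeatureTable, covariates: Sequence[str] = ("class",)
) -> tuple[CombatModel, np.ndarray]:
    """Least-squares fit of the location/scale model and standardization.

    Returns the partially filled model (``alpha_hat`` .. ``delta2_hat``)
    and the standardized matrix ``Z = (y - alpha - X beta) / sigma``.

    Raises
    ------
    ConfoundingError
        If a covariate is collinear with the batch indicators.
    ValueError
        If any feature has zero variance overall (named in the message).
    """
    require_harmonizable(table)
    Y = table.values
    n, G = Y.shape
    X, levels, cov_names = _design_matrix(table, covariates)
    I, C = len(levels), len(cov_names)
    n_i = np.array([int((table.batch_labels == b).sum()) for b in levels])

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfoundingError(
            "covariates are confounded with batch; batch effects are "
            "unidentifiable"
        )

    var_all = Y.var(axis=0)
    dead = [table.feature_names[g] for g in np.where(var_all == 0)[0]]
    if dead:
        raise ValueError(f"zero-variance features: {dead}")

    # per-batch means + covariate slopes, then weighted grand mean so the
    # batch effects average (weighted by batch size) to zero
    B_hat, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_means = B_hat[:I]              # (I, G)
    beta_hat = B_hat[I:]                 # (C, G)
    alpha_hat = (n_i / n) @ batch_means  # (G,)

    resid = Y - X @ B_hat
    sigma2_hat = (resid**2).sum(axis=0) / n  # pooled, denominator N

    stand_ref = alpha_hat[None, :]
    if C:
        stand_ref = stand_ref + X[:, I:] @ beta_hat
    Z = (Y - stand_ref) / np.sqrt(sigma2_hat)

    gamma_hat = np.empty((I, G))
    delta2_hat = np.empty((I, G))
    floored = False
    for i, b in enumerate(levels):
        zi = Z[table.batch_labels == b]
        gamma_hat[i] = zi.mean(axis=0)
        d2 = zi.var(axis=0, ddof=1)
        if np.any(d2 < DELTA2_FLOOR):
            floored = True
            warnings.warn(
                "within-batch variance near zero; floored at "
                f"{DELTA2_FLOOR:g} for batch {b!r}", RuntimeWarning
            )
            d2 = np.maximum(d2, DELTA2_FLOOR)
        delta2_hat[i] = d2

    model = CombatModel(
        batch_levels=list(levels),
        design_columns=list(cov_names),
        n_per_batch=n_i,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        sigma2_hat=sigma2_hat,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        variance_floored=floored,
    )
    return model, Z


def eb_hyperpriors(model: CombatModel) -> CombatModel:
    """Method-of-moments hyperprior estimates across features, per batch.

    Normal prior on gamma: empirical mean and variance of ``gamma_hat``.
    Inverse-gamma prior on delta**2: shape/scale matched to the empirical
    mean ``m`` and variance ``s2`` of ``delta2_hat``:
    ``lambda = (2 s2 + m^2) / s2``, ``theta = (m s2 + m^3) / s2``.
    """
    if model.gamma_hat.shape[1] < 3:
        raise ValueError("hyperpriors need at least 3 features")
    model.hyper_gamma_mean = model.gamma_hat.mean(axis=1)
    model.hyper_gamma_var = model.gamma_hat.var(axis=1, ddof=1)
    m = model.delta2_hat.mean(axis=1)
    s2 = model.delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (2.0 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
    # degenerate spread across features: fall back to a diffuse prior
    bad = ~np.isfinite(lam)
    lam[bad] = 2.0 + 1e-8
    theta[bad] = m[bad] * (lam[bad] - 1.0)
    model.hyper_delta_lambda = lam
    model.hyper_delta_theta = theta
    return model


def _postmean(g_hat, g_bar, n, d2_star, t2):
    """Conditional posterior mean of gamma given delta**2."""
    if np.isinf(t2):
        return g_hat.copy()
    return (t2 * n * g_hat + d2_star * g_bar) / (t2 * n + d2_star)


def _postvar(sum_sq, n, lam, theta):
    """Conditional posterior mean of delta**2 given gamma."""
    return (0.5 * sum_sq + theta) / (n / 2.0 + lam - 1.0)


def eb_adjust(
    model: CombatModel,
    Z: np.ndarray,
    batch_labels: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> CombatModel:
    """Iterate the conditional posterior updates to their fixed point.

    Alternates the precision-weighted gamma update and the inverse-gamma
    delta**2 update until the largest absolute parameter change drops
    below ``tol``. Non-convergence sets ``converged=False`` and warns
    rather than failing.
    """
    if model.hyper_gamma_mean is None:
        raise ValueError("fit hyperpriors before eb_adjust")
    I, G = model.gamma_hat.shape
    gamma_star = model.gamma_hat.copy()
    delta2_star = model.delta2_hat.copy()
    n_iter_max = 0
    converged = True
    for i, b in enumerate(model.batch_levels):
        zi = Z[batch_labels == b]
        n = zi.shape[0]
        g_hat = model.gamma_hat[i]
        d2_hat = model.delta2_hat[i]
        g_bar = model.hyper_gamma_mean[i]
        t2 = model.hyper_gamma_var[i]
        lam = model.hyper_delta_lambda[i]
        theta = model.hyper_delta_theta[i]
        g_old, d2_old = g_hat.copy(), d2_hat.copy()
        change = np.inf
        it = 0
        while change > tol and it < max_iter:
            g_new = _postmean(g_hat, g_bar, n, d2_old, t2)
            sum_sq = ((zi - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = _postvar(sum_sq, n, lam, theta)
            change = max(
                np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
                np.abs(d2_new - d2_old).max() / np.maximum(np.abs(d2_old), 1e-12).max(),
            )
            g_old, d2_old = g_new, d2_new
            it += 1
        if change > tol:
            converged = False
            warnings.warn(
                f"EB updates for batch {b!r} did not converge in "
                f"{max_iter} iterations (last change {change:.3g})",
                RuntimeWarning,
            )
        gamma_star[i] = g_old
        delta2_star[i] = d2_old
        n_iter_max = max(n_iter_max, it)
    model.gamma_star = gamma_star
    model.delta2_star = np.maximum(delta2_star, DELTA2_FLOOR)
    model.n_iter = n_iter_max
    model.converged = converged
    return model


def harmonize(
    table: FeatureTable,
    covariates: Sequence[str] = ("class",),
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[FeatureTable, CombatModel | None]:
    """Full pipeline: standardize, fit EB priors, shrink, back-transform.

    The class label is passed as a protected covariate so the biological
    signal survives harmonization. A single-batch table is returned
    unchanged with a warning (nothing to harmonize).
    """
    if len(table.batch_levels) < 2:
        warnings.warn("single batch: harmonization is the identity",
                      RuntimeWarning)
        return table.with_values(table.values.copy()), None
    model, Z = fit_standardize(table, covariates)
    eb_hyperpriors(model)
    eb_adjust(model, Z, table.batch_labels, tol=tol, max_iter=max_iter)

    X, levels, _ = _design_matrix(table, covariates)
    I = len(levels)
    stand_ref = model.alpha_hat[None, :]
    if model.beta_hat.shape[0]:
        stand_ref = stand_ref + X[:, I:] @ model.beta_hat

    out = np.empty_like(table.values)
    sigma = np.sqrt(model.sigma2_hat)
    for i, b in enumerate(levels):
        mask = table.batch_labels == b
        z_adj = (Z[mask] - model.gamma_star[i]) / np.sqrt(model.delta2_star[i])
        out[mask] = z_adj * sigma + stand_ref[mask]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("harmonized output contains non-finite values")
    return table.with_values(out), model
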