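"""Independent straight-from-the-equations ComBat reference.

Coded with explicit per-feature loops and scalar arithmetic, deliberately
sharing no code with the package implementation, as the oracle for the
harmonization equivalence tests.
"""

from __future__ import annotations

import numpy as np


def reference_harmonize(values, batch_labels, class_labels,
                        tol=1e-10, max_iter=5000):
    """Parametric EB location/scale harmonization, feature by feature.

    values: (n, G); batch_labels: (n,) categorical; class_labels: (n,) 0/1.
    Returns the harmonized matrix.
    """
    values = np.asarray(values, dtype=float)
    n, G = values.shape
    batches = list(dict.fromkeys(batch_labels.tolist()))
    I = len(batches)
    masks = [np.asarray(batch_labels) == b for b in batches]
    n_i = np.array([m.sum() for m in masks])
    x = np.asarray(class_labels, dtype=float)

    # least squares per feature: y = sum_i mu_i 1{batch i} + x * beta
    alpha = np.zeros(G)
    beta = np.zeros(G)
    sigma2 = np.zeros(G)
    Z = np.zeros_like(values)
    design = np.zeros((n, I + 1))
    for i, m in enumerate(masks):
        design[m, i] = 1.0
    design[:, I] = x
    for g in range(G):
        coef, *_ = np.linalg.lstsq(design, values[:, g], rcond=None)
        mu = coef[:I]
        beta[g] = coef[I]
        alpha[g] = float(np.dot(n_i / n, mu))
        resid = values[:, g] - design @ coef
        sigma2[g] = float((resid**2).sum() / n)
        Z[:, g] = (values[:, g] - alpha[g] - x * beta[g]) / np.sqrt(sigma2[g])

    gamma_hat = np.zeros((I, G))
    delta2_hat = np.zeros((I, G))
    for i, m in enumerate(masks):
        for g in range(G):
            zi = Z[m, g]
            gamma_hat[i, g] = zi.mean()
            delta2_hat[i, g] = zi.var(ddof=1)

    out = np.zeros_like(values)
    for i, m in enumerate(masks):
        g_bar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var(ddof=1)
        md = delta2_hat[i].mean()
        s2 = delta2_hat[i].var(ddof=1)
        lam = (2.0 * s2 + md**2) / s2
        theta = (md * s2 + md**3) / s2
        ni = int(n_i[i])

        g_star = gamma_hat[i].copy()
        d2_star = delta2_hat[i].copy()
        for _ in range(max_iter):
            g_new = np.array([
                (t2 * ni * gamma_hat[i, g] + d2_star[g] * g_bar)
                / (t2 * ni + d2_star[g])
                for g in range(G)
            ])
            d2_new = np.array([
                (theta + 0.5 * float(((Z[m, g] - g_new[g]) ** 2).sum()))
                / (ni / 2.0 + lam - 1.0)
                for g in range(G)
            ])
            if (np.abs(g_new - g_star).max() < tol
                    and np.abs(d2_new - d2_star).max() < tol):
                g_star, d2_star = g_new, d2_new
                break
            g_star, d2_star = g_new, d2_new

        for g in range(G):
            z_adj = (Z[m, g] - g_star[g]) / np.sqrt(d2_star[g])
            out[m, g] = (z_adj * np.sqrt(sigma2[g]) + alpha[g]
                         + x[m] * beta[g])
    return out
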