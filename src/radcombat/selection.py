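"""L1-penalized feature screening.

A lasso regression of the binary class label on the standardized features
ranks features by absolute coefficient; the top ``n_keep`` nonzero
coefficients form the working feature set for the downstream comparison.
Selection is deliberately computed once (on unharmonized data) so the
with/without-harmonization arms share an identical feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso

from .datatypes import FeatureTable

__all__ = ["SelectionResult", "lasso_select"]


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    selected_names: list[str]
    coefficients: np.ndarray  # lasso coefficients of the selected features
    penalty: float
    n_requested: int

    def to_dict(self) -> dict:
        return {
            "selected_names": self.selected_names,
            "coefficients": [float(c) for c in self.coefficients],
            "penalty": self.penalty,
            "n_requested": self.n_requested,
        }


def lasso_select(
    table: FeatureTable,
    penalty: float = 0.1,
    n_keep: int = 20,
    max_iter: int = 1000,
) -> SelectionResult:
    """Select up to ``n_keep`` features by |lasso coefficient|.

    Features are standardized (zero mean, unit variance, on this input
    only) before the fit; ties in |coefficient| break by feature name so
    the result is fully deterministic.

    Raises
    ------
    SelectionError
        If the penalty zeroes every coefficient (advises lowering it).
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if n_keep < 1:
        raise ValueError("n_keep must be positive")
    X = table.values
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - X.mean(axis=0)) / sd_safe
    y = table.class_labels.astype(float)

    model = Lasso(alpha=penalty, max_iter=max_iter)
    model.fit(Xs, y)
    coef = model.coef_.copy()
    coef[sd == 0] = 0.0  # constant features carry no information
    nonzero = np.nonzero(coef)[0]
    if nonzero.size == 0:
        raise SelectionError(
            f"lasso at penalty {penalty} zeroed every coefficient; "
            "try a smaller penalty"
        )
    order = sorted(
        nonzero, key=lambda g: (-abs(coef[g]), table.feature_names[g])
    )[:n_keep]
    return SelectionResult(
        [table.feature_names[g] for g in order],
        coef[order],
        float(penalty),
        int(n_keep),
    )
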