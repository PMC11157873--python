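"""Common data containers shared by every pipeline stage.

The central currency is :class:`FeatureTable`: a samples x features matrix of
radiomic feature values together with a per-sample batch label (scanner
manufacturer) and a binary class label (cartridge texture; 0 = rubber,
1 = 50% ABS honeycomb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]

#: reserved leading columns of the CSV serialization
_META_COLS = ("sample_id", "batch", "class")


@dataclass
class FeatureTable:
    """Samples x features matrix with batch and class annotations.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Feature values; must be finite.
    feature_names : list of str
        Unique column names, one per feature.
    batch_labels : ndarray of str or int, shape (n_samples,)
        Scanner-manufacturer (batch) label per sample.
    class_labels : ndarray of int, shape (n_samples,)
        Binary texture class per sample (0 or 1).
    sample_ids : list of str, optional
        Stable row identifiers; generated as ``s0000..`` when omitted.
    """

    values: np.ndarray
    feature_names: list[str]
    batch_labels: np.ndarray
    class_labels: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.batch_labels = np.asarray(self.batch_labels)
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        n, g = self.values.shape
        if len(self.feature_names) != g:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {g} columns"
            )
        if len(set(self.feature_names)) != g:
            raise ValueError("feature names must be unique")
        if self.batch_labels.shape != (n,) or self.class_labels.shape != (n,):
            raise ValueError("label vectors must match the number of samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain NaN or infinity")
        if not np.isin(self.class_labels, (0, 1)).all():
            raise ValueError("class labels must be binary (0/1)")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def batch_levels(self) -> list:
        """Batch identifiers in first-appearance order."""
        seen: dict = {}
        for b in self.batch_labels:
            seen.setdefault(b, None)
        return list(seen)

    def batch_sizes(self) -> dict:
        return {b: int((self.batch_labels == b).sum()) for b in self.batch_levels}

    def subset_features(self, names: list[str]) -> "FeatureTable":
        """Column-subset preserving sample annotations."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            self.values[:, idx],
            list(names),
            self.batch_labels.copy(),
            self.class_labels.copy(),
            list(self.sample_ids),
        )

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        """Same annotations, new value matrix (e.g. after harmonization)."""
        return FeatureTable(
            np.asarray(values, dtype=float),
            list(self.feature_names),
            self.batch_labels.copy(),
            self.class_labels.copy(),
            list(self.sample_ids),
        )

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "class", self.class_labels)
        df.insert(0, "batch", self.batch_labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        feats = [c for c in df.columns if c not in _META_COLS]
        return cls(
            df[feats].to_numpy(dtype=float),
            feats,
            df["batch"].to_numpy(),
            df["class"].to_numpy(dtype=int),
            [str(s) for s in df["sample_id"]],
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


def require_harmonizable(table: FeatureTable) -> None:
    """Validate the >=2 batches / >=2 samples-per-batch contract."""
    sizes = table.batch_sizes()
    if len(sizes) < 2:
        raise ValueError("need at least 2 batches")
    small = [b for b, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")
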