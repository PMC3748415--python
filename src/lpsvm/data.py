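"""Core data container for binary classification problems.

A :class:`Dataset` bundles a dense sample-by-feature matrix with labels in
{-1, +1} and, for synthetic benchmarks, the set of ground-truth relevant
feature indices (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Feature matrix plus binary labels.

    Parameters
    ----------
    features
        Real matrix of shape ``(m, n)``; must be finite.
    labels
        Vector of length ``m`` with entries in ``{-1, +1}``.
    relevant_indices
        Optional ground-truth set of informative feature columns (0-based),
        available for synthetic data only.
    """

    features: np.ndarray
    labels: np.ndarray
    relevant_indices: frozenset | None = field(default=None)

    def __post_init__(self) -> None:
        self.features = np.ascontiguousarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.float64).ravel()
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError(
                f"label count {self.labels.shape[0]} does not match "
                f"sample count {self.features.shape[0]}"
            )
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite entries")
        if not np.isin(self.labels, (-1.0, 1.0)).all():
            raise ValueError("labels must all be -1 or +1")
        if self.relevant_indices is not None:
            self.relevant_indices = frozenset(int(j) for j in self.relevant_indices)
            if any(j < 0 or j >= self.n_features for j in self.relevant_indices):
                raise ValueError("relevant_indices out of feature range")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def has_both_classes(self) -> bool:
        return bool((self.labels > 0).any() and (self.labels < 0).any())

    def take(self, indices: np.ndarray) -> "Dataset":
        """Row subset (copy), preserving relevant-feature annotation."""
        idx = np.asarray(indices, dtype=np.intp)
        return Dataset(
            self.features[idx].copy(),
            self.labels[idx].copy(),
            relevant_indices=self.relevant_indices,
        )
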