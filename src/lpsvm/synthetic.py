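"""Synthetic benchmark data with known relevant features.

Implements the classic Weston-style feature-selection benchmark: each
sample has 100 features of which 6 are informative.  The label y is +-1
with equal probability.  Per sample a coin with success probability 0.7
decides which block of three features carries the class signal: the
signal block is drawn from N(3y, 1), N(2.2y, 1), N(1.4y, 1), the other
block from N(0, 1), and the remaining 94 features are pure noise drawn
from a zero-mean normal with variance 20.  Inputs are subsequently scaled
to zero mean and unit standard deviation.

Because the relevant columns are known ({0..5}, 0-based), feature
selection can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset

__all__ = ["WestonSpec", "Scaler", "generate_weston", "standardize", "split"]


@dataclass
class WestonSpec:
    """Parameters of the synthetic benchmark generator.

    ``noise_variance`` follows the variance convention, so the noise
    features have standard deviation sqrt(20) by default; since every
    feature is standardized downstream, this choice does not affect the
    fitted models on noise columns.
    """

    n_samples: int
    n_features: int = 100
    relevant_means: tuple = (3.0, 2.2, 1.4)
    primary_block_prob: float = 0.7
    noise_variance: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_features < 6:
            raise ValueError("need at least the 6 relevant features")
        if not 0.0 <= self.primary_block_prob <= 1.0:
            raise ValueError("primary_block_prob must lie in [0, 1]")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be > 0")


def generate_weston(spec: WestonSpec, return_assignment: bool = False):
    """Draw a seeded benchmark dataset; same spec -> bit-identical data.

    With ``return_assignment=True`` also returns the per-sample boolean
    mask that is True where the first block (features 0-2) carries the
    class signal.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_samples, spec.n_features
    mu = np.asarray(spec.relevant_means, dtype=np.float64)
    y = np.where(rng.random(m) < 0.5, 1.0, -1.0)
    primary = rng.random(m) < spec.primary_block_prob
    signal = rng.standard_normal((m, 3)) + y[:, None] * mu[None, :]
    null = rng.standard_normal((m, 3))
    x = np.empty((m, n))
    x[:, 0:3] = np.where(primary[:, None], signal, null)
    x[:, 3:6] = np.where(primary[:, None], null, signal)
    x[:, 6:] = rng.normal(0.0, np.sqrt(spec.noise_variance), size=(m, n - 6))
    data = Dataset(x, y, relevant_indices=frozenset(range(6)))
    if return_assignment:
        return data, primary
    return data


@dataclass
class Scaler:
    """Per-feature affine transform fitted on training data.

    Centers to zero mean and scales to unit standard deviation (population
    denominator m).
    """

    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, features: np.ndarray) -> "Scaler":
        mean = features.mean(axis=0)
        scale = features.std(axis=0)  # ddof=0
        zero = np.flatnonzero(scale == 0.0)
        if zero.size:
            raise ValueError(
                f"feature {int(zero[0])} has zero variance; cannot standardize"
            )
        return cls(mean_=mean, scale_=scale)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean_) / self.scale_

    def apply(self, data: Dataset) -> Dataset:
        return Dataset(
            self.transform(data.features),
            data.labels.copy(),
            relevant_indices=data.relevant_indices,
        )


def standardize(train: Dataset, others: list[Dataset] | tuple = ()):
    """Standardize ``train`` and apply the same transform to ``others``.

    The scaler is fitted on the training split only, so no information
    from held-out data leaks into preprocessing.  Returns
    ``(train_std, others_std, scaler)``.
    """
    if train.n_samples == 0:
        raise ValueError("training data is empty")
    scaler = Scaler.fit(train.features)
    return scaler.apply(train), [scaler.apply(d) for d in others], scaler


def split(data: Dataset, n_train: int, seed: int):
    """Seeded uniform train/validation split without replacement.

    Permutations are redrawn (up to 100 times) until the training part
    contains both classes.
    """
    if not 0 < n_train < data.n_samples:
        raise ValueError("n_train must lie strictly between 0 and n_samples")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        perm = rng.permutation(data.n_samples)
        train_idx, valid_idx = perm[:n_train], perm[n_train:]
        labels = data.labels[train_idx]
        if (labels > 0).any() and (labels < 0).any():
            return data.take(train_idx), data.take(valid_idx)
    raise ValueError(
        "could not obtain a training split containing both classes "
        "after 100 attempts"
    )
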