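"""Hybrid class balancing: nested negative downsampling plus SMOTE.

Two-class protein benchmarks are typically heavily skewed (here roughly
one positive per ten negatives), and a classifier fit on the raw data
drifts toward the majority class.  The treatment implemented here meets
the classes at a common size n:

* negatives are downsampled WITHOUT replacement to n by taking the first
  n elements of a single seed-determined permutation, so the retained
  subsets are nested — S(n) is a subset of S(m) whenever n < m under the
  same seed.  This removes subset-sampling randomness as a confounder
  when sweeping n;
* positives are oversampled to n with SMOTE: each synthetic point is an
  interpolation between a minority sample x and one of its K nearest
  minority neighbours x_n (Euclidean metric on the descriptor features).

At n = (positive count) the treatment degenerates to pure downsampling;
at n = (negative count) to pure oversampling.

Balancing is meant for the training partition only (of each CV fold, and
of the train/independent split); held-out data must stay untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .descriptors import FeatureMatrix

#: SMOTE interpolation variants.
#: ``standard-smote`` is the canonical x + u*(x_n - x) with one uniform
#: draw u per synthetic row.  ``paper-literal`` is x + u*|x - x_n|
#: componentwise, which only moves coordinates upward; it is kept for
#: fidelity with sources that print the formula with an absolute value.
Variant = Literal["standard-smote", "paper-literal"]


@dataclass(frozen=True)
class BalanceConfig:
    """Parameters of the hybrid balancing step."""

    n: int
    k_neighbors: int = 5
    seed: int = 0
    variant: Variant = "standard-smote"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.variant not in ("standard-smote", "paper-literal"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class BalancedSet:
    """A class-balanced feature set with a full audit trail."""

    features: FeatureMatrix
    labels: np.ndarray
    synthetic_mask: np.ndarray  # True for SMOTE-generated rows
    negative_subset_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.synthetic_mask = np.asarray(self.synthetic_mask, dtype=bool)

    @property
    def n_synthetic(self) -> int:
        return int(self.synthetic_mask.sum())


def downsample_negatives(
    features: FeatureMatrix,
    labels: np.ndarray,
    n: int,
    seed: int,
) -> np.ndarray:
    """Return indices of n retained negatives: the first n elements of one
    seed-determined permutation of the negative rows (sorted for output
    stability).  Prefix-of-permutation sampling makes retained sets nested
    across n for a fixed seed."""
    labels = np.asarray(labels, dtype=int)
    neg_idx = np.flatnonzero(labels == 0)
    if n < 1:
        raise ValueError("n must be positive")
    if n > len(neg_idx):
        raise ValueError(
            f"cannot retain {n} negatives: only {len(neg_idx)} available"
        )
    perm = np.random.default_rng(seed).permutation(len(neg_idx))
    return np.sort(neg_idx[perm[:n]])


def smote_positives(
    features: FeatureMatrix,
    labels: np.ndarray,
    target: int,
    k_neighbors: int = 5,
    seed: int = 0,
    variant: Variant = "standard-smote",
) -> np.ndarray:
    """Generate (target - positive count) synthetic positive rows.

    Seed samples are chosen round-robin over the positives (any remainder
    beyond whole rounds is assigned by the seeded RNG), the neighbour
    uniformly among the K nearest positives, and the interpolation factor
    u ~ Uniform(0,1) is drawn once per synthetic row.  Ties in neighbour
    distance resolve to the lowest row index.

    Returns an array of shape (target - n_pos, dimension); empty when
    target equals the current positive count.
    """
    labels = np.asarray(labels, dtype=int)
    pos_idx = np.flatnonzero(labels == 1)
    n_pos = len(pos_idx)
    if n_pos < 2:
        raise ValueError("SMOTE needs at least 2 positive samples")
    if k_neighbors >= n_pos:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be < positive count {n_pos}"
        )
    if target < n_pos:
        raise ValueError(
            f"target {target} below current positive count {n_pos}"
        )
    X = features.values[pos_idx]
    n_new = target - n_pos
    if n_new == 0:
        return np.empty((0, X.shape[1]))

    # K nearest minority neighbours of every positive, self excluded.
    # sklearn orders equal-distance neighbours by index, matching the
    # lowest-row-index tie-break.
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    rounds, remainder = divmod(n_new, n_pos)
    seeds = np.concatenate(
        [np.tile(np.arange(n_pos), rounds),
         rng.choice(n_pos, size=remainder, replace=False)]
    ).astype(int)
    chosen = neighbor_idx[seeds, rng.integers(0, k_neighbors, size=n_new)]
    u = rng.uniform(0.0, 1.0, size=n_new)[:, None]
    x, xn = X[seeds], X[chosen]
    if variant == "standard-smote":
        return x + u * (xn - x)
    if variant == "paper-literal":
        return x + u * np.abs(x - xn)
    raise ValueError(f"unknown variant {variant!r}")


def hybrid_balance(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    config: BalanceConfig | None = None,
) -> BalancedSet:
    """Downsample negatives to n and SMOTE positives up to n.

    Original positive rows are all retained unchanged; synthetic rows are
    appended after them and flagged in ``synthetic_mask``.  Output row
    order: positives (originals then synthetic), then retained negatives.
    """
    if config is None:
        raise ValueError("a BalanceConfig is required")
    if labels is None:
        if features.labels is None:
            raise ValueError("labels required (none attached to features)")
        labels = features.labels
    labels = np.asarray(labels, dtype=int)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if not (len(pos_idx) <= config.n <= len(neg_idx)):
        raise ValueError(
            f"n={config.n} outside the hybrid range "
            f"[{len(pos_idx)}, {len(neg_idx)}]"
        )

    keep_neg = downsample_negatives(features, labels, config.n, config.seed)
    synthetic = smote_positives(
        features, labels, config.n,
        config.k_neighbors, config.seed, config.variant,
    )

    values = np.vstack(
        [features.values[pos_idx], synthetic, features.values[keep_neg]]
    )
    row_ids = (
        [features.row_ids[i] for i in pos_idx]
        + [f"synthetic_{j}" for j in range(len(synthetic))]
        + [features.row_ids[i] for i in keep_neg]
    )
    out_labels = np.concatenate(
        [np.ones(config.n, dtype=int), np.zeros(config.n, dtype=int)]
    )
    mask = np.zeros(2 * config.n, dtype=bool)
    mask[len(pos_idx): len(pos_idx) + len(synthetic)] = True
    balanced = FeatureMatrix(
        values, row_ids, list(features.column_names),
        features.descriptor, out_labels,
    )
    return BalancedSet(
        balanced, out_labels, mask,
        [features.row_ids[i] for i in keep_neg],
    )
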