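"""Gradient-boosted tree classification with a leaves/depth/rate surface.

The primary learner is a histogram-based gradient-boosted decision tree
(LightGBM); a random forest and an alternative boosting backend (XGBoost)
sit behind the same interface so descriptor benchmarks can compare the
three families without branching code.

The tuned surface is (num_leaves, max_depth, learning_rate).  A leaf-wise
tree with ``num_leaves`` leaves needs depth at least
``ceil(log2(num_leaves + 1))`` to be representable, so configurations with
a bounded depth below that are rejected before fitting.

Determinism contract: fixed seed + single-threaded execution give
bit-identical scores.  Multi-threading can be enabled explicitly, waiving
the contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd

from .descriptors import DescriptorConfig, FeatureMatrix

logger = logging.getLogger(__name__)

ALGORITHMS = ("gbdt-histogram", "random-forest", "gbdt-alternative")


def min_max_depth(num_leaves: int) -> int:
    """Smallest tree depth at which ``num_leaves`` leaves are representable:
    ceil(log2(num_leaves + 1)).  E.g. 31 leaves need depth >= 5."""
    if num_leaves < 2:
        raise ValueError("a split tree has at least 2 leaves")
    return math.ceil(math.log2(num_leaves + 1))


@dataclass(frozen=True)
class ClassifierConfig:
    """Learner choice plus the tuned hyperparameter surface.

    ``max_depth=None`` leaves the depth unbounded.  ``extra_params`` is
    passed through to the backend (e.g. ``min_child_samples`` for tiny
    training sets).
    """

    algorithm: str = "gbdt-histogram"
    num_leaves: int = 31
    max_depth: int | None = 10
    learning_rate: float = 0.08
    n_estimators: int = 100
    seed: int = 0
    n_threads: int = 1
    extra_params: tuple[tuple[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"expected one of {ALGORITHMS}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.num_leaves < 2:
            raise ValueError("num_leaves must be >= 2")
        if self.max_depth is not None:
            needed = min_max_depth(self.num_leaves)
            if self.max_depth < needed:
                raise ValueError(
                    f"max_depth={self.max_depth} cannot represent "
                    f"{self.num_leaves} leaves (needs >= {needed})"
                )

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return replace(self, seed=seed)


@dataclass
class TrainedModel:
    """A fitted learner plus the provenance needed to use it safely."""

    learner: Any
    dimension: int
    config: ClassifierConfig
    descriptor: DescriptorConfig | None = None
    column_checksum: str | None = None

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(
        path: str | Path, expect_checksum: str | None = None
    ) -> "TrainedModel":
        model = joblib.load(path)
        if (
            expect_checksum is not None
            and model.column_checksum is not None
            and model.column_checksum != expect_checksum
        ):
            raise ValueError(
                "feature column checksum mismatch: model was trained on "
                f"{model.column_checksum}, got {expect_checksum}"
            )
        return model


def _filter_extras(estimator, extra: dict) -> dict:
    """Keep only extra params the backend accepts (they are
    backend-specific; unknown ones are dropped with a warning)."""
    valid = estimator.get_params()
    kept = {k: v for k, v in extra.items() if k in valid}
    for k in extra.keys() - kept.keys():
        logger.warning(
            "extra param %r not understood by %s; ignored",
            k, type(estimator).__name__,
        )
    return kept


def _build_learner(config: ClassifierConfig):
    extra = dict(config.extra_params)
    if config.algorithm == "gbdt-histogram":
        import lightgbm

        est = lightgbm.LGBMClassifier(
            num_leaves=config.num_leaves,
            max_depth=-1 if config.max_depth is None else config.max_depth,
            learning_rate=config.learning_rate,
            n_estimators=config.n_estimators,
            random_state=config.seed,
            n_jobs=config.n_threads,
            deterministic=config.n_threads == 1,
            force_row_wise=True,
            verbose=-1,
        )
        return est.set_params(**_filter_extras(est, extra))
    if config.algorithm == "random-forest":
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            max_leaf_nodes=config.num_leaves,
            random_state=config.seed,
            n_jobs=config.n_threads,
        )
        return est.set_params(**_filter_extras(est, extra))
    import xgboost

    est = xgboost.XGBClassifier(
        max_leaves=config.num_leaves,
        max_depth=0 if config.max_depth is None else config.max_depth,
        grow_policy="lossguide",
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        random_state=config.seed,
        nthread=config.n_threads,
        tree_method="hist",
        eval_metric="logloss",
    )
    return est.set_params(**_filter_extras(est, extra))


def train(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    config: ClassifierConfig | None = None,
) -> TrainedModel:
    """Fit the configured learner on a feature matrix.

    Requires at least two samples of each class; the config's
    representability constraint is enforced at construction time.
    """
    if config is None:
        config = ClassifierConfig()
    if labels is None:
        if features.labels is None:
            raise ValueError("labels required (none attached to features)")
        labels = features.labels
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    learner = _build_learner(config)
    learner.fit(features.values, labels)
    return TrainedModel(
        learner,
        features.dimension,
        config,
        features.descriptor,
        features.column_checksum(),
    )


def predict_scores(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Positive-class probability per sample, in [0, 1]."""
    if features.dimension != model.dimension:
        raise ValueError(
            f"feature dimension {features.dimension} does not match "
            f"training dimension {model.dimension}"
        )
    import warnings

    with warnings.catch_warnings():
        # LightGBM autogenerates feature names at fit time; sklearn then
        # warns when predict sees a plain ndarray.  Harmless here.
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        scores = model.learner.predict_proba(features.values)[:, 1]
    return np.clip(scores, 0.0, 1.0)


def predict_labels(
    model: TrainedModel, features: FeatureMatrix, threshold: float = 0.5
) -> np.ndarray:
    """Hard 0/1 labels at the given score threshold (default 0.5)."""
    return (predict_scores(model, features) >= threshold).astype(int)


def grid_search(
    features: FeatureMatrix,
    labels: np.ndarray | None,
    num_leaves_grid: list[int],
    max_depth_grid: list[int | None],
    learning_rate_grid: list[float],
    folds: int = 5,
    seed: int = 0,
    base_config: ClassifierConfig | None = None,
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Exhaustive CV evaluation over the leaves x depth x rate grid.

    Grid points whose depth cannot represent the requested leaf count are
    skipped with a warning.  Returns the winning config (best MCC, ties
    broken by AUROC then smaller num_leaves) and the full per-point metric
    table.
    """
    from .evaluate import cross_validate  # local import: avoids a cycle

    if not (num_leaves_grid and max_depth_grid and learning_rate_grid):
        raise ValueError("grid axes must be non-empty")
    if base_config is None:
        base_config = ClassifierConfig()
    rows = []
    for leaves, depth, rate in product(
        num_leaves_grid, max_depth_grid, learning_rate_grid
    ):
        try:
            config = replace(
                base_config,
                num_leaves=leaves,
                max_depth=depth,
                learning_rate=rate,
                seed=seed,
            )
        except ValueError as exc:
            logger.warning(
                "skipping grid point leaves=%s depth=%s rate=%s: %s",
                leaves, depth, rate, exc,
            )
            continue
        report = cross_validate(features, labels, config, folds, seed=seed)
        rows.append(
            {
                "num_leaves": leaves,
                "max_depth": depth,
                "learning_rate": rate,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "accuracy": report.accuracy,
                "mcc": report.mcc,
                "auroc": report.auroc,
            }
        )
    if not rows:
        raise ValueError("no valid grid points")
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mcc", "auroc", "num_leaves"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    best = order.iloc[0]
    best_config = replace(
        base_config,
        num_leaves=int(best["num_leaves"]),
        max_depth=None if pd.isna(best["max_depth"])
        else int(best["max_depth"]),
        learning_rate=float(best["learning_rate"]),
        seed=seed,
    )
    return best_config, table
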