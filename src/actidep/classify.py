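"""Random-forest episode classification on a chosen feature subset.

The classifier follows the canonical random-forest defaults: 500 trees,
sqrt(p) candidate features per split, unlimited depth, bootstrap n-out-of-n
sampling.  The positive class is 1 (condition / depressive episode); a tied
majority vote predicts positive.  Evaluation reuses the same 70/30
stratified split machinery as feature selection so both stages can share one
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from actidep.features import N_FEATURES, FeatureVector, feature_matrix
from actidep.selection import SplitSpec, split_indices
from actidep.validate import ConfusionCounts, ValidationReport, confusion, metrics


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings (canonical library defaults)."""

    n_trees: int = 500
    candidate_features_per_split: int | str = "sqrt"
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class RFModel:
    """A fitted forest bound to the feature subset it was trained on."""

    estimator: RandomForestClassifier
    feature_set: tuple[int, ...]


@dataclass
class ExperimentResult:
    """One dataset x feature-set classification run."""

    dataset: str
    feature_set: tuple[int, ...]
    counts: ConfusionCounts
    report: ValidationReport


def train_rf(train: list[FeatureVector], feature_set, config: RFConfig = RFConfig()) -> RFModel:
    """Fit a random forest on the given feature columns of the training set."""
    cols = tuple(sorted(feature_set))
    if not cols or min(cols) < 0 or max(cols) >= N_FEATURES:
        raise ValueError(f"feature indices must lie in 0..{N_FEATURES - 1}")
    X, y = feature_matrix(train)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.candidate_features_per_split,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X[:, cols], y)
    return RFModel(estimator=est, feature_set=cols)


def predict_labels(model: RFModel, vectors: list[FeatureVector]) -> np.ndarray:
    """Majority vote over the forest; a tie predicts the positive class."""
    if not vectors:
        return np.array([], dtype=int)
    X, _ = feature_matrix(vectors)
    if X.shape[1] != N_FEATURES:
        raise ValueError("vectors must carry the full 24-column feature matrix")
    proba = model.estimator.predict_proba(X[:, model.feature_set])
    pos_col = list(model.estimator.classes_).index(1)
    return (proba[:, pos_col] >= 0.5).astype(int)


def run_experiment(
    dataset_vectors: list[FeatureVector],
    feature_set,
    split_spec: SplitSpec,
    rf_config: RFConfig = RFConfig(),
    dataset_name: str = "",
) -> ExperimentResult:
    """Split, train, predict the test set, and compute validation metrics."""
    _, y = feature_matrix(dataset_vectors)
    train_idx, test_idx = split_indices(y, split_spec)
    train = [dataset_vectors[i] for i in train_idx]
    test = [dataset_vectors[i] for i in test_idx]
    model = train_rf(train, feature_set, rf_config)
    pred = predict_labels(model, test)
    counts = confusion(y[test_idx], pred)
    return ExperimentResult(
        dataset=dataset_name,
        feature_set=model.feature_set,
        counts=counts,
        report=metrics(counts),
    )
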