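"""Greedy forward feature selection scored by logistic-regression accuracy.

Feature subsets are scored by fitting an unpenalized binomial logistic
regression on 70% of the windows and measuring classification accuracy on the
held-out 30% (single stratified split, fixed seed).  Selection starts from
the best single feature and greedily adds the feature that maximizes held-out
accuracy, recording the trace for set sizes 2..max_features; ties go to the
lowest feature index.  ``best_k`` is the size of the first recorded set
achieving the maximum accuracy in the trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split as _sk_split

from actidep.features import N_FEATURES, FeatureVector, feature_matrix


@dataclass(frozen=True)
class SplitSpec:
    """A single train/test partition: fraction, seed, stratification flag."""

    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class SelectionTrace:
    """Ordered (feature set, held-out accuracy) rows of one greedy run."""

    rows: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    best_k: int = 0

    def best_set(self, k: int | None = None) -> tuple[int, ...]:
        """The recorded set of size ``k`` (default: size ``best_k``)."""
        k = self.best_k if k is None else k
        for feats, _ in self.rows:
            if len(feats) == k:
                return feats
        raise KeyError(f"no recorded set of size {k}")

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("set,accuracy\n")
            for feats, acc in self.rows:
                fh.write(f"\"[{','.join(map(str, feats))}]\",{acc:.4f}\n")


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Index-level 70/30 partition shared by selection and classification."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 observations to split")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    n_train = int(round(spec.train_fraction * n))
    idx = np.arange(n)
    train_idx, test_idx = _sk_split(
        idx,
        train_size=n_train,
        random_state=spec.seed,
        shuffle=True,
        stratify=labels if spec.stratified else None,
    )
    return train_idx, test_idx


def split_train_test(
    vectors: list[FeatureVector], spec: SplitSpec
) -> tuple[list[FeatureVector], list[FeatureVector]]:
    """Partition feature vectors into disjoint train and test lists."""
    _, y = feature_matrix(vectors)
    train_idx, test_idx = split_indices(y, spec)
    return [vectors[i] for i in train_idx], [vectors[i] for i in test_idx]


def _fit_lr(X_train, y_train):
    model = LogisticRegression(C=np.inf, max_iter=2000, solver="lbfgs")
    with warnings.catch_warnings():
        # a capped-iteration fit is still scored; surface one warning
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X_train, y_train)
    return model


def lr_accuracy(
    feature_indices,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
) -> float:
    """Held-out accuracy of a logistic regression on the given columns.

    ``train`` and ``test`` are (X, y) pairs over the full 24-column feature
    matrix; the model sees only the requested columns.  Prediction threshold
    is 0.5.
    """
    cols = sorted(feature_indices)
    if not cols or min(cols) < 0 or max(cols) >= N_FEATURES:
        raise ValueError(f"feature indices must lie in 0..{N_FEATURES - 1}")
    X_train, y_train = train
    X_test, y_test = test
    model = _fit_lr(X_train[:, cols], y_train)
    pred = (model.predict_proba(X_test[:, cols])[:, 1] >= 0.5).astype(int)
    return float(np.mean(pred == y_test))


def forward_select(
    vectors: list[FeatureVector],
    spec: SplitSpec,
    max_features: int = 10,
    candidates: list[int] | None = None,
) -> SelectionTrace:
    """Greedy forward selection over the 24 features.

    Returns the trace of (set, accuracy) rows for set sizes 2..max_features
    (the greedy chain internally starts from the best singleton).
    """
    X, y = feature_matrix(vectors)
    train_idx, test_idx = split_indices(y, spec)
    train = (X[train_idx], y[train_idx])
    test = (X[test_idx], y[test_idx])

    pool = list(range(N_FEATURES)) if candidates is None else sorted(candidates)
    if len(pool) < 2:
        raise ValueError("need at least 2 candidate features")
    max_features = min(max_features, len(pool))

    selected: list[int] = []
    trace = SelectionTrace()
    while len(selected) < max_features:
        best_feat, best_acc = None, -1.0
        for f in pool:
            if f in selected:
                continue
            acc = lr_accuracy(selected + [f], train, test)
            if acc > best_acc:  # ties keep the lowest index (pool is sorted)
                best_feat, best_acc = f, acc
        selected.append(best_feat)
        if len(selected) >= 2:
            trace.rows.append((tuple(sorted(selected)), best_acc))
    best_row = max(trace.rows, key=lambda r: r[1])
    for feats, acc in trace.rows:  # first set attaining the maximum
        if acc == best_row[1]:
            trace.best_k = len(feats)
            break
    return trace
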