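"""Comparison baselines: k-nearest-neighbour and kernel SVM.

These operate directly on the normalized 1024-wide ISI vectors and delegate
to scikit-learn; they are reference points for the learned-feature pipeline,
not part of it.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = ["knn_baseline", "svm_baseline"]


def knn_baseline(train_X, train_y, test_X, k_neighbors: int = 5) -> np.ndarray:
    """Euclidean majority-vote KNN (ties resolve to the smallest label)."""
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    clf = KNeighborsClassifier(n_neighbors=k_neighbors, metric="euclidean")
    clf.fit(np.atleast_2d(train_X), np.asarray(train_y))
    return clf.predict(np.atleast_2d(test_X))


def svm_baseline(train_X, train_y, test_X, kernel: str = "rbf",
                 C: float = 1.0) -> np.ndarray:
    """Soft-margin kernel SVM (one-vs-rest decision shape)."""
    clf = SVC(kernel=kernel, C=C, decision_function_shape="ovr")
    clf.fit(np.atleast_2d(train_X), np.asarray(train_y))
    return clf.predict(np.atleast_2d(test_X))
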