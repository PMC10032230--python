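"""In-distribution exercise classification and grouping-level mapping.

Three classifier families:

* random forest on engineered features or FCN embeddings (100 trees, Gini
  splits, sqrt-of-features candidates, bootstrap — pinned explicitly so
  behaviour is reproducible);
* the FCN itself, trained end-to-end on raw windows (see
  :mod:`rehabsense.fcn`);
* a patient-specific k-nearest-neighbour classifier fitted on one
  patient's support session (k = 3, Euclidean), predicting the majority
  class of the neighbours with a three-way tie resolved by the single
  nearest neighbour.

Labels can be coarsened before training with :func:`apply_grouping`, which
maps exercise names onto the motion-grouping hierarchy of the taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .taxonomy import Taxonomy


def apply_grouping(labels, taxonomy: Taxonomy, level: str) -> np.ndarray:
    """Map exercise-level labels onto a grouping level (OOD passes through)."""
    return np.array([taxonomy.map_label(lbl, level) for lbl in np.asarray(labels, dtype=object)], dtype=object)


@dataclass
class RandomForestModel:
    """Fitted random forest with explicit class order."""

    classes: list[str]
    grouping_level: str = "exercise"
    _rf: RandomForestClassifier = field(default=None, repr=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._rf.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes, dtype=object)[proba.argmax(axis=1)]


def fit_random_forest(
    X: np.ndarray, y, seed: int = 0, grouping_level: str = "exercise"
) -> RandomForestModel:
    """100-tree Gini random forest with sqrt-of-features splits and bootstrap."""
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError(f"random forest requires >= 2 classes, got {classes}")
    rf = RandomForestClassifier(
        n_estimators=100,
        criterion="gini",
        max_features="sqrt",
        max_depth=None,
        bootstrap=True,
        random_state=seed,
    ).fit(np.asarray(X, dtype=float), y.astype(str))
    order = [list(rf.classes_).index(c) for c in classes]
    model = RandomForestModel(classes=classes, grouping_level=grouping_level)
    model._rf = _ReorderedForest(rf, order)
    return model


class _ReorderedForest:
    """Presents a fitted forest's probabilities in a fixed class order."""

    def __init__(self, rf: RandomForestClassifier, order: list[int]):
        self.rf, self.order = rf, order

    def predict_proba(self, X):
        return self.rf.predict_proba(X)[:, self.order]


@dataclass
class PatientKNNClassifier:
    """Majority-vote KNN over one patient's support session.

    Ties among the k neighbours fall back to the class of the single
    nearest neighbour, which is deterministic and distance-consistent.
    """

    k: int = 3
    classes: list[str] = field(default_factory=list)
    grouping_level: str = "exercise"
    _nn: NearestNeighbors = field(default=None, repr=False)
    _labels: np.ndarray = field(default=None, repr=False)

    def fit(self, support_X: np.ndarray, support_y) -> "PatientKNNClassifier":
        support_X = np.asarray(support_X, dtype=float)
        if support_X.ndim != 2 or len(support_X) == 0:
            raise ValueError("empty support set; record must be excluded upstream")
        self._labels = np.asarray(support_y, dtype=object)
        self.classes = sorted(set(self._labels.tolist()))
        self._nn = NearestNeighbors(n_neighbors=min(self.k, len(support_X))).fit(support_X)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._nn is None:
            raise RuntimeError("patient KNN classifier not fitted")
        _, idx = self._nn.kneighbors(np.asarray(X, dtype=float))
        out = np.empty(len(idx), dtype=object)
        for i, nbrs in enumerate(idx):
            votes: dict[str, int] = {}
            for j in nbrs:
                votes[self._labels[j]] = votes.get(self._labels[j], 0) + 1
            best = max(votes.values())
            winners = [c for c, v in votes.items() if v == best]
            if len(winners) == 1:
                out[i] = winners[0]
            else:
                out[i] = self._labels[nbrs[0]]  # nearest-neighbour tie-break
        return out
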