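"""Out-of-distribution scoring and sensitivity-constrained calibration.

All detectors share one convention: ``score`` measures OOD-ness (higher =
more likely non-exercise) and a window is kept as exercise iff its score is
at or below the calibrated threshold τ. Exercise is the positive class, so
sensitivity is the fraction of true-exercise windows kept.

Five detector families are provided:

* ``kmeans`` — unsupervised; distance to the nearest KMeans centroid
  fitted on in-distribution training features;
* ``softmax`` — 1 − max softmax probability of an FCN trained on
  in-distribution classes only;
* ``patient_knn`` — mean Euclidean distance to the k = 3 nearest rows of a
  patient's support session (their most recent supervised session);
* ``proxy`` (random-forest or FCN base) — a proxy non-exercise class,
  size-matched to the in-distribution data, is added as an extra training
  class, turning OOD detection into supervised classification; score is
  the predicted probability of the proxy class;
* ``proxy_patient_knn`` — support augmented with proxy rows; score is the
  fraction of the k nearest neighbours that are proxy.

Thresholds are selected to maximise specificity subject to a minimum
sensitivity of 0.90 on exercise-only calibration scores: τ is the smallest
observed score covering at least the target fraction of calibration
windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .fcn import FCNModel
from .preprocess import WindowSet
from .taxonomy import OOD_LABEL

logger = logging.getLogger(__name__)

SENSITIVITY_TARGET = 0.90
K_NEIGHBORS = 3


def calibrate_threshold(scores_exercise: np.ndarray, sensitivity_target: float = SENSITIVITY_TARGET) -> float:
    """Smallest observed score whose coverage of the calibration exercise
    scores meets the sensitivity target.

    The prediction rule is "exercise iff score ≤ τ", so picking the
    smallest adequate τ maximises specificity subject to the sensitivity
    constraint, and the achieved calibration sensitivity is ≥ target by
    construction.
    """
    s = np.sort(np.asarray(scores_exercise, dtype=float))
    if s.size == 0:
        raise ValueError("cannot calibrate a threshold on empty scores")
    if not 0 < sensitivity_target <= 1:
        raise ValueError(f"sensitivity target {sensitivity_target} outside (0, 1]")
    k = math.ceil(sensitivity_target * s.size)
    return float(s[k - 1])


@dataclass
class Detector:
    """Base OOD scorer with a lazily calibrated threshold."""

    kind: str = "base"
    threshold: float | None = None
    sensitivity_target: float = SENSITIVITY_TARGET
    calibration_info: dict = field(default_factory=dict)

    def score(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def calibrate(self, calibration_scores: np.ndarray) -> float:
        """Fix τ from scores of known-exercise calibration windows."""
        tau = calibrate_threshold(calibration_scores, self.sensitivity_target)
        self.threshold = tau
        achieved = float(np.mean(np.asarray(calibration_scores) <= tau))
        self.calibration_info = {
            "n_calibration": int(np.size(calibration_scores)),
            "achieved_sensitivity": achieved,
        }
        return tau

    def detect(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (scores, keep-mask); requires a calibrated threshold."""
        scores = self.score(X)
        if self.threshold is None:
            raise RuntimeError(f"{self.kind}: threshold not calibrated")
        return scores, scores <= self.threshold


@dataclass
class KMeansDetector(Detector):
    kind: str = "kmeans"
    n_clusters: int = 8
    seed: int = 0
    _km: KMeans | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray) -> "KMeansDetector":
        X = np.asarray(X, dtype=float)
        if not 1 <= self.n_clusters <= len(X):
            raise ValueError(
                f"n_clusters={self.n_clusters} invalid for {len(X)} training rows"
            )
        self._km = KMeans(
            n_clusters=self.n_clusters, n_init=10, random_state=self.seed
        ).fit(X)
        return self

    @property
    def centroids(self) -> np.ndarray:
        return self._km.cluster_centers_

    def score(self, X) -> np.ndarray:
        if self._km is None:
            raise RuntimeError("KMeans detector not fitted")
        d = self._km.transform(np.asarray(X, dtype=float))
        return d.min(axis=1)


@dataclass
class SoftmaxDetector(Detector):
    """1 − max softmax confidence of an in-distribution FCN."""

    kind: str = "softmax"
    model: FCNModel | None = field(default=None, repr=False)

    def score(self, X) -> np.ndarray:
        if self.model is None or not self.model.fitted:
            raise RuntimeError("softmax detector requires a fitted FCN")
        proba = self.model.predict_proba(X)
        return 1.0 - proba.max(axis=1)


@dataclass
class PatientKNNDetector(Detector):
    """Mean distance to the k nearest support rows of one patient."""

    kind: str = "patient_knn"
    k: int = K_NEIGHBORS
    _nn: NearestNeighbors | None = field(default=None, repr=False)
    _support: np.ndarray | None = field(default=None, repr=False)

    def fit(self, support: np.ndarray) -> "PatientKNNDetector":
        support = np.asarray(support, dtype=float)
        if support.ndim != 2 or len(support) == 0:
            raise ValueError("empty support set; record must be excluded upstream")
        if len(support) < self.k:
            logger.warning(
                "support has only %d rows (< k=%d); using all of them",
                len(support),
                self.k,
            )
        self._support = support
        self._nn = NearestNeighbors(n_neighbors=min(self.k, len(support))).fit(support)
        return self

    def score(self, X) -> np.ndarray:
        if self._nn is None:
            raise RuntimeError("patient KNN detector not fitted")
        dist, _ = self._nn.kneighbors(np.asarray(X, dtype=float))
        return dist.mean(axis=1)

    def leave_one_out_scores(self) -> np.ndarray:
        """Score each support row against the rest of the support.

        Used for patient-specific calibration: scoring support rows against
        the full support would include each row's zero self-distance and
        bias τ low.
        """
        support = self._support
        n = len(support)
        if n < 2:
            return np.zeros(1)
        k = min(self.k, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(support)
        dist, _ = nn.kneighbors(support)
        return dist[:, 1:].mean(axis=1)  # drop the zero self-distance


@dataclass
class ProxyDetector(Detector):
    """Supervised OOD detection via an explicit proxy non-exercise class.

    ``base`` selects the classifier: "random_forest" or "fcn" score with
    the predicted probability of the proxy class (multi-class probabilities
    collapsed by summing the exercise classes); "patient_knn" scores with
    the fraction of the k nearest support rows that are proxy.
    """

    kind: str = "proxy"
    base: str = "random_forest"
    k: int = K_NEIGHBORS
    _clf: object = field(default=None, repr=False)
    _ood_index: int | None = field(default=None, repr=False)
    _nn: NearestNeighbors | None = field(default=None, repr=False)
    _support_is_proxy: np.ndarray | None = field(default=None, repr=False)
    _oob_exercise_scores: np.ndarray | None = field(default=None, repr=False)

    def oob_exercise_scores(self) -> np.ndarray:
        """Out-of-bag proxy-class probabilities of the training exercise rows.

        Honest calibration scores for the random-forest base: each row is
        scored only by trees that never saw it, avoiding the near-zero
        resubstitution scores that would drive the threshold degenerately
        low.
        """
        if self._oob_exercise_scores is None or not len(self._oob_exercise_scores):
            raise RuntimeError("out-of-bag scores only available for a fitted random-forest base")
        return self._oob_exercise_scores

    def fit(self, X, y, seed: int = 0) -> "ProxyDetector":
        y = np.asarray(y, dtype=object)
        if OOD_LABEL not in y:
            raise ValueError("proxy detector requires rows labelled with the proxy class")
        if self.base == "patient_knn":
            X = np.asarray(X, dtype=float)
            self._support_is_proxy = y == OOD_LABEL
            self._nn = NearestNeighbors(n_neighbors=min(self.k, len(X))).fit(X)
            return self
        if self.base == "random_forest":
            from sklearn.ensemble import RandomForestClassifier

            # explicit hyperparameters (100 trees, Gini, sqrt features,
            # bootstrap); OOB kept so calibration can use honest
            # training-split scores instead of resubstitution
            rf = RandomForestClassifier(
                n_estimators=100,
                criterion="gini",
                max_features="sqrt",
                max_depth=None,
                bootstrap=True,
                oob_score=True,
                random_state=seed,
            ).fit(np.asarray(X, dtype=float), y.astype(str))
            self._clf = rf
            self._ood_index = list(rf.classes_).index(OOD_LABEL)
            oob = rf.oob_decision_function_[:, self._ood_index]
            keep = (y != OOD_LABEL) & np.isfinite(oob)
            self._oob_exercise_scores = oob[keep]
            return self
        if self.base == "fcn":
            if not isinstance(X, FCNModel):
                raise TypeError(
                    "base='fcn' expects a fitted FCNModel trained with the proxy class"
                )
            if OOD_LABEL not in X.classes:
                raise ValueError("FCN was not trained with the proxy class")
            self._clf = X
            self._ood_index = X.classes.index(OOD_LABEL)
            return self
        raise ValueError(f"unknown proxy base {self.base!r}")

    def score(self, X) -> np.ndarray:
        if self.base == "patient_knn":
            if self._nn is None:
                raise RuntimeError("proxy patient-KNN detector not fitted")
            _, idx = self._nn.kneighbors(np.asarray(X, dtype=float))
            return self._support_is_proxy[idx].mean(axis=1)
        if self._clf is None:
            raise RuntimeError("proxy detector not fitted")
        proba = self._clf.predict_proba(X)
        # P(proxy) = 1 − Σ exercise-class probabilities
        return proba[:, self._ood_index]


def exercise_calibration_scores(detector: Detector, X_exercise) -> np.ndarray:
    """Scores of known-exercise calibration windows for threshold selection."""
    if isinstance(detector, PatientKNNDetector) and X_exercise is None:
        return detector.leave_one_out_scores()
    return detector.score(X_exercise)
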