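"""Experiment orchestration: the method × feature × grouping grid.

Builds windows and features for a cohort once, then for each
cross-validation fold and grouping level fits the requested OOD detectors
and in-distribution classifiers, calibrates thresholds on training-split
exercise windows (patient-specific detectors calibrate on their support
session, leave-one-out), and evaluates:

* *clinic-style*: last-session test windows of held-out subjects as
  positives against size-matched proxy windows as negatives;
* *home-style*: per home record against the exact ground-truth mask,
  record-averaged (with pooled AUROC reported alongside).

Proxy subjects are split in half: one half supplies the proxy training
class, the other the clinic-style evaluation negatives, so evaluation
negatives are never seen in training. Results are emitted in long format
(method, feature, task, grouping, fold, metric, value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fcn as fcn_mod
from .classify import PatientKNNClassifier, apply_grouping, fit_random_forest
from .evaluation import (
    CVPlan,
    assert_no_leakage,
    auroc,
    binary_metrics,
    evaluate_record,
    make_cv_plan,
)
from .features import FeatureScaler, engineered_features
from .ood import (
    KMeansDetector,
    PatientKNNDetector,
    ProxyDetector,
    SoftmaxDetector,
)
from .preprocess import PreprocessConfig, WindowSet, preprocess_record
from .records import Manifest
from .synthetic import SyntheticCohort
from .taxonomy import DEFAULT_TAXONOMY, GROUPING_LEVELS, OOD_LABEL, Taxonomy

logger = logging.getLogger(__name__)

DETECTOR_KINDS = (
    "kmeans_engineered",
    "kmeans_embedding",
    "softmax_threshold",
    "patient_knn_engineered",
    "patient_knn_embedding",
    "proxy_rf_engineered",
    "proxy_rf_embedding",
    "proxy_fcn",
    "proxy_patient_knn",
)

CLASSIFIER_KINDS = (
    "rf_engineered",
    "rf_embedding",
    "fcn_supervised",
    "patient_knn_engineered",
    "patient_knn_embedding",
)

_FCN_DETECTORS = {
    "kmeans_embedding",
    "softmax_threshold",
    "patient_knn_embedding",
    "proxy_rf_embedding",
}
_FCN_CLASSIFIERS = {"rf_embedding", "fcn_supervised", "patient_knn_embedding"}


@dataclass(frozen=True)
class ExperimentConfig:
    groupings: tuple = GROUPING_LEVELS
    detectors: tuple = DETECTOR_KINDS
    classifiers: tuple = CLASSIFIER_KINDS
    n_folds: int = 5
    sensitivity_target: float = 0.90
    standardize: bool = True
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fcn_epochs: int = 8
    fcn_learning_rate: float = 0.001
    fcn_batch_size: int = 64
    fcn_max_train_windows: int = 512
    max_embedding_fit_windows: int = 600
    max_calibration_windows: int = 600
    seed: int = 0

    def validate(self) -> None:
        bad = [k for k in self.detectors if k not in DETECTOR_KINDS]
        bad += [k for k in self.classifiers if k not in CLASSIFIER_KINDS]
        bad += [g for g in self.groupings if g not in GROUPING_LEVELS]
        if bad:
            raise ValueError(f"unknown experiment grid entries: {bad}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, < 2^31)."""
    h = 2166136261
    for byte in f"{stage}:{global_seed}".encode():
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h % (2**31 - 1)


# ---------------------------------------------------------------------------
# cohort data: windows + engineered features, computed once


@dataclass
class CohortData:
    clinic: WindowSet
    home: WindowSet
    proxy: WindowSet
    clinic_eng: np.ndarray
    home_eng: np.ndarray
    proxy_eng: np.ndarray
    manifest: Manifest
    home_true_exercise: np.ndarray  # per home window: ground-truth exercise?


def build_cohort_data(
    cohort: SyntheticCohort, pcfg: PreprocessConfig | None = None
) -> CohortData:
    """Preprocess every record of an in-memory cohort and featurize once."""
    pcfg = pcfg or PreprocessConfig()
    clinic_sets, home_sets, proxy_sets = [], [], []
    for subj in cohort.manifest.subjects:
        for sess in subj.clinic_sessions:
            for e in sess.records:
                clinic_sets.append(
                    preprocess_record(cohort.records[e.record_id], cohort.labels[e.record_id], pcfg)
                )
        for e in subj.home_records:
            home_sets.append(
                preprocess_record(cohort.records[e.record_id], cohort.labels[e.record_id], pcfg)
            )
    for e in cohort.manifest.proxy_records:
        proxy_sets.append(
            preprocess_record(cohort.records[e.record_id], cohort.labels[e.record_id], pcfg)
        )
    clinic = WindowSet.concatenate(clinic_sets)
    home = WindowSet.concatenate(home_sets)
    proxy = WindowSet.concatenate(proxy_sets)
    return CohortData(
        clinic=clinic,
        home=home,
        proxy=proxy,
        clinic_eng=engineered_features(clinic.windows),
        home_eng=engineered_features(home.windows) if len(home) else np.zeros((0, 60)),
        proxy_eng=engineered_features(proxy.windows) if len(proxy) else np.zeros((0, 60)),
        manifest=cohort.manifest,
        home_true_exercise=home.labels != OOD_LABEL if len(home) else np.zeros(0, dtype=bool),
    )


def load_cohort_data(manifest: Manifest, pcfg: PreprocessConfig | None = None) -> CohortData:
    """Build :class:`CohortData` from an on-disk cohort via its manifest."""
    from .records import InertialRecord, LabelTrack  # noqa: F401

    cohort = SyntheticCohort(config=None, manifest=manifest)
    for subj in manifest.subjects:
        groups = [(sess.session_index, "clinic", e) for sess in subj.clinic_sessions for e in sess.records]
        groups += [(None, "home", e) for e in subj.home_records]
        for sess_idx, setting, e in groups:
            cohort.records[e.record_id] = manifest.load_record(e, subj.subject_id, sess_idx, setting)
            track = manifest.load_labels(e)
            cohort.labels[e.record_id] = track if track is not None else LabelTrack(e.record_id, [])
    for e in manifest.proxy_records:
        cohort.records[e.record_id] = manifest.load_record(e, "proxy", None, "home")
        track = manifest.load_labels(e)
        cohort.labels[e.record_id] = track if track is not None else LabelTrack(e.record_id, [])
    return build_cohort_data(cohort, pcfg)


# ---------------------------------------------------------------------------
# per-fold fitted state


@dataclass
class FoldModels:
    """Everything fitted on one fold's training split at one grouping."""

    grouping: str
    scaler: FeatureScaler | None
    fcn_in: "fcn_mod.FCNModel | None" = None  # in-distribution classes only
    fcn_proxy: "fcn_mod.FCNModel | None" = None  # + proxy class
    embeddings: dict = field(default_factory=dict)  # cache: id(array-key) → emb


def _subsample(rng: np.random.Generator, n: int, cap: int) -> np.ndarray:
    if n <= cap:
        return np.arange(n)
    return np.sort(rng.choice(n, size=cap, replace=False))


class FoldRunner:
    """Fits and evaluates the method grid for one CV fold."""

    def __init__(
        self,
        data: CohortData,
        plan: CVPlan,
        fold: int,
        cfg: ExperimentConfig,
        taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    ):
        self.data = data
        self.plan = plan
        self.fold = fold
        self.cfg = cfg
        self.taxonomy = taxonomy
        self.rng = np.random.default_rng(stage_seed(cfg.seed, f"fold{fold}"))

        meta = data.clinic.meta
        test_subjects = set(plan.fold_subjects(fold))
        self.test_subjects = test_subjects
        in_train = ~meta["subject_id"].isin(test_subjects).to_numpy()
        assert_no_leakage(meta.loc[in_train, "subject_id"], plan, fold)
        is_exercise = data.clinic.labels != OOD_LABEL
        self.train_ex_idx = np.nonzero(in_train & is_exercise)[0]

        # proxy split by proxy record: first half trains, second half evaluates
        proxy_records = list(dict.fromkeys(data.proxy.meta["record_id"]))
        half = (len(proxy_records) + 1) // 2
        train_recs = set(proxy_records[:half])
        self.proxy_train_idx = np.nonzero(
            data.proxy.meta["record_id"].isin(train_recs).to_numpy()
        )[0]
        self.proxy_eval_idx = np.nonzero(
            ~data.proxy.meta["record_id"].isin(train_recs).to_numpy()
        )[0]

        self.scaler = None
        if cfg.standardize:
            self.scaler = FeatureScaler().fit(data.clinic_eng[self.train_ex_idx])
        # fixed subsamples so every detector family calibrates on the same
        # windows and embedding caches are reused across families
        self.cal_idx = self.train_ex_idx[
            _subsample(self.rng, len(self.train_ex_idx), cfg.max_calibration_windows)
        ]
        self.fit_idx = self.train_ex_idx[
            _subsample(self.rng, len(self.train_ex_idx), cfg.max_embedding_fit_windows)
        ]
        self._models: dict[str, FoldModels] = {}
        self._emb_cache: dict[tuple, np.ndarray] = {}

    # -- representations ----------------------------------------------------

    def eng(self, which: str, idx: np.ndarray) -> np.ndarray:
        X = {"clinic": self.data.clinic_eng, "home": self.data.home_eng, "proxy": self.data.proxy_eng}[which][idx]
        return self.scaler.transform(X) if self.scaler is not None else X

    def _windows(self, which: str, idx: np.ndarray) -> np.ndarray:
        ws = {"clinic": self.data.clinic, "home": self.data.home, "proxy": self.data.proxy}[which]
        return ws.windows[idx]

    def emb(self, model_key: str, grouping: str, which: str, idx: np.ndarray) -> np.ndarray:
        model = getattr(self.models(grouping), model_key)
        out = np.empty((len(idx), model.config.embedding_width))
        missing = []
        for pos, i in enumerate(idx):
            hit = self._emb_cache.get((model_key, grouping, which, int(i)))
            if hit is None:
                missing.append((pos, int(i)))
            else:
                out[pos] = hit
        if missing:
            arr = self._windows(which, np.array([i for _, i in missing]))
            new = model.extract_embeddings(arr)
            for (pos, i), row in zip(missing, new):
                self._emb_cache[(model_key, grouping, which, i)] = row
                out[pos] = row
        return out

    # -- fitted models per grouping -----------------------------------------

    def grouped_labels(self, labels: np.ndarray, grouping: str) -> np.ndarray:
        return apply_grouping(labels, self.taxonomy, grouping)

    def models(self, grouping: str) -> FoldModels:
        if grouping in self._models:
            return self._models[grouping]
        fm = FoldModels(grouping=grouping, scaler=self.scaler)
        cfg = self.cfg
        need_in = bool(_FCN_DETECTORS.intersection(cfg.detectors)) or bool(
            _FCN_CLASSIFIERS.intersection(cfg.classifiers)
        )
        need_proxy = "proxy_fcn" in cfg.detectors
        fcn_cfg = fcn_mod.FCNConfig(
            batch_size=cfg.fcn_batch_size,
            learning_rate=cfg.fcn_learning_rate,
            epochs=cfg.fcn_epochs,
            seed=stage_seed(cfg.seed, f"fcn-{self.fold}-{grouping}"),
        )
        if need_in:
            idx = self.train_ex_idx[
                _subsample(self.rng, len(self.train_ex_idx), cfg.fcn_max_train_windows)
            ]
            labels = self.grouped_labels(self.data.clinic.labels[idx], grouping)
            fm.fcn_in = fcn_mod.train_fcn(self._windows("clinic", idx), labels, fcn_cfg)
        if need_proxy:
            n_in = min(len(self.train_ex_idx), cfg.fcn_max_train_windows // 2)
            idx_in = self.train_ex_idx[_subsample(self.rng, len(self.train_ex_idx), n_in)]
            idx_px = self.proxy_train_idx[
                _subsample(self.rng, len(self.proxy_train_idx), n_in)
            ]
            windows = np.concatenate(
                [self._windows("clinic", idx_in), self._windows("proxy", idx_px)]
            )
            labels = np.concatenate(
                [
                    self.grouped_labels(self.data.clinic.labels[idx_in], grouping),
                    np.full(len(idx_px), OOD_LABEL, dtype=object),
                ]
            )
            fm.fcn_proxy = fcn_mod.train_fcn(
                windows, labels, replace(fcn_cfg, seed=fcn_cfg.seed + 1)
            )
        self._models[grouping] = fm
        return fm

    # -- detectors -----------------------------------------------------------

    def _proxy_train_matched(self, n_match: int) -> np.ndarray:
        """Proxy training rows size-matched to the in-distribution count."""
        idx = self.proxy_train_idx
        if len(idx) >= n_match:
            return idx[_subsample(self.rng, len(idx), n_match)]
        extra = self.rng.choice(idx, size=n_match - len(idx), replace=True)
        return np.concatenate([idx, extra])

    def fit_detector(self, kind: str, grouping: str):
        """Fit + calibrate one detector family.

        Returns either a single pooled detector or, for patient-specific
        kinds, a dict subject_id → detector (subjects without a support
        session are absent).
        """
        cfg = self.cfg
        target = cfg.sensitivity_target
        cal_idx = self.cal_idx
        n_classes = len(
            set(self.grouped_labels(self.data.clinic.labels[self.train_ex_idx], grouping))
        )
        if kind == "kmeans_engineered":
            det = KMeansDetector(
                n_clusters=n_classes,
                seed=stage_seed(cfg.seed, f"km-{self.fold}-{grouping}"),
                sensitivity_target=target,
            )
            det.fit(self.eng("clinic", self.train_ex_idx))
            det.calibrate(det.score(self.eng("clinic", cal_idx)))
            return det
        if kind == "kmeans_embedding":
            det = KMeansDetector(
                kind="kmeans_embedding",
                n_clusters=n_classes,
                seed=stage_seed(cfg.seed, f"kme-{self.fold}-{grouping}"),
                sensitivity_target=target,
            )
            det.fit(self.emb("fcn_in", grouping, "clinic", self.fit_idx))
            det.calibrate(det.score(self.emb("fcn_in", grouping, "clinic", cal_idx)))
            return det
        if kind == "softmax_threshold":
            det = SoftmaxDetector(model=self.models(grouping).fcn_in, sensitivity_target=target)
            det.calibrate(det.score(self._windows("clinic", cal_idx)))
            return det
        if kind in ("patient_knn_engineered", "patient_knn_embedding"):
            out = {}
            for sp in self.plan.folds[self.fold]:
                sup_idx = self._support_indices(sp)
                if sup_idx is None:
                    continue
                X = (
                    self.eng("clinic", sup_idx)
                    if kind.endswith("engineered")
                    else self.emb("fcn_in", grouping, "clinic", sup_idx)
                )
                det = PatientKNNDetector(kind=kind, sensitivity_target=target)
                det.fit(X)
                det.calibrate(det.leave_one_out_scores())
                out[sp.subject_id] = det
            return out
        if kind in ("proxy_rf_engineered", "proxy_rf_embedding"):
            feats = "engineered" if kind.endswith("engineered") else "embedding"
            in_idx = self.train_ex_idx if feats == "engineered" else self.fit_idx
            px_idx = self._proxy_train_matched(len(in_idx))
            if feats == "engineered":
                X_in = self.eng("clinic", in_idx)
                X_px = self.eng("proxy", px_idx)
                X_cal = self.eng("clinic", cal_idx)
            else:
                X_in = self.emb("fcn_in", grouping, "clinic", in_idx)
                X_px = self.emb("fcn_in", grouping, "proxy", px_idx)
                X_cal = self.emb("fcn_in", grouping, "clinic", cal_idx)
            y = np.concatenate(
                [
                    self.grouped_labels(self.data.clinic.labels[in_idx], grouping),
                    np.full(len(px_idx), OOD_LABEL, dtype=object),
                ]
            )
            det = ProxyDetector(kind=kind, base="random_forest", sensitivity_target=target)
            det.fit(
                np.concatenate([X_in, X_px]), y, seed=stage_seed(cfg.seed, f"prf-{self.fold}-{grouping}")
            )
            try:
                det.calibrate(det.oob_exercise_scores())
            except RuntimeError:  # degenerate OOB (tiny training set)
                det.calibrate(det.score(X_cal))
            return det
        if kind == "proxy_fcn":
            det = ProxyDetector(kind=kind, base="fcn", sensitivity_target=target)
            det.fit(self.models(grouping).fcn_proxy, np.array([OOD_LABEL]))
            det.calibrate(det.score(self._windows("clinic", cal_idx)))
            return det
        if kind == "proxy_patient_knn":
            out = {}
            for sp in self.plan.folds[self.fold]:
                sup_idx = self._support_indices(sp)
                if sup_idx is None:
                    continue
                px_idx = self._proxy_train_matched(len(sup_idx))
                X_sup = self.eng("clinic", sup_idx)
                X_px = self.eng("proxy", px_idx)
                y = np.concatenate(
                    [
                        np.full(len(sup_idx), "exercise", dtype=object),
                        np.full(len(px_idx), OOD_LABEL, dtype=object),
                    ]
                )
                det = ProxyDetector(kind=kind, base="patient_knn", sensitivity_target=target)
                det.fit(np.concatenate([X_sup, X_px]), y)
                det.calibrate(det.score(X_sup))
                out[sp.subject_id] = det
            return out
        raise ValueError(f"unknown detector kind {kind!r}")

    def _support_indices(self, sp) -> np.ndarray | None:
        """Exercise-window indices of a subject's support session."""
        if sp.support_session is None or not sp.support_records:
            return None
        meta = self.data.clinic.meta
        rec_ids = {e.record_id for e in sp.support_records}
        mask = (
            meta["record_id"].isin(rec_ids).to_numpy()
            & (self.data.clinic.labels != OOD_LABEL)
        )
        idx = np.nonzero(mask)[0]
        return idx if len(idx) else None

    def _test_indices(self, sp) -> np.ndarray:
        meta = self.data.clinic.meta
        rec_ids = {e.record_id for e in sp.test_records}
        mask = (
            meta["record_id"].isin(rec_ids).to_numpy()
            & (self.data.clinic.labels != OOD_LABEL)
        )
        return np.nonzero(mask)[0]

    def detector_inputs(self, kind: str, grouping: str, which: str, idx: np.ndarray):
        if kind in ("softmax_threshold", "proxy_fcn"):
            return self._windows(which, idx)
        if kind.endswith("embedding"):
            return self.emb("fcn_in", grouping, which, idx)
        return self.eng(which, idx)

    # -- evaluation ----------------------------------------------------------

    def evaluate_detector_clinic(self, kind: str, grouping: str, fitted) -> list[dict]:
        """Clinic-style: per test subject, exercise positives vs proxy negatives."""
        rows = []
        per_subject = {m: [] for m in ("auroc", "f1", "sensitivity", "specificity", "accuracy")}
        eval_pool = self.proxy_eval_idx
        for sp in self.plan.folds[self.fold]:
            det = fitted.get(sp.subject_id) if isinstance(fitted, dict) else fitted
            if det is None:
                continue
            pos_idx = self._test_indices(sp)
            if len(pos_idx) == 0:
                continue
            neg_idx = eval_pool[_subsample(self.rng, len(eval_pool), len(pos_idx))]
            X_pos = self.detector_inputs(kind, grouping, "clinic", pos_idx)
            X_neg = self.detector_inputs(kind, grouping, "proxy", neg_idx)
            scores = np.concatenate([det.score(X_pos), det.score(X_neg)])
            truth = np.concatenate(
                [np.ones(len(pos_idx), dtype=bool), np.zeros(len(neg_idx), dtype=bool)]
            )
            keep = scores <= det.threshold
            m = binary_metrics(keep, truth)
            m["auroc"] = auroc(-scores, truth)
            for name, val in m.items():
                per_subject[name].append(val)
        for metric, vals in per_subject.items():
            vals = [v for v in vals if not np.isnan(v)]
            if vals:
                rows.append(
                    {
                        "method": kind,
                        "task": "ood_clinic",
                        "grouping": grouping,
                        "fold": self.fold,
                        "metric": metric,
                        "value": float(np.mean(vals)),
                    }
                )
        return rows

    def evaluate_detector_home(self, kind: str, grouping: str, fitted) -> list[dict]:
        """Home-style: per-record metrics vs ground-truth masks, then averaged."""
        rows = []
        meta = self.data.home.meta
        per_record = {m: [] for m in ("auroc", "f1", "sensitivity", "specificity", "accuracy")}
        pooled_scores, pooled_truth = [], []
        for sp in self.plan.folds[self.fold]:
            det = fitted.get(sp.subject_id) if isinstance(fitted, dict) else fitted
            if det is None:
                continue
            subj_mask = meta["subject_id"].to_numpy() == sp.subject_id
            for rid in dict.fromkeys(meta.loc[subj_mask, "record_id"]):
                idx = np.nonzero((meta["record_id"] == rid).to_numpy())[0]
                X = self.detector_inputs(kind, grouping, "home", idx)
                scores, keep = det.detect(X)
                truth = self.data.home_true_exercise[idx]
                m = evaluate_record(scores, keep, truth)
                for name, val in m.items():
                    if not np.isnan(val):
                        per_record[name].append(val)
                pooled_scores.append(scores)
                pooled_truth.append(truth)
        for metric, vals in per_record.items():
            if vals:
                rows.append(
                    {
                        "method": kind,
                        "task": "ood_home",
                        "grouping": grouping,
                        "fold": self.fold,
                        "metric": metric,
                        "value": float(np.mean(vals)),
                    }
                )
        if pooled_scores:
            scores = np.concatenate(pooled_scores)
            truth = np.concatenate(pooled_truth)
            if truth.any() and (~truth).any():
                rows.append(
                    {
                        "method": kind,
                        "task": "ood_home_pooled",
                        "grouping": grouping,
                        "fold": self.fold,
                        "metric": "auroc",
                        "value": auroc(-scores, truth),
                    }
                )
        return rows

    def fit_classifier(self, kind: str, grouping: str):
        y_tr = self.grouped_labels(self.data.clinic.labels[self.train_ex_idx], grouping)
        seed = stage_seed(self.cfg.seed, f"clf-{kind}-{self.fold}-{grouping}")
        if kind == "rf_engineered":
            return fit_random_forest(
                self.eng("clinic", self.train_ex_idx), y_tr, seed=seed, grouping_level=grouping
            )
        if kind == "rf_embedding":
            y_fit = self.grouped_labels(self.data.clinic.labels[self.fit_idx], grouping)
            return fit_random_forest(
                self.emb("fcn_in", grouping, "clinic", self.fit_idx),
                y_fit,
                seed=seed,
                grouping_level=grouping,
            )
        if kind == "fcn_supervised":
            return self.models(grouping).fcn_in
        if kind in ("patient_knn_engineered", "patient_knn_embedding"):
            out = {}
            for sp in self.plan.folds[self.fold]:
                sup_idx = self._support_indices(sp)
                if sup_idx is None:
                    continue
                X = (
                    self.eng("clinic", sup_idx)
                    if kind.endswith("engineered")
                    else self.emb("fcn_in", grouping, "clinic", sup_idx)
                )
                y = self.grouped_labels(self.data.clinic.labels[sup_idx], grouping)
                out[sp.subject_id] = PatientKNNClassifier(grouping_level=grouping).fit(X, y)
            return out
        raise ValueError(f"unknown classifier kind {kind!r}")

    def classifier_inputs(self, kind: str, grouping: str, which: str, idx: np.ndarray):
        if kind == "fcn_supervised":
            return self._windows(which, idx)
        if kind.endswith("embedding"):
            return self.emb("fcn_in", grouping, which, idx)
        return self.eng(which, idx)

    def evaluate_classifier(self, kind: str, grouping: str, fitted) -> list[dict]:
        accs = []
        exercise_preds = {}  # subject → (pred, true) at exercise level, for coarsening
        for sp in self.plan.folds[self.fold]:
            clf = fitted.get(sp.subject_id) if isinstance(fitted, dict) else fitted
            if clf is None:
                continue
            idx = self._test_indices(sp)
            if len(idx) == 0:
                continue
            X = self.classifier_inputs(kind, grouping, "clinic", idx)
            pred = np.asarray(clf.predict(X), dtype=object)
            true = self.grouped_labels(self.data.clinic.labels[idx], grouping)
            accs.append(float(np.mean(pred == true)))
            if grouping == "exercise":
                exercise_preds[sp.subject_id] = (pred, self.data.clinic.labels[idx])
        rows = []
        if accs:
            rows.append(
                {
                    "method": kind,
                    "task": "classification",
                    "grouping": grouping,
                    "fold": self.fold,
                    "metric": "accuracy",
                    "value": float(np.mean(accs)),
                }
            )
        # coarsening theorem: mapped exercise-level predictions can never be
        # less accurate than the exercise-level predictions themselves
        for pred, true in exercise_preds.values():
            base = np.mean(pred == true)
            for level in GROUPING_LEVELS:
                mapped = np.mean(
                    self.grouped_labels(pred, level) == self.grouped_labels(true, level)
                )
                if mapped < base - 1e-12:
                    raise AssertionError(
                        f"coarsening violated: {level} accuracy {mapped:.4f} < "
                        f"exercise accuracy {base:.4f}"
                    )
        return rows

    def run(self) -> pd.DataFrame:
        rows = []
        for grouping in self.cfg.groupings:
            for kind in self.cfg.detectors:
                try:
                    fitted = self.fit_detector(kind, grouping)
                    rows += self.evaluate_detector_clinic(kind, grouping, fitted)
                    if len(self.data.home):
                        rows += self.evaluate_detector_home(kind, grouping, fitted)
                except Exception:  # one method must not abort the others
                    logger.exception("detector %s/%s failed on fold %d", kind, grouping, self.fold)
            for kind in self.cfg.classifiers:
                try:
                    fitted = self.fit_classifier(kind, grouping)
                    rows += self.evaluate_classifier(kind, grouping, fitted)
                except Exception:
                    logger.exception("classifier %s/%s failed on fold %d", kind, grouping, self.fold)
        return pd.DataFrame(rows)


def run_experiment(
    data: CohortData,
    cfg: ExperimentConfig,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> pd.DataFrame:
    """Run the full grid over all folds; returns the long-format results."""
    cfg.validate()
    plan = make_cv_plan(data.manifest, n_folds=cfg.n_folds, seed=stage_seed(cfg.seed, "cv"))
    frames = []
    for fold in range(cfg.n_folds):
        runner = FoldRunner(data, plan, fold, cfg, taxonomy)
        frames.append(runner.run())
        logger.info("fold %d done", fold)
    out = pd.concat(frames, ignore_index=True)
    return out
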