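"""Subject-wise cross-validation, exclusion rules, and metrics.

Evaluation follows a five-fold cross-validation split **by subject**: all
records of a subject land in exactly one test fold, and no window from a
test-fold subject ever enters training. Within each test subject, the most
recent supervised session is the test set and the second-to-last session is
the patient-specific *support* set. Test records whose class has no
supporting data in an earlier session of the same subject are excluded —
for every method, so all methods see identical test sets.

Metrics: rank-based AUROC (ties count 0.5), F1, sensitivity, specificity,
and accuracy; exercise is the positive class. Records containing no true
exercise contribute specificity only. Fold aggregation reports the mean and
the standard error SD(fold means)/√n_folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .records import Manifest, RecordEntry
from .taxonomy import OOD_LABEL

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class SubjectPlan:
    subject_id: str
    test_session: int
    support_session: int | None  # None → excluded from patient-specific methods
    test_records: list[RecordEntry] = field(default_factory=list)
    support_records: list[RecordEntry] = field(default_factory=list)
    home_records: list[RecordEntry] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (record_id, reason)


@dataclass
class CVPlan:
    n_folds: int
    seed: int
    folds: list[list[SubjectPlan]] = field(default_factory=list)

    def fold_subjects(self, fold: int) -> list[str]:
        return [sp.subject_id for sp in self.folds[fold]]

    def train_subjects(self, fold: int) -> list[str]:
        test = set(self.fold_subjects(fold))
        return [
            sp.subject_id
            for f, plans in enumerate(self.folds)
            for sp in plans
            if sp.subject_id not in test and f != fold
        ]


def make_cv_plan(manifest: Manifest, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Partition subjects into folds and resolve test/support sessions.

    Subjects are shuffled by the seed and dealt round-robin into folds of
    as equal size as possible. The support-exclusion rule drops any test
    record with a class unseen in that subject's earlier sessions.
    """
    subjects = manifest.subjects
    if len(subjects) < n_folds:
        raise ValueError(f"{len(subjects)} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds: list[list[SubjectPlan]] = [[] for _ in range(n_folds)]
    for pos, si in enumerate(order):
        subj = subjects[si]
        if not subj.clinic_sessions:
            logger.warning("subject %s has no clinic sessions; skipped", subj.subject_id)
            continue
        sessions = sorted(subj.clinic_sessions, key=lambda s: s.session_index)
        test_sess = sessions[-1]
        support_sess = sessions[-2] if len(sessions) >= 2 else None
        if support_sess is None:
            logger.info(
                "subject %s has < 2 sessions; excluded from patient-specific methods",
                subj.subject_id,
            )
        earlier_classes = {
            c for sess in sessions[:-1] for e in sess.records for c in e.classes
        }
        test_records, excluded = [], []
        for entry in test_sess.records:
            missing = [c for c in entry.classes if c not in earlier_classes]
            if missing:
                excluded.append(
                    (entry.record_id, f"no earlier-session support for {missing}")
                )
            else:
                test_records.append(entry)
        folds[pos % n_folds].append(
            SubjectPlan(
                subject_id=subj.subject_id,
                test_session=test_sess.session_index,
                support_session=None if support_sess is None else support_sess.session_index,
                test_records=test_records,
                support_records=[] if support_sess is None else list(support_sess.records),
                home_records=list(subj.home_records),
                excluded=excluded,
            )
        )
    return CVPlan(n_folds=n_folds, seed=seed, folds=folds)


def assert_no_leakage(train_subject_ids, plan: CVPlan, fold: int) -> None:
    """Raise if any training row belongs to a subject in the given test fold."""
    test = set(plan.fold_subjects(fold))
    leaked = sorted(set(np.asarray(train_subject_ids, dtype=object)) & test)
    if leaked:
        raise AssertionError(f"training rows leak test-fold subjects: {leaked}")


# ---------------------------------------------------------------------------
# metrics


def auroc(scores, positive_mask) -> float:
    """Rank-based (Mann–Whitney) AUROC; higher score = more positive.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(positive_mask, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined without both a positive and a negative")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def binary_metrics(pred_mask, true_mask) -> dict[str, float]:
    """F1, sensitivity, specificity, accuracy for exercise-vs-not masks.

    Undefined entries (no positives / no negatives present) are NaN so
    callers can apply the record-exclusion rule explicitly.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    true = np.asarray(true_mask, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = 0.0 if np.isnan(sens) else sens
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    if tp + fn == 0:
        f1 = float("nan")
    acc = (tp + tn) / len(pred) if len(pred) else float("nan")
    return {"f1": f1, "sensitivity": sens, "specificity": spec, "accuracy": acc}


def evaluate_record(scores, keep_mask, true_exercise_mask) -> dict[str, float]:
    """Per-record detector metrics against the ground-truth exercise mask.

    ``scores`` are OOD-ness scores (negated internally for AUROC so that
    exercise is the positive class). A record with no true-exercise windows
    contributes specificity (and accuracy) only; one with no true
    non-exercise windows contributes sensitivity only.
    """
    true = np.asarray(true_exercise_mask, dtype=bool)
    out = binary_metrics(keep_mask, true)
    if true.any() and (~true).any():
        out["auroc"] = auroc(-np.asarray(scores, dtype=float), true)
    else:
        out["auroc"] = float("nan")
    return out


def aggregate_folds(per_fold: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Mean and standard error over folds, per (method, metric, …) group.

    SE = SD(fold means)/√n with population SD, matching the bracketed
    standard errors of cross-validated result tables.
    """
    group_cols = [c for c in per_fold.columns if c not in (value_col, "fold")]

    def _agg(g: pd.DataFrame) -> pd.Series:
        vals = g[value_col].astype(float).dropna().to_numpy()
        n = len(vals)
        if n == 0:
            return pd.Series({"mean": float("nan"), "se": float("nan"), "n_folds": 0})
        return pd.Series(
            {
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=0) / np.sqrt(n)),
                "n_folds": n,
            }
        )

    return per_fold.groupby(group_cols, dropna=False).apply(_agg, include_groups=False).reset_index()


def run_two_stage(detector, classifier, X_detect, X_classify) -> np.ndarray:
    """Apply the calibrated detector then label the kept windows.

    ``X_detect`` and ``X_classify`` are the detector's and classifier's
    aligned input representations for the same windows. Windows flagged
    OOD receive the reserved OOD label.
    """
    _, keep = detector.detect(X_detect)
    out = np.full(len(keep), OOD_LABEL, dtype=object)
    if keep.any():
        kept = (
            X_classify[keep]
            if isinstance(X_classify, np.ndarray)
            else X_classify.select(keep)
        )
        out[keep] = classifier.predict(kept)
    return out
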