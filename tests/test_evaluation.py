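import numpy as np
import pandas as pd
import pytest

from rehabsense.evaluation import (
    aggregate_folds,
    assert_no_leakage,
    auroc,
    binary_metrics,
    evaluate_record,
    make_cv_plan,
)
from rehabsense.records import Manifest, RecordEntry, SessionEntry, SubjectEntry


def brute_force_auroc(scores, positive):
    """All-pairs comparison: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(positive, bool)]
    neg = scores[~np.asarray(positive, bool)]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# AUROC


@pytest.mark.parametrize(
    "scores,positive,expected",
    [
        ([2, 3, 0, 1], [1, 1, 0, 0], 1.0),
        ([3, 1, 2, 0], [1, 1, 0, 0], 0.75),
        ([1, 1], [1, 0], 0.5),
    ],
)
def test_auroc_examples(scores, positive, expected):
    assert auroc(scores, positive) == pytest.approx(expected)
    assert brute_force_auroc(scores, positive) == pytest.approx(expected)


def test_auroc_matches_brute_force_with_ties(rng):
    for _ in range(30):
        n = int(rng.integers(4, 25))
        scores = rng.integers(0, 6, n).astype(float)  # heavy ties
        positive = rng.random(n) < 0.5
        if positive.all() or not positive.any():
            continue
        assert auroc(scores, positive) == pytest.approx(
            brute_force_auroc(scores, positive), abs=1e-12
        )


def test_auroc_invariant_under_monotone_transform(rng):
    scores = rng.normal(0, 1, 200)
    positive = rng.random(200) < 0.4
    base = auroc(scores, positive)
    for f in (lambda s: 3 * s + 2, np.exp, lambda s: s**3):
        assert auroc(f(scores), positive) == pytest.approx(base, abs=1e-12)


def test_auroc_single_class_errors():
    with pytest.raises(ValueError, match="undefined"):
        auroc([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# binary metrics


def test_binary_metrics_confusion_arithmetic():
    # TP=3, FP=1, FN=1, TN=5
    pred = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    true = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    m = binary_metrics(pred, true)
    assert m["sensitivity"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(5 / 6)
    assert m["f1"] == pytest.approx(0.75)
    assert m["accuracy"] == pytest.approx(0.8)


def test_binary_metrics_edges():
    perfect = binary_metrics([1, 0, 1], [1, 0, 1])
    assert all(perfect[k] == 1.0 for k in ("f1", "sensitivity", "specificity", "accuracy"))
    nothing = binary_metrics([0, 0, 0], [1, 1, 0])
    assert nothing["sensitivity"] == 0.0 and nothing["f1"] == 0.0
    with pytest.raises(ValueError, match="shapes"):
        binary_metrics([1], [1, 0])


def test_evaluate_record_exclusion_rules():
    # pure-OOD record: sensitivity/F1/AUROC undefined, specificity defined
    m = evaluate_record([0.9, 0.8], [False, False], [False, False])
    assert m["specificity"] == 1.0
    assert np.isnan(m["sensitivity"]) and np.isnan(m["f1"]) and np.isnan(m["auroc"])
    m = evaluate_record([0.1, 0.9], [True, False], [False, False])
    assert m["specificity"] == 0.5
    # mixed record, perfect detection (low score = exercise)
    m = evaluate_record([0.1, 0.9], [True, False], [True, False])
    assert m["auroc"] == 1.0 and m["f1"] == 1.0


# ---------------------------------------------------------------------------
# aggregation


def test_fold_aggregation_mean_and_se():
    df = pd.DataFrame(
        {
            "method": ["m"] * 2 + ["m"] * 2,
            "metric": ["auroc"] * 2 + ["f1"] * 2,
            "fold": [0, 1, 0, 1],
            "value": [0.8, 0.9, 0.7, 0.7],
        }
    )
    agg = aggregate_folds(df).set_index("metric")
    assert agg.loc["auroc", "mean"] == pytest.approx(0.85)
    assert agg.loc["auroc", "se"] == pytest.approx(0.05 / np.sqrt(2))
    assert agg.loc["f1", "se"] == 0.0  # identical folds


# ---------------------------------------------------------------------------
# CV planning


def _manifest(n_subjects=10, sessions_per_subject=3, classes=("A", "B")):
    subjects = []
    for s in range(n_subjects):
        subj = SubjectEntry(subject_id=f"S{s}")
        for i in range(sessions_per_subject):
            subj.clinic_sessions.append(
                SessionEntry(
                    session_index=i,
                    records=[
                        RecordEntry(f"S{s}-c{i}", f"S{s}-c{i}.csv", None, list(classes))
                    ],
                )
            )
        subjects.append(subj)
    return Manifest(subjects=subjects)


def test_cv_plan_fold_sizes_and_determinism():
    plan1 = make_cv_plan(_manifest(10), n_folds=5, seed=3)
    plan2 = make_cv_plan(_manifest(10), n_folds=5, seed=3)
    assert [len(f) for f in plan1.folds] == [2, 2, 2, 2, 2]
    assert [
        [sp.subject_id for sp in f] for f in plan1.folds
    ] == [[sp.subject_id for sp in f] for f in plan2.folds]
    # each subject appears in exactly one fold
    all_ids = [sp.subject_id for f in plan1.folds for sp in f]
    assert sorted(all_ids) == sorted(set(all_ids))


def test_cv_plan_sessions_and_support():
    plan = make_cv_plan(_manifest(5, sessions_per_subject=4), n_folds=5, seed=0)
    for fold in plan.folds:
        for sp in fold:
            assert sp.test_session == 3
            assert sp.support_session == 2


def test_support_exclusion_rule():
    m = _manifest(5, sessions_per_subject=3)
    # subject S0's last session gains a record of class Z never seen before
    m.subjects[0].clinic_sessions[-1].records.append(
        RecordEntry("S0-z", "S0-z.csv", None, ["Z"])
    )
    plan = make_cv_plan(m, n_folds=5, seed=0)
    sp = next(sp for f in plan.folds for sp in f if sp.subject_id == "S0")
    assert [rid for rid, _ in sp.excluded] == ["S0-z"]
    assert all(e.record_id != "S0-z" for e in sp.test_records)
    assert len(sp.test_records) == 1  # the supported record stays


def test_single_session_subject_excluded_from_patient_specific():
    m = _manifest(6, sessions_per_subject=2)
    m.subjects[0].clinic_sessions = m.subjects[0].clinic_sessions[:1]
    plan = make_cv_plan(m, n_folds=5, seed=0)
    sp = next(sp for f in plan.folds for sp in f if sp.subject_id == "S0")
    assert sp.support_session is None and sp.support_records == []


def test_leakage_assertion():
    plan = make_cv_plan(_manifest(10), n_folds=5, seed=1)
    test_subject = plan.fold_subjects(0)[0]
    with pytest.raises(AssertionError, match=test_subject):
        assert_no_leakage([test_subject, "S999"], plan, 0)
    assert_no_leakage(plan.train_subjects(0), plan, 0)  # clean split passes
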