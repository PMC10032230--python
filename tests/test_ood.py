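import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rehabsense.fcn import small_scale_config, train_fcn
from rehabsense.ood import (
    KMeansDetector,
    PatientKNNDetector,
    ProxyDetector,
    SoftmaxDetector,
    calibrate_threshold,
)
from rehabsense.taxonomy import OOD_LABEL


def brute_force_min_centroid_distance(X, centroids):
    return np.array(
        [min(np.sqrt(((x - c) ** 2).sum()) for c in centroids) for x in X]
    )


def brute_force_knn_mean(X, support, k):
    out = []
    for x in X:
        d = sorted(np.sqrt(((support - x) ** 2).sum(axis=1)))
        out.append(np.mean(d[: min(k, len(d))]))
    return np.array(out)


# ---------------------------------------------------------------------------
# KMeans detector


def test_kmeans_score_zero_at_centroid(rng):
    X = rng.normal(0, 1, (50, 4))
    det = KMeansDetector(n_clusters=3, seed=0).fit(X)
    assert det.score(det.centroids[:1])[0] == pytest.approx(0.0, abs=1e-9)


def test_kmeans_recovers_separated_blobs(rng):
    a = rng.normal(0, 0.05, (100, 3)) + np.array([5.0, 0.0, 0.0])
    b = rng.normal(0, 0.05, (100, 3)) + np.array([-5.0, 0.0, 0.0])
    det = KMeansDetector(n_clusters=2, seed=1).fit(np.vstack([a, b]))
    cents = det.centroids[np.argsort(det.centroids[:, 0])]
    np.testing.assert_allclose(cents[0], b.mean(axis=0), atol=0.1)
    np.testing.assert_allclose(cents[1], a.mean(axis=0), atol=0.1)


def test_kmeans_score_matches_brute_force(rng):
    X = rng.normal(0, 2, (80, 5))
    det = KMeansDetector(n_clusters=4, seed=0).fit(X)
    q = rng.normal(0, 3, (100, 5))
    np.testing.assert_allclose(
        det.score(q), brute_force_min_centroid_distance(q, det.centroids), rtol=1e-9
    )


def test_kmeans_parameter_errors(rng):
    with pytest.raises(ValueError, match="n_clusters"):
        KMeansDetector(n_clusters=0).fit(rng.normal(size=(5, 2)))
    with pytest.raises(ValueError, match="n_clusters"):
        KMeansDetector(n_clusters=9).fit(rng.normal(size=(5, 2)))


# ---------------------------------------------------------------------------
# softmax detector


def test_softmax_score_is_one_minus_confidence(rng):
    t = np.arange(64) / 50.0
    X = np.stack(
        [np.outer(np.sin(2 * np.pi * 5 * t), np.ones(6)) for _ in range(20)]
        + [np.ones((64, 6)) for _ in range(20)]
    ) + rng.normal(0, 0.05, (40, 64, 6))
    y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
    model = train_fcn(X, y, small_scale_config(epochs=5, seed=0))
    det = SoftmaxDetector(model=model)
    scores = det.score(X)
    proba = model.predict_proba(X)
    np.testing.assert_allclose(scores, 1.0 - proba.max(axis=1), atol=1e-12)
    # closed-form cases of the score rule itself
    assert 1.0 - np.max([1.0, 0.0, 0.0]) == 0.0
    assert 1.0 - np.max([0.5, 0.3, 0.2]) == 0.5


def test_softmax_unfitted_errors():
    with pytest.raises(RuntimeError, match="fitted FCN"):
        SoftmaxDetector(model=None).score(np.zeros((1, 10, 6)))


# ---------------------------------------------------------------------------
# patient-specific KNN detector


def test_patient_knn_mean_distance_example():
    support = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    det = PatientKNNDetector().fit(support)
    score = det.score(np.array([[0.0, 0.0]]))[0]
    assert score == pytest.approx((0.0 + 1.0 + 2.0) / 3.0)


def test_patient_knn_small_support_uses_all_rows(rng, caplog):
    support = rng.normal(0, 1, (2, 3))
    det = PatientKNNDetector().fit(support)
    q = rng.normal(0, 1, (5, 3))
    np.testing.assert_allclose(det.score(q), brute_force_knn_mean(q, support, 2), rtol=1e-9)


def test_patient_knn_matches_brute_force(rng):
    support = rng.normal(0, 1, (30, 6))
    det = PatientKNNDetector().fit(support)
    q = rng.normal(0, 2, (100, 6))
    np.testing.assert_allclose(det.score(q), brute_force_knn_mean(q, support, 3), rtol=1e-9)


def test_patient_knn_empty_support_errors():
    with pytest.raises(ValueError, match="empty support"):
        PatientKNNDetector().fit(np.zeros((0, 3)))


def test_leave_one_out_excludes_self(rng):
    support = rng.normal(0, 1, (10, 4))
    loo = PatientKNNDetector().fit(support).leave_one_out_scores()
    assert (loo > 0).all()  # zero self-distances removed


# ---------------------------------------------------------------------------
# proxy detectors


def test_proxy_knn_fraction_rule(rng):
    X_ex = rng.normal(0, 0.1, (10, 3))
    X_px = rng.normal(0, 0.1, (10, 3)) + 100.0
    y = np.array(["ex"] * 10 + [OOD_LABEL] * 10, dtype=object)
    det = ProxyDetector(base="patient_knn").fit(np.vstack([X_ex, X_px]), y)
    assert det.score(np.array([[100.0, 100.0, 100.0]]))[0] == 1.0
    assert det.score(np.array([[0.0, 0.0, 0.0]]))[0] == 0.0


def test_proxy_rf_separable_resubstitution(rng):
    X_ex = rng.normal(0, 0.5, (100, 4))
    X_px = rng.normal(0, 0.5, (100, 4)) + 50.0
    y = np.array(["ex"] * 100 + [OOD_LABEL] * 100, dtype=object)
    det = ProxyDetector(base="random_forest").fit(np.vstack([X_ex, X_px]), y, seed=0)
    assert det.score(X_ex).max() < 0.5
    assert det.score(X_ex).mean() == pytest.approx(0.0, abs=0.05)
    assert det.score(X_px).min() > 0.5


def test_proxy_requires_proxy_rows(rng):
    y = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
    with pytest.raises(ValueError, match="proxy"):
        ProxyDetector(base="random_forest").fit(rng.normal(size=(10, 3)), y)


# ---------------------------------------------------------------------------
# calibration


@pytest.mark.parametrize(
    "scores,target,expected",
    [
        ([0.1, 0.2, 0.3, 0.9], 0.75, 0.3),
        ([0.1, 0.2, 0.3, 0.9], 0.90, 0.9),
        ([0.5, 0.5, 0.5], 0.9, 0.5),
        ([0.5, 0.5, 0.5], 0.1, 0.5),
    ],
)
def test_calibrate_threshold_enumeration(scores, target, expected):
    tau = calibrate_threshold(np.array(scores), target)
    assert tau == pytest.approx(expected)
    # exhaustive check: tau is the smallest observed score meeting the target
    for cand in sorted(scores):
        frac = np.mean(np.array(scores) <= cand)
        if frac >= target:
            assert tau == pytest.approx(cand)
            break


def test_calibrate_threshold_errors():
    with pytest.raises(ValueError, match="empty"):
        calibrate_threshold(np.array([]))
    with pytest.raises(ValueError, match="target"):
        calibrate_threshold(np.array([1.0]), 0.0)


@given(
    scores=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
    target=st.floats(0.01, 1.0),
)
def test_calibration_sensitivity_guarantee(scores, target):
    """Achieved sensitivity on the calibration scores is always >= target."""
    tau = calibrate_threshold(np.array(scores), target)
    achieved = np.mean(np.array(scores) <= tau)
    assert achieved >= target


def test_detect_threshold_semantics(rng):
    det = PatientKNNDetector().fit(rng.normal(0, 1, (10, 3)))
    q = rng.normal(0, 1, (50, 3))
    with pytest.raises(RuntimeError, match="not calibrated"):
        det.detect(q)
    det.threshold = np.inf
    _, keep = det.detect(q)
    assert keep.all()
    det.threshold = -np.inf
    _, keep = det.detect(q)
    assert not keep.any()
    det.threshold = 1.0
    scores, keep = det.detect(q)
    np.testing.assert_array_equal(keep, scores <= 1.0)


def test_threshold_monotonicity(rng):
    """Raising tau never decreases the number of windows kept."""
    det = PatientKNNDetector().fit(rng.normal(0, 1, (10, 3)))
    q = rng.normal(0, 1, (100, 3))
    kept = []
    for tau in np.linspace(0, 3, 13):
        det.threshold = tau
        kept.append(int(det.detect(q)[1].sum()))
    assert all(a <= b for a, b in zip(kept, kept[1:]))


def test_scores_pure_on_duplicates(rng):
    det = KMeansDetector(n_clusters=2, seed=0).fit(rng.normal(size=(20, 3)))
    q = rng.normal(size=(1, 3))
    dup = np.vstack([q, q])
    s = det.score(dup)
    assert s[0] == s[1]


def test_proxy_rf_oob_calibration_scores(rng):
    """OOB calibration scores are honest: nonzero for most training rows and
    the calibrated threshold still meets the sensitivity target."""
    X_ex = rng.normal(0, 1.0, (150, 4))
    X_px = rng.normal(0, 1.0, (150, 4)) + 3.0
    y = np.array(["ex"] * 150 + [OOD_LABEL] * 150, dtype=object)
    det = ProxyDetector(base="random_forest").fit(np.vstack([X_ex, X_px]), y, seed=0)
    oob = det.oob_exercise_scores()
    assert len(oob) == 150
    assert oob.mean() > det.score(X_ex).mean()  # resubstitution is optimistic
    det.calibrate(oob)
    assert det.calibration_info["achieved_sensitivity"] >= det.sensitivity_target
    with pytest.raises(RuntimeError, match="out-of-bag"):
        ProxyDetector(base="patient_knn").oob_exercise_scores()
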