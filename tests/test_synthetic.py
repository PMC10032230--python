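import numpy as np
import pytest

from rehabsense.features import engineered_features
from rehabsense.synthetic import (
    ADL_REGIMES,
    GRAVITY,
    GeneratorConfig,
    SubjectProfile,
    generate_adl_segment,
    generate_bout,
    generate_cohort,
    make_class_templates,
    sample_rep_periods,
)
from rehabsense.taxonomy import DEFAULT_TAXONOMY, OOD_LABEL
from scipy.spatial.transform import Rotation


def test_period_distribution_moments(rng):
    p = sample_rep_periods(10_000, rng)
    assert 3.7 <= p.mean() <= 3.9
    assert p.std() == pytest.approx(2.3, rel=0.1)
    skew = np.mean((p - p.mean()) ** 3) / p.std() ** 3
    assert skew > 0  # right-skewed
    assert (p > 0).all()


def test_templates_deterministic_and_degenerate_limit():
    t1 = make_class_templates(["Resisted row", "Push up"], seed=5)
    t2 = make_class_templates(["Resisted row", "Push up"], seed=5)
    for k in t1:
        np.testing.assert_array_equal(t1[k].amp, t2[k].amp)
        np.testing.assert_array_equal(t1[k].orientation, t2[k].orientation)
    flat = make_class_templates(["Resisted row", "Push up"], seed=5, sep=0.0)
    np.testing.assert_allclose(flat["Resisted row"].amp, flat["Push up"].amp)
    np.testing.assert_allclose(
        flat["Resisted row"].orientation, flat["Push up"].orientation
    )
    with pytest.raises(ValueError, match="duplicate"):
        make_class_templates(["Resisted row", "Resisted row"])


def test_within_group_templates_more_similar_than_between():
    """Classes sharing a simple-motion group get correlated templates."""
    classes = [
        "Active shoulder flexion",  # Elevation
        "Active shoulder abduction",  # Elevation
        "Assisted shoulder external rotation",  # Rotation
        "Assisted shoulder internal rotation",  # Rotation
    ]
    within, between = [], []
    for seed in range(100):
        t = make_class_templates(classes, seed=seed)
        vecs = {c: t[c].coefficients for c in classes}
        mean = np.mean(list(vecs.values()), axis=0)
        dev = {c: v - mean for c, v in vecs.items()}

        def cos(a, b):
            return float(dev[a] @ dev[b] / (np.linalg.norm(dev[a]) * np.linalg.norm(dev[b])))

        within += [cos(classes[0], classes[1]), cos(classes[2], classes[3])]
        between += [cos(classes[0], classes[2]), cos(classes[1], classes[3])]
    assert np.mean(within) > np.mean(between)


def test_bout_gravity_only_limit():
    """No noise, no motion: accelerometer norm is exactly g."""
    cfg = GeneratorConfig(accel_noise_sd=0.0, gyro_noise_sd=0.0)
    t = make_class_templates(["Resisted row", "Push up"], seed=0)["Resisted row"]
    t.amp[:] = 0.0
    profile = SubjectProfile("S0", Rotation.identity(), 1.0, ["Resisted row"])
    sig, dur = generate_bout(t, profile, 3, np.random.default_rng(0), cfg)
    norms = np.linalg.norm(sig[:, :3], axis=1)
    np.testing.assert_allclose(norms, GRAVITY, atol=1e-9)
    np.testing.assert_allclose(sig[:, 3:], 0.0, atol=1e-9)
    assert dur == pytest.approx(len(sig) / cfg.sample_rate)


def test_bout_duration_tracks_sampled_periods(rng):
    cfg = GeneratorConfig()
    t = make_class_templates(list(cfg.classes), seed=0)[cfg.classes[0]]
    profile = SubjectProfile("S0", Rotation.identity(), 1.0, [cfg.classes[0]])
    durs = [generate_bout(t, profile, 5, rng, cfg)[1] for _ in range(200)]
    assert np.mean(durs) == pytest.approx(5 * 3.8, rel=0.1)


def test_adl_static_limit_and_determinism():
    cfg = GeneratorConfig(accel_noise_sd=0.0, gyro_noise_sd=0.0)
    sig = generate_adl_segment(0.0, 5.0, np.random.default_rng(1), cfg)
    np.testing.assert_allclose(np.linalg.norm(sig[:, :3], axis=1), GRAVITY, atol=1e-9)
    a = generate_adl_segment(0.5, 5.0, np.random.default_rng(2), cfg)
    b = generate_adl_segment(0.5, 5.0, np.random.default_rng(2), cfg)
    np.testing.assert_array_equal(a, b)


def test_adl_gyro_rms_monotone_in_intensity():
    intensities = [ADL_REGIMES["rest"], ADL_REGIMES["gesturing"], ADL_REGIMES["walking"]]
    cfg = GeneratorConfig()
    means = []
    for intensity in intensities:
        rms = [
            np.sqrt(
                (generate_adl_segment(intensity, 10.0, np.random.default_rng(s), cfg)[:, 3:] ** 2).mean()
            )
            for s in range(20)
        ]
        means.append(np.mean(rms))
    assert means[0] < means[1] < means[2]


def test_cohort_counts_and_structure():
    cfg = GeneratorConfig(
        n_subjects=6,
        n_sessions=3,
        seed=1,
        home_records_per_subject=0,
        n_proxy_subjects=2,
        proxy_minutes_per_subject=0.5,
    )
    cohort = generate_cohort(cfg)
    n_clinic = sum(
        len(s.records) for subj in cohort.manifest.subjects for s in subj.clinic_sessions
    )
    assert n_clinic == 18  # one record per subject-session
    assert len(cohort.manifest.subjects) == 6
    assert len(cohort.manifest.proxy_records) == 2
    for subj in cohort.manifest.subjects:
        assert [s.session_index for s in subj.clinic_sessions] == [0, 1, 2]
        for sess in subj.clinic_sessions:
            for e in sess.records:
                assert cohort.labels[e.record_id].classes == e.classes
                assert len(e.classes) == cfg.classes_per_subject


def test_home_record_mask_bookkeeping(small_cohort):
    """Exercise samples in the mask match the scheduled bout durations."""
    subj = small_cohort.manifest.subjects[0]
    entry = subj.home_records[0]
    record = small_cohort.records[entry.record_id]
    track = small_cohort.labels[entry.record_id]
    assert len(track.intervals) > 0
    mask = track.mask(record.timestamps)
    scheduled = sum(t1 - t0 for t0, t1, _ in track.intervals)
    measured = np.sum(mask != OOD_LABEL) / 50.0
    assert measured == pytest.approx(scheduled, abs=0.1 * len(track.intervals) + 0.5)


def test_full_determinism_under_seed():
    cfg = GeneratorConfig(
        n_subjects=2, n_sessions=2, seed=9, home_records_per_subject=1,
        home_duration=40, long_rest_duration=10, n_proxy_subjects=1,
        proxy_minutes_per_subject=0.5,
    )
    c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
    assert set(c1.records) == set(c2.records)
    for rid in c1.records:
        np.testing.assert_array_equal(c1.records[rid].timestamps, c2.records[rid].timestamps)
        np.testing.assert_array_equal(c1.records[rid].accel, c2.records[rid].accel)
        assert c1.labels[rid].intervals == c2.labels[rid].intervals


def test_written_cohort_is_identical_across_runs(tmp_path):
    cfg = GeneratorConfig(
        n_subjects=1, n_sessions=2, seed=4, home_records_per_subject=0,
        n_proxy_subjects=1, proxy_minutes_per_subject=0.5,
    )
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_cohort(cfg).write(d1)
    generate_cohort(cfg).write(d2)
    f1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    f2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
    assert f1 == f2
    for rel in f1:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()


def test_invalid_config_lists_fields():
    with pytest.raises(ValueError, match="sep"):
        GeneratorConfig(sep=-1.0)


def test_classification_separability_increases_with_class_separation():
    """Held-out simple-motion accuracy is non-decreasing in the separation
    scalar (3-point grid, averaged over 3 seeds)."""
    from rehabsense.classify import apply_grouping, fit_random_forest
    from rehabsense.pipeline import build_cohort_data

    grid = [0.15, 0.6, 1.5]
    means = []
    for sep in grid:
        accs = []
        for seed in range(3):
            cfg = GeneratorConfig(
                n_subjects=4,
                n_sessions=2,
                classes_per_subject=3,
                reps_per_bout=(3, 5),
                sep=sep,
                seed=100 + seed,
                home_records_per_subject=0,
                n_proxy_subjects=0,
            )
            data = build_cohort_data(generate_cohort(cfg))
            meta = data.clinic.meta
            ex = data.clinic.labels != OOD_LABEL
            test_subj = data.manifest.subjects[-1].subject_id
            tr = ex & (meta["subject_id"] != test_subj).to_numpy()
            te = ex & (meta["subject_id"] == test_subj).to_numpy()
            y = apply_grouping(data.clinic.labels, DEFAULT_TAXONOMY, "simple_motion")
            model = fit_random_forest(data.clinic_eng[tr], y[tr], seed=0)
            accs.append(float(np.mean(model.predict(data.clinic_eng[te]) == y[te])))
        means.append(np.mean(accs))
    assert means[0] <= means[1] + 1e-9
    assert means[1] <= means[2] + 1e-9
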