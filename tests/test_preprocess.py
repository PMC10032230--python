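import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rehabsense.preprocess import (
    PreprocessConfig,
    assign_window_labels,
    preprocess_record,
    resample_uniform,
    segment_sliding_windows,
    split_at_gaps,
)
from rehabsense.records import InertialRecord, LabelTrack
from rehabsense.taxonomy import OOD_LABEL


def _record(t, values=None, rng=None):
    t = np.asarray(t, dtype=float)
    if values is None:
        rng = rng or np.random.default_rng(0)
        values = rng.normal(0, 1, (len(t), 6))
    return InertialRecord(
        record_id="r",
        subject_id="S0",
        session_index=0,
        setting="clinic",
        timestamps=t,
        accel=values[:, :3],
        gyro=values[:, 3:],
    )


def test_resample_identity_on_uniform_input(rng):
    rec = _record(np.arange(200) / 50.0, rng=rng)
    out = resample_uniform(rec, 50.0)
    np.testing.assert_allclose(out.timestamps, rec.timestamps, atol=1e-9)
    np.testing.assert_allclose(out.channels, rec.channels, atol=1e-9)


def test_resample_linear_midpoint():
    values = np.zeros((2, 6))
    values[1, 0] = 4.0
    rec = _record([0.0, 0.04], values)
    out = resample_uniform(rec, 50.0)
    np.testing.assert_allclose(out.timestamps, [0.0, 0.02, 0.04], atol=1e-12)
    np.testing.assert_allclose(out.accel[:, 0], [0.0, 2.0, 4.0], atol=1e-12)


def test_resample_jittered_sine_accuracy(rng):
    """Linear interpolation of a jittered 1 Hz sine stays within 1% amplitude."""
    n = 500
    t = np.arange(n) / 50.0 + rng.uniform(-0.004, 0.004, n)
    t[0] = 0.0
    assert np.all(np.diff(t) > 0)
    amplitude = 2.5
    values = np.tile(amplitude * np.sin(2 * np.pi * 1.0 * t)[:, None], (1, 6))
    out = resample_uniform(_record(t, values), 50.0)
    analytic = amplitude * np.sin(2 * np.pi * 1.0 * out.timestamps)
    assert np.abs(out.accel[:, 0] - analytic).max() < 0.01 * amplitude


def test_resample_too_short_errors():
    with pytest.raises(ValueError, match="too short"):
        resample_uniform(_record([0.0, 0.01]), 50.0)


@pytest.mark.parametrize("n,expected", [(500, 1), (1000, 11), (549, 1), (550, 2)])
def test_window_counts(n, expected, rng):
    cfg = PreprocessConfig()
    ws = segment_sliding_windows(_record(np.arange(n) / 50.0, rng=rng), cfg)
    assert len(ws) == expected


def test_short_record_warns_not_raises(rng, caplog):
    ws = segment_sliding_windows(_record(np.arange(100) / 50.0, rng=rng), PreprocessConfig())
    assert len(ws) == 0


@given(
    n=st.integers(20, 400),
    L=st.integers(2, 60),
    s=st.integers(1, 60),
)
def test_window_count_formula_matches_enumeration(n, L, s):
    """floor((N-L)/s)+1 windows, verified against brute-force enumeration."""
    if s > L or n < L:
        return
    starts = []
    i = 0
    while i + L <= n:  # brute-force enumerator
        starts.append(i)
        i += s
    cfg = PreprocessConfig(target_rate=1.0, window_seconds=L, step_samples=s)
    rec = _record(np.arange(n) * 1.0, np.zeros((n, 6)))
    ws = segment_sliding_windows(rec, cfg)
    assert len(ws) == len(starts) == (n - L) // s + 1
    np.testing.assert_array_equal(ws.meta["start_time"].to_numpy(), np.array(starts, float))


def test_windows_are_exact_slices(rng):
    rec = _record(np.arange(700) / 50.0, rng=rng)
    cfg = PreprocessConfig()
    ws = segment_sliding_windows(rec, cfg)
    for w, start in zip(ws.windows, ws.meta["start_time"]):
        i0 = int(round(start * 50))
        np.testing.assert_array_equal(w, rec.channels[i0 : i0 + 500])


@pytest.mark.parametrize(
    "intervals,expected",
    [
        ([(0.0, 10.0, "A")], "A"),  # fully inside
        ([(0.0, 6.0, "A")], "A"),  # 60% A vs 40% unlabelled
        ([(0.0, 5.0, "A"), (5.0, 10.0, "B")], OOD_LABEL),  # 50/50 tie
        ([(0.0, 4.9, "A")], OOD_LABEL),  # below majority
    ],
)
def test_window_label_majority_rule(intervals, expected, rng):
    cfg = PreprocessConfig()
    rec = _record(np.arange(500) / 50.0, rng=rng)
    ws = segment_sliding_windows(rec, cfg)
    labelled = assign_window_labels(ws, LabelTrack("r", intervals), cfg, rec.timestamps)
    assert labelled.labels[0] == expected


def test_gap_splitting_no_interpolation_across_dropouts(rng):
    t = np.concatenate([np.arange(300) / 50.0, 10.0 + np.arange(300) / 50.0])
    rec = _record(t, rng=rng)
    parts = split_at_gaps(rec, max_gap_seconds=1.0)
    assert len(parts) == 2
    assert all(len(p) == 300 for p in parts)
    # full pipeline: windows never span the gap
    ws = preprocess_record(rec, None)
    assert len(ws) == 0  # each 6 s part is shorter than one 10 s window


def test_resampling_idempotent(rng):
    rec = _record(np.arange(300) / 50.0, rng=rng)
    once = resample_uniform(rec, 50.0)
    twice = resample_uniform(once, 50.0)
    np.testing.assert_allclose(once.channels, twice.channels, atol=1e-12)


def test_windowset_save_load_round_trip(tmp_path, rng):
    rec = _record(np.arange(700) / 50.0, rng=rng)
    ws = segment_sliding_windows(rec, PreprocessConfig())
    ws.save(tmp_path / "ws")
    from rehabsense.preprocess import WindowSet

    back = WindowSet.load(tmp_path / "ws")
    np.testing.assert_array_equal(back.windows, ws.windows)
    assert list(back.meta["record_id"]) == list(ws.meta["record_id"])
    np.testing.assert_allclose(back.meta["start_time"], ws.meta["start_time"])
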