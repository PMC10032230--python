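"""Uniform resampling and sliding-window segmentation.

Smartwatch sensors sample asynchronously at roughly 50 Hz; every stream is
first linearly interpolated onto an exact 50 Hz grid anchored at the
record's first timestamp. Windows of 10 s (500 samples) are then taken with
a step of 50 samples (1 s, 90 % overlap) and labelled by strict majority
vote over the per-sample label mask; windows without a strict majority
class fall back to the out-of-distribution label.

Sensor dropouts are not interpolated across: a gap larger than
``max_gap_seconds`` splits the record into independently resampled
sub-records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import InertialRecord, LabelTrack
from .taxonomy import OOD_LABEL

logger = logging.getLogger(__name__)

UNLABELLED = "__unlabelled__"


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate: float = 50.0  # Hz
    window_seconds: float = 10.0
    step_samples: int = 50
    majority_fraction: float = 0.5
    max_gap_seconds: float = 1.0

    @property
    def window_samples(self) -> int:
        return int(round(self.target_rate * self.window_seconds))

    def __post_init__(self) -> None:
        if not 1 <= self.step_samples <= self.window_samples:
            raise ValueError(
                f"step_samples={self.step_samples} outside [1, {self.window_samples}]"
            )


@dataclass
class WindowSet:
    """Fixed-length window tensor with per-window provenance metadata.

    ``windows`` has shape (W, L, 6) in channel order ax, ay, az, gx, gy, gz;
    ``meta`` has one row per window with columns label, subject_id,
    session_index, record_id, setting, start_time.
    """

    windows: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[2] != 6:
            raise ValueError(f"windows must be (W, L, 6), got {self.windows.shape}")
        if len(self.meta) != len(self.windows):
            raise ValueError("metadata rows do not match window count")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    def select(self, mask_or_index) -> "WindowSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return WindowSet(self.windows[idx], self.meta.iloc[idx].reset_index(drop=True))

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Persist as ``<prefix>.npz`` (tensor) + ``<prefix>.csv`` (metadata)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tensor_path = prefix.with_suffix(".npz")
        meta_path = prefix.with_suffix(".csv")
        np.savez_compressed(tensor_path, windows=self.windows)
        self.meta.to_csv(meta_path, index=False)
        return tensor_path, meta_path

    @classmethod
    def load(cls, prefix: str | Path) -> "WindowSet":
        prefix = Path(prefix)
        with np.load(prefix.with_suffix(".npz")) as blob:
            windows = blob["windows"]
        meta = pd.read_csv(prefix.with_suffix(".csv"), keep_default_na=False)
        meta["session_index"] = pd.to_numeric(meta["session_index"], errors="coerce")
        return cls(windows, meta)

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return WindowSet(
                np.zeros((0, 1, 6)),
                pd.DataFrame(
                    columns=[
                        "label",
                        "subject_id",
                        "session_index",
                        "record_id",
                        "setting",
                        "start_time",
                    ]
                ),
            )
        return WindowSet(
            np.concatenate([s.windows for s in sets], axis=0),
            pd.concat([s.meta for s in sets], ignore_index=True),
        )


def resample_uniform(record: InertialRecord, target_rate: float = 50.0) -> InertialRecord:
    """Linearly interpolate a record onto a uniform grid at ``target_rate``.

    Output timestamps are 0, 1/f, 2/f, … relative to the first input
    timestamp, never extending past the last input timestamp (no
    extrapolation).
    """
    t = record.timestamps - record.timestamps[0]
    duration = t[-1]
    if duration < 2.0 / target_rate:
        raise ValueError(
            f"record {record.record_id!r} duration {duration:.4f}s too short to "
            f"resample at {target_rate} Hz"
        )
    n_out = int(np.floor(duration * target_rate)) + 1
    new_t = np.arange(n_out) / target_rate
    channels = record.channels
    out = np.empty((n_out, 6))
    for c in range(6):
        out[:, c] = np.interp(new_t, t, channels[:, c])
    return replace(
        record,
        timestamps=new_t,
        accel=out[:, :3],
        gyro=out[:, 3:],
    )


def split_at_gaps(record: InertialRecord, max_gap_seconds: float = 1.0) -> list[InertialRecord]:
    """Split a record into sub-records at timestamp gaps > ``max_gap_seconds``."""
    gaps = np.nonzero(np.diff(record.timestamps) > max_gap_seconds)[0]
    if gaps.size == 0:
        return [record]
    bounds = [0, *(gaps + 1), len(record)]
    parts = []
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        if b - a < 2:
            continue
        parts.append(
            replace(
                record,
                record_id=f"{record.record_id}#part{i}",
                timestamps=record.timestamps[a:b],
                accel=record.accel[a:b],
                gyro=record.gyro[a:b],
            )
        )
    return parts


def segment_sliding_windows(record: InertialRecord, cfg: PreprocessConfig) -> WindowSet:
    """Cut a uniformly sampled record into overlapping fixed-length windows.

    Windows start at sample offsets 0, s, 2s, …; a trailing partial window
    is discarded, giving floor((N − L)/s) + 1 windows for N ≥ L. A record
    shorter than one window yields an empty set with a warning rather than
    an error.
    """
    L = cfg.window_samples
    s = cfg.step_samples
    n = len(record)
    channels = record.channels
    if n < L:
        logger.warning(
            "record %s has %d samples < window length %d; no windows produced",
            record.record_id,
            n,
            L,
        )
        starts = np.array([], dtype=int)
    else:
        starts = np.arange(0, n - L + 1, s)
    windows = np.stack([channels[i : i + L] for i in starts]) if len(starts) else np.zeros(
        (0, L, 6)
    )
    meta = pd.DataFrame(
        {
            "label": UNLABELLED,
            "subject_id": record.subject_id,
            "session_index": record.session_index,
            "record_id": record.record_id,
            "setting": record.setting,
            "start_time": record.timestamps[starts] if len(starts) else np.array([]),
        }
    )
    return WindowSet(windows, meta)


def assign_window_labels(
    ws: WindowSet,
    labels: LabelTrack,
    cfg: PreprocessConfig,
    timestamps: np.ndarray,
) -> WindowSet:
    """Label windows by strict majority over the per-sample mask.

    A window gets class c iff c covers strictly more than
    ``majority_fraction`` of its samples; otherwise it is labelled OOD
    (ties included). ``timestamps`` are the uniform record timestamps the
    windows were cut from.
    """
    mask = labels.mask(timestamps)
    L = cfg.window_samples
    rate = cfg.target_rate
    new_labels = []
    for start in ws.meta["start_time"]:
        i0 = int(round(start * rate))
        votes = pd.Series(mask[i0 : i0 + L]).value_counts()
        top = votes.idxmax()
        if votes.loc[top] > cfg.majority_fraction * L and top != OOD_LABEL:
            # strict-majority requirement; also guard against ties
            tied = (votes == votes.loc[top]).sum() > 1
            new_labels.append(OOD_LABEL if tied else top)
        else:
            new_labels.append(OOD_LABEL)
    out = ws.meta.copy()
    out["label"] = new_labels
    return WindowSet(ws.windows, out)


def preprocess_record(
    record: InertialRecord,
    labels: LabelTrack | None,
    cfg: PreprocessConfig | None = None,
) -> WindowSet:
    """Full preprocessing: gap split → resample → segment → label."""
    cfg = cfg or PreprocessConfig()
    parts = []
    for sub in split_at_gaps(record, cfg.max_gap_seconds):
        try:
            uniform = resample_uniform(sub, cfg.target_rate)
        except ValueError:
            continue
        ws = segment_sliding_windows(uniform, cfg)
        if labels is not None and len(ws):
            # interval times are in the original record clock; shift to the
            # sub-record clock established by resampling
            offset = sub.timestamps[0] - record.timestamps[0]
            shifted = LabelTrack(
                labels.record_id,
                [
                    (max(t0 - offset, 0.0), t1 - offset, name)
                    for t0, t1, name in labels.intervals
                    if t1 - offset > 0
                ],
            )
            ws = assign_window_labels(ws, shifted, cfg, uniform.timestamps)
        parts.append(ws)
    return WindowSet.concatenate(parts)
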