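"""Domain types and file I/O for inertial records, labels, and manifests.

A *record* is one continuous wear period of the smartwatch: per-sample
timestamps (seconds from record start) plus a 3-axis accelerometer stream
(m/s², gravity included — raw sensor convention) and a 3-axis gyroscope
stream (rad/s). Records are stored one per CSV file with columns exactly
``t,ax,ay,az,gx,gy,gz``.

Labels live in a JSON sidecar as half-open intervals ``[t_start, t_end)``
carrying an exercise class name or the reserved OOD label; samples outside
every interval are out-of-distribution by convention. A JSON manifest
organises records by subject and session (ordered supervised clinic
sessions, unsupervised home records, and an optional proxy
activities-of-daily-living set).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .taxonomy import OOD_LABEL, Taxonomy

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


class RecordFormatError(ValueError):
    """CSV header or shape does not match the record format."""


class EmptyRecordError(ValueError):
    """Fewer than two valid samples after filtering."""


class TimestampOrderError(ValueError):
    """Timestamps not strictly increasing; carries the first offending index."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"timestamps not strictly increasing at index {index}")


class ManifestValidationError(ValueError):
    pass


@dataclass
class InertialRecord:
    """Timestamped 6-channel inertial stream for one wear period."""

    record_id: str
    subject_id: str
    session_index: int | None  # order among supervised sessions; None at home
    setting: str  # "clinic" | "home"
    timestamps: np.ndarray  # (N,) seconds, strictly increasing
    accel: np.ndarray  # (N, 3) m/s², gravity included
    gyro: np.ndarray  # (N, 3) rad/s
    dropped_rows: int = 0  # non-finite rows removed at read time

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.setting not in ("clinic", "home"):
            raise ValueError(f"setting must be 'clinic' or 'home', got {self.setting!r}")
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise RecordFormatError(
                f"accel/gyro shapes {self.accel.shape}/{self.gyro.shape} "
                f"do not match {n} timestamps"
            )
        if n < 2:
            raise EmptyRecordError(f"record {self.record_id!r} has {n} valid samples")
        diffs = np.diff(self.timestamps)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            raise TimestampOrderError(int(bad[0]) + 1)
        if not (
            np.isfinite(self.timestamps).all()
            and np.isfinite(self.accel).all()
            and np.isfinite(self.gyro).all()
        ):
            raise ValueError(f"record {self.record_id!r} contains non-finite values")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def channels(self) -> np.ndarray:
        """(N, 6) array in channel order ax, ay, az, gx, gy, gz."""
        return np.hstack([self.accel, self.gyro])


@dataclass
class LabelTrack:
    """Half-open labelled intervals for one record.

    ``intervals`` is a list of ``(t_start, t_end, class_name)`` with
    ``t_start < t_end`` and no pairwise overlap. Class names must resolve in
    the taxonomy or equal the reserved OOD label.
    """

    record_id: str
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for t0, t1, name in self.intervals:
            t0, t1 = float(t0), float(t1)
            if not (0.0 <= t0 < t1):
                raise ValueError(
                    f"invalid interval [{t0}, {t1}) in labels for {self.record_id!r}"
                )
            cleaned.append((t0, t1, str(name)))
        cleaned.sort(key=lambda iv: iv[0])
        for (a0, a1, _), (b0, _b1, _n) in zip(cleaned, cleaned[1:]):
            if b0 < a1:
                raise ValueError(
                    f"overlapping label intervals in {self.record_id!r}: "
                    f"[{a0}, {a1}) and starting {b0}"
                )
        self.intervals = cleaned

    def validate_classes(self, taxonomy: Taxonomy) -> None:
        unknown = sorted(
            {n for _, _, n in self.intervals if n != OOD_LABEL and n not in taxonomy}
        )
        if unknown:
            raise ValueError(f"label classes not in taxonomy: {unknown}")

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, name in self.intervals:
            if name != OOD_LABEL:
                seen.setdefault(name)
        return list(seen)

    def mask(self, timestamps: np.ndarray) -> np.ndarray:
        """Per-sample class assignment; samples outside all intervals → OOD."""
        timestamps = np.asarray(timestamps, dtype=float)
        out = np.full(len(timestamps), OOD_LABEL, dtype=object)
        for t0, t1, name in self.intervals:
            out[(timestamps >= t0) & (timestamps < t1)] = name
        return out


# ---------------------------------------------------------------------------
# record CSV I/O


def read_record(
    path: str | Path,
    record_id: str | None = None,
    subject_id: str = "unknown",
    session_index: int | None = None,
    setting: str = "clinic",
) -> InertialRecord:
    """Read an inertial record from CSV.

    Rows containing non-finite values are dropped (count logged and stored
    on the record). Metadata not supplied explicitly defaults from the file
    name / arguments; :meth:`Manifest.load_record` supplies it from the
    manifest.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if tuple(header) != RECORD_COLUMNS:
            raise RecordFormatError(
                f"{path}: expected columns {','.join(RECORD_COLUMNS)}, "
                f"got {','.join(header)}"
            )
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise RecordFormatError(f"{path}: unparseable numeric data: {exc}") from exc
    if data.size and data.shape[1] != 7:
        raise RecordFormatError(f"{path}: expected 7 columns, got {data.shape[1]}")
    if data.size == 0:
        raise EmptyRecordError(f"{path}: no data rows")
    finite = np.isfinite(data).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("dropped %d non-finite rows reading %s", dropped, path)
    data = data[finite]
    if len(data) < 2:
        raise EmptyRecordError(f"{path}: fewer than 2 valid rows after filtering")
    return InertialRecord(
        record_id=record_id or path.stem,
        subject_id=subject_id,
        session_index=session_index,
        setting=setting,
        timestamps=data[:, 0],
        accel=data[:, 1:4],
        gyro=data[:, 4:7],
        dropped_rows=dropped,
    )


def write_record(record: InertialRecord, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([record.timestamps, record.accel, record.gyro])
    np.savetxt(
        path, data, delimiter=",", header=",".join(RECORD_COLUMNS), comments="", fmt="%.12g"
    )
    return path


def read_label_track(path: str | Path) -> LabelTrack:
    with open(path) as fh:
        obj = json.load(fh)
    return LabelTrack(
        record_id=obj["record_id"],
        intervals=[(float(a), float(b), str(c)) for a, b, c in obj["intervals"]],
    )


def write_label_track(track: LabelTrack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(
            {"record_id": track.record_id, "intervals": [list(iv) for iv in track.intervals]},
            fh,
            indent=1,
        )
    return path


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RecordEntry:
    """One record's manifest entry; paths are relative to the manifest."""

    record_id: str
    record_path: str
    label_path: str | None = None
    classes: list[str] = field(default_factory=list)  # cached from the sidecar


@dataclass
class SessionEntry:
    session_index: int
    records: list[RecordEntry] = field(default_factory=list)


@dataclass
class SubjectEntry:
    subject_id: str
    clinic_sessions: list[SessionEntry] = field(default_factory=list)
    home_records: list[RecordEntry] = field(default_factory=list)


@dataclass
class Manifest:
    """Dataset index: per-subject ordered clinic sessions plus home records."""

    subjects: list[SubjectEntry] = field(default_factory=list)
    proxy_records: list[RecordEntry] = field(default_factory=list)
    root: Path = field(default_factory=Path)
    name: str = "cohort"

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subject(self, subject_id: str) -> SubjectEntry:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def iter_clinic_records(self):
        for subj in self.subjects:
            for sess in subj.clinic_sessions:
                for entry in sess.records:
                    yield subj.subject_id, sess.session_index, entry

    def validate(self) -> None:
        missing = []
        for subj in self.subjects:
            indices = [s.session_index for s in subj.clinic_sessions]
            if indices != sorted(indices) or len(set(indices)) != len(indices):
                raise ManifestValidationError(
                    f"subject {subj.subject_id!r}: session indices {indices} "
                    "not strictly ordered"
                )
            entries = [e for s in subj.clinic_sessions for e in s.records]
            entries += subj.home_records
            for entry in entries:
                for rel in (entry.record_path, entry.label_path):
                    if rel is not None and not (self.root / rel).exists():
                        missing.append(str(rel))
        for entry in self.proxy_records:
            if not (self.root / entry.record_path).exists():
                missing.append(str(entry.record_path))
        if missing:
            raise ManifestValidationError(f"manifest references missing files: {missing}")

    def load_record(
        self, entry: RecordEntry, subject_id: str, session_index: int | None, setting: str
    ) -> InertialRecord:
        return read_record(
            self.root / entry.record_path,
            record_id=entry.record_id,
            subject_id=subject_id,
            session_index=session_index,
            setting=setting,
        )

    def load_labels(self, entry: RecordEntry) -> LabelTrack | None:
        if entry.label_path is None:
            return None
        return read_label_track(self.root / entry.label_path)


def _entry_to_json(entry: RecordEntry) -> dict:
    return {
        "record_id": entry.record_id,
        "record_path": entry.record_path,
        "label_path": entry.label_path,
        "classes": entry.classes,
    }


def _entry_from_json(obj: dict) -> RecordEntry:
    return RecordEntry(
        record_id=obj["record_id"],
        record_path=obj["record_path"],
        label_path=obj.get("label_path"),
        classes=list(obj.get("classes", [])),
    )


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj = {
        "name": manifest.name,
        "subjects": [
            {
                "subject_id": s.subject_id,
                "clinic_sessions": [
                    {
                        "session_index": sess.session_index,
                        "records": [_entry_to_json(e) for e in sess.records],
                    }
                    for sess in s.clinic_sessions
                ],
                "home_records": [_entry_to_json(e) for e in s.home_records],
            }
            for s in manifest.subjects
        ],
        "proxy_records": [_entry_to_json(e) for e in manifest.proxy_records],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
    return path


def load_manifest(path: str | Path, validate: bool = True) -> Manifest:
    path = Path(path)
    with open(path) as fh:
        obj = json.load(fh)
    manifest = Manifest(
        subjects=[
            SubjectEntry(
                subject_id=s["subject_id"],
                clinic_sessions=[
                    SessionEntry(
                        session_index=int(sess["session_index"]),
                        records=[_entry_from_json(e) for e in sess["records"]],
                    )
                    for sess in s["clinic_sessions"]
                ],
                home_records=[_entry_from_json(e) for e in s.get("home_records", [])],
            )
            for s in obj["subjects"]
        ],
        proxy_records=[_entry_from_json(e) for e in obj.get("proxy_records", [])],
        root=path.parent,
        name=obj.get("name", "cohort"),
    )
    if validate:
        manifest.validate()
    return manifest
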