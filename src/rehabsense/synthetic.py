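"""Seeded synthetic IMU cohort generator.

Emulates the statistical structure the pipeline assumes, without any
biomechanical model:

* each exercise class has a *template*: a gravity orientation (the wrist
  attitude held during the exercise) plus three harmonic
  amplitude/phase coefficient sets per channel. Classes in the same
  simple-motion group share a correlated component, so coarser groupings
  genuinely ease classification; the class-separation scalar ``sep``
  scales all template differences (``sep = 0`` collapses every class onto
  one template);
* repetition periods are right-skewed, drawn from a lognormal
  moment-matched to mean 3.8 s and SD 2.3 s;
* subjects differ by a random wrist rotation and amplitude scale
  (technique variation, ``subject_var``); sessions add a smaller drift
  (``session_drift``);
* clinic records are session-long sequences of labelled exercise bouts
  separated by short rests; home records interleave bouts, rest
  (including long near-static stretches), and activities of daily living
  (ADL), with exact ground-truth masks;
* a proxy ADL set is generated from disjoint "proxy subjects" with a
  different intensity-regime mixture than home non-exercise data, so the
  proxy is a deliberately imperfect stand-in for the true OOD
  distribution.

Accelerometer output includes gravity (raw sensor convention); timestamps
can be jittered to exercise the resampling stage. Everything is
deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .records import (
    InertialRecord,
    LabelTrack,
    Manifest,
    RecordEntry,
    SessionEntry,
    SubjectEntry,
    write_label_track,
    write_manifest,
    write_record,
)
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy

GRAVITY = 9.81

#: Default 8 classes spanning all 6 simple-motion groups.
DEFAULT_CLASSES = (
    "Active shoulder flexion",
    "Active shoulder abduction",
    "Assisted shoulder external rotation",
    "Resisted shoulder internal rotation",
    "Resisted row",
    "Resisted triceps pull down",
    "Resisted lat pull down",
    "Press up against wall",
)

#: ADL intensity regimes: (gyro-scale multiplier, periodic-component flag)
ADL_REGIMES = {
    "rest": 0.03,
    "gesturing": 0.45,
    "walking": 1.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 20
    n_sessions: int = 4
    classes: tuple = DEFAULT_CLASSES
    classes_per_subject: int = 4
    reps_per_bout: tuple = (5, 8)  # inclusive range
    rep_period_mean: float = 3.8  # s
    rep_period_sd: float = 2.3  # s
    sep: float = 1.0  # class-separation scalar
    subject_var: float = 0.30  # inter-subject technique variation
    session_drift: float = 0.12  # per-session drift
    accel_noise_sd: float = 0.2  # m/s²
    gyro_noise_sd: float = 0.1  # rad/s
    accel_amp: float = 2.0  # m/s², fundamental harmonic
    gyro_amp: float = 1.2  # rad/s, fundamental harmonic
    sample_rate: float = 50.0  # Hz
    timestamp_jitter: float = 0.004  # s, uniform; 0 → exactly uniform
    home_records_per_subject: int = 1
    home_duration: float = 420.0  # s target per home record
    home_mix: tuple = (0.35, 0.40, 0.25)  # bout / rest / ADL weights
    long_rest_duration: float = 120.0  # one guaranteed near-static stretch
    n_proxy_subjects: int = 6
    proxy_minutes_per_subject: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = []
        for name in ("sep", "subject_var", "session_drift", "accel_noise_sd",
                     "gyro_noise_sd", "timestamp_jitter"):
            if getattr(self, name) < 0:
                bad.append(name)
        if self.rep_period_mean <= 0 or self.rep_period_sd < 0:
            bad.append("rep_period_mean/sd")
        if len(set(self.classes)) != len(self.classes):
            bad.append("classes (duplicates)")
        if bad:
            raise ValueError(f"invalid generator config fields: {bad}")


def default_benchmark_config(seed: int = 7) -> GeneratorConfig:
    """The canonical benchmark cohort: 20 subjects × 4 sessions × 8 classes."""
    return GeneratorConfig(seed=seed)


# ---------------------------------------------------------------------------
# repetition periods


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal moment-matched to the given mean and SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_rep_periods(
    n: int, rng: np.random.Generator, mean: float = 3.8, sd: float = 2.3
) -> np.ndarray:
    """Right-skewed per-repetition periods (s)."""
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


# ---------------------------------------------------------------------------
# class templates


@dataclass
class ClassTemplate:
    name: str
    orientation: np.ndarray  # unit gravity direction during the exercise
    amp: np.ndarray  # (6, 3) harmonic amplitudes per channel
    phase: np.ndarray  # (6, 3) harmonic phases

    @property
    def coefficients(self) -> np.ndarray:
        """Flat coefficient vector used for similarity diagnostics."""
        return np.concatenate([self.orientation * GRAVITY, self.amp.ravel()])


def make_class_templates(
    classes,
    seed: int = 0,
    sep: float = 1.0,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    accel_amp: float = 2.0,
    gyro_amp: float = 1.2,
) -> dict[str, ClassTemplate]:
    """Per-class motion templates with within-group correlation.

    Each template is a shared base plus ``sep``-scaled deviations: a
    simple-motion-group deviation (weight 0.7) shared by all classes in the
    group, and a smaller class-specific deviation (weight 0.35). Classes in
    a group therefore stay closer to each other than to other groups.
    """
    classes = list(classes)
    if len(set(classes)) != len(classes):
        raise ValueError("duplicate class names")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    base_orient = np.array([0.25, -0.35, 0.9])
    base_orient /= np.linalg.norm(base_orient)
    harmonics = 3
    base_amp = np.outer(
        np.array([accel_amp] * 3 + [gyro_amp] * 3), 1.0 / np.arange(1, harmonics + 1)
    )
    base_phase = rng.uniform(0, 2 * np.pi, size=(6, harmonics))

    groups = {taxonomy.map_label(c, "simple_motion") for c in classes}
    group_dev = {
        g: {
            "orient": rng.standard_normal(3),
            "amp": rng.standard_normal((6, harmonics)),
            "phase": rng.standard_normal((6, harmonics)),
        }
        for g in sorted(groups)
    }
    templates: dict[str, ClassTemplate] = {}
    for name in classes:
        g = group_dev[taxonomy.map_label(name, "simple_motion")]
        dev_o = rng.standard_normal(3)
        dev_a = rng.standard_normal((6, harmonics))
        dev_p = rng.standard_normal((6, harmonics))
        orient = base_orient + sep * (0.7 * g["orient"] + 0.35 * dev_o)
        orient /= np.linalg.norm(orient)
        amp = base_amp * np.exp(0.5 * sep * (0.7 * g["amp"] + 0.35 * dev_a))
        phase = base_phase + sep * (0.7 * g["phase"] + 0.35 * dev_p)
        templates[name] = ClassTemplate(name, orient, amp, phase)
    return templates


# ---------------------------------------------------------------------------
# subject and session profiles


@dataclass
class SubjectProfile:
    subject_id: str
    rotation: Rotation  # wrist-attitude deviation from the template
    amp_scale: float
    assigned_classes: list[str]


def _subject_profile(
    subject_id: str, classes, cfg: GeneratorConfig, rng: np.random.Generator
) -> SubjectProfile:
    k = min(cfg.classes_per_subject, len(classes))
    assigned = list(rng.choice(list(classes), size=k, replace=False))
    return SubjectProfile(
        subject_id=subject_id,
        rotation=Rotation.from_rotvec(cfg.subject_var * rng.standard_normal(3)),
        amp_scale=float(np.exp(cfg.subject_var * rng.standard_normal() * 0.5)),
        assigned_classes=assigned,
    )


def _session_drift(cfg: GeneratorConfig, rng: np.random.Generator):
    rot = Rotation.from_rotvec(cfg.session_drift * rng.standard_normal(3))
    scale = float(np.exp(cfg.session_drift * rng.standard_normal() * 0.5))
    return rot, scale


# ---------------------------------------------------------------------------
# signal primitives


def generate_bout(
    template: ClassTemplate,
    profile: SubjectProfile,
    n_reps: int,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    session_rot: Rotation | None = None,
    session_scale: float = 1.0,
) -> tuple[np.ndarray, float]:
    """One exercise bout: ``n_reps`` quasi-periodic repetitions.

    Returns the (N, 6) signal at the nominal rate and its duration in
    seconds. Accelerometer = rotated gravity + harmonic motion + noise;
    gyroscope = harmonic motion + noise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rot = profile.rotation if session_rot is None else session_rot * profile.rotation
    scale = profile.amp_scale * session_scale
    periods = sample_rep_periods(n_reps, rng, cfg.rep_period_mean, cfg.rep_period_sd)
    dt = 1.0 / cfg.sample_rate
    chunks = []
    for T in periods:
        n = max(int(round(T / dt)), 2)
        t = np.arange(n) * dt
        motion = np.zeros((n, 6))
        for h in range(template.amp.shape[1]):
            motion += (
                template.amp[:, h] * np.sin(2 * np.pi * (h + 1) * t[:, None] / T + template.phase[:, h])
            )
        motion *= scale
        chunks.append(motion)
    motion = np.concatenate(chunks, axis=0)
    g_vec = rot.apply(template.orientation) * GRAVITY
    sig = np.empty_like(motion)
    sig[:, :3] = g_vec + rot.apply(motion[:, :3]) + cfg.accel_noise_sd * rng.standard_normal(
        (len(motion), 3)
    )
    sig[:, 3:] = rot.apply(motion[:, 3:]) + cfg.gyro_noise_sd * rng.standard_normal(
        (len(motion), 3)
    )
    return sig, len(motion) * dt


def generate_adl_segment(
    intensity: float,
    duration: float,
    rng: np.random.Generator,
    cfg: GeneratorConfig | None = None,
    periodic: bool = False,
) -> np.ndarray:
    """Non-exercise motion: mean-reverting (OU) wander scaled by intensity.

    ``intensity`` 0 gives near-static rest (gravity plus sensor noise);
    ``periodic`` adds a walking-like 1.9 Hz component. Returns an (N, 6)
    signal at the nominal rate.
    """
    cfg = cfg or GeneratorConfig()
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = 1.0 / cfg.sample_rate
    n = max(int(round(duration / dt)), 2)
    theta, sigma = 1.5, 2.0
    x = np.zeros((n, 6))
    step = sigma * np.sqrt(dt) * rng.standard_normal((n - 1, 6))
    for i in range(1, n):
        x[i] = x[i - 1] * (1 - theta * dt) + step[i - 1]
    x *= intensity
    if periodic:
        t = np.arange(n) * dt
        ph = rng.uniform(0, 2 * np.pi, size=6)
        x += intensity * 0.8 * np.sin(2 * np.pi * 1.9 * t[:, None] + ph)
    orient = rng.standard_normal(3)
    orient /= np.linalg.norm(orient)
    out = np.empty_like(x)
    out[:, :3] = orient * GRAVITY + x[:, :3] + cfg.accel_noise_sd * rng.standard_normal((n, 3))
    out[:, 3:] = x[:, 3:] + cfg.gyro_noise_sd * rng.standard_normal((n, 3))
    return out


# ---------------------------------------------------------------------------
# records and cohort


def _timestamps(n: int, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / cfg.sample_rate
    if cfg.timestamp_jitter > 0:
        jitter = rng.uniform(-cfg.timestamp_jitter, cfg.timestamp_jitter, size=n)
        jitter[0] = 0.0
        t = t + jitter
    return t


def _assemble_record(
    record_id: str,
    subject_id: str,
    session_index: int | None,
    setting: str,
    pieces: list[tuple[np.ndarray, str | None]],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[InertialRecord, LabelTrack]:
    """Concatenate (signal, class-or-None) pieces into a labelled record."""
    sig = np.concatenate([p[0] for p in pieces], axis=0)
    dt = 1.0 / cfg.sample_rate
    intervals = []
    cursor = 0
    for chunk, cls in pieces:
        if cls is not None:
            intervals.append((cursor * dt, (cursor + len(chunk)) * dt, cls))
        cursor += len(chunk)
    record = InertialRecord(
        record_id=record_id,
        subject_id=subject_id,
        session_index=session_index,
        setting=setting,
        timestamps=_timestamps(len(sig), cfg, rng),
        accel=sig[:, :3],
        gyro=sig[:, 3:],
    )
    return record, LabelTrack(record_id=record_id, intervals=intervals)


@dataclass
class SyntheticCohort:
    """In-memory cohort: manifest skeleton plus records and label tracks."""

    config: GeneratorConfig
    manifest: Manifest
    records: dict[str, InertialRecord] = field(default_factory=dict)
    labels: dict[str, LabelTrack] = field(default_factory=dict)
    templates: dict[str, ClassTemplate] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        """Materialize the cohort as CSV records + JSON sidecars + manifest."""
        out_dir = Path(out_dir)
        for rid, record in self.records.items():
            write_record(record, out_dir / "records" / f"{rid}.csv")
            if rid in self.labels:
                write_label_track(self.labels[rid], out_dir / "labels" / f"{rid}.json")
        self.manifest.root = out_dir
        path = write_manifest(self.manifest, out_dir / "manifest.json")
        self.manifest.validate()
        return path


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort for a config (deterministic)."""
    root = np.random.default_rng(cfg.seed)
    # independent streams per concern keep record content stable under
    # changes elsewhere in the generator
    rng_subjects, rng_records, rng_proxy = root.spawn(3)

    templates = make_class_templates(
        cfg.classes,
        seed=cfg.seed,
        sep=cfg.sep,
        accel_amp=cfg.accel_amp,
        gyro_amp=cfg.gyro_amp,
    )
    cohort = SyntheticCohort(
        config=cfg,
        manifest=Manifest(name=f"synthetic-seed{cfg.seed}"),
        templates=templates,
    )

    def _add(entry_list, record, track):
        cohort.records[record.record_id] = record
        cohort.labels[record.record_id] = track
        entry_list.append(
            RecordEntry(
                record_id=record.record_id,
                record_path=f"records/{record.record_id}.csv",
                label_path=f"labels/{record.record_id}.json",
                classes=track.classes,
            )
        )

    for si in range(cfg.n_subjects):
        subject_id = f"S{si:02d}"
        profile = _subject_profile(subject_id, cfg.classes, cfg, rng_subjects)
        subj_entry = SubjectEntry(subject_id=subject_id)

        for sess in range(cfg.n_sessions):
            drift_rot, drift_scale = _session_drift(cfg, rng_records)
            pieces: list[tuple[np.ndarray, str | None]] = []
            for cls in profile.assigned_classes:
                rest = generate_adl_segment(
                    ADL_REGIMES["rest"], rng_records.uniform(2.0, 4.0), rng_records, cfg
                )
                pieces.append((rest, None))
                n_reps = int(rng_records.integers(cfg.reps_per_bout[0], cfg.reps_per_bout[1] + 1))
                bout, _ = generate_bout(
                    templates[cls], profile, n_reps, rng_records, cfg, drift_rot, drift_scale
                )
                pieces.append((bout, cls))
            pieces.append(
                (generate_adl_segment(ADL_REGIMES["rest"], rng_records.uniform(2.0, 4.0), rng_records, cfg), None)
            )
            record, track = _assemble_record(
                f"{subject_id}-clinic{sess}", subject_id, sess, "clinic", pieces, cfg, rng_records
            )
            sess_entry = SessionEntry(session_index=sess)
            _add(sess_entry.records, record, track)
            subj_entry.clinic_sessions.append(sess_entry)

        for hi in range(cfg.home_records_per_subject):
            pieces = []
            total = 0.0
            # one guaranteed long near-static stretch
            long_rest = generate_adl_segment(
                ADL_REGIMES["rest"], cfg.long_rest_duration, rng_records, cfg
            )
            pieces.append((long_rest, None))
            total += cfg.long_rest_duration
            while total < cfg.home_duration:
                kind = rng_records.choice(("bout", "rest", "adl"), p=cfg.home_mix)
                if kind == "bout":
                    cls = str(rng_records.choice(profile.assigned_classes))
                    n_reps = int(
                        rng_records.integers(cfg.reps_per_bout[0], cfg.reps_per_bout[1] + 1)
                    )
                    sig, dur = generate_bout(templates[cls], profile, n_reps, rng_records, cfg)
                    pieces.append((sig, cls))
                    total += dur
                elif kind == "rest":
                    dur = float(rng_records.uniform(20.0, 60.0))
                    pieces.append(
                        (generate_adl_segment(ADL_REGIMES["rest"], dur, rng_records, cfg), None)
                    )
                    total += dur
                else:
                    regime = str(rng_records.choice(("gesturing", "walking"), p=(0.6, 0.4)))
                    dur = float(rng_records.uniform(20.0, 60.0))
                    pieces.append(
                        (
                            generate_adl_segment(
                                ADL_REGIMES[regime], dur, rng_records, cfg,
                                periodic=regime == "walking",
                            ),
                            None,
                        )
                    )
                    total += dur
            record, track = _assemble_record(
                f"{subject_id}-home{hi}", subject_id, None, "home", pieces, cfg, rng_records
            )
            _add(subj_entry.home_records, record, track)

        cohort.manifest.subjects.append(subj_entry)

    # proxy ADL set from disjoint subjects: heavier gesturing/walking mixture
    # than home non-exercise (a deliberately imperfect OOD stand-in)
    for pi in range(cfg.n_proxy_subjects):
        pieces = []
        total = 0.0
        while total < cfg.proxy_minutes_per_subject * 60.0:
            regime = str(rng_proxy.choice(("rest", "gesturing", "walking"), p=(0.2, 0.45, 0.35)))
            dur = float(rng_proxy.uniform(15.0, 45.0))
            pieces.append(
                (
                    generate_adl_segment(
                        ADL_REGIMES[regime], dur, rng_proxy, cfg, periodic=regime == "walking"
                    ),
                    None,
                )
            )
            total += dur
        record, track = _assemble_record(
            f"P{pi:02d}-proxy", f"P{pi:02d}", None, "home", pieces, cfg, rng_proxy
        )
        cohort.records[record.record_id] = record
        cohort.labels[record.record_id] = track
        cohort.manifest.proxy_records.append(
            RecordEntry(
                record_id=record.record_id,
                record_path=f"records/{record.record_id}.csv",
                label_path=f"labels/{record.record_id}.json",
                classes=[],
            )
        )
    return cohort
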