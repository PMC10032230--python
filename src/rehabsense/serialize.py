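"""Single-archive persistence for fitted models with a format version tag."""

from __future__ import annotations

from pathlib import Path

import joblib

FORMAT_VERSION = 1


def save_model(obj, path: str | Path, meta: dict | None = None) -> Path:
    """Serialize a fitted detector/classifier (plus metadata) to one archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"format_version": FORMAT_VERSION, "meta": meta or {}, "model": obj}, path)
    return path


def load_model(path: str | Path):
    """Load an archive written by :func:`save_model`; returns (model, meta)."""
    blob = joblib.load(path)
    version = blob.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {version!r}")
    return blob["model"], blob["meta"]
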