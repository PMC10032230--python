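"""Exercise taxonomy and motion groupings.

The shoulder-rehabilitation programme covered by this package comprises 18
exercise classes. Each exercise carries three attributes — its motion (e.g.
flexion, row), a coarser "simple motion" category (e.g. elevation), and the
body position it is performed in — which define a hierarchy of groupings
used to coarsen classification labels:

====================  =============================================
grouping level        label produced
====================  =============================================
exercise              the exercise name itself (identity)
motion                motion attribute
motion_position       ``"<motion>-<position>"``
simple_motion         simple-motion attribute
simple_motion_position  ``"<simple motion>-<position>"``
====================  =============================================

The reserved out-of-distribution label maps to itself at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Reserved label for non-exercise (out-of-distribution) data.
OOD_LABEL = "OOD"

#: Recognised grouping levels, finest to coarsest along each branch.
GROUPING_LEVELS = (
    "exercise",
    "motion",
    "motion_position",
    "simple_motion",
    "simple_motion_position",
)


@dataclass(frozen=True)
class TaxonomyEntry:
    exercise: str
    motion: str
    simple_motion: str
    position: str


@dataclass
class Taxonomy:
    """Mapping from exercise names to motion-grouping attributes."""

    entries: list[TaxonomyEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.exercise for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate exercise names in taxonomy: {dupes}")
        self._by_name = {e.exercise: e for e in self.entries}

    @property
    def exercise_names(self) -> list[str]:
        return [e.exercise for e in self.entries]

    @property
    def simple_motion_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.simple_motion)
        return list(seen)

    @property
    def motion_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.motion)
        return list(seen)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def map_label(self, label: str, level: str) -> str:
        """Map an exercise-level label to the given grouping level.

        The reserved OOD label is passed through unchanged. Unknown labels
        raise ``KeyError`` naming the offending label.
        """
        if level not in GROUPING_LEVELS:
            raise ValueError(
                f"unknown grouping level {level!r}; expected one of {GROUPING_LEVELS}"
            )
        if label == OOD_LABEL:
            return label
        entry = self._by_name.get(label)
        if entry is None:
            raise KeyError(f"label {label!r} not in taxonomy")
        if level == "exercise":
            return label
        if level == "motion":
            return entry.motion
        if level == "motion_position":
            return f"{entry.motion}-{entry.position}"
        if level == "simple_motion":
            return entry.simple_motion
        return f"{entry.simple_motion}-{entry.position}"

    def subset(self, names: list[str]) -> "Taxonomy":
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"labels not in taxonomy: {missing}")
        return Taxonomy([self._by_name[n] for n in names])


def _entry(exercise: str, motion: str, simple: str, position: str) -> TaxonomyEntry:
    return TaxonomyEntry(exercise, motion, simple, position)


# The 18-exercise rehabilitation taxonomy. Exercises prescribed in more than
# one position share a base name; those are disambiguated with the position
# in parentheses so names stay unique.
DEFAULT_TAXONOMY = Taxonomy(
    [
        _entry("Active shoulder flexion", "Flexion", "Elevation", "Upright"),
        _entry("Active shoulder abduction", "Abduction", "Elevation", "Upright"),
        _entry("Assisted shoulder flexion", "Flexion", "Elevation", "Upright"),
        _entry("Assisted shoulder flexion (lying)", "Flexion", "Elevation", "Lying"),
        _entry(
            "Shoulder girdle stabilization with elevation",
            "Flexion",
            "Elevation",
            "Upright",
        ),
        _entry(
            "Assisted shoulder external rotation",
            "External rotation",
            "Rotation",
            "Upright",
        ),
        _entry(
            "Assisted shoulder internal rotation",
            "Internal rotation",
            "Rotation",
            "Upright",
        ),
        _entry(
            "Assisted shoulder internal rotation (side-lying)",
            "Internal rotation",
            "Rotation",
            "Side-lying",
        ),
        _entry(
            "Resisted shoulder internal rotation",
            "Internal rotation",
            "Rotation",
            "Upright, adducted",
        ),
        _entry(
            "Resisted shoulder external rotation",
            "External rotation",
            "Rotation",
            "Upright, adducted",
        ),
        _entry(
            "Resisted shoulder external rotation (abducted)",
            "External rotation",
            "Rotation",
            "Upright, abducted",
        ),
        _entry("Resisted row", "Row", "Row", "Bent over"),
        _entry("Resisted triceps pull down", "Elbow-extension", "Elbow-flexion", "Upright"),
        _entry("Resisted lat pull down", "Pull down", "Pull down", "Upright"),
        _entry(
            "Resisted lat pull down (external rotation)",
            "Pull down",
            "Pull down",
            "Upright",
        ),
        _entry("Press up against wall", "Press up", "Press up", "Upright"),
        _entry("Resisted seratus anterior", "Press up", "Press up", "Upright"),
        _entry("Push up", "Press up", "Press up", "Prone"),
    ]
)
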