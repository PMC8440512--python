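"""Domain types, file I/O and quality control for two-triangle animation recordings.

The recording model mirrors the touchscreen animation task: two equilateral
triangles (one red, one blue) are dragged around a rectangular canvas while
per-frame centroid positions (pixels) and rotation angles (degrees) are
captured at a nominal 133 frames/s for 45 s.

File formats are plain text: a long-format CSV with ``#key=value`` metadata
header lines, and an equivalent JSON mirror.  Both round-trip exactly.
"""

from __future__ import annotations

import enum
import json

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WordCategory",
    "MENTAL_WORDS",
    "NONMENTAL_WORDS",
    "AnimationRecording",
    "RatingTrial",
    "QCReport",
    "ValidationError",
    "read_recording",
    "write_recording",
    "read_ratings",
    "write_ratings",
    "qc_filter",
]


class WordCategory(enum.Enum):
    """The five target words of the animation task.

    Three are mental-state words (the animator depicts one triangle reacting
    to the other's mind) and two are non-mental, goal-directed words.
    """

    MOCKING = "mocking"
    SEDUCING = "seducing"
    SURPRISING = "surprising"
    FOLLOWING = "following"
    FIGHTING = "fighting"

    @property
    def is_mental(self) -> bool:
        return self in MENTAL_WORDS


MENTAL_WORDS = frozenset(
    {WordCategory.MOCKING, WordCategory.SEDUCING, WordCategory.SURPRISING}
)
NONMENTAL_WORDS = frozenset({WordCategory.FOLLOWING, WordCategory.FIGHTING})


class ValidationError(ValueError):
    """Raised when a recording or rating trial violates its invariants."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class AnimationRecording:
    """Per-frame positions and rotations of the red and blue triangles.

    Positions are centroid coordinates in pixels, rotations in degrees in
    [0, 360).  ``t`` is in seconds and strictly increasing.
    """

    animation_id: str
    animator_id: str
    word: WordCategory
    frame_rate_hz: float
    canvas_px: tuple[int, int]
    t: np.ndarray
    red_xy: np.ndarray  # (n, 2) pixels
    red_rot: np.ndarray  # (n,) degrees in [0, 360)
    blue_xy: np.ndarray
    blue_rot: np.ndarray

    def __post_init__(self) -> None:
        t = _as_float_array(self.t, "t")
        object.__setattr__(self, "t", t)
        for name in ("red_xy", "blue_xy"):
            xy = np.asarray(getattr(self, name), dtype=float)
            if xy.shape != (t.size, 2):
                raise ValidationError(f"{name} must have shape (n_frames, 2)")
            object.__setattr__(self, name, xy)
        for name in ("red_rot", "blue_rot"):
            rot = _as_float_array(getattr(self, name), name)
            if rot.size != t.size:
                raise ValidationError(f"{name} length does not match t")
            object.__setattr__(self, name, rot)
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        w, h = self.canvas_px
        if w <= 0 or h <= 0:
            raise ValidationError("canvas dimensions must be positive")
        if t.size < 2:
            raise ValidationError("recording needs at least 2 frames")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"timestamps not strictly increasing at frame {bad[0] + 1}"
            )
        for name, xy in (("red", self.red_xy), ("blue", self.blue_xy)):
            out = np.nonzero(
                (xy[:, 0] < 0) | (xy[:, 0] > w) | (xy[:, 1] < 0) | (xy[:, 1] > h)
            )[0]
            if out.size:
                raise ValidationError(
                    f"{name} position outside canvas at frame {out[0]}"
                )
        for name, rot in (("red", self.red_rot), ("blue", self.blue_rot)):
            out = np.nonzero((rot < 0) | (rot >= 360))[0]
            if out.size:
                raise ValidationError(
                    f"{name} rotation outside [0, 360) at frame {out[0]}"
                )

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __eq__(self, other) -> bool:  # dataclass default breaks on arrays
        if not isinstance(other, AnimationRecording):
            return NotImplemented
        return (
            self.animation_id == other.animation_id
            and self.animator_id == other.animator_id
            and self.word == other.word
            and self.frame_rate_hz == other.frame_rate_hz
            and tuple(self.canvas_px) == tuple(other.canvas_px)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.red_xy, other.red_xy)
            and np.array_equal(self.red_rot, other.red_rot)
            and np.array_equal(self.blue_xy, other.blue_xy)
            and np.array_equal(self.blue_rot, other.blue_rot)
        )


@dataclass(frozen=True)
class RatingTrial:
    """One observer's five 1-10 ratings of one animation."""

    observer_id: str
    animation_id: str
    target_word: WordCategory
    ratings: dict[WordCategory, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [w for w in WordCategory if w not in self.ratings]
        if missing:
            raise ValidationError(f"missing ratings for {missing}")
        for w, r in self.ratings.items():
            if not (1.0 <= r <= 10.0):
                raise ValidationError(f"rating for {w.value} outside [1, 10]: {r}")


@dataclass(frozen=True)
class QCReport:
    """Outcome of the quality-control screen for one recording."""

    animation_id: str
    passed: bool
    reasons: tuple[str, ...]
    visited_quadrants: frozenset[int]
    duration_s: float

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValidationError("passed must equal 'no failure reasons'")


# ---------------------------------------------------------------------------
# I/O

_CSV_COLUMNS = ("t", "red_x", "red_y", "red_rot", "blue_x", "blue_y", "blue_rot")


def _format_float(x: float) -> str:
    return repr(float(x))


def write_recording(rec: AnimationRecording, path, dialect: str = "csv") -> None:
    """Write a recording to ``path`` in CSV or JSON form.

    Deterministic: identical recordings produce byte-identical files.
    """
    path = Path(path)
    if dialect == "csv":
        lines = [
            f"#animation_id={rec.animation_id}",
            f"#animator_id={rec.animator_id}",
            f"#word={rec.word.value}",
            f"#frame_rate_hz={_format_float(rec.frame_rate_hz)}",
            f"#canvas_w={rec.canvas_px[0]}",
            f"#canvas_h={rec.canvas_px[1]}",
            ",".join(_CSV_COLUMNS),
        ]
        for i in range(rec.n_frames):
            row = (
                rec.t[i],
                rec.red_xy[i, 0],
                rec.red_xy[i, 1],
                rec.red_rot[i],
                rec.blue_xy[i, 0],
                rec.blue_xy[i, 1],
                rec.blue_rot[i],
            )
            lines.append(",".join(_format_float(v) for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "json":
        payload = {
            "animation_id": rec.animation_id,
            "animator_id": rec.animator_id,
            "word": rec.word.value,
            "frame_rate_hz": rec.frame_rate_hz,
            "canvas_px": list(rec.canvas_px),
            "frames": [
                {
                    "t": rec.t[i],
                    "red": {
                        "x_px": rec.red_xy[i, 0],
                        "y_px": rec.red_xy[i, 1],
                        "rot_deg": rec.red_rot[i],
                    },
                    "blue": {
                        "x_px": rec.blue_xy[i, 0],
                        "y_px": rec.blue_xy[i, 1],
                        "rot_deg": rec.blue_rot[i],
                    },
                }
                for i in range(rec.n_frames)
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def read_recording(path, dialect: str | None = None) -> AnimationRecording:
    """Read a recording written by :func:`write_recording`.

    ``dialect`` defaults to the file suffix.  Malformed rows and invariant
    violations raise with the offending frame index in the message.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "csv":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        header_seen = False
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if tuple(c.strip() for c in line.split(",")) != _CSV_COLUMNS:
                    raise ValidationError(f"unexpected column header: {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != len(_CSV_COLUMNS):
                raise ValidationError(f"malformed row at line {lineno}: {line!r}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValidationError(
                    f"non-numeric value at line {lineno}: {line!r}"
                ) from exc
        required = {"animation_id", "animator_id", "word", "frame_rate_hz",
                    "canvas_w", "canvas_h"}
        missing = required - meta.keys()
        if missing:
            raise ValidationError(f"missing metadata keys: {sorted(missing)}")
        data = np.asarray(rows, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValidationError("recording needs at least 2 frames")
        return AnimationRecording(
            animation_id=meta["animation_id"],
            animator_id=meta["animator_id"],
            word=WordCategory(meta["word"]),
            frame_rate_hz=float(meta["frame_rate_hz"]),
            canvas_px=(int(meta["canvas_w"]), int(meta["canvas_h"])),
            t=data[:, 0],
            red_xy=data[:, 1:3],
            red_rot=data[:, 3],
            blue_xy=data[:, 4:6],
            blue_rot=data[:, 6],
        )
    if dialect == "json":
        payload = json.loads(path.read_text())
        frames = payload["frames"]
        return AnimationRecording(
            animation_id=payload["animation_id"],
            animator_id=payload["animator_id"],
            word=WordCategory(payload["word"]),
            frame_rate_hz=float(payload["frame_rate_hz"]),
            canvas_px=tuple(int(v) for v in payload["canvas_px"]),
            t=np.array([f["t"] for f in frames], dtype=float),
            red_xy=np.array(
                [[f["red"]["x_px"], f["red"]["y_px"]] for f in frames], dtype=float
            ),
            red_rot=np.array([f["red"]["rot_deg"] for f in frames], dtype=float),
            blue_xy=np.array(
                [[f["blue"]["x_px"], f["blue"]["y_px"]] for f in frames], dtype=float
            ),
            blue_rot=np.array([f["blue"]["rot_deg"] for f in frames], dtype=float),
        )
    raise ValueError(f"unknown dialect: {dialect!r}")


_RATING_COLUMNS = (
    "observer_id",
    "animation_id",
    "target_word",
    "mocking",
    "seducing",
    "surprising",
    "following",
    "fighting",
)


def write_ratings(trials: list[RatingTrial], path) -> None:
    """Write rating trials as a flat CSV, one row per (observer, animation)."""
    lines = [",".join(_RATING_COLUMNS)]
    for tr in trials:
        row = [tr.observer_id, tr.animation_id, tr.target_word.value]
        row += [_format_float(tr.ratings[WordCategory(w)]) for w in _RATING_COLUMNS[3:]]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ratings(path) -> list[RatingTrial]:
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split(",")) != _RATING_COLUMNS:
        raise ValidationError("unexpected ratings header")
    trials = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(_RATING_COLUMNS):
            raise ValidationError(f"malformed ratings row at line {lineno}")
        trials.append(
            RatingTrial(
                observer_id=parts[0],
                animation_id=parts[1],
                target_word=WordCategory(parts[2]),
                ratings={
                    WordCategory(w): float(v)
                    for w, v in zip(_RATING_COLUMNS[3:], parts[3:])
                },
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Quality control


def _visited_quadrants(rec: AnimationRecording) -> frozenset[int]:
    # Quadrants indexed 1..4 row-major: 1 = left/top half-open split of the
    # canvas; boundary points go to the lower-index quadrant (left/top).
    w, h = rec.canvas_px
    quads: set[int] = set()
    for xy in (rec.red_xy, rec.blue_xy):
        right = xy[:, 0] > w / 2
        bottom = xy[:, 1] > h / 2
        q = 1 + right.astype(int) + 2 * bottom.astype(int)
        quads.update(np.unique(q).tolist())
    return frozenset(quads)


def qc_filter(
    rec: AnimationRecording,
    min_duration_s: float = 22.5,
    min_quadrants: int = 2,
) -> QCReport:
    """Screen a recording for sufficient length and canvas coverage.

    The original screen was visual; this operationalizes it: the recording
    fails ``too_short`` when its duration is below ``min_duration_s``
    (default half of the 45 s task window) and fails
    ``insufficient_quadrant_coverage`` unless the union of quadrants visited
    by the two triangles' centroids exceeds ``min_quadrants`` (default 2,
    i.e. a pass requires more than two of the four equal canvas quadrants).
    """
    quads = _visited_quadrants(rec)
    reasons = []
    if rec.duration_s < min_duration_s:
        reasons.append("too_short")
    if len(quads) <= min_quadrants:
        reasons.append("insufficient_quadrant_coverage")
    return QCReport(
        animation_id=rec.animation_id,
        passed=not reasons,
        reasons=tuple(reasons),
        visited_quadrants=quads,
        duration_s=rec.duration_s,
    )
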