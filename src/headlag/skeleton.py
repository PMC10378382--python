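"""Keypoint schema and the in-memory skeleton sequence container.

The schema is the thirteen-landmark whole-body set emitted by video pose
trackers (head, shoulders, elbows, wrists, pelves, knees, ankles), plus the
five-landmark "domain knowledge" subset relevant to head-lag scoring
(head, both shoulders, both pelves).

Pull-to-sit (PTS) outcomes follow the Hammersmith Infant Neurological
Examination ordinal scale and are restricted to the levels 0, 1 and 3 used
for head-lag grading; level 2 is not a valid label here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SchemaError

#: Canonical ordering of the thirteen whole-body keypoints.
KEYPOINTS_13: tuple[str, ...] = (
    "head",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pelvis",
    "right_pelvis",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: The five keypoints most relevant to detecting head lag.
KEYPOINTS_5: tuple[str, ...] = (
    "head",
    "left_shoulder",
    "right_shoulder",
    "left_pelvis",
    "right_pelvis",
)

#: Valid ordinal pull-to-sit levels (0 < 1 < 3; 2 is rejected).
PTS_LEVELS: tuple[int, ...] = (0, 1, 3)

_SUBSETS = {"thirteen": KEYPOINTS_13, "five": KEYPOINTS_5}


def validate_level(level: int) -> int:
    """Validate a pull-to-sit level label, returning it as a plain int."""
    lvl = int(level)
    if lvl not in PTS_LEVELS:
        raise SchemaError(f"invalid PTS level {level!r}: must be one of {PTS_LEVELS}")
    return lvl


def keypoint_subset(name: str) -> tuple[str, ...]:
    """Resolve a subset name ('thirteen' or 'five') to an ordered keypoint tuple."""
    try:
        return _SUBSETS[name]
    except KeyError:
        raise SchemaError(
            f"unknown keypoint subset {name!r}: expected 'thirteen' or 'five'"
        ) from None


@dataclass(frozen=True)
class SkeletonSequence:
    """An ordered sequence of skeleton frames with named keypoints.

    Parameters
    ----------
    sequence_id
        Opaque identifier, preserved through I/O.
    coords
        Array of shape ``(n_frames, n_keypoints, dim)`` with ``dim`` 2 or 3.
        2D coordinates follow the image convention (y grows downward) as
        emitted by pose estimators; downstream math is convention-agnostic.
    keypoints
        Ordered keypoint names matching the second axis of ``coords``; must
        be the thirteen-keypoint schema or its five-keypoint subset.
    label
        Optional pull-to-sit level in {0, 1, 3}.
    frame_rate
        Optional frames per second, informational only.
    """

    sequence_id: str
    coords: np.ndarray
    keypoints: tuple[str, ...] = KEYPOINTS_13
    label: int | None = None
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "keypoints", tuple(self.keypoints))
        if coords.ndim != 3:
            raise SchemaError(
                f"coords must have shape (n_frames, n_keypoints, dim); got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise SchemaError("sequence must contain at least one frame")
        if coords.shape[2] not in (2, 3):
            raise SchemaError(f"dimensionality must be 2 or 3, got {coords.shape[2]}")
        if self.keypoints not in (KEYPOINTS_13, KEYPOINTS_5):
            unknown = set(self.keypoints) - set(KEYPOINTS_13)
            if unknown:
                raise SchemaError(f"unknown keypoint names: {sorted(unknown)}")
            raise SchemaError(
                "keypoints must be the full thirteen-keypoint schema or the "
                f"five-keypoint subset, got {self.keypoints}"
            )
        if coords.shape[1] != len(self.keypoints):
            raise SchemaError(
                f"coords second axis ({coords.shape[1]}) does not match "
                f"keypoint count ({len(self.keypoints)})"
            )
        bad = ~np.isfinite(coords)
        if bad.any():
            f, k, _ = np.argwhere(bad)[0]
            raise SchemaError(
                f"non-finite coordinate at frame {f}, keypoint {self.keypoints[k]!r}"
            )
        if self.label is not None:
            object.__setattr__(self, "label", validate_level(self.label))

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.coords.shape[1]

    @property
    def dimensionality(self) -> int:
        return self.coords.shape[2]

    def index_of(self, keypoint: str) -> int:
        try:
            return self.keypoints.index(keypoint)
        except ValueError:
            raise SchemaError(f"keypoint {keypoint!r} not in sequence") from None

    def frame(self, i: int) -> dict[str, np.ndarray]:
        """Return frame ``i`` as a mapping keypoint name -> coordinate array."""
        return {name: self.coords[i, j].copy() for j, name in enumerate(self.keypoints)}

    def with_coords(self, coords: np.ndarray) -> "SkeletonSequence":
        """Copy of this sequence with replaced coordinates (same metadata)."""
        return replace(self, coords=coords)


def select_keypoints(seq: SkeletonSequence, subset: str) -> SkeletonSequence:
    """Restrict a sequence to a named keypoint subset ('thirteen' or 'five').

    Selecting 'thirteen' from a thirteen-keypoint sequence is the identity;
    selecting 'five' keeps head, both shoulders and both pelves. Frame count
    and order are unchanged.
    """
    target = keypoint_subset(subset)
    if seq.keypoints == target:
        return seq
    missing = [k for k in target if k not in seq.keypoints]
    if missing:
        raise SchemaError(
            f"cannot select subset {subset!r}: sequence lacks keypoints {missing}"
        )
    idx = [seq.keypoints.index(k) for k in target]
    return replace(seq, coords=seq.coords[:, idx, :], keypoints=target)


@dataclass(frozen=True)
class CanonicalSequence:
    """A preprocessed sequence: fixed frame count, lateral view, [0, 1]² coords.

    This is the unit the fuzzy classifier consumes: exactly ``n_frames``
    frames of ``k`` keypoints, each a 2D coordinate min-max normalized per
    axis over the whole sequence.
    """

    sequence_id: str
    coords: np.ndarray  # (N, k, 2)
    keypoints: tuple[str, ...]
    label: int | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "keypoints", tuple(self.keypoints))
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise SchemaError(
                f"canonical coords must have shape (N, k, 2); got {coords.shape}"
            )
        if not np.isfinite(coords).all():
            raise SchemaError("canonical coordinates must be finite")
        if coords.min() < -1e-12 or coords.max() > 1 + 1e-12:
            raise SchemaError("canonical coordinates must lie in [0, 1]")
        if self.label is not None:
            object.__setattr__(self, "label", validate_level(self.label))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]
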