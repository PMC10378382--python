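"""Canonicalization of skeleton sequences to a normalized lateral view.

A recording may have any duration, camera angle, subject position and
scale. This module standardizes all four, in order:

1. **Frame standardization** — uniformly subsample every sequence to the
   dataset-minimum frame count ``N`` (endpoints always retained, since the
   lying start and sitting end are shared across recordings).
2. **2D→3D lifting** — a pluggable adapter contract for monocular lifting
   networks; 3D input passes through unchanged.
3. **Canonical rotation** — three planar rotations (XY, then XZ, then YZ)
   that place the first-frame torso axis (mid-pelvis → mid-shoulder) along
   +Y and the mediolateral axis (average of the two left→right vectors
   through shoulders and pelves) along ±Z, i.e. a true side view.
4. **Projection** — drop the Z axis.
5. **Min-max normalization** — per axis, over all frames × keypoints of
   the sequence, into [0, 1].

Each planar rotation is the standard 2×2 rotation
``(x, y) ↦ (x cosθ − y sinθ, x sinθ + y cosθ)`` applied to one coordinate
pair; the three together form an extrinsic Tait–Bryan decomposition, so an
exact canonicalizing rotation always maps onto this parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import (
    AdapterContractError,
    DegenerateGeometryError,
    DegenerateRangeError,
    HeadlagError,
    PipelineStageError,
)
from .skeleton import CanonicalSequence, SkeletonSequence, select_keypoints

Lifter = Callable[[dict[str, np.ndarray]], dict[str, Sequence[float]]]

_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass(frozen=True)
class RotationSpec:
    """Three planar rotation angles (radians) applied in order XY, XZ, YZ."""

    theta_xy: float
    theta_xz: float
    theta_yz: float

    def matrix(self) -> np.ndarray:
        """The composed 3×3 rotation matrix (XY applied first)."""
        return (
            _plane_matrix("yz", self.theta_yz)
            @ _plane_matrix("xz", self.theta_xz)
            @ _plane_matrix("xy", self.theta_xy)
        )


def _plane_matrix(plane: str, theta: float) -> np.ndarray:
    i, j = _PLANES[plane]
    c, s = math.cos(theta), math.sin(theta)
    rot = np.eye(3)
    rot[i, i] = c
    rot[i, j] = -s
    rot[j, i] = s
    rot[j, j] = c
    return rot


# ---------------------------------------------------------------------------
# temporal standardization
# ---------------------------------------------------------------------------


def subsample_indices(m: int, n: int) -> np.ndarray:
    """Original frame indices retained when standardizing m frames down to n.

    Uniform resampling ``round(i·(m−1)/(n−1))`` for ``i = 0..n−1`` (half
    rounds up). The first and last frames are always retained, and for
    ``m ≈ 2n`` this coincides with dropping every second frame.
    """
    if n < 1 or m < 1:
        raise HeadlagError("frame counts must be positive")
    if n > m:
        raise HeadlagError(
            f"cannot standardize {m} frames up to {n}: upsampling is refused; "
            "choose N as the dataset minimum frame count"
        )
    if n == 1:
        return np.array([0])
    pos = np.arange(n) * (m - 1) / (n - 1)
    return np.floor(pos + 0.5).astype(int)


def standardize_frames(seq: SkeletonSequence, n_frames: int) -> SkeletonSequence:
    """Subsample a sequence to exactly ``n_frames`` frames (order preserved)."""
    idx = subsample_indices(seq.n_frames, int(n_frames))
    if len(idx) == seq.n_frames:
        return seq
    return seq.with_coords(seq.coords[idx])


def choose_n(dataset: Iterable[SkeletonSequence]) -> int:
    """The standard frame count: the minimum frame count over the dataset."""
    counts = [seq.n_frames for seq in dataset]
    if not counts:
        raise HeadlagError("cannot choose N from an empty dataset")
    return min(counts)


# ---------------------------------------------------------------------------
# 2D -> 3D lifting adapter
# ---------------------------------------------------------------------------


def lift_to_3d(seq: SkeletonSequence, lifter: Lifter | None = None) -> SkeletonSequence:
    """Lift a 2D sequence to 3D through a caller-supplied adapter.

    The adapter maps one 2D frame (keypoint name → (x, y)) to one 3D frame
    over the same keypoint names. 3D input is passed through unchanged
    (monocular lifting already done upstream, or synthetic 3D data).
    """
    if seq.dimensionality == 3:
        return seq
    if lifter is None:
        raise AdapterContractError(
            "sequence is 2D and no lifting adapter was supplied; pass a "
            "lifter or provide 3D input"
        )
    lifted = np.empty((seq.n_frames, seq.n_keypoints, 3))
    for f in range(seq.n_frames):
        out = lifter(seq.frame(f))
        if set(out) != set(seq.keypoints):
            raise AdapterContractError(
                f"lifter returned keypoints {sorted(out)} for frame {f}; "
                f"expected {sorted(seq.keypoints)}"
            )
        for j, name in enumerate(seq.keypoints):
            vec = np.asarray(out[name], dtype=float)
            if vec.shape != (3,) or not np.isfinite(vec).all():
                raise AdapterContractError(
                    f"lifter returned invalid coordinates for {name!r} "
                    f"in frame {f}: {out[name]!r}"
                )
            lifted[f, j] = vec
    return seq.with_coords(lifted)


# ---------------------------------------------------------------------------
# canonical rotation
# ---------------------------------------------------------------------------


def _body_axes(frame: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    try:
        l_sh = np.asarray(frame["left_shoulder"], dtype=float)
        r_sh = np.asarray(frame["right_shoulder"], dtype=float)
        l_pel = np.asarray(frame["left_pelvis"], dtype=float)
        r_pel = np.asarray(frame["right_pelvis"], dtype=float)
    except KeyError as exc:
        raise DegenerateGeometryError(f"frame lacks keypoint {exc}") from None
    torso = (l_sh + r_sh) / 2 - (l_pel + r_pel) / 2
    mediolateral = ((r_sh - l_sh) + (r_pel - l_pel)) / 2
    return torso, mediolateral


def compute_canonical_rotation(frame: dict[str, np.ndarray]) -> RotationSpec:
    """Rotation placing the torso along +Y and the mediolateral axis along ±Z.

    The torso axis runs from the pelvis midpoint to the shoulder midpoint;
    the mediolateral axis is the average of the left→right shoulder and
    left→right pelvis vectors. The sign convention orients the body so that
    after rotation the *left* shoulder has the larger Z (all sequences face
    the same way once projected). Angles are extracted with atan2, so each
    lies in (−π, π].
    """
    torso, medio = _body_axes(frame)
    t_norm = np.linalg.norm(torso)
    m_norm = np.linalg.norm(medio)
    scale = max(t_norm, m_norm)
    if t_norm <= 1e-12 * max(scale, 1.0):
        raise DegenerateGeometryError("zero-length torso axis")
    if m_norm <= 1e-12 * max(scale, 1.0):
        raise DegenerateGeometryError("zero-length mediolateral axis")

    # left→right points toward −Z so that left-side keypoints get z ≥ right.
    e_z = -medio / m_norm
    y_raw = torso - (torso @ e_z) * e_z
    y_norm = np.linalg.norm(y_raw)
    if y_norm <= 1e-9 * t_norm:
        raise DegenerateGeometryError("torso and mediolateral axes are parallel")
    e_y = y_raw / y_norm
    e_x = np.cross(e_y, e_z)
    rot = np.stack([e_x, e_y, e_z])  # rows: target basis -> R @ torso ∝ +Y

    # Tait–Bryan extraction: rot = YZ(a) @ XZ(b) @ XY(c).
    sb = -rot[0, 2]
    cb = math.hypot(rot[0, 0], rot[0, 1])
    theta_xz = math.atan2(sb, cb)
    if cb > 1e-12:
        theta_xy = math.atan2(-rot[0, 1], rot[0, 0])
        theta_yz = math.atan2(-rot[1, 2], rot[2, 2])
    else:  # gimbal lock: XY and YZ rotations share an axis; put all in YZ
        theta_xy = 0.0
        theta_yz = math.atan2(rot[2, 1], rot[1, 1])
    return RotationSpec(theta_xy=theta_xy, theta_xz=theta_xz, theta_yz=theta_yz)


def apply_rotation(
    seq: SkeletonSequence,
    rotation: RotationSpec | str = "first_frame",
) -> SkeletonSequence:
    """Apply planar rotations (XY, then XZ, then YZ) to every frame.

    ``rotation`` is a :class:`RotationSpec`, or a policy string:
    ``'first_frame'`` computes one rigid camera correction from the first
    frame's lying posture (default — the camera is fixed within a
    recording, and per-frame canonicalization would partially cancel the
    torso-elevation signal); ``'per_frame'`` re-canonicalizes each frame.
    """
    if seq.dimensionality != 3:
        raise HeadlagError("apply_rotation requires a 3D sequence")
    if isinstance(rotation, RotationSpec):
        return seq.with_coords(seq.coords @ rotation.matrix().T)
    if rotation == "first_frame":
        spec = compute_canonical_rotation(seq.frame(0))
        return seq.with_coords(seq.coords @ spec.matrix().T)
    if rotation == "per_frame":
        out = np.empty_like(seq.coords)
        for f in range(seq.n_frames):
            spec = compute_canonical_rotation(seq.frame(f))
            out[f] = seq.coords[f] @ spec.matrix().T
        return seq.with_coords(out)
    raise HeadlagError(f"unknown rotation reference {rotation!r}")


def project_to_2d(seq: SkeletonSequence) -> SkeletonSequence:
    """Project onto the XY plane by dropping the Z coordinate."""
    if seq.dimensionality != 3:
        raise HeadlagError("project_to_2d requires a 3D sequence")
    return seq.with_coords(seq.coords[:, :, :2])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(seq: SkeletonSequence | CanonicalSequence) -> CanonicalSequence:
    """Min-max normalize each axis over all frames × keypoints into [0, 1].

    The extrema are taken per sequence (not per frame and not across the
    dataset), which standardizes subject position and size between
    recordings. A zero-range axis is a degenerate recording and raises
    :class:`DegenerateRangeError` naming the axis.
    """
    coords = np.asarray(seq.coords, dtype=float)
    if coords.shape[-1] != 2:
        raise HeadlagError("normalize requires a 2D sequence; project first")
    lo = coords.min(axis=(0, 1))
    hi = coords.max(axis=(0, 1))
    span = hi - lo
    for axis_idx, axis_name in enumerate("xy"):
        if span[axis_idx] <= 0:
            raise DegenerateRangeError(axis_name)
    out = (coords - lo) / span
    return CanonicalSequence(
        sequence_id=seq.sequence_id,
        coords=np.clip(out, 0.0, 1.0),
        keypoints=seq.keypoints,
        label=seq.label,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def preprocess_pipeline(
    seq: SkeletonSequence,
    n_frames: int,
    subset: str = "thirteen",
    lifter: Lifter | None = None,
    rotation_reference: str = "first_frame",
) -> CanonicalSequence:
    """Full canonicalization: standardize → lift → rotate → project → select → normalize.

    Deterministic given its inputs. Errors raised inside a stage are
    re-raised as :class:`PipelineStageError` naming the stage, chained to
    the original exception.
    """
    stages: list[tuple[str, Callable]] = [
        ("standardize_frames", lambda s: standardize_frames(s, n_frames)),
        ("lift_to_3d", lambda s: lift_to_3d(s, lifter)),
        ("apply_rotation", lambda s: apply_rotation(s, rotation_reference)),
        ("project_to_2d", project_to_2d),
        ("select_keypoints", lambda s: select_keypoints(s, subset)),
        ("normalize", normalize),
    ]
    out = seq
    for name, stage in stages:
        try:
            out = stage(out)
        except HeadlagError as exc:
            raise PipelineStageError(name, exc) from exc
    return out
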