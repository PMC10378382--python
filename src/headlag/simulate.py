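"""Synthetic pull-to-sit skeleton sequences with controllable head lag.

The generator is a minimal sagittal kinematic chain: a pelvis-anchored
torso segment is swept from lying (elevation 0°, torso horizontal) to
sitting (90°), a neck/head segment trails the torso axis by a per-sequence
head-lag angle, and limbs articulate with small random jitter. Shoulders
and pelves are offset along the mediolateral (Z) axis, so the underlying
motion lives in a perfect side view; a random camera rotation,
translation and uniform scale then produce the arbitrary viewing
conditions the preprocessing must undo. Isotropic Gaussian coordinate
noise (a stand-in for pose-estimator jitter) is added *before* the camera
transform.

Head-lag severity defines the class, following the Hammersmith criteria:
a head that follows the torso within 15° (side view) scores level 3,
while a head-to-torso angle beyond 30° scores level 0; level 1 sits in
between. Each preset clips its sampled lag to the corresponding band, so
class membership is guaranteed, not merely probable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, HeadlagError
from .skeleton import KEYPOINTS_13, SkeletonSequence, validate_level

#: Head-lag presets per pull-to-sit level: sampling distribution (degrees)
#: and the hard band the sample is clipped to.
LEVEL_PRESETS: dict[int, dict[str, float | tuple[float, float]]] = {
    0: {"head_lag_mean": 60.0, "head_lag_sd": 8.0, "head_lag_range": (30.0, 90.0)},
    1: {"head_lag_mean": 22.0, "head_lag_sd": 5.0, "head_lag_range": (15.0, 30.0)},
    3: {"head_lag_mean": 5.0, "head_lag_sd": 3.0, "head_lag_range": (0.0, 15.0)},
}


@dataclass(frozen=True)
class PTSMotionParams:
    """Parameters of one synthetic pull-to-sit recording.

    Angles are in degrees; segment lengths in units of the torso length.
    ``noise_sd`` is the coordinate noise standard deviation as a fraction
    of torso length. Camera ranges bound the random view transform.
    """

    n_frames: int = 90
    head_lag_mean: float = 22.0
    head_lag_sd: float = 5.0
    head_lag_range: tuple[float, float] = (15.0, 30.0)
    limb_pose_sd: float = 5.0
    noise_sd: float = 0.01
    torso_length: float = 1.0
    head_length: float = 0.35
    shoulder_width: float = 0.35
    pelvis_width: float = 0.28
    arm_length: float = 0.30
    leg_length: float = 0.45
    camera_rotation: bool = True
    camera_translation: float = 2.0
    camera_scale_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise HeadlagError("n_frames must be >= 1")
        if self.head_lag_mean < 0 or self.head_lag_sd < 0 or self.noise_sd < 0:
            raise HeadlagError("head-lag and noise parameters must be >= 0")


def params_for_level(level: int, **overrides) -> PTSMotionParams:
    """Default motion parameters for a pull-to-sit level, with overrides."""
    preset = LEVEL_PRESETS[validate_level(level)]
    merged = {**preset, **overrides}
    return PTSMotionParams(**merged)


def torso_profile(n_frames: int) -> np.ndarray:
    """Torso elevation per frame: monotone 0° → 90° with eased endpoints."""
    s = np.linspace(0.0, 1.0, n_frames)
    return 90.0 * (1.0 - np.cos(np.pi * s)) / 2.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3×3 rotation via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sagittal(angle_deg: np.ndarray | float, length: float) -> np.ndarray:
    """A segment of given length at an in-plane angle from the +Y axis.

    0° points along +Y (the lying direction); 90° along +X (upright).
    """
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return length * np.stack(
        [np.sin(a), np.cos(a), np.zeros_like(a)], axis=-1
    )


def generate_sequence(
    level: int,
    params: PTSMotionParams | None = None,
    seed: int | np.random.SeedSequence | None = None,
    sequence_id: str | None = None,
) -> SkeletonSequence:
    """Generate one labeled 3D pull-to-sit sequence.

    Deterministic given ``seed``. The sampled head-lag angle is constant
    over the sweep and clipped to the level's band, so the Hammersmith
    angular criterion holds at every frame.
    """
    level = validate_level(level)
    if params is None:
        params = params_for_level(level)
    rng = np.random.default_rng(seed)
    n = params.n_frames

    lag = rng.normal(params.head_lag_mean, params.head_lag_sd)
    lag = float(np.clip(lag, *params.head_lag_range))

    elevation = torso_profile(n)  # (n,)
    mid_pelvis = np.zeros((n, 3))
    mid_shoulder = mid_pelvis + _sagittal(elevation, params.torso_length)
    head = mid_shoulder + _sagittal(elevation - lag, params.head_length)

    z_sh = np.array([0.0, 0.0, params.shoulder_width / 2.0])
    z_pel = np.array([0.0, 0.0, params.pelvis_width / 2.0])

    def limb_jitter(size):
        return rng.normal(0.0, params.limb_pose_sd, size=size)

    # Arms raised toward the examiner's pull, legs resting along the support.
    arm_upper = elevation + 60.0 + limb_jitter((2, n))   # (side, frame)
    arm_lower = arm_upper + 15.0 + limb_jitter((2, n))
    leg_upper = limb_jitter((2, n)) * 0.5
    leg_lower = leg_upper + limb_jitter((2, n)) * 0.5

    coords = np.empty((n, 13, 3))
    kp = {name: i for i, name in enumerate(KEYPOINTS_13)}
    coords[:, kp["head"]] = head
    for s, (sign, side) in enumerate(((1.0, "left"), (-1.0, "right"))):
        shoulder = mid_shoulder + sign * z_sh
        pelvis = mid_pelvis + sign * z_pel
        elbow = shoulder + _sagittal(arm_upper[s], params.arm_length)
        wrist = elbow + _sagittal(arm_lower[s], params.arm_length)
        knee = pelvis + _sagittal(leg_upper[s], params.leg_length)
        ankle = knee + _sagittal(leg_lower[s], params.leg_length)
        coords[:, kp[f"{side}_shoulder"]] = shoulder
        coords[:, kp[f"{side}_pelvis"]] = pelvis
        coords[:, kp[f"{side}_elbow"]] = elbow
        coords[:, kp[f"{side}_wrist"]] = wrist
        coords[:, kp[f"{side}_knee"]] = knee
        coords[:, kp[f"{side}_ankle"]] = ankle

    if params.noise_sd > 0:
        coords += rng.normal(
            0.0, params.noise_sd * params.torso_length, size=coords.shape
        )

    # Fixed camera per recording: rotation, uniform scale, translation.
    if params.camera_rotation:
        coords = coords @ _random_rotation(rng).T
    lo, hi = params.camera_scale_range
    coords *= math.exp(rng.uniform(math.log(lo), math.log(hi)))
    coords += rng.uniform(-params.camera_translation, params.camera_translation, 3)

    if sequence_id is None:
        sequence_id = f"synthetic_L{level}"
    return SkeletonSequence(
        sequence_id=sequence_id,
        coords=coords,
        keypoints=KEYPOINTS_13,
        label=level,
        frame_rate=30.0,
    )


def measure_head_lag(seq: SkeletonSequence) -> np.ndarray:
    """Per-frame head-to-torso angle in degrees.

    The angle between the mid-shoulder→head segment and the torso axis
    (mid-pelvis→mid-shoulder); 0° means the head exactly continues the
    torso line. Rotation-, translation- and scale-invariant.
    """
    if seq.dimensionality != 3:
        raise HeadlagError("measure_head_lag requires a 3D sequence")
    idx = {name: seq.index_of(name) for name in
           ("head", "left_shoulder", "right_shoulder", "left_pelvis", "right_pelvis")}
    mid_sh = (seq.coords[:, idx["left_shoulder"]] + seq.coords[:, idx["right_shoulder"]]) / 2
    mid_pel = (seq.coords[:, idx["left_pelvis"]] + seq.coords[:, idx["right_pelvis"]]) / 2
    torso = mid_sh - mid_pel
    neck = seq.coords[:, idx["head"]] - mid_sh
    nt = np.linalg.norm(torso, axis=1)
    nn = np.linalg.norm(neck, axis=1)
    if (nt <= 0).any() or (nn <= 0).any():
        raise DegenerateGeometryError("zero-length torso or neck segment")
    cosang = np.einsum("ij,ij->i", torso, neck) / (nt * nn)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def generate_dataset(
    counts: dict[int, int] | None = None,
    seed: int = 0,
    overrides: dict[int, dict] | None = None,
    frame_count_range: tuple[int, int] = (90, 180),
) -> list[SkeletonSequence]:
    """Generate a labeled synthetic dataset.

    ``counts`` maps level → number of sequences; the default (84, 106, 80)
    mirrors the class balance of a realistic clinical PTS collection of
    270 recordings. Frame counts vary uniformly within
    ``frame_count_range`` to exercise temporal standardization.
    Deterministic given ``seed``; each sequence draws from an independent
    spawned stream.
    """
    if counts is None:
        counts = {0: 84, 1: 106, 3: 80}
    overrides = overrides or {}
    master = np.random.SeedSequence(int(seed))
    sequences: list[SkeletonSequence] = []
    lo, hi = frame_count_range
    if lo > hi or lo < 1:
        raise HeadlagError(f"invalid frame_count_range {frame_count_range}")
    levels = sorted(counts)
    children = master.spawn(sum(max(c, 0) for c in counts.values()))
    child_iter = iter(children)
    for level in levels:
        for i in range(counts[level]):
            child = next(child_iter)
            n_frames = int(
                np.random.default_rng(child.spawn(1)[0]).integers(lo, hi + 1)
            )
            params = params_for_level(
                level, n_frames=n_frames, **overrides.get(level, {})
            )
            sequences.append(
                generate_sequence(
                    level,
                    params=params,
                    seed=child,
                    sequence_id=f"L{level}_{i:03d}",
                )
            )
    return sequences


def manifest(sequences: list[SkeletonSequence]) -> pd.DataFrame:
    """Tabular manifest (sequence_id, label, n_frames) of a dataset."""
    return pd.DataFrame(
        {
            "sequence_id": [s.sequence_id for s in sequences],
            "label": [s.label for s in sequences],
            "n_frames": [s.n_frames for s in sequences],
        }
    )
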