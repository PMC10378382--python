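"""Instance-based fuzzy classification of canonical skeleton sequences.

For each pull-to-sit level, a bank of triangular membership functions
(MFs) — one per (frame, keypoint, axis) — is fitted from training
sequences: the triangle's apex sits at the mean coordinate Avg, its feet
at ``LB = Avg − 3·Sd`` and ``UB = Avg + 3·Sd`` (a normally distributed
coordinate falls inside with probability 99.73%). This MF bank is the
level's "prior knowledge".

A test sequence is scored against a level by

* per keypoint: ``poss = sqrt(MF_X(x) · MF_Y(y))`` (geometric mean of the
  two axis memberships),
* per frame: ``FramePoss = mean over keypoints of poss``,
* per sequence: ``fp = mean over frames of FramePoss``,

and classified as the level whose model gives the maximum final
possibility ``fp``. Ties (including the all-zero case) break to the
lowest level — the clinically conservative choice, flagging possible
delay — with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import HeadlagError, SchemaError
from .skeleton import PTS_LEVELS, CanonicalSequence, validate_level

#: Half-width of the acceptance window of a degenerate (zero-Sd) MF.
DEGENERATE_EPS = 1e-9


@dataclass(frozen=True)
class TriangularMF:
    """One triangular membership function: feet at lb/ub, apex at avg.

    ``sd`` (the fitted standard deviation) is retained for diagnostics;
    the triangle itself is fully determined by (lb, avg, ub).
    """

    lb: float
    avg: float
    ub: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.lb <= self.avg <= self.ub) or self.sd < 0:
            raise HeadlagError(
                f"invalid MF: need lb <= avg <= ub and sd >= 0, got {self}"
            )

    def __call__(self, x: float) -> float:
        return mf_value(self, x)


def fit_mf(values: Sequence[float], ddof: int = 0) -> TriangularMF:
    """Fit a triangular MF to observed coordinate values.

    Avg is the arithmetic mean and Sd the population standard deviation
    (``ddof=0``; the three-sigma bounds treat the training values as the
    distribution itself — ``ddof=1`` is exposed for sensitivity analysis).
    A single value yields the degenerate MF lb = avg = ub.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise HeadlagError("cannot fit an MF to an empty collection")
    if not np.isfinite(arr).all():
        raise HeadlagError("MF training values must be finite")
    avg = float(arr.mean())
    sd = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return TriangularMF(lb=avg - 3 * sd, avg=avg, ub=avg + 3 * sd, sd=sd)


def mf_value(mf: TriangularMF, x: float) -> float:
    """Evaluate a triangular MF at x, in [0, 1].

    Piecewise linear: rising from lb to the apex at avg, falling to ub,
    zero outside. A degenerate MF (zero width) accepts only x within
    ``DEGENERATE_EPS`` of its apex.
    """
    return float(
        _evaluate_bank(
            np.array(mf.lb), np.array(mf.avg), np.array(mf.ub), np.array(x)
        )
    )


def _evaluate_bank(
    lb: np.ndarray, avg: np.ndarray, ub: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Vectorized triangular MF evaluation, broadcasting x against the bank."""
    lo_width = avg - lb
    hi_width = ub - avg
    with np.errstate(divide="ignore", invalid="ignore"):
        rising = (x - lb) / lo_width
        falling = (ub - x) / hi_width
    val = np.where(x < avg, rising, falling)
    val = np.clip(val, 0.0, 1.0)
    degenerate = (lo_width <= 0) & (hi_width <= 0)
    if np.any(degenerate):
        val = np.where(
            degenerate,
            (np.abs(x - avg) <= DEGENERATE_EPS).astype(float),
            val,
        )
    return val


@dataclass(frozen=True)
class FuzzyLevelModel:
    """The MF bank ("prior knowledge") of one pull-to-sit level.

    Arrays ``avg`` and ``sd`` have shape (N, k, 2) — frame × keypoint ×
    axis — for N × k × 2 triangular MFs in total.
    """

    level: int
    avg: np.ndarray
    sd: np.ndarray
    keypoints: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", validate_level(self.level))
        avg = np.asarray(self.avg, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "avg", avg)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "keypoints", tuple(self.keypoints))
        if avg.ndim != 3 or avg.shape[2] != 2 or avg.shape != sd.shape:
            raise HeadlagError(
                f"MF bank arrays must share shape (N, k, 2); got {avg.shape} / {sd.shape}"
            )
        if avg.shape[1] != len(self.keypoints):
            raise HeadlagError("keypoint names do not match MF bank width")
        if (sd < 0).any():
            raise HeadlagError("MF standard deviations must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.avg.shape[0]

    @property
    def k(self) -> int:
        return self.avg.shape[1]

    @property
    def lb(self) -> np.ndarray:
        return self.avg - 3 * self.sd

    @property
    def ub(self) -> np.ndarray:
        return self.avg + 3 * self.sd

    def mf(self, frame: int, keypoint: int | str, axis: int | str) -> TriangularMF:
        """The individual MF at (frame, keypoint, axis) ('x'/'y' or 0/1)."""
        if isinstance(keypoint, str):
            keypoint = self.keypoints.index(keypoint)
        if isinstance(axis, str):
            axis = {"x": 0, "y": 1}[axis]
        avg = float(self.avg[frame, keypoint, axis])
        sd = float(self.sd[frame, keypoint, axis])
        return TriangularMF(lb=avg - 3 * sd, avg=avg, ub=avg + 3 * sd, sd=sd)


def fit_level_model(
    training: Iterable[CanonicalSequence],
    level: int | None = None,
    ddof: int = 0,
) -> FuzzyLevelModel:
    """Fit one level's MF bank from canonical training sequences.

    Every sequence must share N and the keypoint set; the MF at each
    (frame, keypoint, axis) is fitted across the sequences' coordinate
    values at that position. ``level`` defaults to the (unanimous) label
    of the training sequences.
    """
    seqs = list(training)
    if not seqs:
        raise HeadlagError("fit_level_model needs at least one training sequence")
    first = seqs[0]
    for s in seqs[1:]:
        if s.coords.shape != first.coords.shape or s.keypoints != first.keypoints:
            raise HeadlagError(
                "training sequences must share frame count and keypoint set: "
                f"{s.sequence_id!r} has shape {s.coords.shape}, expected "
                f"{first.coords.shape}"
            )
    if level is None:
        labels = {s.label for s in seqs}
        if len(labels) != 1 or None in labels:
            raise HeadlagError(
                "level not given and training labels are absent or mixed"
            )
        level = labels.pop()
    stack = np.stack([s.coords for s in seqs])  # (n_seq, N, k, 2)
    avg = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=ddof) if len(seqs) > ddof else np.zeros_like(avg)
    return FuzzyLevelModel(level=level, avg=avg, sd=sd, keypoints=first.keypoints)


# ---------------------------------------------------------------------------
# possibility computation and classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PossibilityReport:
    """Possibilities of one sequence under one or more level models.

    ``per_keypoint[level]`` has shape (N, k); ``per_frame[level]`` shape
    (N,); ``fp[level]`` is the final possibility. ``predicted`` is set by
    :func:`classify`; ``degenerate`` flags a tie broken by convention.
    """

    fp: dict[int, float]
    per_frame: dict[int, np.ndarray]
    per_keypoint: dict[int, np.ndarray]
    predicted: int | None = None
    degenerate: bool = False


def _check_compatible(seq: CanonicalSequence, model: FuzzyLevelModel) -> None:
    if seq.coords.shape[:2] != model.avg.shape[:2]:
        raise HeadlagError(
            f"sequence {seq.sequence_id!r} has shape {seq.coords.shape[:2]}, "
            f"model for level {model.level} expects {model.avg.shape[:2]}"
        )
    if seq.keypoints != model.keypoints:
        raise HeadlagError(
            f"sequence {seq.sequence_id!r} keypoints do not match model "
            f"for level {model.level}"
        )


def _poss_grid(coords: np.ndarray, model: FuzzyLevelModel) -> np.ndarray:
    """Per-keypoint possibilities; coords (..., N, k, 2) -> (..., N, k)."""
    memb = _evaluate_bank(model.lb, model.avg, model.ub, coords)
    return np.sqrt(memb[..., 0] * memb[..., 1])


def possibility(seq: CanonicalSequence, model: FuzzyLevelModel) -> PossibilityReport:
    """Score one sequence under one level model (no classification)."""
    _check_compatible(seq, model)
    poss = _poss_grid(seq.coords, model)
    frame_poss = poss.mean(axis=-1)
    fp = float(frame_poss.mean())
    return PossibilityReport(
        fp={model.level: fp},
        per_frame={model.level: frame_poss},
        per_keypoint={model.level: poss},
    )


def classify(
    seq: CanonicalSequence, models: dict[int, FuzzyLevelModel]
) -> PossibilityReport:
    """Classify a sequence by maximum final possibility over the level models.

    All three levels must be present. Equal maximal fp values (including
    all-zero) break to the lowest level with a warning.
    """
    missing = [lvl for lvl in PTS_LEVELS if lvl not in models]
    if missing:
        raise HeadlagError(f"missing level models: {missing}")
    fp: dict[int, float] = {}
    per_frame: dict[int, np.ndarray] = {}
    per_keypoint: dict[int, np.ndarray] = {}
    for lvl in PTS_LEVELS:
        rep = possibility(seq, models[lvl])
        fp[lvl] = rep.fp[lvl]
        per_frame[lvl] = rep.per_frame[lvl]
        per_keypoint[lvl] = rep.per_keypoint[lvl]
    best = max(fp.values())
    winners = [lvl for lvl in PTS_LEVELS if fp[lvl] == best]
    degenerate = len(winners) > 1
    if degenerate:
        warnings.warn(
            f"sequence {seq.sequence_id!r}: tied final possibilities "
            f"{fp}; predicting lowest level {winners[0]}",
            stacklevel=2,
        )
    return PossibilityReport(
        fp=fp,
        per_frame=per_frame,
        per_keypoint=per_keypoint,
        predicted=winners[0],
        degenerate=degenerate,
    )


def classify_batch(
    coords: np.ndarray, models: dict[int, FuzzyLevelModel]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized classification of stacked canonical coordinates.

    ``coords`` has shape (n_seq, N, k, 2). Returns ``(predicted, fps)``
    where ``predicted`` is (n_seq,) of levels and ``fps`` is (n_seq, 3)
    ordered by level (0, 1, 3). Ties break to the lowest level silently
    (argmax over the level-ordered axis).
    """
    fps = np.stack(
        [_poss_grid(coords, models[lvl]).mean(axis=(-2, -1)) for lvl in PTS_LEVELS],
        axis=-1,
    )
    predicted = np.asarray(PTS_LEVELS)[np.argmax(fps, axis=-1)]
    return predicted, fps


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_models(models: dict[int, FuzzyLevelModel], path) -> None:
    """Write level models to a structured-text (YAML) file.

    Per level: N, k, keypoint order, then per (frame, keypoint) the four
    numbers LB, Avg, UB, Sd for X and for Y. Floats round-trip exactly.
    """
    docs = []
    for lvl in sorted(models):
        m = models[lvl]
        lb, ub = m.lb, m.ub
        frames = []
        for f in range(m.n_frames):
            per_kp = {}
            for j, name in enumerate(m.keypoints):
                per_kp[name] = {
                    axis: [
                        float(arr[f, j, a])
                        for arr in (lb, m.avg, ub, m.sd)
                    ]
                    for a, axis in enumerate(("x", "y"))
                }
            frames.append(per_kp)
        docs.append(
            {
                "level": int(m.level),
                "n_frames": m.n_frames,
                "k": m.k,
                "keypoints": list(m.keypoints),
                "mfs": frames,  # each entry: {keypoint: {axis: [LB, Avg, UB, Sd]}}
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"levels": docs}, fh, sort_keys=False)


def load_models(path) -> dict[int, FuzzyLevelModel]:
    """Read level models written by :func:`save_models`."""
    with open(Path(path), "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "levels" not in doc:
        raise SchemaError(f"{path}: not a model file")
    models: dict[int, FuzzyLevelModel] = {}
    for entry in doc["levels"]:
        keypoints = tuple(entry["keypoints"])
        n, k = int(entry["n_frames"]), int(entry["k"])
        avg = np.empty((n, k, 2))
        sd = np.empty((n, k, 2))
        for f, per_kp in enumerate(entry["mfs"]):
            for j, name in enumerate(keypoints):
                for a, axis in enumerate(("x", "y")):
                    _, avg[f, j, a], _, sd[f, j, a] = per_kp[name][axis]
        models[int(entry["level"])] = FuzzyLevelModel(
            level=int(entry["level"]), avg=avg, sd=sd, keypoints=keypoints
        )
    return models
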