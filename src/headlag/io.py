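"""Plain-text I/O for skeleton sequences.

Two dialects are supported:

* **long-table** (``.csv``): one row per frame x keypoint, header
  ``sequence_id,frame,keypoint,x,y[,z]``; the ``z`` column is absent for 2D
  data. Metadata travels in leading comment lines such as ``# label=3``.
  Frames are 0-based and contiguous.
* **structured-text** (``.yaml``): one YAML document per sequence with
  fields ``sequence_id``, ``label``, ``dimensionality``, ``frame_rate``,
  ``keypoints`` and ``frames`` (a list of per-frame keypoint maps).

Coordinates are written with 17 significant digits so a write/read
round-trip is bit-exact for float64.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .skeleton import KEYPOINTS_13, KEYPOINTS_5, CanonicalSequence, SkeletonSequence

_FMT = "%.17g"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("long-table", "structured-text"):
            raise SchemaError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix.lower() in (".yaml", ".yml"):
        return "structured-text"
    return "long-table"


def _keypoint_order(names: set[str]) -> tuple[str, ...]:
    """Map a set of keypoint names to the canonical schema ordering."""
    if names == set(KEYPOINTS_13):
        return KEYPOINTS_13
    if names == set(KEYPOINTS_5):
        return KEYPOINTS_5
    unknown = names - set(KEYPOINTS_13)
    if unknown:
        raise SchemaError(f"unknown keypoint names: {sorted(unknown)}")
    missing13 = set(KEYPOINTS_13) - names
    missing5 = set(KEYPOINTS_5) - names
    shorter = missing5 if len(missing5) < len(missing13) else missing13
    raise SchemaError(f"incomplete keypoint set: missing {sorted(shorter)}")


# ---------------------------------------------------------------------------
# long-table dialect
# ---------------------------------------------------------------------------


def _read_long_table(path: Path) -> SkeletonSequence:
    meta: dict[str, str] = {}
    body_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                item = line[1:].strip()
                if "=" in item:
                    key, _, value = item.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            body_lines.append(line)
    if not body_lines:
        raise SchemaError(f"{path}: empty long-table file")
    df = pd.read_csv(
        _io.StringIO("".join(body_lines)),
        dtype={"keypoint": str},
        float_precision="round_trip",
    )
    required = {"sequence_id", "frame", "keypoint", "x", "y"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: long-table header must contain {sorted(required)}"
        )
    dim = 3 if "z" in df.columns else 2

    names = _keypoint_order(set(df["keypoint"]))
    frames = np.sort(df["frame"].unique())
    n = len(frames)
    if not np.array_equal(frames, np.arange(n)):
        raise SchemaError(f"{path}: frame indices must be 0-based and contiguous")

    axes = ["x", "y", "z"][:dim]
    coords = np.full((n, len(names), dim), np.nan)
    kp_index = {k: j for j, k in enumerate(names)}
    fi = df["frame"].to_numpy()
    ki = df["keypoint"].map(kp_index).to_numpy()
    coords[fi, ki] = df[axes].to_numpy(dtype=float)

    nan_cells = np.isnan(coords).any(axis=2)
    if nan_cells.any():
        f, k = np.argwhere(nan_cells)[0]
        raise SchemaError(
            f"{path}: missing keypoint {names[k]!r} in frame {f}"
        )

    seq_ids = df["sequence_id"].unique()
    if len(seq_ids) != 1:
        raise SchemaError(f"{path}: file must contain exactly one sequence_id")

    label = int(meta["label"]) if "label" in meta else None
    frame_rate = float(meta["frame_rate"]) if "frame_rate" in meta else None
    return SkeletonSequence(
        sequence_id=str(seq_ids[0]),
        coords=coords,
        keypoints=names,
        label=label,
        frame_rate=frame_rate,
    )


def _write_long_table(seq: SkeletonSequence, path: Path) -> None:
    dim = seq.dimensionality
    axes = ["x", "y", "z"][:dim]
    with open(path, "w", encoding="utf-8") as fh:
        if seq.label is not None:
            fh.write(f"# label={seq.label}\n")
        if seq.frame_rate is not None:
            fh.write(f"# frame_rate={_FMT % seq.frame_rate}\n")
        fh.write("sequence_id,frame,keypoint," + ",".join(axes) + "\n")
        for f in range(seq.n_frames):
            for j, name in enumerate(seq.keypoints):
                vals = ",".join(_FMT % v for v in seq.coords[f, j])
                fh.write(f"{seq.sequence_id},{f},{name},{vals}\n")


# ---------------------------------------------------------------------------
# structured-text dialect
# ---------------------------------------------------------------------------


def _read_structured(path: Path) -> SkeletonSequence:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: structured-text file must hold one mapping")
    for key in ("sequence_id", "dimensionality", "frames"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    dim = int(doc["dimensionality"])
    raw_frames = doc["frames"]
    if not raw_frames:
        raise SchemaError(f"{path}: 'frames' must be non-empty")
    names = _keypoint_order(set(raw_frames[0]))
    coords = np.full((len(raw_frames), len(names), dim), np.nan)
    for f, frame in enumerate(raw_frames):
        for j, name in enumerate(names):
            if name not in frame:
                raise SchemaError(f"{path}: missing keypoint {name!r} in frame {f}")
            vec = frame[name]
            if len(vec) != dim:
                raise SchemaError(
                    f"{path}: frame {f} keypoint {name!r} has {len(vec)} "
                    f"coordinates, expected {dim}"
                )
            coords[f, j] = vec
        extra = set(frame) - set(names)
        if extra:
            raise SchemaError(f"{path}: unknown keypoint names: {sorted(extra)}")
    return SkeletonSequence(
        sequence_id=str(doc["sequence_id"]),
        coords=coords,
        keypoints=names,
        label=doc.get("label"),
        frame_rate=doc.get("frame_rate"),
    )


def _write_structured(seq: SkeletonSequence, path: Path) -> None:
    doc: dict = {
        "sequence_id": seq.sequence_id,
        "label": seq.label,
        "dimensionality": seq.dimensionality,
        "frame_rate": seq.frame_rate,
        "keypoints": list(seq.keypoints),
        "frames": [
            {name: [float(v) for v in seq.coords[f, j]]
             for j, name in enumerate(seq.keypoints)}
            for f in range(seq.n_frames)
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------


def read_sequence(path, format: str | None = None) -> SkeletonSequence:
    """Read a skeleton sequence from a long-table or structured-text file.

    ``format`` may be 'long-table', 'structured-text', or None to infer
    from the file suffix (.yaml/.yml -> structured-text, else long-table).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "structured-text":
        return _read_structured(path)
    return _read_long_table(path)


def write_sequence(seq: SkeletonSequence, path, format: str | None = None) -> None:
    """Write a skeleton sequence; the emitted file re-reads to an equal one."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "structured-text":
        _write_structured(seq, path)
    else:
        _write_long_table(seq, path)


def write_canonical(seq: CanonicalSequence, path) -> None:
    """Write a canonical sequence in the long-table dialect.

    A ``# canonical N=<N> k=<k>`` comment records the standardized shape.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# canonical N={seq.n_frames} k={seq.k}\n")
        if seq.label is not None:
            fh.write(f"# label={seq.label}\n")
        fh.write("sequence_id,frame,keypoint,x,y\n")
        for f in range(seq.n_frames):
            for j, name in enumerate(seq.keypoints):
                vals = ",".join(_FMT % v for v in seq.coords[f, j])
                fh.write(f"{seq.sequence_id},{f},{name},{vals}\n")


def read_canonical(path) -> CanonicalSequence:
    """Read a canonical sequence written by :func:`write_canonical`."""
    seq = _read_long_table(Path(path))
    if seq.dimensionality != 2:
        raise SchemaError(f"{path}: canonical sequences are 2D")
    return CanonicalSequence(
        sequence_id=seq.sequence_id,
        coords=seq.coords,
        keypoints=seq.keypoints,
        label=seq.label,
    )
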