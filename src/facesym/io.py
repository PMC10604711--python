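"""Landmark-frame and depth-image I/O.

Consumes the per-frame CSV emitted by facial-landmark trackers in the
OpenFace dialect (2D pixel columns ``x_0..x_67``/``y_0..y_67``, 3D columns
``X_*``/``Y_*``/``Z_*`` with depth in mm, head-pose angles, confidence and
success flags) and 16-bit single-channel depth images in mm.  Both space
padded and plain headers occur in the wild; columns are matched by stripped
name, never by position.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import EmptySequenceError, FormatError

__all__ = [
    "LandmarkFrame",
    "FrameSequence",
    "DepthImage",
    "read_openface_csv",
    "write_openface_csv",
    "select_min_yaw_frame",
    "read_depth_image",
    "write_depth_image",
    "read_manifest",
]

#: Default confidence floor below which frames are dropped before analysis.
DEFAULT_CONFIDENCE_FLOOR = 0.75


@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame's facial landmarks with pose and quality metadata.

    ``points`` holds the 3D landmark coordinates as an (n, 3) float array:
    x (px, rightward), y (px, downward, image origin top-left) and z (depth,
    mm).  The 2D pixel landmarks are by construction the (x, y) columns of
    the same array — z is the added channel.
    """

    frame_index: int
    points: np.ndarray  # (n_landmarks, 3): x px, y px, z mm
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    confidence: float = 1.0
    success: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.isfinite([self.yaw, self.pitch, self.roll]).all():
            raise ValueError("pose angles must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    @property
    def landmarks_2d(self) -> np.ndarray:
        """(n, 2) pixel coordinates."""
        return self.points[:, :2]

    @property
    def landmarks_3d(self) -> np.ndarray:
        """(n, 3) coordinates (x px, y px, z mm)."""
        return self.points

    def replace(self, **kwargs) -> "LandmarkFrame":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class FrameSequence:
    """Ordered frames of one subject's capture session."""

    frames: tuple[LandmarkFrame, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class DepthImage:
    """H×W grid of depth values in mm; 0 marks an invalid pixel (no return)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("depth image must be a 2-D grid")
        if np.any(vals < 0):
            raise ValueError("depth values must be >= 0")
        object.__setattr__(self, "values", vals)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# OpenFace-dialect CSV


def _landmark_columns(columns: Sequence[str], prefix: str) -> list[str]:
    pat = re.compile(rf"^{re.escape(prefix)}_(\d+)$")
    hits = sorted(
        (int(m.group(1)), c) for c in columns if (m := pat.match(c)) is not None
    )
    return [c for _, c in hits]


def read_openface_csv(
    path: str | Path,
    *,
    n_landmarks: int = 68,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    exclude_frames: Iterable[int] = (),
    subject_id: str | None = None,
) -> FrameSequence:
    """Read a per-frame landmark CSV in the OpenFace dialect.

    Frames flagged ``success == 0`` or with confidence below
    ``confidence_floor`` are dropped, as are frame indices listed in
    ``exclude_frames`` (the hook for manually flagged closed-eye or
    otherwise unusable frames).  Row order is preserved.  Units pass
    through unchanged: x, y in pixels, Z in mm.

    Raises
    ------
    FormatError
        If a required column is missing or the landmark count is wrong.
    EmptySequenceError
        If no frame survives filtering.
    """
    path = Path(path)
    # round_trip parsing keeps write-then-read coordinate identity bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]

    for col in ("frame", "success"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")

    x2d = _landmark_columns(df.columns, "x")
    y2d = _landmark_columns(df.columns, "y")
    x3d = _landmark_columns(df.columns, "X")
    y3d = _landmark_columns(df.columns, "Y")
    z3d = _landmark_columns(df.columns, "Z")
    for name, cols in (("x", x2d), ("y", y2d), ("X", x3d), ("Y", y3d), ("Z", z3d)):
        if not cols:
            raise FormatError(f"{path}: missing per-landmark columns '{name}_*'")
        if len(cols) != n_landmarks:
            raise FormatError(
                f"{path}: expected {n_landmarks} '{name}_*' columns, "
                f"found {len(cols)}"
            )

    if "yaw" in df.columns:
        yaw = df["yaw"].to_numpy(float)
        pitch = df.get("pitch", pd.Series(0.0, index=df.index)).to_numpy(float)
        roll = df.get("roll", pd.Series(0.0, index=df.index)).to_numpy(float)
    elif "pose_Ry" in df.columns:
        # OpenFace stores head pose in radians: Rx pitch, Ry yaw, Rz roll.
        yaw = np.degrees(df["pose_Ry"].to_numpy(float))
        pitch = np.degrees(df.get("pose_Rx", pd.Series(0.0, index=df.index)).to_numpy(float))
        roll = np.degrees(df.get("pose_Rz", pd.Series(0.0, index=df.index)).to_numpy(float))
    else:
        raise FormatError(
            f"{path}: missing pose columns ('pose_Ry' or 'yaw')"
        )

    conf = (
        df["confidence"].to_numpy(float)
        if "confidence" in df.columns
        else np.ones(len(df))
    )
    success = df["success"].to_numpy()
    frame_idx = df["frame"].to_numpy(int)
    excluded = set(int(i) for i in exclude_frames)

    X = df[x3d].to_numpy(float)
    Y = df[y3d].to_numpy(float)
    Z = df[z3d].to_numpy(float)

    frames = []
    for i in range(len(df)):
        if not bool(success[i]) or conf[i] < confidence_floor:
            continue
        if frame_idx[i] in excluded:
            continue
        pts = np.column_stack([X[i], Y[i], Z[i]])
        frames.append(
            LandmarkFrame(
                frame_index=int(frame_idx[i]),
                points=pts,
                yaw=float(yaw[i]),
                pitch=float(pitch[i]),
                roll=float(roll[i]),
                confidence=float(conf[i]),
                success=True,
            )
        )
    if not frames:
        raise EmptySequenceError(f"{path}: no successful frames after filtering")
    return FrameSequence(frames=tuple(frames), subject_id=subject_id or path.stem)


def write_openface_csv(seq: FrameSequence, path: str | Path) -> None:
    """Write a FrameSequence as an OpenFace-dialect CSV.

    Coordinates are written at full ``repr`` precision so a write-then-read
    round trip reproduces them bit-exactly.  The 2D pixel columns duplicate
    the (x, y) of the 3D columns, as the tracker's own output does for the
    aligned streams consumed here.
    """
    n = seq.frames[0].n_landmarks
    cols: dict[str, list] = {
        "frame": [],
        "confidence": [],
        "success": [],
        "pose_Rx": [],
        "pose_Ry": [],
        "pose_Rz": [],
    }
    for prefix in ("x", "y", "X", "Y", "Z"):
        for i in range(n):
            cols[f"{prefix}_{i}"] = []
    for f in seq.frames:
        cols["frame"].append(f.frame_index)
        cols["confidence"].append(f.confidence)
        cols["success"].append(int(f.success))
        cols["pose_Rx"].append(np.radians(f.pitch))
        cols["pose_Ry"].append(np.radians(f.yaw))
        cols["pose_Rz"].append(np.radians(f.roll))
        for i in range(n):
            cols[f"x_{i}"].append(f.points[i, 0])
            cols[f"y_{i}"].append(f.points[i, 1])
            cols[f"X_{i}"].append(f.points[i, 0])
            cols[f"Y_{i}"].append(f.points[i, 1])
            cols[f"Z_{i}"].append(f.points[i, 2])
    pd.DataFrame(cols).to_csv(path, index=False)


def select_min_yaw_frame(seq: FrameSequence) -> LandmarkFrame:
    """The frame with the smallest absolute yaw angle.

    The near-frontal frame minimizes out-of-plane foreshortening before the
    mirror comparison.  Ties on \\|yaw\\| are broken by the smallest frame
    index, which makes the choice order-stable.
    """
    if len(seq) == 0:
        raise EmptySequenceError("cannot select a frame from an empty sequence")
    return min(seq.frames, key=lambda f: (abs(f.yaw), f.frame_index))


# ---------------------------------------------------------------------------
# Depth images


def read_depth_image(path: str | Path) -> DepthImage:
    """Read a 16-bit single-channel depth image (values in mm).

    Raises
    ------
    FormatError
        For multi-channel or non-16-bit input.
    """
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: depth image must be single-channel, got shape {arr.shape}")
    if arr.dtype != np.uint16:
        raise FormatError(f"{path}: depth image must be 16-bit, got dtype {arr.dtype}")
    return DepthImage(values=arr)


def write_depth_image(depth: DepthImage, path: str | Path) -> None:
    """Write a depth image as 16-bit PNG (lossless for integer mm)."""
    vals = np.asarray(depth.values)
    if vals.dtype != np.uint16:
        if np.any(vals < 0) or np.any(vals > np.iinfo(np.uint16).max):
            raise ValueError("depth values out of uint16 range")
        vals = vals.astype(np.uint16)
    iio.imwrite(Path(path), vals)


# ---------------------------------------------------------------------------
# Cohort manifests


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: ``subject_id``, ``group``, ``landmark_csv_path``;
    optional: ``depth_png_path``.  Relative paths are resolved against the
    manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    for col in ("subject_id", "group", "landmark_csv_path"):
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing column '{col}'")
    base = path.parent
    df["landmark_csv_path"] = [
        str((base / p)) if not Path(p).is_absolute() else str(p)
        for p in df["landmark_csv_path"]
    ]
    if "depth_png_path" in df.columns:
        df["depth_png_path"] = [
            None if (pd.isna(p) or p == "") else (str(base / p) if not Path(p).is_absolute() else str(p))
            for p in df["depth_png_path"]
        ]
    else:
        df["depth_png_path"] = None
    return df
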