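"""Depth repair for facial contour landmarks.

Stereo and structured-light cameras return unreliable depth exactly where
the face silhouette meets the background, which is where the jawline
landmarks sit.  The repair splits the depth image into a near (face) and a
far (background) cluster with 1-D 2-means, then replaces the depth of any
landmark whose pixel landed in the background cluster by the mean depth of
the face pixels inside a 7×7 window around it; if the whole window is
background, the median depth of all landmarks (pre-repair) is used instead.
Only z is ever modified — pixel coordinates are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateInputError
from .io import DepthImage, LandmarkFrame

__all__ = ["ForegroundMask", "cluster_foreground", "repair_landmark_depths"]

WINDOW_HALF = 3  # 7×7 replacement window


@dataclass(frozen=True)
class ForegroundMask:
    """Binary face/background labelling of a depth image.

    ``labels`` is True where the pixel belongs to the face (near) cluster.
    Invalid pixels (depth 0) are always labelled background.
    """

    labels: np.ndarray  # bool H×W, True = face
    face_mean_depth: float
    background_mean_depth: float

    def __post_init__(self) -> None:
        if self.face_mean_depth >= self.background_mean_depth:
            raise ValueError("face cluster must be nearer than background")


def cluster_foreground(depth: DepthImage, seed: int = 0) -> ForegroundMask:
    """Split a depth image into face and background clusters.

    K-means with k=2 (k-means++ init, 10 restarts, seeded) on the 1-D valid
    (nonzero) depth values; the cluster with the smaller mean depth is the
    face.  One-dimensional 2-means is effectively deterministic; the
    restarts only guard against pathological initializations.
    """
    vals = np.asarray(depth.values, dtype=float)
    valid = vals > 0
    valid_vals = vals[valid]
    if np.unique(valid_vals).size < 2:
        raise DegenerateInputError(
            "depth image needs at least 2 distinct valid depth values to cluster"
        )
    km = KMeans(n_clusters=2, init="k-means++", n_init=10, random_state=seed)
    assignments = km.fit_predict(valid_vals.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    face_cluster = int(np.argmin(centers))

    labels = np.zeros(vals.shape, dtype=bool)
    labels[valid] = assignments == face_cluster
    face_mean = float(valid_vals[assignments == face_cluster].mean())
    bg_vals = valid_vals[assignments != face_cluster]
    bg_mean = float(bg_vals.mean()) if bg_vals.size else float("inf")
    return ForegroundMask(
        labels=labels, face_mean_depth=face_mean, background_mean_depth=bg_mean
    )


def _pixel_positions(frame: LandmarkFrame, shape: tuple[int, int]) -> np.ndarray:
    """Landmark pixel (row, col) positions, clipped to the image bounds."""
    h, w = shape
    cols = np.clip(np.rint(frame.points[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.rint(frame.points[:, 1]).astype(int), 0, h - 1)
    return np.column_stack([rows, cols])


def repair_landmark_depths(
    frame: LandmarkFrame, mask: ForegroundMask, depth: DepthImage
) -> LandmarkFrame:
    """Replace background-contaminated landmark depths.

    For each landmark whose pixel is background-labelled, z becomes the mean
    depth of face-labelled pixels in the 7×7 window centred on it (clipped
    at image borders); with no face pixel in the window, z becomes the
    median of all landmark depths taken before any repair (single pass, so
    the result is independent of landmark order).  Landmarks on face pixels
    and all x, y coordinates are unchanged.
    """
    if mask.labels.shape != depth.values.shape:
        raise ValueError("mask and depth image dimensions differ")
    vals = np.asarray(depth.values, dtype=float)
    pos = _pixel_positions(frame, vals.shape)
    h, w = vals.shape

    pre_repair_median = float(np.median(frame.points[:, 2]))
    new_points = frame.points.copy()
    n_repaired = 0
    for i, (r, c) in enumerate(pos):
        if mask.labels[r, c]:
            continue
        r0, r1 = max(0, r - WINDOW_HALF), min(h, r + WINDOW_HALF + 1)
        c0, c1 = max(0, c - WINDOW_HALF), min(w, c + WINDOW_HALF + 1)
        window_face = mask.labels[r0:r1, c0:c1]
        if window_face.any():
            new_points[i, 2] = vals[r0:r1, c0:c1][window_face].mean()
        else:
            new_points[i, 2] = pre_repair_median
        n_repaired += 1
    if n_repaired == 0:
        return frame
    return frame.replace(points=new_points)
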