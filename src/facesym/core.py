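"""Landmark superimposition asymmetry distances (LSADs).

The measure compares a face with its own mirror image.  The landmark set is
reflected about a vertical axis and relabelled so left and right swap roles;
the right hemiface of the mirror is then the (reflected) left hemiface of
the original.  Both 29-point right hemifaces are normalized — per-axis in
the image plane by the mean absolute deviation of the landmarks from their
centroid (``dx`` horizontally, ``dy`` vertically), and in depth by a scalar
coefficient ``c`` that weights millimetres into the normalized frame — and
rigidly superimposed (rotation + translation, no scaling, no reflection) by
minimizing the summed squared 3D alignment error.  The residual in-plane
distance left at each landmark pair after this best rigid fit is that
pair's LSAD; depth residuals are deliberately excluded from the distance
itself, depth only steers the fit.

A perfectly bilaterally symmetric face therefore scores 0 at every pair,
and the measures are invariant to translation, camera distance and
per-axis image scale by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, PipelineStageError
from .io import DepthImage, FrameSequence, LandmarkFrame, select_min_yaw_frame
from .pairs import PairTable, default_pair_table

__all__ = [
    "NormCoefficients",
    "NormalizedHemiface",
    "AlignmentResult",
    "LSADProfile",
    "DEFAULT_DEPTH_COEFFICIENT",
    "normalization_coefficients",
    "mirror_frame",
    "normalize_hemiface",
    "procrustes_align",
    "compute_lsads",
    "lsad_pipeline",
]

#: Depth coefficient selected by significance-count maximization on the
#: study cohort the method was developed on.
DEFAULT_DEPTH_COEFFICIENT = 0.016


@dataclass(frozen=True)
class NormCoefficients:
    """Per-axis normalization: dx, dy in px; c the unitless depth weight."""

    dx: float
    dy: float
    c: float = DEFAULT_DEPTH_COEFFICIENT

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise DegenerateGeometryError("dx and dy must be positive")
        if self.c < 0:
            raise ValueError("depth coefficient c must be >= 0")


@dataclass(frozen=True)
class NormalizedHemiface:
    """29 normalized right-hemiface coordinates, centred on their centroid."""

    points: np.ndarray  # (n_pairs, 3)
    centroid_used: np.ndarray  # (3,) raw-unit centroid subtracted
    coeffs: NormCoefficients


@dataclass(frozen=True)
class AlignmentResult:
    """Best rigid superimposition of the original hemiface onto the mirror."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,), zero for centred inputs
    aligned_points: np.ndarray  # (n_pairs, 3)
    sum_squared_error: float


@dataclass(frozen=True)
class LSADProfile:
    """Per-pair asymmetry distances and their sum for one subject."""

    lsad: np.ndarray  # (n_pairs,), >= 0, indexed by pair label order
    lsad_sum: float


def normalization_coefficients(frame: LandmarkFrame) -> NormCoefficients:
    """In-plane normalization coefficients from all landmarks of a frame.

    ``dx`` is the mean absolute horizontal distance between each landmark
    and the landmark centroid; ``dy`` likewise vertically.  Dividing by
    them removes the dependence on face size and camera distance in the
    image plane.  Depth needs no such factor — landmark depth differences
    do not change when the subject moves along the camera axis — so ``c``
    is left at its default here and supplied by the caller downstream.
    """
    xy = frame.points[:, :2]
    centroid = xy.mean(axis=0)
    dev = np.abs(xy - centroid)
    dx, dy = dev.mean(axis=0)
    if dx <= 0 or dy <= 0:
        raise DegenerateGeometryError(
            "landmarks are colinear along an axis; normalization undefined"
        )
    return NormCoefficients(dx=float(dx), dy=float(dy))


def mirror_frame(frame: LandmarkFrame, pairs: PairTable | None = None) -> LandmarkFrame:
    """Horizontally flipped, relabelled copy of a frame.

    Every x is reflected about the vertical axis through the landmark
    centroid (x -> 2x̄ − x); y and z are unchanged.  Left/right pair
    indices are then swapped so the mirror keeps the standard landmark
    ordering; midline indices keep their slots.  Any vertical axis would
    give identical LSADs (centring removes translation); the centroid axis
    keeps intermediate values small.  Mirroring is an involution.
    """
    if pairs is None:
        pairs = default_pair_table()
    x_bar = frame.points[:, 0].mean()
    reflected = frame.points.copy()
    reflected[:, 0] = 2.0 * x_bar - reflected[:, 0]
    perm = pairs.swap_permutation()
    return frame.replace(points=reflected[perm], yaw=-frame.yaw, roll=-frame.roll)


def normalize_hemiface(
    frame: LandmarkFrame,
    pairs: PairTable | None = None,
    coeffs: NormCoefficients | None = None,
) -> NormalizedHemiface:
    """Extract and normalize the 29 right-hemiface landmarks.

    The hemiface's own 3D centroid is subtracted, x is divided by ``dx``,
    y by ``dy`` and the centred z is multiplied by ``c``.  ``dx``/``dy``
    are computed once from the original frame's full landmark set and
    shared with the mirror (reflection preserves absolute deviations, so
    this is self-consistent).
    """
    if pairs is None:
        pairs = default_pair_table()
    if coeffs is None:
        coeffs = normalization_coefficients(frame)
    hemi = frame.points[pairs.right_indices]
    centroid = hemi.mean(axis=0)
    centred = hemi - centroid
    norm = np.empty_like(centred)
    norm[:, 0] = centred[:, 0] / coeffs.dx
    norm[:, 1] = centred[:, 1] / coeffs.dy
    norm[:, 2] = coeffs.c * centred[:, 2]
    return NormalizedHemiface(points=norm, centroid_used=centroid, coeffs=coeffs)


def _kabsch(P: np.ndarray, Q: np.ndarray, allow_scaling: bool) -> tuple[np.ndarray, float]:
    """Proper rotation R (and scale s) minimizing ||s R P - Q||^2 for centred sets."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scaling:
        denom = (P * P).sum()
        s = float((S * np.diag(D)).sum() / denom) if denom > 0 else 1.0
    else:
        s = 1.0
    return R, s


def procrustes_align(
    original: NormalizedHemiface,
    mirror: NormalizedHemiface,
    *,
    allow_scaling: bool = False,
) -> AlignmentResult:
    """Rigid superimposition of the original hemiface onto the mirror.

    Solves the orthogonal Procrustes problem in closed form (Kabsch SVD)
    for the proper rotation minimizing the summed squared 3D alignment
    error; improper solutions (reflections) are forbidden by the
    determinant correction, which also resolves rank-deficient point sets
    deterministically.  Both inputs are already centred, so the optimal
    translation is zero.  ``allow_scaling`` switches to a similarity fit
    for sensitivity analysis; the standard measure is rigid.
    """
    P = original.points
    Q = mirror.points
    if P.shape != Q.shape:
        raise ValueError("hemifaces must have matching point counts")
    R, s = _kabsch(P, Q, allow_scaling)
    aligned = s * (P @ R.T)
    resid = aligned - Q
    return AlignmentResult(
        rotation=R,
        translation=np.zeros(3),
        aligned_points=aligned,
        sum_squared_error=float((resid * resid).sum()),
    )


def compute_lsads(
    alignment: AlignmentResult,
    mirror: NormalizedHemiface,
    pairs: PairTable | None = None,
) -> LSADProfile:
    """Per-pair in-plane residual distances after the rigid fit.

    LSAD_i is the 2D (x, y) Euclidean distance between the aligned original
    hemiface point and its mirror counterpart; depth residuals are excluded
    from the distance by design — depth participates only in the alignment
    objective.  The profile's sum is the aggregate asymmetry measure.
    """
    diff = alignment.aligned_points[:, :2] - mirror.points[:, :2]
    lsad = np.sqrt((diff * diff).sum(axis=1))
    return LSADProfile(lsad=lsad, lsad_sum=float(lsad.sum()))


def _pipeline_stages(
    seq: FrameSequence,
    depth: DepthImage | None,
    pairs: PairTable,
    seed: int,
):
    """Shared front half of the pipeline: frame choice, repair, mirror."""
    frame = select_min_yaw_frame(seq)
    if depth is not None:
        from .depth import cluster_foreground, repair_landmark_depths

        mask = cluster_foreground(depth, seed=seed)
        frame = repair_landmark_depths(frame, mask, depth)
    coeffs2d = normalization_coefficients(frame)
    mirrored = mirror_frame(frame, pairs)
    return frame, mirrored, coeffs2d


def lsad_pipeline(
    seq: FrameSequence,
    depth: DepthImage | None = None,
    c: float = DEFAULT_DEPTH_COEFFICIENT,
    pairs: PairTable | None = None,
    *,
    seed: int = 0,
    allow_scaling: bool = False,
) -> LSADProfile:
    """Full asymmetry measurement for one subject.

    Composes: minimum-|yaw| frame selection → optional depth repair →
    normalization coefficients → mirror construction → hemiface
    normalization of original and mirror (same dx, dy, c) → rigid
    Procrustes superimposition → per-pair LSADs.  Stage failures are
    re-raised with the failing stage's name.
    """
    if pairs is None:
        pairs = default_pair_table()
    stage = "frame_selection"
    try:
        frame, mirrored, coeffs2d = _pipeline_stages(seq, depth, pairs, seed)
        stage = "normalization"
        coeffs = NormCoefficients(dx=coeffs2d.dx, dy=coeffs2d.dy, c=c)
        orig_n = normalize_hemiface(frame, pairs, coeffs)
        mirr_n = normalize_hemiface(mirrored, pairs, coeffs)
        stage = "alignment"
        alignment = procrustes_align(orig_n, mirr_n, allow_scaling=allow_scaling)
        stage = "lsad"
        return compute_lsads(alignment, mirr_n, pairs)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        raise PipelineStageError(stage, exc) from exc
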