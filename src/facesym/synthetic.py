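"""Synthetic 68-landmark 3D faces and cohorts with controlled asymmetry.

The generator stands in for captured patient images: it produces a
bilaterally symmetric neutral-face landmark template with plausible
proportions (~300 px jaw width at ~500 mm camera distance, ~30 mm nose
relief), injects known left-hemiface displacements as ground-truth
asymmetry, jitters landmarks with Gaussian noise, applies rigid head pose,
and renders depth images whose contour landmarks can be deliberately
dropped onto the background so the depth-repair rules are exercised
deterministically.  Everything is reproducible from a seed.

Template coordinates (and symmetric jitter) are quantized to 1/64 px so
that the bilateral-symmetry invariant x_left = 2*x̄ − x_right holds
bit-exactly, not merely to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    NormCoefficients,
    mirror_frame,
    normalization_coefficients,
    normalize_hemiface,
)
from .io import (
    DepthImage,
    FrameSequence,
    LandmarkFrame,
    write_depth_image,
    write_openface_csv,
)
from .pairs import PairTable, default_pair_table

__all__ = [
    "FaceTemplate",
    "CohortSpec",
    "SubjectRecord",
    "make_template",
    "inject_asymmetry",
    "alignment_neutral_offsets",
    "pose_and_project",
    "render_depth_with_background",
    "simulate_cohort_frames",
    "simulate_cohort",
]

_CX = 640.0  # template face midline, px
_QUANT = 64.0  # coordinate quantum 1/64 px (dyadic, keeps symmetry exact)

# Right-hemiface landmarks: index -> (x offset from midline, y px, z mm).
_RIGHT: dict[int, tuple[float, float, float]] = {
    # jaw, outermost -> chin
    0: (150, 320, 520), 1: (148, 365, 518), 2: (142, 408, 516),
    3: (132, 448, 514), 4: (115, 485, 512), 5: (92, 517, 510),
    6: (64, 543, 508), 7: (33, 560, 506),
    # eyebrow, outer -> inner
    17: (115, 295, 500), 18: (95, 285, 498), 19: (72, 280, 496),
    20: (48, 283, 495), 21: (25, 290, 494),
    # nostril flare
    31: (28, 410, 483), 32: (15, 415, 480),
    # eye: outer corner, upper lid x2, inner corner, lower lid x2
    36: (88, 330, 502), 37: (72, 324, 501), 38: (52, 324, 501),
    39: (35, 330, 500), 40: (52, 337, 501), 41: (72, 337, 502),
    # mouth: outer lip corner/top, lower outer, inner
    48: (52, 475, 498), 49: (34, 465, 495), 50: (14, 459, 493),
    59: (34, 492, 496), 58: (16, 497, 494),
    60: (46, 475, 497), 61: (22, 470, 494), 65: (22, 480, 495),
}

# Midline landmarks: index -> (y px, z mm).
_MIDLINE: dict[int, tuple[float, float]] = {
    8: (566, 505),   # chin tip
    27: (315, 490), 28: (340, 484), 29: (365, 477), 30: (390, 470),  # nose ridge/tip
    33: (418, 478),  # nose base
    51: (457, 492), 57: (499, 493),  # outer lip centres
    62: (469, 493), 66: (482, 494),  # inner lip centres
}


def _quantize(a: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(a, dtype=float) * _QUANT) / _QUANT


@dataclass(frozen=True)
class FaceTemplate:
    """Bilaterally symmetric neutral-face landmark set at frontal pose."""

    points: np.ndarray  # (68, 3): x px, y px, z mm

    def to_frame(self, frame_index: int = 1) -> LandmarkFrame:
        return LandmarkFrame(frame_index=frame_index, points=self.points.copy())


def make_template(seed: int = 0, pairs: PairTable | None = None) -> FaceTemplate:
    """Deterministic symmetric face template with seeded individual variation.

    The seed drives a small smooth jitter (SD 2 px / 1.5 mm) applied to the
    right hemiface and midline and mirrored exactly to the left, so every
    template satisfies the bilateral-symmetry invariants exactly while
    different seeds give different individuals.
    """
    if pairs is None:
        pairs = default_pair_table()
    rng = np.random.default_rng(np.random.SeedSequence([887101, int(seed)]))
    pts = np.zeros((pairs.n_landmarks, 3))
    jitter_xy = _quantize(rng.normal(0.0, 2.0, size=(pairs.n_landmarks, 2)))
    jitter_z = _quantize(rng.normal(0.0, 1.5, size=pairs.n_landmarks))
    for idx, (off, y, z) in _RIGHT.items():
        pts[idx] = (
            _CX - (off + jitter_xy[idx, 0]),
            y + jitter_xy[idx, 1],
            z + jitter_z[idx],
        )
    for r, l in pairs.pairs:
        pts[l] = (2.0 * _CX - pts[r, 0], pts[r, 1], pts[r, 2])
    for idx, (y, z) in _MIDLINE.items():
        pts[idx] = (_CX, y + jitter_xy[idx, 1], z + jitter_z[idx])
    return FaceTemplate(points=_quantize(pts))


def inject_asymmetry(
    face: FaceTemplate,
    offsets: np.ndarray,
    pairs: PairTable | None = None,
) -> tuple[LandmarkFrame, np.ndarray]:
    """Displace left-hemiface landmarks by known offsets.

    ``offsets`` is a (68, 3) array in raw units (px, px, mm); only rows at
    left-hemiface indices are applied — the right hemiface and midline stay
    untouched, so the injected asymmetry is exactly the applied field.
    Returns the displaced frame together with the ground-truth per-pair
    planar displacement magnitude in normalized units (the frame's own
    dx/dy), ordered by pair label.
    """
    if pairs is None:
        pairs = default_pair_table()
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (pairs.n_landmarks, 3):
        raise ValueError(f"offsets must have shape ({pairs.n_landmarks}, 3)")
    if not np.isfinite(offsets).all():
        raise ValueError("offsets must be finite")
    pts = face.points.copy()
    left = pairs.left_indices
    pts[left] += offsets[left]
    frame = LandmarkFrame(frame_index=1, points=pts)
    coeffs = normalization_coefficients(frame)
    truth = np.hypot(
        offsets[left, 0] / coeffs.dx, offsets[left, 1] / coeffs.dy
    )
    return frame, truth


def alignment_neutral_offsets(
    face: FaceTemplate,
    pair_label: int,
    delta: float,
    direction: tuple[float, float] = (1.0, 0.0),
    c: float = 0.016,
    pairs: PairTable | None = None,
) -> np.ndarray:
    """Planar left-hemiface offsets that do not move the rigid fit.

    Starts from a planar displacement of magnitude ``delta`` (normalized
    units) at the left landmark of ``pair_label`` and projects the
    29-point displacement field out of the similarity-transform subspace
    (translations, infinitesimal rotations, scaling) of the normalized
    mirror hemiface.  To first order the Procrustes solution is then
    unchanged by the injection, so each pair's measured LSAD equals the
    planar magnitude of its row — recovery tests are not confounded by the
    fit re-optimizing.  Returns raw (68, 3) offsets (nonzero only at left
    indices); the ground truth is recovered via :func:`inject_asymmetry`.
    """
    if pairs is None:
        pairs = default_pair_table()
    if not 1 <= pair_label <= pairs.n_pairs:
        raise ValueError("pair_label out of range")
    frame = face.to_frame()
    coeffs2d = normalization_coefficients(frame)
    coeffs = NormCoefficients(dx=coeffs2d.dx, dy=coeffs2d.dy, c=c)
    mirror = normalize_hemiface(mirror_frame(frame, pairs), pairs, coeffs)
    M = mirror.points  # (n_pairs, 3), centred
    n = pairs.n_pairs

    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    E = np.zeros((n, 2))
    E[pair_label - 1] = delta * u

    # Planar components of the similarity generators at configuration M.
    # A planar field is 3D-orthogonal to a generator iff it is orthogonal
    # to the generator's planar slice, so the projection stays planar.
    x, y, z = M[:, 0], M[:, 1], M[:, 2]
    zeros = np.zeros(n)
    ones = np.ones(n)
    basis = np.stack(
        [
            np.column_stack([ones, zeros]),   # translation x
            np.column_stack([zeros, ones]),   # translation y
            np.column_stack([zeros, -z]),     # rotation about x
            np.column_stack([z, zeros]),      # rotation about y
            np.column_stack([-y, x]),         # rotation about z
            np.column_stack([x, y]),          # scaling
        ]
    )  # (6, n, 2)
    B = basis.reshape(6, -1).T  # (2n, 6)
    e = E.ravel()
    coef, *_ = np.linalg.lstsq(B, e, rcond=None)
    e_perp = e - B @ coef
    E_perp = e_perp.reshape(n, 2)

    # Back to raw units on the left landmarks.  The mirror reflects x, so a
    # +x displacement of the normalized mirror point is a -x raw move of the
    # underlying left landmark.
    raw = np.zeros((pairs.n_landmarks, 3))
    left = pairs.left_indices
    raw[left, 0] = -E_perp[:, 0] * coeffs.dx
    raw[left, 1] = E_perp[:, 1] * coeffs.dy
    return raw


def _rotation_matrix(yaw: float, pitch: float, roll: float) -> np.ndarray:
    """Rz(roll) @ Rx(pitch) @ Ry(yaw), angles in degrees.

    y is the image-vertical axis (yaw turns the head left/right), x the
    horizontal axis (pitch nods), z the camera axis (roll tilts in-plane).
    """
    ya, pa, ra = np.radians([yaw, pitch, roll])
    cy, sy = np.cos(ya), np.sin(ya)
    cp, sp = np.cos(pa), np.sin(pa)
    cr, sr = np.cos(ra), np.sin(ra)
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    Rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])
    return Rz @ Rx @ Ry


def pose_and_project(
    frame: LandmarkFrame,
    yaw: float = 0.0,
    pitch: float = 0.0,
    roll: float = 0.0,
    distance_mm: float | None = None,
) -> LandmarkFrame:
    """Apply rigid head pose about the landmark centroid.

    Pixels and millimetres are treated as commensurate for the rotation (a
    fixture convention: ~1 px ≈ 1 mm at the template's 500 mm working
    distance).  ``distance_mm`` shifts the whole face along the camera axis
    so its mean depth equals the given distance.  The stored pose angles
    are updated by the applied rotation.
    """
    for a in (yaw, pitch, roll):
        if abs(a) > 30:
            raise ValueError("pose angles limited to ±30°")
    R = _rotation_matrix(yaw, pitch, roll)
    centroid = frame.points.mean(axis=0)
    pts = (frame.points - centroid) @ R.T + centroid
    if distance_mm is not None:
        pts = pts.copy()
        pts[:, 2] += distance_mm - pts[:, 2].mean()
    return frame.replace(
        points=pts,
        yaw=frame.yaw + yaw,
        pitch=frame.pitch + pitch,
        roll=frame.roll + roll,
    )


def render_depth_with_background(
    frame: LandmarkFrame,
    background_depth_mm: float = 1800.0,
    contaminate: tuple[int, ...] = (),
    full_window_background: tuple[int, ...] = (),
    shape: tuple[int, int] = (720, 1280),
    depth_gradient: float = 0.05,
) -> DepthImage:
    """Depth image with the face on a constant-depth background.

    Face pixels fill an ellipse around the landmarks with a smooth
    depth profile (mean landmark depth plus a vertical gradient, mm per
    px); everything else is background.  Landmarks listed in
    ``contaminate`` get their own pixel set to the background depth (their
    7×7 window keeps face pixels, so repair uses the window mean);
    landmarks in ``full_window_background`` get the whole 7×7 window set
    to background, forcing the median fallback.
    """
    h, w = shape
    img = np.full((h, w), int(round(background_depth_mm)), dtype=np.uint16)
    xy = frame.points[:, :2]
    cx, cy = xy.mean(axis=0)
    margin = 30.0
    ax = (xy[:, 0].max() - xy[:, 0].min()) / 2 + margin
    ay = (xy[:, 1].max() - xy[:, 1].min()) / 2 + margin
    rows, cols = np.mgrid[0:h, 0:w]
    ellipse = ((cols - cx) / ax) ** 2 + ((rows - cy) / ay) ** 2 <= 1.0
    base = frame.points[:, 2].mean()
    face_vals = np.rint(base + depth_gradient * (rows - cy)).astype(np.uint16)
    img[ellipse] = face_vals[ellipse]

    def _pix(i: int) -> tuple[int, int]:
        col = int(np.clip(np.rint(frame.points[i, 0]), 0, w - 1))
        row = int(np.clip(np.rint(frame.points[i, 1]), 0, h - 1))
        return row, col

    bg = np.uint16(int(round(background_depth_mm)))
    for i in contaminate:
        r, c = _pix(int(i))
        img[r, c] = bg
    for i in full_window_background:
        r, c = _pix(int(i))
        img[max(0, r - 3): r + 4, max(0, c - 3): c + 4] = bg
    return DepthImage(values=img)


# ---------------------------------------------------------------------------
# Cohorts

_REGIONS = ("face_edge", "eyebrows", "nostrils", "eyes", "mouth")


def _region_dict(value: float) -> dict[str, float]:
    return {r: value for r in _REGIONS}


@dataclass(frozen=True)
class CohortSpec:
    """Study-conditions recipe for a two-group synthetic cohort.

    Asymmetry magnitudes are in normalized (LSAD) units; every face carries
    some baseline asymmetry (real faces are never perfectly symmetric), and
    a group contrast is created by raising a region's mean for the case
    group.  Pose, working distance and per-landmark noise emulate a seated
    capture session at 40–60 cm.
    """

    n_case: int = 150
    n_control: int = 150
    asymmetry_mean_case: dict[str, float] = field(default_factory=lambda: _region_dict(0.05))
    asymmetry_mean_control: dict[str, float] = field(default_factory=lambda: _region_dict(0.05))
    asymmetry_sd: float = 0.02  # between subject-pair SD of the magnitude
    landmark_noise_sd_px: float = 0.5
    landmark_noise_sd_mm: float = 2.0
    yaw_range: tuple[float, float] = (-10.0, 10.0)
    pitch_range: tuple[float, float] = (-5.0, 5.0)
    roll_range: tuple[float, float] = (-5.0, 5.0)
    distance_range_mm: tuple[float, float] = (400.0, 600.0)
    frames_per_subject: int = 30
    frontal_yaw: float = 2.0  # the guaranteed near-frontal frame stays within this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.asymmetry_sd < 0 or self.landmark_noise_sd_px < 0 or self.landmark_noise_sd_mm < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.frames_per_subject < 1:
            raise ValueError("need at least one frame per subject")
        for rng_ in (self.yaw_range, self.pitch_range, self.roll_range, self.distance_range_mm):
            if not np.isfinite(rng_).all():
                raise ValueError("ranges must be finite")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    sequence: FrameSequence
    truth: np.ndarray  # (29,) injected per-pair planar magnitude, normalized


def _subject_frames(
    spec: CohortSpec,
    group: str,
    idx: int,
    pairs: PairTable,
) -> SubjectRecord:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0 if group == "case" else 1, idx]))
    template = make_template(seed=int(rng.integers(2**31)), pairs=pairs)
    means = spec.asymmetry_mean_case if group == "case" else spec.asymmetry_mean_control

    frame0 = template.to_frame()
    coeffs = normalization_coefficients(frame0)
    offsets = np.zeros((pairs.n_landmarks, 3))
    left = pairs.left_indices
    mags = np.empty(pairs.n_pairs)
    for k, region in enumerate(pairs.regions):
        m = max(0.0, rng.normal(means[region], spec.asymmetry_sd))
        theta = rng.uniform(0, 2 * np.pi)
        offsets[left[k], 0] = m * np.cos(theta) * coeffs.dx
        offsets[left[k], 1] = m * np.sin(theta) * coeffs.dy
        mags[k] = m
    base_frame, truth = inject_asymmetry(template, offsets, pairs)

    frames = []
    for f in range(spec.frames_per_subject):
        noise = np.column_stack(
            [
                rng.normal(0, spec.landmark_noise_sd_px, size=(pairs.n_landmarks, 2)),
                rng.normal(0, spec.landmark_noise_sd_mm, size=pairs.n_landmarks),
            ]
        )
        noisy = base_frame.replace(points=base_frame.points + noise, frame_index=f + 1)
        if f == 0:
            yaw = rng.uniform(-spec.frontal_yaw, spec.frontal_yaw)
        else:
            yaw = rng.uniform(*spec.yaw_range)
        posed = pose_and_project(
            noisy,
            yaw=yaw,
            pitch=rng.uniform(*spec.pitch_range),
            roll=rng.uniform(*spec.roll_range),
            distance_mm=rng.uniform(*spec.distance_range_mm),
        )
        frames.append(posed.replace(confidence=0.99))
    sid = f"{group}_{idx:04d}"
    return SubjectRecord(
        subject_id=sid,
        group=group,
        sequence=FrameSequence(frames=tuple(frames), subject_id=sid),
        truth=mags,
    )


def simulate_cohort_frames(
    spec: CohortSpec, pairs: PairTable | None = None
) -> list[SubjectRecord]:
    """Generate a two-group cohort in memory, fully determined by the seed."""
    if pairs is None:
        pairs = default_pair_table()
    records = [_subject_frames(spec, "case", i, pairs) for i in range(spec.n_case)]
    records += [_subject_frames(spec, "control", i, pairs) for i in range(spec.n_control)]
    return records


def simulate_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    pairs: PairTable | None = None,
    *,
    write_depth: bool = False,
    background_depth_mm: float = 1800.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a synthetic cohort to disk in the formats the readers consume.

    Per subject: an OpenFace-dialect landmark CSV (and optionally a 16-bit
    depth PNG of the near-frontal frame).  Returns (manifest, ground truth)
    DataFrames; both are also written as ``manifest.csv`` and
    ``ground_truth.csv`` in ``out_dir``.
    """
    if pairs is None:
        pairs = default_pair_table()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = simulate_cohort_frames(spec, pairs)

    manifest_rows = []
    truth_rows = []
    for rec in records:
        csv_name = f"{rec.subject_id}.csv"
        write_openface_csv(rec.sequence, out / csv_name)
        depth_name = ""
        if write_depth:
            depth_name = f"{rec.subject_id}_depth.png"
            frontal = min(rec.sequence.frames, key=lambda fr: (abs(fr.yaw), fr.frame_index))
            depth_img = render_depth_with_background(
                frontal, background_depth_mm=background_depth_mm
            )
            write_depth_image(depth_img, out / depth_name)
        manifest_rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "landmark_csv_path": csv_name,
                "depth_png_path": depth_name,
            }
        )
        row = {"subject_id": rec.subject_id, "group": rec.group}
        row.update({f"pair_{k+1}": rec.truth[k] for k in range(pairs.n_pairs)})
        truth_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return manifest, truth
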