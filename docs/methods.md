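# Methods

## The model

`facesym` treats facial asymmetry as a landmark registration problem. A
face that is perfectly bilaterally symmetric is indistinguishable from its
own mirror image up to a rigid motion; whatever in-plane distance remains
between corresponding landmarks *after* the best rigid superimposition of
the face onto its mirror is therefore a pure asymmetry signal, uncontaminated
by head pose, face size or camera placement. The per-pair residuals are the
landmark superimposition asymmetry distances (LSADs); their sum is the
aggregate measure, giving 30 measures per subject (29 pairs + sum).

Assumptions worth stating explicitly:

- Landmark correspondence is given by the tracker's fixed 68-point scheme;
  the bilateral pairing (29 pairs grouped as face edge 8, eyebrows 5,
  nostrils 2, eyes 6, mouth 8; 10 midline points) is structural, not
  estimated. Report labels 1–29 run outermost→innermost within each
  region; the literature never prints an explicit index map, so this
  ordering is an assumption isolated in one table (`facesym.pairs`) for
  easy change.
- The analyzed frame is the minimum-|yaw| frame of the session; residual
  pose enters the measurement error (quantified below).
- Only the in-plane (x, y) residual defines the distance. Depth
  participates in the alignment objective — weighted by the coefficient
  *c* — but not in the distance itself, because consumer depth sensors are
  far noisier than their pixel localization.

## Pipeline stages and numerical choices

**Frame selection.** Frames flagged unsuccessful or below a confidence
floor (default 0.75) are dropped; an explicit per-frame exclusion list
covers manually flagged closed-eye frames. Ties on |yaw| resolve to the
earliest frame index, making selection order-stable.

**Depth repair.** Contour landmarks sit on the silhouette, where stereo
depth frequently returns the background or nothing. The depth image is
split by 1-D 2-means (k-means++, 10 restarts, fixed seed; one-dimensional
2-means is effectively deterministic, the restarts only guard degenerate
initializations); zero depth is treated as background and excluded from
clustering. A background-labelled landmark's depth becomes the mean of
face pixels in the 7×7 window centred on it; if the window holds no face
pixel, the median of all 68 landmark depths. The median uses *pre-repair*
depths in a single pass, so results do not depend on landmark index order
(even-count median = mean of the two central values).

**Normalization.** dₓ and d_y are the mean absolute deviations of all 68
landmarks from their centroid — the average horizontal (vertical) distance
between centroid and landmarks. (The signed-deviation form Σ(xᵢ−x̄)/68 is
identically zero and cannot be a scale; the absolute-value form is the
quantity the prose of the method describes.) They are computed once from
the original frame and shared with the mirror, which is self-consistent
because reflection preserves absolute deviations. Depth is not normalized
per-axis: landmark depth *differences* are invariant to camera distance.
The hemiface centring uses the 29 right-hemiface landmarks' own 3D
centroid.

**Mirroring.** x → 2x̄ − x about the 68-landmark centroid axis, followed
by the left/right index swap. Any vertical axis gives identical LSADs
(centring removes translation); the centroid axis keeps intermediate
numbers small. Mirroring is an involution (bit-exact on dyadic
coordinates, to two roundings otherwise).

**Rigid superimposition.** Closed-form orthogonal Procrustes (Kabsch SVD)
with determinant correction: reflections are never admitted, and
rank-deficient configurations resolve deterministically through the same
corrected decomposition. Both point sets are centred, so the optimal
translation is zero. A similarity mode (optimal uniform scaling) exists
behind `allow_scaling=True` for sensitivity analysis only; the measure is
rigid.

**Depth coefficient.** *c* converts mm into the normalized frame inside
the alignment objective. Default 0.016. The tuning procedure reproduces
the in-sample selection rule: over a grid (default 0.000–0.050, step
0.001 — fine enough to resolve the third decimal), recompute all 30
measures per subject at each candidate, run one-tailed (case > control)
independent t-tests, count p < α (default 0.05, uncorrected) and keep the
count-maximizing value, smallest *c* on ties. The front half of the
pipeline (frame choice, repair, dₓ/d_y, mirror) does not depend on *c* and
is computed once per subject; the per-candidate back half consumes exactly
those objects, so the shortcut is bit-identical to rerunning the full
pipeline. This selection is circular by design (chosen and evaluated on
the same subjects); the package reproduces the procedure and leaves
held-out validation to the user.

**Group comparison.** Per measure, an independent two-sample t-test;
pooled-variance (Student) by default for parity with conventional
statistical-package output, Welch behind a flag. Reported p-values are
two-sided; no multiple-testing correction by default (an optional
Benjamini–Hochberg flag is an extension, off by default). Zero-variance
degenerate inputs: equal means → (t, p) = (0, 1); unequal → (±∞, 0), the
limit of the statistic.

## Invariances and the pose bound

Exact (float-tolerance) invariances, asserted by tests: whole-face
translation in x, y, z; camera-distance shifts; per-axis scaling of x or y
about the centroid; a symmetric frontal face scores identically zero.

Residual head pose is **not** exactly removed in general, because the
normalization is anisotropic: the rigid fit happens after axes are scaled
by 1/dₓ, 1/d_y, c, and a rotation conjugated by an anisotropic scaling is
no longer a rotation. Two measured facts document this:

- Pure yaw is absorbed *exactly* (residual ~1e-13, asserted < 1e-6) when
  the depth weight matches the observed in-plane scale, c = 1/dₓ of the
  analyzed frame — then the x–z block of the normalization is conformal
  and the mirror relation is an exact rotation.
- At the default c = 0.016 and the template's ~50 mm depth relief, the
  measured LSAD-sum residual of a perfectly symmetric face is ≈ 1.1 at
  |yaw| = 10° and scales roughly linearly with yaw; the suite asserts the
  measured bound ≤ 1.5 for |yaw| ≤ 10°. At the ≤ 2° yaw of a selected
  near-frontal frame the residual is an order of magnitude smaller and
  behaves as shared measurement noise: it affects both cohorts of a
  comparison identically and cancels from the group contrast.

## The synthetic generator

The generator defines the conditions under which every guarantee is
demonstrated. It emulates: a 68-landmark neutral face with plausible
proportions (jaw width ~300 px at ~500 mm, eye-centre separation ~124 px,
nose relief ~30 mm; fixture choices, not claims about any population),
seeded symmetric individual variation (SD 2 px / 1.5 mm, mirrored exactly;
coordinates quantized to 1/64 px so the bilateral-symmetry invariants are
bit-exact in IEEE double), controlled left-hemiface displacements as
ground-truth asymmetry, per-landmark Gaussian noise (defaults 0.5 px in
x, y; 2 mm in z), rigid head pose (defaults |yaw| ≤ 10°, |pitch|, |roll| ≤
5°, with one guaranteed near-frontal frame per session), working distance
400–600 mm, and 30 frames per subject. Cohorts default to 150 + 150
subjects with a baseline asymmetry magnitude of 0.05 normalized units per
region (between-subject SD 0.02) in both groups — real faces are never
perfectly symmetric — and a group contrast is created by raising a
region's case-group mean. The generator's effect-size convention: raising
the face-edge mean from 0.05 to 0.09 realizes an average per-pair Cohen's
d ≈ 0.8 in the measured LSADs (measured at n = 400 + 400; the per-pair
range is ~0.5–1.1 because the rigid fit absorbs more of the displacement
at high-leverage outer-jaw landmarks).

"Alignment-neutral" injected offsets — used wherever recovery is compared
to ground truth — are planar displacement fields projected out of the
similarity-transform subspace (translations, infinitesimal rotations,
scaling) of the normalized mirror hemiface, so the rigid fit is unchanged
to first order and the measured LSAD equals the injected magnitude
(observed recovery ratio 1.000 at δ = 0.15).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: tracker landmark-localization bias (noise is
independent Gaussian, real tracker error is spatially correlated and
pose-dependent), facial expression, occlusion, perspective projection
(pose is applied as a rigid transform with pixels and millimetres treated
as commensurate at the 500 mm working distance), skin texture, and any
demographic structure. Depth images are rendered as a smooth elliptical
face patch on a constant background — enough to exercise the repair rules
deterministically, far from real sensor noise.

## Problem sizes used in the checks

The statistical-calibration check runs 200 replicate null cohorts of
150 + 150 subjects at one frame per subject and no depth channel (the
c-independent stages are exercised separately); the power check runs 50
(tests) / 30 (acceptance script) replicates with the shifted face-edge
region; recovery uses a 40-subject cohort; the rigid-fit oracle uses 50
(tests) / 20 (script) random 29-point instances against a 15° Euler grid
refined by Nelder–Mead (the refinement converges far below grid
resolution) plus 1,000 random rotations. These sizes give Monte-Carlo
standard errors well inside the asserted bands (e.g. SE ≈ 0.1 on the mean
null significant count of ≈ 1.5). The observed null mean count runs
slightly above 30α·= 1.5 (≈ 1.6) because the 30 LSAD measures are
positively correlated and right-skewed; the t-test is only asymptotically
exact on such data.

## Known limitations

- The in-sample tuning of *c* is reproduced as specified, circularity
  included.
- Pair labels 1–29 within each region follow the outermost→innermost
  convention; if an external table uses the reverse, remap in
  `facesym.pairs`.
- The synthetic cohorts inject planar asymmetry only; with no depth
  asymmetry in the signal, tuning on synthetic data tends to choose small
  *c* (depth weighting only adds alignment noise there).
- Pose robustness is approximate under the anisotropic default
  normalization (see the measured bound above); the method relies on
  near-frontal frame selection.
- `reference.py` carries published group-level descriptive values for a
  150/150 dementia-vs-control cohort at c = 0.016, used only for
  arithmetic consistency checks and as a scale reference — none of the
  computations on user data read them.
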