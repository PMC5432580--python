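# Methods

## Problem setting

A structure-from-motion (SfM) reconstruction of a head wearing an EEG cap
is a textured triangular mesh in an arbitrary coordinate frame: unknown
rotation, translation, and — because single-camera SfM cannot recover
absolute scale — an unknown isotropic scale, here anywhere between 1 and 5
relative to metric units. Electrode positions read off that mesh are only
useful once the mesh is mapped into the subject's MRI space. The package
implements that mapping, the texture-based electrode detection, the
template labeling, and the accompanying evaluation machinery.

All coordinates are millimetres. Meshes carry per-face-corner UV
coordinates (Wavefront convention: V measured from the bottom of the
texture image; U outside [0, 1] wraps, which is how seam-crossing faces
are represented). Every spatial object carries a `frame_id` tag so frame
mixing fails loudly rather than silently.

## Coregistration

**Scaling.** Corresponding facial segments are selected on the model and
on the MRI scalp surface — the rigid region around the nose bone
(forehead, eyebrows, cheekbones), which deforms least between sessions.
The model-to-MRI scale is the ratio of the segments' mean
point-to-centroid distances (centroid = per-axis arithmetic mean). The
ratio is exact under similarity transforms of either segment and needs no
point correspondences.

**Rigid alignment.** The scaled model segment is aligned to the MRI
segment with point-to-point ICP: nearest-neighbor correspondences from a
KD-tree, closed-form least-squares rotation/translation (SVD; reflections
rejected by construction — anatomical meshes must not mirror), stop when
the RMS distance changes by less than `tol` (default 1e-6 mm) or after
`max_iter` (default 100) iterations. `trim_frac` optionally drops the
worst fraction of correspondences each iteration, a headless stand-in for
interactively removing mismatched mesh parts (default 0 = off).

**Initialization.** Interactive pre-orientation is replaced by an
automatic coarse init: both segments are centered, their principal axes
aligned, and of the four proper sign combinations the one with the lowest
nearest-neighbor RMS wins. Plain ICP from an identity init demonstrably
stalls in local minima on smooth facial patches for rotations as small as
10°, so the coarse init is applied in every coregistration. The full
model-to-MRI transform is the composition scale → rigid.

**Fiducial baseline.** The digitizer-style alternative builds a canonical
head frame from three landmarks per side — origin at the preauricular
midpoint, x toward the right preauricular point, y toward the nasion
within the landmark plane, z their cross product — and composes
src→canonical→dst. It is exact on noiseless landmarks; the evaluation
therefore injects per-fiducial isotropic Gaussian noise, default σ = 2 mm,
matching the stated technical inaccuracy of common electromagnetic
digitizers. The σ value is a package assumption: only the qualitative
ordering (surface matching beats noisy fiducials for σ ≥ 1 mm) is
asserted, not a specific baseline error.

## Electrode detection

The texture is converted to grayscale and binarized at a global threshold
chosen to maximize between-class variance (Otsu) unless given; polarity is
configurable (`bright` default, `dark`, or `minority`). The binarized mesh
is rendered orthographically from 10 viewpoints — azimuths
{0°, 72°, 144°, 216°, 288°} at elevations {20°, 55°} above the head's
horizontal plane, chosen to cover the cap with overlap — at 0.5 mm/pixel.
The rasterizer generates fragments over triangle bounding boxes,
barycentrically interpolates depth, and resolves visibility with a
z-buffer; each covered pixel records the winning face and its barycentric
coordinates, which is the exact inverse mapping used later for
back-projection.

Circles are found per view with a circular Hough transform over the
radius range 2–8 mm (converted to pixels through the view's pixel pitch;
physical electrode size is scale-invariant, pixels are not), accumulating
on the foreground boundary. Normalized-accumulator maxima above the
sensitivity (default 0.45) survive; a cross-radius non-maximum suppression
drops peaks within `r_min` of a stronger one, and centers are refined to
sub-pixel precision as the foreground centroid within the detected radius.
Each center is mapped to the 3-D surface through the render's
face/barycentric lookup; detections on background pixels are dropped with
a warning. Multi-view candidates are merged by single-linkage clustering
at 10 mm (about half the minimum inter-electrode spacing of dense caps);
each cluster reduces to its centroid, ordered by descending cluster size
then ascending z, so output is independent of input order. A
`correction_hook` lets callers add/remove/move candidates before labeling,
mirroring the manual-correction step of interactive use; the CLI exposes
it as an edit file. Raw positions can finally be projected onto the MRI
scalp by exact point-to-triangle closest-point queries (KD-tree candidate
prefilter with a circumradius exactness bound; verified against a
brute-force all-triangles oracle).

## Labeling

Templates are fully labeled layouts sharing one label inventory (stored
normalized: centered, unit RMS radius). For each of the default seven
templates the alignment onto the unlabeled set is initialized from the
automatically detected Fpz/Oz landmarks plus the cloud centroid (a
three-point similarity fit) and refined with affine ICP (12-parameter,
positive determinant enforced to prevent mirror-image label flips; a
degenerate collapse aborts the iteration).

Landmark detection: the best-fit-sphere center and the cloud centroid give
a vertical axis, refined by the best-fit plane of the top of the cap
(which is azimuthally symmetric, so its normal is a tilt-free vertical);
the left-right axis is the in-plane mirror-symmetry axis found by direct
angular scan; Fpz/Oz are the extreme midline electrodes of the lower cap
band along the anterior-posterior axis, with anterior identified as the
sparser side of the lower band (caps extend below the inion at the back
but not over the face). When that density margin is below 2 electrodes the
orientation is declared ambiguous and both assignments are trialed.

Because grid-structured layouts have strong ICP local minima at alignments
rotated by one electrode slot — and nearly exact minima at 180° — each
template additionally trials inits from an exhaustive sweep of the
azimuthal rotation (10° steps, vertical axes matched, scale from RMS
radii); the init with the lowest post-ICP mean nearest-neighbor residual
wins. Each template then proposes, per input electrode, the label of its
nearest template electrode; the final label is the mode of the seven
proposals, ties broken by lowest template index, and duplicated winners
resolved by a minimum-total-distance assignment over the conflicting
electrodes and unclaimed labels. Labeling requires matching electrode
counts; sets with missing or extra electrodes are out of scope.

## Evaluation

`mesh_deviation` matches each test vertex to the closest *vertex* of the
reference mesh (the convention of the original evaluation; exact
point-to-triangle distance is available as `mode="triangle"`), recording
per-axis absolute offsets and the Euclidean distance, with mean, median,
sample SD, and 95th-percentile summaries. `electrode_deviation` is the
per-electrode L² distance on label- or order-matched sets, with an
exclusion list for unreliable reference electrodes.
`pure_position_deviation` removes the globally optimal rigid transform
before measuring residuals, separating the method's intrinsic error from
coregistration error; with matched correspondences the closed-form Kabsch
solve *is* the converged ICP solution and is provably optimal, so it is
used directly (a random-restart oracle test confirms optimality).

The coregistration simulation applies `n_reps` seeded random similarity
transforms — per-axis rotation angles uniform in [1°, 360°] composed as
Rz·Ry·Rx, per-axis translations uniform in [1, 100] mm, scale uniform in
[1, 5] for the surface method only (digitizer data is metric, so its
perturbations are rigid) — coregisters each perturbed copy back, and pools
the per-electrode distances to the originals.

Wilcoxon's signed-rank test (two-sided) drops zero differences and
midranks ties; for up to 12 remaining pairs the null distribution of the
positive-rank sum is enumerated exactly over all sign assignments,
otherwise a normal approximation with tie and continuity corrections is
used. Both regimes are tested against an independent enumeration oracle
and against scipy.

## Synthetic data

`make_head` builds a radially parameterized deformed sphere, base radius
90 mm (an adult head), with fixed Gaussian surface features — nose tip and
bridge, brow, cheekbones, chin, occiput, amplitudes 5–22 mm — plus a small
seeded random smooth deformation (8 bumps, σ≈1.2 mm amplitude) so no two
heads are identical. The mesh is a latitude/longitude grid (default 96
rows) with the texture seam placed at azimuth 189°, at least 8° from every
electrode column of the canonical layout. Fiducials and the facial-segment
vertex list are returned as ground truth. `paint_electrodes` paints
geodesically circular discs (default 4 mm radius) by testing each texel's
3-D surface position against the electrode centers, so discs stay round on
the surface regardless of chart distortion, including across the seam and
at the pole. `make_mri_like` voxelizes the head interior (default 1.5 mm
voxels, 1 mm smoothing, mild noise) into a world frame offset by a known
rigid transform. The canonical 68-channel layout uses rings at elevations
{90°, 68°, 46°, 24°, 2°} with a five-electrode sub-equatorial posterior
band, 10-20-like names including Fpz and Oz, left-right symmetric.

What passing tests show — and what they do not: the synthetic heads have
ideal contrast, no hair, no specularity, no SfM reconstruction noise, and
geometrically perfect discs. Results on them validate the *geometry* of
the pipeline (transform recovery, rendering/back-projection consistency,
vote logic) at the sub-millimetre level; they do not predict detection
rates on real photographs, where texture quality dominates. The ~0.4 mm
end-to-end detection error on clean synthetic heads is the floor set by
pixel pitch and Hough quantization, not an expected real-world figure.

## Numerical choices and limitations

- Best-fit rotations reject reflections by flipping the smallest singular
  vector; collinear point sets raise a degeneracy error (second singular
  value below 1e-10 of the largest).
- ICP convergence is |ΔRMS| < 1e-6 mm; the objective is monotone
  non-increasing (asserted in tests).
- Problem sizes in the tests and the acceptance script: 96-row meshes
  (~18k vertices), 100 coregistration repetitions, one full 10-view
  detection run, 50 labeling repetitions — the sample sizes of the
  simulated study, chosen to estimate the reported means stably.
- Scalp extraction defaults (threshold 0.10 of the 99th-percentile
  intensity, closing radius 2 voxels) suit T1-like head/background
  contrast; the synthetic round-trip tests use 0.5, the unbiased level for
  noise-free binary volumes.
- Non-goals: structure-from-motion itself, deformable registration,
  point-to-plane ICP, color-based electrode classification, labeling sets
  whose electrode count differs from the templates.
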