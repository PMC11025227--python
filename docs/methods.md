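# Methods

This note documents the models, parameter choices and numerical decisions
behind `cartival`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic experiments do and do not
show about real data.

## Coordinate and grid conventions

World coordinates are millimetres. A `LabelVolume` maps voxel index
(i, j, k) to `origin + spacing·(i, j, k)` — indices address voxel *centers*,
axis order (x, y, z). Only isotropic grids with identity direction matrices
are accepted; anisotropic or oblique volumes are rejected at load rather
than silently resampled, because every volume-conservation argument below
assumes a cubic voxel. Label resampling is nearest-neighbour (labels are
categorical; interpolation would manufacture non-label values), so a rigid
resampling conserves foreground volume up to one boundary shell
(≤ surface area × voxel pitch). The mm/voxel-center convention is a package
choice: segmentation exports in the wild do not agree on one, and all I/O
paths normalise to it on read.

## The phantom

`generate_case` builds a cartilage plateau as a 2D thickness field t(x, y)
over a 75 × 50 mm plateau: two circular condylar patches (default radii
18 and 16 mm, centred at x = ∓19 mm) with full thickness
(`base_thickness_mm`, default 2.2 mm) over the patch interior and a
cosine-squared taper over the outer 25 % of each radius, smoothed by a
fixed 1 mm Gaussian. The smoothed taper is then *cut* at 25 % of base
thickness, leaving a ~0.55 mm step at the margin. The step is deliberate:
articular cartilage terminates abruptly at its margin, and a zero-slope
taper makes the rasterised footprint boundary pathologically sensitive to
millimetre-scale thickness noise — a modelling artefact, not biology.
Full-thickness defects are sharp disks zeroed *after* smoothing, so defect
edges stay crisp in volumes and photographs alike.

Per case the generator rasterises:

- **CT gold standard** — indicator 0 ≤ z ≤ t(x, y) at 0.2 mm, CT frame;
- **MRI model** — thickness field β·t + n, rasterised at 0.4 mm on a grid in
  the MRI frame (the CT frame pulled back through the inverse of the true
  transform). β = `thickness_bias` ∈ (0, 1] is the multiplicative thickness
  underestimation; n is a smooth Gaussian noise field (sd
  `boundary_noise_sd_mm`, default 0.3 mm; 2 mm correlation length)
  emulating inter-modality boundary uncertainty of about one CT voxel;
- **photo** — the z-projection of the CT-frame cartilage at 0.1 mm/px
  (the calibrated scale of a grid-paper photograph);
- **landmarks** — six ordered fiducials (anterior rim, two per patch,
  posterior rim, two per patch); the MRI-side copy receives isotropic
  Gaussian measurement noise (default sd 0.5 mm) *after* correspondence, so
  landmark pairs correspond by index but imperfectly in space;
- **truth** — the rigid MRI→CT transform, available for recovery studies.

MRI voxel centers are snapped to half-spacing offsets so no center sits
exactly on the z = 0 cut plane (a center on the boundary makes a whole
voxel layer flip on float rounding).

`generate_cohort` draws per-case parameters: β from [0.5, 0.9] by default
(the regime in which thickness underestimation is the dominant model error),
patch radii jittered ±15 % and base thickness ±10 % (between-patient
anatomical spread; without it a cohort's true volumes vary less than the
measurement noise and volume correlations are meaningless), 0–3 defects of
radius 2–6 mm, poses up to 25° / 15 mm (large enough that unregistered
overlap is near zero, small enough that six landmarks make registration
well-posed). Everything is bit-deterministic under the seed.

What the phantom does **not** model: bone and soft-tissue background,
MRI/CT image formation (volumes are clean labels, not images), curved
subchondral bone (the resection face is flat), ligament stumps, and any
spatial correlation between defect burden and thickness bias. Passing tests
therefore demonstrate that the *pipeline* measures what it claims under
known ground truth — not that any particular segmentation model is accurate
on patients.

## Track A: simulated photography

`pca_rectify` aligns the mesh's principal axes (vertex covariance) with
x ≥ y ≥ z by variance and centres the centroid. Axis signs must be
deterministic and, crucially, *consistent between the MRI and CT meshes of
the same specimen*: a z-flip mirrors the silhouette, and the 2D alignment
search deliberately excludes mirror candidates (a photograph and a top-down
render share handedness). For a closed surface the area-weighted normal sum
is identically zero and a face-count vote between the top and bottom of a
slab is near-degenerate, so the primary z-orientation cue is the sign of
the third central moment of vertex z: a flat resection face below a domed
articular face skews the distribution positive. The face-normal vote and a
largest-component-positive rule remain as fallbacks for symmetric meshes;
the x sign uses the same skewness-then-largest-component rule. Rectification
is idempotent to 1e-6.

`render_silhouette` rasterises every projected triangle with an exact
pixel-center point-in-triangle test (triangles bucketed by bounding-box size
so marching-cubes-scale meshes vectorise; for a closed mesh the union of
projected faces *is* the silhouette of the solid). Orthographic projection
is the default: grid-paper calibration converts both images to absolute
millimetres, so optical magnification (the camera's 1.3× zoom) cancels, and
for a ≤ 2.2 mm-thick specimen whose outline lies near the bench plane the
perspective parallax at 140 mm camera distance is well under 1 % of
foreground. The pinhole mode exists to verify exactly that claim rather than
for production use.

`binarize_photo` thresholds (fixed level or Otsu), keeps the largest
connected component, and **preserves interior holes** — full-thickness
defects are morphology of interest, not noise. `align_silhouettes`
resamples both images to the finer pixel scale, superposes centroids,
rotates to match 2D principal axes, and scores both proper-rotation
candidates (θ, θ + 180°) by DSC with a deterministic first-wins tie-break;
near-isotropic shapes fall back to centroid-only alignment with a warning.
How the two binary images are mutually aligned (and with what threshold the
photo was binarised) is under-determined in the field; both choices are
therefore explicit, logged in every report, and configurable.

## Track B: registration

`landmark_align` is the closed-form least-squares rigid solution via SVD of
the 3×3 cross-covariance with the determinant correction enforcing a proper
rotation (warning when the unconstrained optimum is a reflection). Collinear
landmark sets are rejected. `surface_cloud` samples the mask iso-surface
uniformly by triangle area, with replacement, deterministic under seed.

`icp_refine` is point-to-point ICP: exact nearest-neighbour correspondences
(k-d tree) from the transformed source to the destination, optional
worst-fraction trimming, closed-form update on the kept pairs. Diagnostics
record the per-iteration RMS correspondence distance — the quantity the
squared-error update provably never increases (the arithmetic mean can
fluctuate at micro-scales) — and the termination reason; convergence is a
change below `tol_mm`.

Defaults (`max_iter` 500, `tol_mm` 1e-6, 10 000 samples per surface,
`outlier_trim_fraction` 0) encode two lessons measured on this geometry:

- *Fraction-trimming is harmful under complete overlap.* On a thin plateau
  essentially all in-plane registration information lives in the rim band,
  which holds roughly the worst-matched tenth of the points; trimming 10 %
  discards exactly those correspondences and creates fixed points 2–6° of
  in-plane twist away from truth even on noise-free data (the objective at
  truth is then *lower* than at the ICP fixed point — a convergence failure,
  not a different optimum). Trimming remains available for the
  partial-overlap, outlier-contaminated clouds it is designed for.
- *The in-plane valley is shallow.* A loose tolerance reads slow progress
  along it as convergence; 1e-6 mm with a 500-iteration cap recovers
  default-noise poses to ≲ 1° / 0.3 mm.

Correspondence is asymmetric (model → gold standard), matching the direction
of evaluation; registration never estimates scale (the specimen is the same
rigid object in both modalities).

## Metrics

`dsc_2d` / `dsc_3d` are exact set counts; results always carry the raw
intersection and mask sizes so any reported quotient can be re-derived. 3D
DSC is evaluated on the CT (0.2 mm) grid — the finer of the two, minimising
resampling loss; the choice of evaluation grid is stated in every report
because the alternative (the coarse grid) systematically flatters the
comparison. Two empty masks raise rather than returning a conventional 0 or
1: a 0/0 DSC almost always means an upstream failure, and silent
conventions hide it. `pearson_r` requires n ≥ 3 and non-constant inputs and
reports the two-sided p-value; p-values are reported, never used for gating
inside the pipeline.

Cross-resolution rasterisation bounds the ideal case: an unbiased,
noise-free phantom scores ≈ 0.95 in 3D DSC (not 1.0) purely because a
0.4 mm rasterisation nearest-neighbour-resampled onto a 0.2 mm grid
disagrees with the fine rasterisation in a ±0.2 mm shell around the
surface; for a ~2 mm-thick structure that shell is ~5 % of the volume. The
same arithmetic is why *real* thin-cartilage 3D DSC values are structurally
depressed relative to 2D ones.

## Pipeline determinism

Every stochastic step (phantom generation, surface sampling) is seeded from
the configuration; reports embed the config hash, the seed, and every
tie-break actually taken (alignment candidate, ICP termination).  Two runs
with the same config and inputs produce bit-identical `cohort.csv` and
`cohort.json`. Problem sizes used in the test-suite experiments are scaled
to the information they need: unit tests use a 36 × 26 mm phantom,
recovery and bias-sweep experiments use the full-size default phantom with
40 and 30 seeded cases respectively.

## Known limitations

- Orthographic rendering is exact only for telecentric optics; the pinhole
  mode quantifies (and the grid calibration absorbs) the difference, but
  lens distortion is out of scope, as is automatic grid detection
  (`mm_per_px` is a declared input).
- Point-to-point ICP has no basin-of-attraction guarantee; a far init on a
  near-symmetric specimen converges to a flagged local optimum (elevated
  RMS), which callers must check — the diagnostics make failure visible but
  not impossible.
- The phantom's thickness bias is spatially uniform per case; real models
  err regionally. A regional bias would depress 3D DSC further at equal
  volume ratio.
- Silhouette DSC compares *aligned* images; any residual alignment error is
  charged against the model. At the default 0.1 mm/px this contributes
  ≲ 0.5 % for plateau-sized objects.
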