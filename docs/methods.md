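# Methods

## Coordinate model

Everything lives in physical µm coordinates.  A raster image carries a
pixel spacing (µm/px per axis) and an origin — the µm position of the
*center* of pixel (0, 0); x is the column axis, y the row axis.  Block-mean
downscaling by factor *f* multiplies the spacing by *f* and moves the
origin to the center of the first block (`origin + (f−1)/2 · spacing`), so
a tissue landmark keeps the same physical coordinates at every pyramid
level and after cropping.  Output sizes are floor-truncated
(`48 960 × 36 480 → 1530 × 1140` at 1/32).  Pyramid levels read from a file
are assumed to be block averages of level 0; the package recomputes
downscales itself so synthetic fixtures need no pre-built pyramid.

Brightness normalization maps the 1st–99th intensity percentiles (defaults;
configurable) linearly onto [0, 255] with clipping.  It exists to make two
differently exposed scans comparable; any common affine window would do,
since the correlation metric is itself invariant to gain and offset.

## Registration

**Direction.** The fitted transform maps fixed (reference, slide 1)
physical points into moving (target, slide 2) space.  All cell coordinates
of slide 1 are pushed through it; no inverse is ever computed.

**Metric.** Negative squared normalized cross-correlation
`C(f, m) = −⟨f−f̄, m−m̄⟩² / (|f−f̄|² |m−m̄|²)` over intensity samples, in
[−1, 0], lower better.  Squaring avoids square roots and makes the sign of
the linear relationship irrelevant.  The metric is evaluated on a seeded
random 10% of fixed-grid pixels (configurable); out-of-overlap samples read
0 from the resampled moving image.

**Stage 1 — rigid.** `T(x) = A(x−c)+t+c`, rotation about the geometric
center of the fixed extent.  Parameters are optimized with L-BFGS-B
(scipy), with the angle rescaled to arc-length at the image half-diagonal
so rotation and translation gradients are commensurate — ITK's LBFGSB
ignores parameter scales, which is why this stage runs on the package's own
sampled-NCC implementation rather than through SimpleITK.  Initialization
is deterministic: translation from the intensity center-of-mass offset,
rotation from a coarse sweep over ±15° in 1° steps (matching the bounded
orientations serial sections actually show), then quasi-Newton refinement
with a 1 µm finite-difference step, `ftol 1e−12`, `gtol 1e−10`, ≤100
iterations.  A user-supplied initial transform (e.g. after a pre-flip for
upside-down scans — a reflection is outside the rigid model) bypasses the
automatic start.  If optimization fails to improve on its start, the start
is returned flagged not-converged.

**Stage 2 — B-spline.** A cubic free-form deformation on a regular
control-point grid spanning the fixed extent padded by one control spacing
per side (configurable), mesh size *M* per axis ⇒ `M + 3` control points
per axis, control spacing `h = padded extent / M`.  Displacement is the
cardinal cubic kernel sum over the 4×4 neighboring control points; the
layout is bit-compatible with SimpleITK's `BSplineTransform`, verified in
tests by comparing the package's kernel-sum evaluation against
`TransformPoint` and an independent brute-force double loop.  Only the
control displacements are optimized (SimpleITK `MetricAsCorrelation` +
`LBFGSB`, gradient tolerance 1e−5, ≤100 iterations, seeded 10% sampling),
composed *after* the fixed rigid stage: setting the registration's
fixed-initial transform to the rigid inverse makes the optimized map
exactly `x ↦ B(R(x))`.  The composite applies rigid first, then adds the
displacement evaluated at the rigidly mapped point.  If the final metric is
worse than the zero-displacement start, the zero-displacement composite is
returned flagged not-converged.

Both stages are single-resolution (the 1/32 image is already the working
scale); no pyramid schedule.  All randomness flows from explicit integer
seeds; identical inputs and seeds reproduce identical transforms.

## Deformation QC

* **Jacobian map**: `det[I + ∂u/∂x]` with `u(x) = T(x) − x`, gradients by
  central differences in physical units (one-sided at borders).  Standard
  sign convention: 1 = area-preserving, > 1 = local expansion of the fixed
  domain.  Some tools label the opposite sign "compression"; the rendered
  legend is therefore configurable rather than hard-coded.  A rigid-only
  composite scores exactly 1 everywhere.
* **Deformation grid**: the regular grid warped by the B-spline
  displacement, control points as dots and their displacements as arrows,
  drawn over the resampled moving image.
* **Mesh sweep**: one shared rigid fit, then a B-spline fit per mesh size;
  each row records the final correlation (−metric) and, when matched
  landmarks are supplied, the median misalignment.  A failing mesh flags
  its row and the sweep continues.  Meshes of 1–10 are the practical range;
  larger meshes buy training correlation but can over-align.
* **Raster correlation**: Pearson correlation of the two slides' 2-D
  cell-count histograms on a shared grid (default bin 100 µm) — an
  automatic whole-slide alignment proxy usable before and after fitting.

## Clipping and integration

Exclusion polygons are GeoJSON in target-slide (slide 2) µm coordinates,
validated on load (≥3 vertices, no self-intersection) and applied after
transformation; regions drawn in reference-slide space must be supplied
pre-transformed.  Membership uses shapely `covers`: boundary points count
as excluded, so an ambiguous cell is dropped rather than kept.  Both
slides' cells inside a region are removed — regions mark tissue that is
non-alignable for the *pair* — which also makes filtering idempotent.
Merging refuses duplicate `(slide_id, cell_id)` pairs and reports kept and
dropped counts per region.  A common marker stained in both panels (e.g.
Cytokeratin) gives a quick sanity check: the fraction of marker⁺ cells with
a marker⁺ partner within a radius, in both directions.

## Synthetic serial slides

The generator emulates a 1/32-downscaled DAPI channel: one contiguous
tissue section (a random smooth blob from an ellipse potential plus
low-frequency Gaussian noise, ~35–40% of the canvas), holding exactly
`n_cells` nuclei — half a uniform carpet, half clustered in hotspots —
splatted as Gaussian blobs (σ 3 µm, band-limited with a 1.5 px Gaussian for
the rendering grid) over smooth tissue autofluorescence.  Defaults:
1530 × 1140 px at 16 µm/px, 5000 nuclei.  Phenotypes are i.i.d. labels
(CK 35%, CD8 15%, other 50%) for exercising the integration and
nearest-neighbor statistics.

It does **not** emulate: true inter-section cell turnover (the twin slide
contains the *same* cells, so integration tests see perfectly matched
tables), staining variation, scanner noise or shading, anisotropic
spacing, or multi-tissue fragments.  Accuracy numbers on these simulations
therefore measure the geometry-recovery capability of the optimizer under
idealized intensity correspondence — the real-tissue error floor is
necessarily higher.

A simulated pair deforms the original with a mesh-3 B-spline whose control
displacements are uniform per component in [−max, +max] (the least-assuming
bounded law; the bound is the testable contract), composed after a bounded
random rigid perturbation (defaults ≤15°, ≤2 mm).  The ground truth stays
analytic and exact; only the deformed *image* is produced through a
numerically inverted dense displacement field (fixed-point inversion,
tolerances ≪ one pixel), which affects image realism but never the truth
used for scoring.  Landmarks are seeded pixels above the original's Otsu
threshold, so they always lie on tissue.

## Validation statistics

Misalignment error is the per-point Euclidean distance between a point
mapped by the ground-truth and by the fitted transform.  Nearest-neighbor
distances are exact minima over the target set (KD-tree, verified against
an exhaustive scan).  The bootstrap CI on a median resamples the distances
with replacement (default 1000 resamples, same size as the input) and takes
the 2.5th/97.5th percentiles of the resample medians; coverage is verified
empirically at 93–97% for n = 200.

## Problem sizes and defaults used in checks

The headline accuracy check runs at the full working scale (1530 × 1140 at
16 µm/px, mesh-3/1000 µm truth, mesh-8 fit, 100 landmarks) and completes in
a few minutes on one CPU; unit and property tests use 400 × 300 px slides
with proportionally smaller perturbations, where a two-step fit takes a few
seconds.  Across seeds the full-scale median landmark error lands around
2–5 µm, under the ~6 µm nucleus-diameter reference.

## Known limitations

* The rigid model cannot represent reflections; upside-down scans need the
  pre-flip flag.
* Exclusion regions are polygons supplied by the user; there is no
  automatic tear/fold detection.
* The B-spline stage optimizes the training correlation; very large mesh
  sizes can over-align (see the sweep tooling) and are not prevented.
* Transform direction is fixed → moving only; mapping slide-2 cells into
  slide-1 space would require a numerical inverse that is deliberately out
  of scope.
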