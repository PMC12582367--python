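# serialign

Align serial multiplex-immunofluorescence (mIF) whole-slide images and
integrate their cell tables into one coordinate system.

## The problem

mIF panels are limited to a handful of markers plus DAPI per slide.  To
phenotype more populations, adjacent ~4 µm sections of the same block are
stained with *different* panels: the two slides share tissue architecture
but contain different physical cells, are scanned in arbitrary orientation,
and are locally deformed by sectioning.  Combining their per-cell readouts
requires estimating the geometric map between the slides, checking that the
implied deformation is tissue-plausible, and excluding regions (tears,
folds, control tissue) that cannot be aligned at all.

`serialign` does this headlessly:

1. **Preprocess** — read the DAPI channel of each pyramidal slide
   (QPTIFF/OME-TIFF), downscale by block mean (default 1/32, e.g.
   48 960 × 36 480 px → 1530 × 1140 px), normalize brightness to a common
   percentile window, optionally crop/pre-flip.
2. **Register** — fit the composite transform fixed → moving
   (slide 1 → slide 2) in two steps, minimizing the negative squared
   normalized cross-correlation on a seeded random fraction of pixels with
   L-BFGS-B:
   - rigid: `T(x) = A(x − c) + t + c` (rotation `A` about center `c`,
     translation `t`);
   - cubic B-spline free-form deformation: displacement `D(x)` interpolated
     from a regular control-point grid, `control points per axis =
     mesh size + spline order`; the composite is `x ↦ y + D(y)`, `y = T(x)`.
3. **QC** — alpha-blended overlay, warped deformation grid with
   control-point displacement arrows, Jacobian-determinant map
   `det[I + ∂u/∂x]` (local area change; 1 = none), mesh-size sweep table,
   and rasterized cell-position correlation.
4. **Integrate** — map slide-1 cell coordinates (µm) through the fitted
   transform, drop cells inside exclusion polygons (GeoJSON, boundary
   counts as excluded), and merge the two panels' phenotypes.
5. **Validate** — a synthetic serial-slide simulator with an exact,
   analytic ground-truth transform, scored by per-landmark Euclidean
   misalignment, nearest-neighbor distances between phenotypes, and a
   bootstrap 95% CI on the median.

## Worked example

```python
import serialign as sa

# 1. synthetic serial pair with known ground truth (400×300 px @ 16 µm/px)
image, cells = sa.generate_synthetic_dapi(n_cells=1500, width=400, height=300,
                                          spacing=16.0, seed=5)
rigid_truth = sa.random_rigid(image, seed=6, max_translation=500.0)
pair = sa.simulate_serial_slide(image, max_displacement=300.0, mesh_size=3,
                                rigid=rigid_truth, seed=7, cells=cells)

# 2. two-step fit
settings = sa.OptimizerSettings(seed=1)
rigid, rigid_report = sa.fit_rigid(pair.original, pair.deformed, settings)
composite, report = sa.fit_bspline(pair.original, pair.deformed, rigid,
                                   mesh_size=8, settings=settings)

# 3. score against ground truth, 4. integrate the panels
result = sa.validate_alignment(pair, composite, n_points=100, seed=9)
moved = sa.transform_cells(cells, composite)
merged, summary = sa.merge_panels(moved, pair.cells_deformed)
```

prints (via the report/result fields):

```
rigid stage:    metric -0.9337
b-spline stage: metric -0.9322 -> -0.9997
median misalignment: 1.30 um (95% CI 1.09-1.45); without alignment: 224.6 um
merged cells: 3000  phenotypes: ['CD8', 'CK', 'other']
```

The metric is the negative squared correlation (−1 = perfect); the B-spline
stage lifts the correlation from 0.93 to 0.9997, and the fitted map
reproduces the hidden simulated deformation to 1.3 µm median — far below a
cell-nucleus diameter (~6 µm) — versus 225 µm with no alignment.  The
merged table holds both panels' cells in slide-2 µm coordinates.

The same pipeline runs from the shell on image files:

```bash
serialign simulate --out sim/                      # synthetic pair + truth
serialign align --slide1-image sim/original.ome.tif \
    --slide2-image sim/deformed.ome.tif \
    --slide1-cells sim/cells_slide1.csv --slide2-cells sim/cells_slide2.csv \
    --downscale 1 --mesh-size 8 --seed 1 --out run/
serialign validate --pair-dir sim/ --transform run/transform.json
```

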