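"""Deformation quality control.

The fitted transform is a hypothesis about how the second section moved
relative to the first; these tools make that hypothesis inspectable:

* Jacobian-determinant map det[I + ∂u/∂x] — local area change of the
  deformation (1 = none, >1 = expansion of the fixed domain under the
  standard convention; the display labeling is configurable because tools
  disagree on which sign to call "compression").
* Warped deformation grid with control points and displacement arrows.
* Mesh-size sweep: correlation and optional landmark error per mesh size.
* Rasterized cell-position correlation before/after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, DegenerateInputError
from .imaging import OverlayImage, RasterImage
from .registration import AlignmentReport, OptimizerSettings, fit_bspline, fit_rigid
from .transforms import BSplineField, CompositeTransform

DEFAULT_RASTER_BIN = 100.0  # µm; cell-position histogram bin


@dataclass
class JacobianMap:
    """Per-pixel determinant of the deformation gradient, on the fixed grid."""

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]


@dataclass
class SweepRow:
    """One mesh size of a sweep: training correlation and optional accuracy."""

    mesh_size: int
    final_correlation: float
    elapsed_seconds: float
    landmark_error_median: float | None = None
    failed: bool = False
    error: str | None = None


def _total_displacement(transform, grid: RasterImage) -> np.ndarray:
    """u(x) = T(x) - x on every grid pixel, shape (H, W, 2) µm."""
    pts = grid.grid_points()
    if isinstance(transform, BSplineField):
        disp = transform.displacement(pts)
    else:
        disp = transform.apply(pts) - pts
    return disp.reshape(grid.height, grid.width, 2)


def jacobian_map(transform, grid: RasterImage) -> JacobianMap:
    """det[I + ∂u/∂x] of the displacement field, central differences in µm.

    Accepts a composite transform, a bare B-spline field, or a rigid
    transform (whose determinant is identically 1, rotations preserving
    area).  Boundary pixels use one-sided differences (np.gradient).
    """
    u = _total_displacement(transform, grid)
    sx, sy = grid.spacing
    dux_dy, dux_dx = np.gradient(u[:, :, 0], sy, sx)
    duy_dy, duy_dx = np.gradient(u[:, :, 1], sy, sx)
    det = (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx
    return JacobianMap(det, grid.spacing, grid.origin)


def deformation_grid_render(transform: CompositeTransform, reference: RasterImage,
                            line_spacing: float | None = None,
                            resampled: RasterImage | None = None) -> OverlayImage:
    """Render the warped regular grid, control points (dots) and displacement
    arrows over the resampled moving image; returns an RGB overlay."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    ext = reference.physical_extent
    if line_spacing is None:
        line_spacing = max(ext) / 20.0
    if line_spacing <= 0:
        raise ArgumentError("line_spacing must be positive")

    fig = Figure(figsize=(8, 8 * ext[1] / ext[0]), dpi=110)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_axes([0, 0, 1, 1])
    background = resampled if resampled is not None else reference
    ax.imshow(background.pixels, cmap="gray",
              extent=[background.origin[0] - background.spacing[0] / 2,
                      background.origin[0] + ext[0] - background.spacing[0] / 2,
                      background.origin[1] + ext[1] - background.spacing[1] / 2,
                      background.origin[1] - background.spacing[1] / 2])

    ox, oy = reference.origin
    n_dense = 200
    xs = np.arange(ox, ox + ext[0] + line_spacing / 2, line_spacing)
    ys = np.arange(oy, oy + ext[1] + line_spacing / 2, line_spacing)
    dense_x = np.linspace(ox, ox + ext[0], n_dense)
    dense_y = np.linspace(oy, oy + ext[1], n_dense)
    for x0 in xs:  # vertical lines
        line = np.stack([np.full(n_dense, x0), dense_y], axis=1)
        warped = line + (transform.apply(line) - transform.rigid.apply(line))
        ax.plot(warped[:, 0], warped[:, 1], color="tab:orange", lw=0.6)
    for y0 in ys:  # horizontal lines
        line = np.stack([dense_x, np.full(n_dense, y0)], axis=1)
        warped = line + (transform.apply(line) - transform.rigid.apply(line))
        ax.plot(warped[:, 0], warped[:, 1], color="tab:orange", lw=0.6)

    if transform.bspline is not None:
        bs = transform.bspline
        _, ny, nx = bs.coefficients.shape
        jx, jy = np.meshgrid(np.arange(nx), np.arange(ny))
        cps = np.stack([bs.grid_origin[0] + jx.ravel() * bs.grid_spacing[0],
                        bs.grid_origin[1] + jy.ravel() * bs.grid_spacing[1]], axis=1)
        disp = np.stack([bs.coefficients[0].ravel(), bs.coefficients[1].ravel()], axis=1)
        ax.plot(cps[:, 0], cps[:, 1], ".", color="tab:blue", ms=4)
        ax.quiver(cps[:, 0], cps[:, 1], disp[:, 0], disp[:, 1],
                  angles="xy", scale_units="xy", scale=1.0, color="black", width=0.002)

    ax.set_xlim(ox - line_spacing, ox + ext[0] + line_spacing)
    ax.set_ylim(oy + ext[1] + line_spacing, oy - line_spacing)
    ax.axis("off")
    canvas.draw()
    rgb = np.asarray(canvas.buffer_rgba())[:, :, :3].copy()
    return OverlayImage(rgb.astype(np.float64), rgb[:, :, 0].astype(np.float64),
                        {"kind": "deformation_grid", "line_spacing": line_spacing})


def mesh_sweep(fixed: RasterImage, moving: RasterImage, mesh_sizes,
               landmarks: tuple[np.ndarray, np.ndarray] | None = None,
               settings: OptimizerSettings | None = None,
               ) -> tuple[list[SweepRow], AlignmentReport]:
    """Fit the rigid stage once, then one B-spline fit per requested mesh size.

    ``landmarks`` is an optional matched pair (fixed-space points,
    true moving-space points); when given, each row records the median
    misalignment of the fitted transform on them.  A failing mesh size flags
    its row and the sweep continues.
    """
    mesh_sizes = list(mesh_sizes)
    if not mesh_sizes or any(m < 1 for m in mesh_sizes):
        raise ArgumentError(f"mesh_sizes must be non-empty, each >= 1: {mesh_sizes}")
    rigid, rigid_report = fit_rigid(fixed, moving, settings)
    rows: list[SweepRow] = []
    for mesh in sorted(mesh_sizes):
        try:
            composite, report = fit_bspline(fixed, moving, rigid, mesh, settings)
            med = None
            if landmarks is not None:
                src, true_dst = landmarks
                err = np.linalg.norm(composite.apply(src) - np.atleast_2d(true_dst), axis=1)
                med = float(np.median(err))
            rows.append(SweepRow(mesh, report.final_correlation,
                                 report.elapsed_seconds, med))
        except Exception as exc:  # keep sweeping the remaining mesh sizes
            rows.append(SweepRow(mesh, float("nan"), 0.0, None, True, str(exc)))
    return rows, rigid_report


def raster_correlation(cells_a, cells_b, bin_size: float = DEFAULT_RASTER_BIN) -> float:
    """Pearson correlation of 2-D cell-count histograms on a shared grid.

    An automatic whole-slide proxy for alignment quality: well-aligned serial
    sections place their cells in the same tissue compartments, so their
    rasterized positions correlate.
    """
    if bin_size <= 0:
        raise ArgumentError("bin_size must be positive")
    a = _xy(cells_a)
    b = _xy(cells_b)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("empty cell table")
    lo = np.minimum(a.min(axis=0), b.min(axis=0))
    hi = np.maximum(a.max(axis=0), b.max(axis=0))
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / bin_size)))
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / bin_size)))
    edges_x = lo[0] + bin_size * np.arange(nx + 1)
    edges_y = lo[1] + bin_size * np.arange(ny + 1)
    ha, _, _ = np.histogram2d(a[:, 0], a[:, 1], bins=[edges_x, edges_y])
    hb, _, _ = np.histogram2d(b[:, 0], b[:, 1], bins=[edges_x, edges_y])
    if ha.std() == 0 or hb.std() == 0:
        raise DegenerateInputError("degenerate (constant) rasterized histogram")
    return float(np.corrcoef(ha.ravel(), hb.ravel())[0, 1])


def _xy(cells) -> np.ndarray:
    if hasattr(cells, "columns"):
        return cells[["x", "y"]].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(cells, dtype=float))
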