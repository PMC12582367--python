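"""Two-step intensity-based registration of downscaled DAPI images.

Stage 1 fits a rigid transform (rotation + translation) by bounded
quasi-Newton (L-BFGS-B) minimization of the negative squared normalized
cross-correlation, computed on a seeded random fraction of fixed-grid
pixels.  Stage 2 starts from that optimum and optimizes only the
control-point displacements of a cubic B-spline field composed after the
rigid stage, through SimpleITK's correlation metric and LBFGSB optimizer.

Both stages operate on the single downscaled resolution; there is no
multi-level pyramid schedule.  Because a rigid perturbation of several
degrees plus millimetres sits outside the plain NCC capture basin, the rigid
stage is initialized deterministically: translation from the intensity
centers of mass, rotation from a coarse bounded sweep, then refinement.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import minimize

from .errors import ArgumentError, DegenerateInputError
from .imaging import RasterImage
from .transforms import SPLINE_ORDER, BSplineField, CompositeTransform, RigidTransform


@dataclass
class OptimizerSettings:
    """Tunable knobs of both optimization stages (all exposed in config)."""

    sampling_fraction: float = 0.1  # fraction of fixed pixels fed to the metric
    max_iterations: int = 100  # per stage
    gradient_tolerance: float = 1e-5  # LBFGSB projected-gradient stop (B-spline stage)
    rigid_gradient_tolerance: float = 1e-10  # scipy L-BFGS-B gtol (rigid stage)
    rigid_function_tolerance: float = 1e-12  # scipy L-BFGS-B ftol (rigid stage)
    rigid_finite_difference_step: float = 1.0  # µm, numeric-gradient step
    rotation_search_deg: float = 15.0  # coarse init sweep half-range
    rotation_search_step_deg: float = 1.0
    domain_padding_spacings: float = 1.0  # B-spline domain pad, in control spacings
    seed: int = 0


@dataclass
class AlignmentReport:
    """Per-stage bookkeeping of one optimization run."""

    stage: str
    initial_metric: float
    final_metric: float
    iterations: int
    converged: bool
    mesh_size: int | None = None
    elapsed_seconds: float = 0.0
    details: dict = field(default_factory=dict)

    @property
    def final_correlation(self) -> float:
        """Pixel-wise correlation, the sign-flipped metric (1 = perfect)."""
        return -self.final_metric


def ncc_metric(fixed_samples, moving_samples) -> float:
    """Negative squared normalized cross-correlation, in [-1, 0]; lower is better.

    C(f, m) = -<f - f̄, m - m̄>² / (|f - f̄|² |m - m̄|²)
    """
    f = np.asarray(fixed_samples, dtype=np.float64).ravel()
    m = np.asarray(moving_samples, dtype=np.float64).ravel()
    if f.shape != m.shape:
        raise ArgumentError(f"length mismatch: {f.shape} vs {m.shape}")
    if f.size < 2:
        raise ArgumentError("need at least 2 samples")
    fc = f - f.mean()
    mc = m - m.mean()
    denom = (fc @ fc) * (mc @ mc)
    if denom == 0.0:
        raise DegenerateInputError("zero-variance input to ncc_metric")
    return -((fc @ mc) ** 2) / denom


def _ncc_or_zero(fc, fc_ss, m) -> float:
    # inner loop of the rigid fit: empty-overlap panes score 0 (worst)
    mc = m - m.mean()
    denom = fc_ss * (mc @ mc)
    if denom == 0.0:
        return 0.0
    return -((fc @ mc) ** 2) / denom


def resample(moving: RasterImage, transform, reference: RasterImage) -> RasterImage:
    """Pull moving-image intensities onto the reference grid through ``transform``.

    Each reference pixel center is mapped into moving space and sampled with
    bilinear interpolation; locations outside the moving extent get 0.
    """
    pts = transform.apply(reference.grid_points())
    idx = moving.physical_to_index(pts)
    vals = ndi.map_coordinates(
        moving.pixels.astype(np.float64),
        [idx[:, 1], idx[:, 0]],
        order=1, mode="constant", cval=0.0,
    )
    return RasterImage(vals.reshape(reference.height, reference.width),
                       reference.spacing, reference.origin)


def _center_of_mass(image: RasterImage) -> np.ndarray:
    a = image.pixels.astype(np.float64)
    tot = a.sum()
    if tot <= 0:
        raise DegenerateInputError("image has no intensity mass")
    rows, cols = np.indices(a.shape)
    return np.array([
        image.origin[0] + (a * cols).sum() / tot * image.spacing[0],
        image.origin[1] + (a * rows).sum() / tot * image.spacing[1],
    ])


def _sample_fixed(fixed: RasterImage, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    n = max(2, int(round(fraction * fixed.pixels.size)))
    idx = rng.choice(fixed.pixels.size, size=min(n, fixed.pixels.size), replace=False)
    rows, cols = np.unravel_index(idx, fixed.pixels.shape)
    samples = fixed.pixels.astype(np.float64)[rows, cols]
    pts = fixed.index_to_physical(cols, rows)
    return samples, pts


def fit_rigid(fixed: RasterImage, moving: RasterImage,
              settings: OptimizerSettings | None = None,
              initial: RigidTransform | None = None,
              ) -> tuple[RigidTransform, AlignmentReport]:
    """Estimate the rigid stage by sampled-NCC L-BFGS-B minimization.

    The rotation center is the geometric center of the fixed extent.  If no
    ``initial`` transform is supplied, translation starts at the
    center-of-mass offset and rotation at the best value of a coarse bounded
    sweep.  Returns the initialization flagged not-converged if optimization
    fails to improve on it.
    """
    settings = settings or OptimizerSettings()
    t0 = time.time()
    if np.ptp(fixed.pixels) == 0 or np.ptp(moving.pixels) == 0:
        raise DegenerateInputError("constant image cannot be registered")

    fsamp, pts = _sample_fixed(fixed, settings.sampling_fraction, settings.seed)
    fc = fsamp - fsamp.mean()
    fc_ss = fc @ fc
    if fc_ss == 0:
        raise DegenerateInputError("sampled fixed pixels are constant")
    marr = moving.pixels.astype(np.float64)
    mox, moy = moving.origin
    msx, msy = moving.spacing

    cx = fixed.origin[0] + (fixed.width - 1) / 2.0 * fixed.spacing[0]
    cy = fixed.origin[1] + (fixed.height - 1) / 2.0 * fixed.spacing[1]
    center = np.array([cx, cy])
    # one scale for all parameters: radians are measured in arc-µm at the
    # half-diagonal so rotation and translation see comparable gradients
    scale = float(np.hypot(*fixed.physical_extent)) / 2.0

    px = pts[:, 0] - cx
    py = pts[:, 1] - cy

    def metric(q: np.ndarray) -> float:
        th = q[0] / scale
        ca, sa = np.cos(th), np.sin(th)
        x = ca * px - sa * py + q[1] + cx
        y = sa * px + ca * py + q[2] + cy
        m = ndi.map_coordinates(marr, [(y - moy) / msy, (x - mox) / msx],
                                order=1, mode="constant", cval=0.0)
        return _ncc_or_zero(fc, fc_ss, m)

    if initial is not None:
        q0 = np.array([initial.angle * scale, initial.translation[0], initial.translation[1]])
        # re-express about our center: A(x-c0)+t0+c0 = A(x-c)+t'+c
        # with t' = t0 + A(c-c0) - (c-c0)
        c0 = np.asarray(initial.center)
        d = center - c0
        q0[1:] = np.asarray(initial.translation) + initial.matrix @ d - d
        start_desc = "user"
    else:
        t_init = _center_of_mass(moving) - _center_of_mass(fixed)
        sweep = np.arange(-settings.rotation_search_deg,
                          settings.rotation_search_deg + 1e-9,
                          settings.rotation_search_step_deg)
        vals = [metric(np.array([np.deg2rad(d) * scale, t_init[0], t_init[1]]))
                for d in sweep]
        best = sweep[int(np.argmin(vals))]
        q0 = np.array([np.deg2rad(best) * scale, t_init[0], t_init[1]])
        start_desc = f"com+sweep({best:+.0f}deg)"

    m0 = metric(q0)
    res = minimize(
        metric, q0, method="L-BFGS-B",
        options=dict(
            maxiter=settings.max_iterations,
            ftol=settings.rigid_function_tolerance,
            gtol=settings.rigid_gradient_tolerance,
            eps=settings.rigid_finite_difference_step,
        ),
    )
    improved = res.fun < m0
    q = res.x if improved else q0
    final = float(res.fun if improved else m0)
    transform = RigidTransform(float(q[0] / scale), (cx, cy), (float(q[1]), float(q[2])))
    report = AlignmentReport(
        stage="rigid",
        initial_metric=float(m0),
        final_metric=final,
        iterations=int(res.nit),
        converged=bool(improved),
        elapsed_seconds=time.time() - t0,
        details={"initialization": start_desc, "message": str(res.message)},
    )
    return transform, report


def _to_sitk_image(image: RasterImage):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(image.pixels.astype(np.float64))
    img.SetSpacing((float(image.spacing[0]), float(image.spacing[1])))
    img.SetOrigin((float(image.origin[0]), float(image.origin[1])))
    return img


def fit_bspline(fixed: RasterImage, moving: RasterImage, init: RigidTransform,
                mesh_size: int, settings: OptimizerSettings | None = None,
                ) -> tuple[CompositeTransform, AlignmentReport]:
    """Optimize B-spline control displacements composed after the rigid stage.

    The transform domain covers the fixed-image extent padded by
    ``settings.domain_padding_spacings`` control spacings per side, so the
    displacement stays defined where the rigid stage maps border pixels.
    If the optimizer ends worse than the zero-displacement start, the
    zero-displacement composite is returned flagged not-converged.
    """
    import SimpleITK as sitk

    settings = settings or OptimizerSettings()
    if mesh_size < 1:
        raise ArgumentError(f"mesh_size must be >= 1, got {mesh_size}")
    t0 = time.time()
    if np.ptp(fixed.pixels) == 0 or np.ptp(moving.pixels) == 0:
        raise DegenerateInputError("constant image cannot be registered")

    fimg = _to_sitk_image(fixed)
    mimg = _to_sitk_image(moving)

    ext = fixed.physical_extent
    h0 = (ext[0] / mesh_size, ext[1] / mesh_size)
    pad = settings.domain_padding_spacings
    dom_origin = (fixed.origin[0] - fixed.spacing[0] / 2.0 - pad * h0[0],
                  fixed.origin[1] - fixed.spacing[1] / 2.0 - pad * h0[1])
    dom_dims = (ext[0] + 2 * pad * h0[0], ext[1] + 2 * pad * h0[1])
    field0 = BSplineField.zeros(dom_origin, dom_dims, mesh_size)
    bs = field0.to_sitk()

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(settings.sampling_fraction, settings.seed + 1)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(bs, inPlace=True)
    # fixed-initial = rigid⁻¹ makes the optimized map exactly B(R(x)):
    # the metric compares fixed(R⁻¹(v)) with moving(B(v)), v on the fixed grid
    reg.SetFixedInitialTransform(init.inverse().to_sitk())
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=settings.gradient_tolerance,
        numberOfIterations=settings.max_iterations,
    )
    initial_metric = float(reg.MetricEvaluate(fimg, mimg))
    fitted = reg.Execute(fimg, mimg)
    final_metric = float(reg.GetMetricValue())
    converged = final_metric <= initial_metric
    if not converged:
        composite = CompositeTransform(init, field0)
        final_metric = initial_metric
    else:
        composite = CompositeTransform(
            init, BSplineField.from_sitk(sitk.BSplineTransform(fitted)))
    report = AlignmentReport(
        stage="bspline",
        initial_metric=initial_metric,
        final_metric=final_metric,
        iterations=int(reg.GetOptimizerIteration()),
        converged=converged,
        mesh_size=mesh_size,
        elapsed_seconds=time.time() - t0,
        details={"stop": reg.GetOptimizerStopConditionDescription()},
    )
    return composite, report
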