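"""Geometric transforms: rigid, B-spline free-form deformation, composite.

The mapping direction is fixed throughout the package: a fitted transform
sends physical points of the *fixed* (reference, slide 1) space into the
*moving* (target, slide 2) space.  A composite applies its rigid stage first
and then adds the B-spline displacement evaluated at the rigidly mapped
point:  ``T(x) = y + D(y)``, ``y = A(x - c) + t + c``.

The B-spline displacement field follows the classic free-form-deformation
model: a regular control-point grid with spacing ``h = domain / mesh_size``
and ``mesh_size + spline_order`` control points per axis, interpolated with
the cardinal cubic B-spline kernel.  The layout is bit-compatible with
SimpleITK's ``BSplineTransform`` (grid origin one spacing before the domain
origin), so transforms fitted by the optimizer can be stored, serialized and
evaluated natively here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError

SPLINE_ORDER = 3  # cubic, the default polynomial degree


def control_point_count(mesh_size: int, spline_order: int = SPLINE_ORDER) -> int:
    """Control points per axis: mesh_size + spline_order."""
    if mesh_size < 1:
        raise ArgumentError(f"mesh_size must be >= 1, got {mesh_size}")
    if spline_order < 0:
        raise ArgumentError(f"spline_order must be >= 0, got {spline_order}")
    return mesh_size + spline_order


def cubic_bspline_kernel(t):
    """Cardinal cubic B-spline β₃(t); support |t| < 2, partition of unity."""
    at = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(at)
    near = at < 1
    far = (at >= 1) & (at < 2)
    out[near] = (4.0 - 6.0 * at[near] ** 2 + 3.0 * at[near] ** 3) / 6.0
    out[far] = (2.0 - at[far]) ** 3 / 6.0
    return out


@dataclass
class RigidTransform:
    """Rotation by ``angle`` about ``center`` plus translation: T(x)=A(x-c)+t+c."""

    angle: float = 0.0  # radians
    center: tuple[float, float] = (0.0, 0.0)  # µm
    translation: tuple[float, float] = (0.0, 0.0)  # µm

    @property
    def matrix(self) -> np.ndarray:
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        return np.array([[ca, -sa], [sa, ca]])

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c = np.asarray(self.center, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        return (pts - c) @ self.matrix.T + t + c

    def inverse(self) -> "RigidTransform":
        a_t = self.matrix.T
        t_inv = -(a_t @ np.asarray(self.translation))
        return RigidTransform(-self.angle, tuple(self.center), tuple(t_inv))

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self):
        import SimpleITK as sitk

        t = sitk.Euler2DTransform()
        t.SetAngle(float(self.angle))
        t.SetCenter(tuple(float(v) for v in self.center))
        t.SetTranslation(tuple(float(v) for v in self.translation))
        return t

    @classmethod
    def from_sitk(cls, t) -> "RigidTransform":
        return cls(t.GetAngle(), tuple(t.GetCenter()), tuple(t.GetTranslation()))

    def to_dict(self) -> dict:
        return {
            "type": "rigid",
            "angle": float(self.angle),
            "center": [float(v) for v in self.center],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["angle"], tuple(d["center"]), tuple(d["translation"]))


@dataclass
class BSplineField:
    """Cubic B-spline displacement field on a regular control-point grid.

    ``coefficients`` has shape (2, ny, nx): per-axis µm displacement
    coefficients on the grid, x component first.  ``grid_origin`` is the µm
    position of control point (0, 0) — one grid spacing *before* the domain
    origin — and ``grid_spacing`` is the control-point pitch per axis.
    Points outside the control grid's support receive zero displacement.
    """

    grid_origin: tuple[float, float]
    grid_spacing: tuple[float, float]
    coefficients: np.ndarray
    spline_order: int = SPLINE_ORDER

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 3 or self.coefficients.shape[0] != 2:
            raise ArgumentError(
                f"coefficients must have shape (2, ny, nx), got {self.coefficients.shape}")
        if self.spline_order != SPLINE_ORDER:
            raise ArgumentError("only cubic (order 3) B-spline fields are supported")

    @property
    def mesh_size(self) -> tuple[int, int]:
        ny, nx = self.coefficients.shape[1:]
        return (nx - self.spline_order, ny - self.spline_order)

    @property
    def domain_origin(self) -> tuple[float, float]:
        return (self.grid_origin[0] + self.grid_spacing[0],
                self.grid_origin[1] + self.grid_spacing[1])

    @property
    def domain_physical_dimensions(self) -> tuple[float, float]:
        mx, my = self.mesh_size
        return (mx * self.grid_spacing[0], my * self.grid_spacing[1])

    @classmethod
    def zeros(cls, domain_origin, domain_physical_dimensions, mesh_size) -> "BSplineField":
        """Identity field over a physical domain with the given mesh size per axis."""
        mx, my = (mesh_size, mesh_size) if np.isscalar(mesh_size) else mesh_size
        if mx < 1 or my < 1:
            raise ArgumentError(f"mesh_size must be >= 1, got {mesh_size}")
        hx = domain_physical_dimensions[0] / mx
        hy = domain_physical_dimensions[1] / my
        nx, ny = mx + SPLINE_ORDER, my + SPLINE_ORDER
        return cls(
            (domain_origin[0] - hx, domain_origin[1] - hy),
            (hx, hy),
            np.zeros((2, ny, nx)),
        )

    def displacement(self, points) -> np.ndarray:
        """Kernel-sum displacement D(x) at physical points, shape (N, 2) µm."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        ux = (pts[:, 0] - self.grid_origin[0]) / self.grid_spacing[0]
        uy = (pts[:, 1] - self.grid_origin[1]) / self.grid_spacing[1]
        lx = np.floor(ux).astype(np.int64)
        ly = np.floor(uy).astype(np.int64)
        _, ny, nx = self.coefficients.shape
        out = np.zeros((pts.shape[0], 2))
        for dy in (-1, 0, 1, 2):
            jy = ly + dy
            wy = cubic_bspline_kernel(uy - jy)
            oky = (jy >= 0) & (jy < ny)
            jyc = np.clip(jy, 0, ny - 1)
            for dx in (-1, 0, 1, 2):
                jx = lx + dx
                wx = cubic_bspline_kernel(ux - jx)
                ok = oky & (jx >= 0) & (jx < nx)
                jxc = np.clip(jx, 0, nx - 1)
                w = np.where(ok, wx * wy, 0.0)
                out[:, 0] += w * self.coefficients[0, jyc, jxc]
                out[:, 1] += w * self.coefficients[1, jyc, jxc]
        return out

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts + self.displacement(pts)

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self):
        import SimpleITK as sitk

        bs = sitk.BSplineTransform(2, self.spline_order)
        _, ny, nx = self.coefficients.shape
        bs.SetFixedParameters((
            float(nx), float(ny),
            float(self.grid_origin[0]), float(self.grid_origin[1]),
            float(self.grid_spacing[0]), float(self.grid_spacing[1]),
            1.0, 0.0, 0.0, 1.0,
        ))
        bs.SetParameters(tuple(np.concatenate(
            [self.coefficients[0].ravel(), self.coefficients[1].ravel()])))
        return bs

    @classmethod
    def from_sitk(cls, bs) -> "BSplineField":
        fixed = bs.GetFixedParameters()
        nx, ny = int(fixed[0]), int(fixed[1])
        origin = (fixed[2], fixed[3])
        spacing = (fixed[4], fixed[5])
        params = np.asarray(bs.GetParameters(), dtype=np.float64)
        coeffs = np.stack([
            params[: nx * ny].reshape(ny, nx),
            params[nx * ny :].reshape(ny, nx),
        ])
        return cls(origin, spacing, coeffs)

    def to_dict(self) -> dict:
        return {
            "type": "bspline",
            "grid_origin": [float(v) for v in self.grid_origin],
            "grid_spacing": [float(v) for v in self.grid_spacing],
            "spline_order": self.spline_order,
            "mesh_size": list(self.mesh_size),
            "coefficients_x": self.coefficients[0].tolist(),
            "coefficients_y": self.coefficients[1].tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineField":
        coeffs = np.stack([np.asarray(d["coefficients_x"]), np.asarray(d["coefficients_y"])])
        return cls(tuple(d["grid_origin"]), tuple(d["grid_spacing"]), coeffs,
                   d.get("spline_order", SPLINE_ORDER))


@dataclass
class CompositeTransform:
    """Rigid stage followed by a B-spline displacement stage (fixed → moving)."""

    rigid: RigidTransform = field(default_factory=RigidTransform)
    bspline: BSplineField | None = None

    @property
    def stages(self) -> list:
        return [self.rigid] if self.bspline is None else [self.rigid, self.bspline]

    def apply(self, points) -> np.ndarray:
        y = self.rigid.apply(points)
        if self.bspline is not None:
            y = y + self.bspline.displacement(y)
        return y

    def to_sitk(self):
        import SimpleITK as sitk

        comp = sitk.CompositeTransform(2)
        if self.bspline is not None:
            comp.AddTransform(self.bspline.to_sitk())
        comp.AddTransform(self.rigid.to_sitk())  # last added is applied first
        return comp

    def to_dict(self) -> dict:
        return {
            "type": "composite",
            "direction": "fixed_to_moving",
            "stages": [s.to_dict() for s in self.stages],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeTransform":
        rigid = None
        bspline = None
        for s in d["stages"]:
            if s["type"] == "rigid":
                rigid = RigidTransform.from_dict(s)
            elif s["type"] == "bspline":
                bspline = BSplineField.from_dict(s)
            else:
                raise ArgumentError(f"unknown stage type {s['type']!r}")
        if rigid is None:
            raise ArgumentError("composite requires a rigid stage")
        return cls(rigid, bspline)


def save_transform(transform: CompositeTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=1)


def load_transform(path) -> CompositeTransform:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("type") != "composite":
        raise ArgumentError(f"not a composite transform file: {path}")
    return CompositeTransform.from_dict(d)
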