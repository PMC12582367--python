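"""Raster image model and whole-slide preprocessing.

A :class:`RasterImage` is a 2-D scalar intensity grid with physical pixel
spacing (µm/px) and a physical origin: the µm coordinate of the *center* of
the pixel at grid index ``(0, 0)``.  x is the column axis, y the row axis.
All geometry bookkeeping in the package goes through this one convention so
that downscaling, pyramid levels and cropping never introduce half-pixel
drift.

Whole-slide inputs are pyramidal TIFF-family files (QPTIFF / OME-TIFF); only
pixel data, pyramid levels and channel count are interpreted — no vendor
metadata parsing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import ArgumentError, DegenerateInputError, FormatError

#: Fallback physical pixel size of the level-0 scan, µm per pixel.
DEFAULT_BASE_SPACING = 0.5

#: Fixed output ceiling of brightness normalization (8-bit-like scale).
NORMALIZED_MAX = 255.0


@dataclass
class RasterImage:
    """2-D intensity grid with physical geometry (the unit of registration)."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)  # (sx, sy) µm per pixel
    origin: tuple[float, float] = (0.0, 0.0)  # µm of pixel-center (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ArgumentError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.width < 1 or self.height < 1:
            raise ArgumentError("image must contain at least one pixel")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ArgumentError(f"spacing must be positive, got {self.spacing}")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def physical_extent(self) -> tuple[float, float]:
        """(width · sx, height · sy) in µm."""
        return (self.width * self.spacing[0], self.height * self.spacing[1])

    def index_to_physical(self, cols, rows) -> np.ndarray:
        """Pixel indices (col, row) -> physical µm points, pixel-center convention."""
        cols = np.asarray(cols, dtype=float)
        rows = np.asarray(rows, dtype=float)
        return np.stack(
            [self.origin[0] + cols * self.spacing[0], self.origin[1] + rows * self.spacing[1]],
            axis=-1,
        )

    def physical_to_index(self, points) -> np.ndarray:
        """Physical µm points -> fractional (col, row) pixel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty_like(pts)
        out[:, 0] = (pts[:, 0] - self.origin[0]) / self.spacing[0]
        out[:, 1] = (pts[:, 1] - self.origin[1]) / self.spacing[1]
        return out

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of every pixel center, shape (H·W, 2)."""
        rows, cols = np.mgrid[0 : self.height, 0 : self.width]
        return self.index_to_physical(cols.ravel(), rows.ravel())


@dataclass
class OverlayImage:
    """RGB rendering of two superposed images plus the scalar alpha blend."""

    pixels: np.ndarray  # (H, W, 3)
    blended: np.ndarray  # (H, W) = (1-alpha)·fixed + alpha·moving
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pyramidal I/O
# ---------------------------------------------------------------------------

def write_pyramidal_tiff(path, channels: np.ndarray, n_levels: int = 1,
                         spacing: float = DEFAULT_BASE_SPACING) -> None:
    """Write a multichannel pyramidal TIFF (level k = block-mean at factor 2**k).

    ``channels`` has shape (C, H, W).  Used by the synthetic simulator and the
    test fixtures; readable by :func:`load_channel` and by any OME-TIFF viewer.
    """
    channels = np.asarray(channels)
    if channels.ndim != 3:
        raise ArgumentError("channels must have shape (C, H, W)")
    with tifffile.TiffWriter(path, ome=True) as tw:
        opts = dict(tile=(128, 128), metadata={
            "axes": "CYX",
            "PhysicalSizeX": spacing, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": spacing, "PhysicalSizeYUnit": "µm",
        })
        tw.write(channels, subifds=n_levels - 1, **opts)
        level = channels
        for _ in range(n_levels - 1):
            level = np.stack([_block_mean(c, 2) for c in level])
            tw.write(level, subfiletype=1, tile=(128, 128))


def load_channel(path, channel_index: int = 0, pyramid_level: int = 0,
                 base_spacing: float | None = None) -> RasterImage:
    """Read one channel of a pyramidal TIFF at one pyramid level.

    ``base_spacing`` is the level-0 µm/px; when None it is taken from the
    file's OME ``PhysicalSizeX`` if present, else 0.5.  Spacing scales with
    the level-0/level width ratio; the origin is kept consistent in physical
    space assuming each level is a block average of level 0 (pixel-center
    convention).
    """
    if not os.path.exists(path):
        raise FormatError(f"image file not found: {path}")
    try:
        tf = tifffile.TiffFile(path)
    except Exception as exc:  # tifffile raises assorted types on non-TIFF input
        raise FormatError(f"not a readable TIFF-family image: {path}") from exc
    with tf:
        if base_spacing is None:
            base_spacing = _ome_spacing(tf) or DEFAULT_BASE_SPACING
        series = tf.series[0]
        levels = series.levels if hasattr(series, "levels") else [series]
        if not 0 <= pyramid_level < len(levels):
            raise ArgumentError(
                f"pyramid_level {pyramid_level} out of range (file has {len(levels)} levels)")
        base = np.asarray(levels[0].shape)
        arr = levels[pyramid_level].asarray()
        if arr.ndim == 2:
            arr = arr[None]
        n_channels = arr.shape[0]
        if not 0 <= channel_index < n_channels:
            raise ArgumentError(
                f"channel out of range: {channel_index} (file has {n_channels} channels)")
        plane = arr[channel_index].astype(np.float64)
    factor = base[-1] / plane.shape[1]
    spacing = base_spacing * factor
    # block center of the first level-k pixel relative to level-0 centers
    shift = (factor - 1) / 2.0 * base_spacing
    return RasterImage(plane, (spacing, spacing), (shift, shift))


def _ome_spacing(tf) -> float | None:
    """PhysicalSizeX from OME-XML metadata, if the file carries one."""
    xml = getattr(tf, "ome_metadata", None)
    if not xml:
        return None
    try:
        import xml.etree.ElementTree as ET

        for el in ET.fromstring(xml).iter():
            size = el.attrib.get("PhysicalSizeX")
            if size is not None:
                return float(size)
    except Exception:
        return None
    return None


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def downscaled_shape(width: int, height: int, factor: int) -> tuple[int, int]:
    """Output (width, height) of :func:`downscale` — metadata only, no pixel I/O."""
    if factor < 1:
        raise ArgumentError(f"downscale factor must be >= 1, got {factor}")
    return (width // factor, height // factor)


def _block_mean(pixels: np.ndarray, factor: int) -> np.ndarray:
    h, w = pixels.shape
    oh, ow = h // factor, w // factor
    trimmed = pixels[: oh * factor, : ow * factor].astype(np.float64)
    return trimmed.reshape(oh, factor, ow, factor).mean(axis=(1, 3))


def downscale(image: RasterImage, factor: int) -> RasterImage:
    """Block-mean downscaling by an integer factor (floor-truncated size).

    Matches the embedded pyramid convention (a 48 960 × 36 480 scan at factor
    32 becomes 1530 × 1140).  Spacing is multiplied by the factor and the
    origin moves to the center of the first block.
    """
    if factor < 1:
        raise ArgumentError(f"downscale factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(image, pixels=image.pixels.copy())
    out = _block_mean(image.pixels, factor)
    if out.size == 0:
        raise ArgumentError(f"factor {factor} exceeds image size {image.pixels.shape}")
    sx, sy = image.spacing
    ox, oy = image.origin
    return RasterImage(
        out,
        (sx * factor, sy * factor),
        (ox + (factor - 1) / 2.0 * sx, oy + (factor - 1) / 2.0 * sy),
    )


def normalize_brightness(image: RasterImage, low_percentile: float = 0.01,
                         high_percentile: float = 0.99) -> RasterImage:
    """Linearly rescale intensities so [p_low, p_high] maps onto [0, 255].

    Serial slides are scanned with different exposure; mapping both onto a
    common percentile window makes their DAPI intensities comparable before
    the correlation metric sees them.  Values outside the window are clipped.
    """
    if not 0 <= low_percentile < high_percentile <= 1:
        raise ArgumentError(
            f"need 0 <= low < high <= 1, got ({low_percentile}, {high_percentile})")
    lo, hi = np.quantile(image.pixels, [low_percentile, high_percentile])
    if hi <= lo:
        raise DegenerateInputError(
            "brightness percentiles coincide (constant or near-constant image)")
    out = np.clip((image.pixels - lo) / (hi - lo), 0.0, 1.0) * NORMALIZED_MAX
    return replace(image, pixels=out)


def crop(image: RasterImage, rectangle: tuple[float, float, float, float]) -> RasterImage:
    """Crop to a physical rectangle (xmin, ymin, xmax, ymax) in µm.

    Pixels whose centers fall inside the rectangle are retained, without
    resampling; the origin is updated so retained pixels keep their physical
    coordinates exactly.
    """
    xmin, ymin, xmax, ymax = rectangle
    if xmax <= xmin or ymax <= ymin:
        raise ArgumentError(f"degenerate rectangle {rectangle}")
    sx, sy = image.spacing
    ox, oy = image.origin
    c0 = max(0, int(np.ceil((xmin - ox) / sx - 1e-9)))
    c1 = min(image.width - 1, int(np.floor((xmax - ox) / sx + 1e-9)))
    r0 = max(0, int(np.ceil((ymin - oy) / sy - 1e-9)))
    r1 = min(image.height - 1, int(np.floor((ymax - oy) / sy + 1e-9)))
    if c1 < c0 or r1 < r0:
        raise ArgumentError(f"rectangle {rectangle} does not intersect the image extent")
    return RasterImage(
        image.pixels[r0 : r1 + 1, c0 : c1 + 1].copy(),
        image.spacing,
        (ox + c0 * sx, oy + r0 * sy),
    )


def flip(image: RasterImage, axis: str) -> RasterImage:
    """Mirror the image about the center of its extent ('horizontal' or 'vertical').

    Stands in for manual pre-alignment of slides scanned upside-down; the
    rigid model itself cannot represent a reflection.
    """
    if axis == "horizontal":
        return replace(image, pixels=image.pixels[:, ::-1].copy())
    if axis == "vertical":
        return replace(image, pixels=image.pixels[::-1, :].copy())
    raise ArgumentError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def blend_overlay(fixed: RasterImage, moving_resampled: RasterImage,
                  alpha: float = 0.5) -> OverlayImage:
    """Alpha-blend two images sharing one grid (moving already resampled).

    The scalar blend is ``(1-alpha)·fixed + alpha·moving``; the RGB rendering
    puts the fixed image in magenta and the moving image in green so
    superposition shows as white/grey.
    """
    if fixed.pixels.shape != moving_resampled.pixels.shape:
        raise ArgumentError(
            f"shape mismatch {fixed.pixels.shape} vs {moving_resampled.pixels.shape}")
    if fixed.spacing != moving_resampled.spacing:
        raise ArgumentError("images must share pixel spacing")
    if not 0 <= alpha <= 1:
        raise ArgumentError(f"alpha must be in [0, 1], got {alpha}")
    f = fixed.pixels.astype(np.float64)
    m = moving_resampled.pixels.astype(np.float64)
    blended = (1 - alpha) * f + alpha * m
    rgb = np.stack([(1 - alpha) * f, alpha * m, (1 - alpha) * f], axis=-1)
    return OverlayImage(rgb, blended, {"alpha": alpha})


def save_png(pixels: np.ndarray, path) -> None:
    """Write a 2-D or RGB float array as an 8-bit PNG (max-scaled)."""
    import imageio.v3 as iio

    arr = np.asarray(pixels, dtype=np.float64)
    top = arr.max()
    arr8 = np.zeros(arr.shape, np.uint8) if top <= 0 else np.clip(
        arr / top * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr8)
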