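"""Color conversion, denoising, resampling and acquisition-geometry bookkeeping.

A dermoscope frames a circular field of known physical diameter (about
17.4 mm for the device this pipeline targets).  Every length-denominated
parameter of the segmentation algorithm is stated in millimetres and
converted to pixels through the :class:`Geometry` of the acquisition, so
results are comparable across cameras and resolutions.

Pixel convention: (row, col), 0-based, pixel centers at integer
coordinates.  The image is assumed square with the circular field centred
at the image midpoint; non-square input is embedded in the smallest
enclosing square before building the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Geometry",
    "LuvImage",
    "rgb_to_luv",
    "median_denoise",
    "downsample_image",
    "build_geometry",
    "embed_in_square",
]

# sRGB (IEC 61966-2-1) linear-RGB -> XYZ matrix, D65 white.  The reference
# white used for L*u*v* is this matrix applied to (1,1,1) so that achromatic
# grays map exactly to u* = v* = 0.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE_D65 = _SRGB_TO_XYZ @ np.ones(3)

# CIE constants for the L* cube-root / linear split
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 3.0) ** 3


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry of a circular dermoscopic field.

    Parameters
    ----------
    center_px : (float, float)
        (row, col) of the field center in pixel coordinates.
    field_radius_mm : float
        Radius ``l`` of the circular imaged area, in mm.
    px_per_mm : float
        Linear scale of the image.
    d1_radius_mm : float
        Radius of the central disk ``d1`` assumed to contain (part of) the
        lesion; the annulus ``d2 = {d1 < r <= l}`` is assumed to contain
        background skin.
    """

    center_px: tuple[float, float]
    field_radius_mm: float
    px_per_mm: float
    d1_radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise InvalidParameterError("px_per_mm must be > 0")
        if not 0 < self.d1_radius_mm < self.field_radius_mm:
            raise InvalidParameterError(
                "d1_radius_mm must lie strictly between 0 and field_radius_mm"
            )

    def mm_to_px(self, mm: float) -> float:
        return mm * self.px_per_mm

    def px_to_mm(self, px: float) -> float:
        return px / self.px_per_mm

    def radius_mm_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Distance of every pixel center from the field center, in mm."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        d = np.hypot(rr - self.center_px[0], cc - self.center_px[1])
        return d / self.px_per_mm

    def field_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return self.radius_mm_map(shape) <= self.field_radius_mm

    def rescaled(self, scale: float) -> "Geometry":
        """Geometry after resampling the image by a linear factor ``scale``.

        Uses the pixel-center convention of :func:`downsample_image`:
        x_new = (x_old + 0.5) * scale - 0.5.
        """
        r, c = self.center_px
        return Geometry(
            center_px=((r + 0.5) * scale - 0.5, (c + 0.5) * scale - 0.5),
            field_radius_mm=self.field_radius_mm,
            px_per_mm=self.px_per_mm * scale,
            d1_radius_mm=self.d1_radius_mm,
        )


@dataclass
class LuvImage:
    """Per-pixel CIE L*, u*, v* channels plus the circular-field validity mask."""

    L: np.ndarray
    u: np.ndarray
    v: np.ndarray
    field_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.field_mask is None:
            self.field_mask = np.ones(self.L.shape, dtype=bool)
        shapes = {self.L.shape, self.u.shape, self.v.shape, self.field_mask.shape}
        if len(shapes) != 1:
            raise InvalidInputError("L, u, v and field_mask must share one shape")
        if not np.all(np.isfinite(self.L[self.field_mask])):
            raise InvalidInputError("L must be finite inside the field mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def stack(self) -> np.ndarray:
        """(H, W, 3) feature array in L*, u*, v* order."""
        return np.stack([self.L, self.u, self.v], axis=-1)


def _srgb_linearize(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def rgb_to_luv(image: np.ndarray, white_point=None, field_mask=None) -> LuvImage:
    """Convert an 8-bit (or [0,1] float) sRGB image to CIE L*u*v*.

    The conversion follows the CIE formulas: sRGB gamma expansion, the
    linear-RGB -> XYZ matrix, then L* from Y/Yn and u*, v* from the (u', v')
    chromaticities relative to the reference white.  ``white_point`` may be
    an (Xn, Yn, Zn) triple; the default is the sRGB-matrix white (D65), which
    makes every achromatic gray exactly achromatic in u*, v*.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise InvalidInputError("expected an (H, W, 3) RGB image")
    rgb = image.astype(np.float64)
    if image.dtype.kind in "ui" or rgb.max() > 1.0:
        rgb = rgb / 255.0
    xyz = _srgb_linearize(rgb) @ _SRGB_TO_XYZ.T

    wp = _WHITE_D65 if white_point is None else np.asarray(white_point, dtype=float)
    Xn, Yn, Zn = wp
    denom_n = Xn + 15.0 * Yn + 3.0 * Zn
    un, vn = 4.0 * Xn / denom_n, 9.0 * Yn / denom_n

    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    yr = Y / Yn
    L = np.where(yr > _EPS, 116.0 * np.cbrt(yr) - 16.0, _KAPPA * yr)
    denom = X + 15.0 * Y + 3.0 * Z
    # Black pixels have an undefined chromaticity; treat them as achromatic.
    safe = denom > 0
    up = np.where(safe, 4.0 * X / np.where(safe, denom, 1.0), un)
    vp = np.where(safe, 9.0 * Y / np.where(safe, denom, 1.0), vn)
    u = 13.0 * L * (up - un)
    v = 13.0 * L * (vp - vn)
    return LuvImage(L=L, u=u, v=v, field_mask=field_mask)


def median_denoise(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-channel median filter with edge replication (5x5 by default)."""
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("median window must be odd and >= 1")
    image = np.asarray(image)
    if image.ndim == 2:
        return ndimage.median_filter(image, size=window, mode="nearest")
    if image.ndim == 3:
        out = np.empty_like(image)
        for ch in range(image.shape[-1]):
            out[..., ch] = ndimage.median_filter(
                image[..., ch], size=window, mode="nearest"
            )
        return out
    raise InvalidInputError("expected a 2-D or 3-D image array")


def downsample_image(
    image: np.ndarray, target_side_px: int = 826
) -> tuple[np.ndarray, float]:
    """Bilinear resize of a square image to ``target_side_px``.

    Returns the resized image (float64) and the linear scale factor
    ``target/source`` used to update the :class:`Geometry`.  Sampling uses
    the pixel-center convention x_src = (x_dst + 0.5) / scale - 0.5 with
    edge replication outside the source grid.
    """
    image = np.asarray(image)
    side = image.shape[0]
    if image.shape[1] != side:
        raise InvalidInputError("downsample_image expects a square image")
    if side < target_side_px:
        raise InvalidParameterError("upsampling is not supported")
    if side == target_side_px:
        return image.astype(np.float64), 1.0
    scale = target_side_px / side
    coords_1d = (np.arange(target_side_px) + 0.5) / scale - 0.5
    rr, cc = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    coords = np.stack([rr, cc])

    def _resize_plane(plane: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            plane.astype(np.float64), coords, order=1, mode="nearest"
        )

    if image.ndim == 2:
        return _resize_plane(image), scale
    out = np.stack([_resize_plane(image[..., ch]) for ch in range(image.shape[-1])], axis=-1)
    return out, scale


def build_geometry(
    field_diameter_mm: float,
    field_diameter_px: float,
    image_shape: tuple[int, int],
    d1_radius_mm: float = 5.0,
) -> Geometry:
    """Geometry with the field centred at the image midpoint.

    ``px_per_mm = field_diameter_px / field_diameter_mm``; e.g. a 17.4 mm
    field spanning 1650 px gives about 94.8 px/mm.
    """
    if field_diameter_mm <= 0 or field_diameter_px <= 0:
        raise InvalidParameterError("field diameters must be positive")
    center = ((image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0)
    return Geometry(
        center_px=center,
        field_radius_mm=field_diameter_mm / 2.0,
        px_per_mm=field_diameter_px / field_diameter_mm,
        d1_radius_mm=d1_radius_mm,
    )


def embed_in_square(image: np.ndarray) -> np.ndarray:
    """Embed a non-square image in the smallest zero-padded square."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h == w:
        return image
    side = max(h, w)
    pad_r, pad_c = side - h, side - w
    pad = [(pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)]
    if image.ndim == 3:
        pad.append((0, 0))
    return np.pad(image, pad, mode="constant")
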