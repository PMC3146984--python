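"""Synthetic dermoscopic frame generator with exact ground-truth masks.

Emulates the acquisition this pipeline targets: a circular imaged field of
17.4 mm diameter on a dark surround, lighter textured background skin, and
a darker (optionally lighter) star-convex lesion whose boundary radius is
modulated by a random harmonic series, at least partially inside the
central 5-mm disk.  Optional dark curvilinear hair strokes provide an
artifact stress test.  The skin-lesion contrast is targeted on the CIE L*
channel: the luminance offset is adjusted iteratively at generation time
until the absolute difference of the median lesion and skin L* values of
the quantized 8-bit image hits the request.

Every draw comes from one seeded generator, so a spec reproduces its image
and mask byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import luv2rgb

from .errors import InvalidParameterError
from .imgproc import Geometry, build_geometry, rgb_to_luv

__all__ = ["SynthSpec", "synth_image", "synth_dataset"]

# Chromaticity of the synthetic skin, in u*, v*.  The lesion's chroma shift
# scales with the luminance contrast (a faint lesion is faint in chroma
# too), referenced to the full-contrast shift at 40 L* units.
_SKIN_UV = (28.0, 26.0)
_LESION_UV_SHIFT_FULL = (-6.0, -5.0)
_UV_SHIFT_REF_CONTRAST = 40.0
_UV_NOISE_SD = 1.0


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dermoscope frame."""

    image_side_px: int = 256
    field_diameter_mm: float = 17.4
    skin_L_mean: float = 72.0
    skin_texture_sd: float = 3.0  # sd of the low-frequency skin texture, L* units
    contrast_L: float = 40.0  # target |median L*(lesion) - median L*(skin)|
    lesion_radius_mm: float = 3.0
    lesion_center_offset_mm: float = 1.0
    border_irregularity: float = 0.25
    border_fade_mm: float = 1.0  # width of the gradual pigment fade at the rim
    lesion_brighter: bool = False
    n_hairs: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side_px < 32:
            raise InvalidParameterError("image_side_px too small")
        if self.contrast_L < 0 or self.lesion_radius_mm <= 0:
            raise InvalidParameterError("contrast_L and lesion_radius_mm must be valid")
        # the lesion must intersect the central assumption disk d1 (r <= 5 mm)
        if self.lesion_center_offset_mm - self.lesion_radius_mm >= 5.0:
            raise InvalidParameterError("lesion would not intersect d1")

    def geometry(self) -> Geometry:
        side = self.image_side_px
        return build_geometry(self.field_diameter_mm, side, (side, side))


def _lesion_mask(
    spec: SynthSpec, geom: Geometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Star-convex blob: polar radius modulated by 3-8 random harmonics.

    Returns the ground-truth mask (the nominal boundary, where the pigment
    profile crosses one half) and the continuous pigment profile itself,
    which ramps linearly from 1 inside the lesion core to 0 across the
    ``border_fade_mm`` band centered on the nominal boundary.
    """
    side = spec.image_side_px
    angle = rng.uniform(0.0, 2.0 * np.pi)
    off_px = geom.mm_to_px(spec.lesion_center_offset_mm)
    cr = geom.center_px[0] + off_px * np.sin(angle)
    cc = geom.center_px[1] + off_px * np.cos(angle)
    n_h = int(rng.integers(3, 9))
    harmonics = np.arange(1, n_h + 1)
    amps = rng.standard_normal(n_h) / harmonics
    phases = rng.uniform(0.0, 2.0 * np.pi, n_h)
    peak = np.abs(amps).sum()
    if peak > 0:
        amps = amps / peak * 0.8  # keep the modulated radius positive

    rr, cc_grid = np.mgrid[0:side, 0:side]
    theta = np.arctan2(rr - cr, cc_grid - cc)
    modulation = np.zeros_like(theta)
    for h, a, p in zip(harmonics, amps, phases):
        modulation += a * np.cos(h * theta + p)
    radius_mm = spec.lesion_radius_mm * (1.0 + spec.border_irregularity * modulation)
    d_mm = np.hypot(rr - cr, cc_grid - cc) / geom.px_per_mm
    signed = (radius_mm - d_mm) / max(spec.border_fade_mm, 1e-9)
    profile = np.clip(signed + 0.5, 0.0, 1.0)
    return d_mm <= radius_mm, profile


def _hair_layer(
    spec: SynthSpec, geom: Geometry, rng: np.random.Generator
) -> np.ndarray:
    """Boolean layer of 1-2-px-wide random-walk hair strokes."""
    side = spec.image_side_px
    layer = np.zeros((side, side), dtype=bool)
    radius_px = geom.mm_to_px(geom.field_radius_mm)
    for _ in range(spec.n_hairs):
        start_angle = rng.uniform(0.0, 2.0 * np.pi)
        r0 = rng.uniform(0.0, 0.7 * radius_px)
        pos = np.array(
            [
                geom.center_px[0] + r0 * np.sin(start_angle),
                geom.center_px[1] + r0 * np.cos(start_angle),
            ]
        )
        heading = rng.uniform(0.0, 2.0 * np.pi)
        n_steps = int(1.2 * radius_px)
        thick = int(rng.integers(1, 3))
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.08)
            pos += np.array([np.sin(heading), np.cos(heading)])
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < side and 0 <= c < side):
                break
            layer[r, c] = True
            if thick == 2 and r + 1 < side:
                layer[r + 1, c] = True
    return layer


def synth_image(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one 8-bit RGB frame and its pixel-accurate lesion mask."""
    rng = np.random.default_rng(spec.rng_seed)
    side = spec.image_side_px
    geom = spec.geometry()
    field = geom.field_mask((side, side))
    lesion, profile = _lesion_mask(spec, geom, rng)

    lowfreq = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma=side / 8.0)
    sd = lowfreq.std()
    lowfreq = lowfreq / sd * spec.skin_texture_sd if sd > 0 else lowfreq
    fine = rng.standard_normal((side, side)) * (spec.skin_texture_sd / 2.0)
    uv_noise = rng.standard_normal((2, side, side)) * _UV_NOISE_SD
    uv_scale = spec.contrast_L / _UV_SHIFT_REF_CONTRAST
    hairs = _hair_layer(spec, geom, rng) if spec.n_hairs > 0 else None

    sign = 1.0 if spec.lesion_brighter else -1.0
    delta = spec.contrast_L
    rgb8 = None
    # A few fixed-point rounds absorb gamut clipping and 8-bit quantization
    # so the realized median L* contrast lands within ~0.5 of the target.
    for _ in range(8):
        L = spec.skin_L_mean + lowfreq + fine
        L = L + sign * delta * profile
        u = np.full((side, side), _SKIN_UV[0]) + uv_noise[0]
        v = np.full((side, side), _SKIN_UV[1]) + uv_noise[1]
        u = u + _LESION_UV_SHIFT_FULL[0] * uv_scale * profile
        v = v + _LESION_UV_SHIFT_FULL[1] * uv_scale * profile
        if hairs is not None:
            L = np.where(hairs, L - 25.0, L)
        L = np.clip(L, 1.0, 99.0)
        rgb = luv2rgb(np.stack([L, u, v], axis=-1))
        rgb = np.clip(rgb, 0.0, 1.0)
        rgb[~field] = 8.0 / 255.0
        rgb8 = np.round(rgb * 255.0).astype(np.uint8)
        luv_meas = rgb_to_luv(rgb8, field_mask=field)
        med_lesion = np.median(luv_meas.L[lesion & field])
        med_skin = np.median(luv_meas.L[field & ~lesion])
        err = spec.contrast_L - abs(med_lesion - med_skin)
        if abs(err) < 0.5:
            break
        delta += err
    return rgb8, lesion & field


def synth_dataset(
    base_spec: SynthSpec,
    n: int,
    contrast_levels,
    rng_seed: int,
    out_dir,
) -> pd.DataFrame:
    """Write ``n`` image/mask pairs cycling through the contrast levels.

    Returns the manifest (also written as ``manifest.csv``) with one row per
    frame: file paths, contrast level, and the per-frame spec seed.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    levels = list(contrast_levels)
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    rows = []
    for i in range(n):
        contrast = float(levels[i % len(levels)])
        spec = replace(base_spec, contrast_L=contrast, rng_seed=int(seeds[i]))
        image, mask = synth_image(spec)
        img_path = out_dir / f"frame_{i:03d}.png"
        mask_path = out_dir / f"frame_{i:03d}_mask.png"
        iio.imwrite(img_path, image)
        iio.imwrite(mask_path, (mask.astype(np.uint8) * 255))
        rows.append(
            {
                "image": str(img_path),
                "mask": str(mask_path),
                "contrast_L": contrast,
                "rng_seed": int(seeds[i]),
                "image_side_px": spec.image_side_px,
                "field_diameter_mm": spec.field_diameter_mm,
                "lesion_radius_mm": spec.lesion_radius_mm,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
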