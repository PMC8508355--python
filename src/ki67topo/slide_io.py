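"""Annotated-slide input: mask construction, rotation normalisation, cropping.

Green hand-drawn contours delimit the tissue available for analysis; red
contours mark exclusions inside green regions. Contour lines are overlay
graphics in saturated primaries, so they are recovered by HSV windows,
closed morphologically (hand-drawn gaps), filled, and removed from the
mask themselves.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.morphology import disk

from .datatypes import AnnotatedSlide, NoTumourRegionError, RegionMask


@dataclass
class HueSpec:
    """HSV window for overlay-contour colours (all in [0, 1])."""

    hue_lo: float
    hue_hi: float
    sat_min: float = 0.4
    val_min: float = 0.3

    def select(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        if self.hue_lo <= self.hue_hi:
            in_hue = (h >= self.hue_lo) & (h <= self.hue_hi)
        else:  # wrap-around window (red)
            in_hue = (h >= self.hue_lo) | (h <= self.hue_hi)
        return in_hue & (s >= self.sat_min) & (v >= self.val_min)


# overlay lines are saturated primaries; high saturation floors keep
# tissue hues (pale pinks, DAB browns) out of the contour masks
GREEN_SPEC = HueSpec(0.22, 0.45, sat_min=0.6, val_min=0.4)
RED_SPEC = HueSpec(0.95, 0.05, sat_min=0.85, val_min=0.5)


def load_slide(path, um_per_px: float | None = None) -> AnnotatedSlide:
    """Read a PNG/BMP/TIFF export; resolution from the flag or a sidecar JSON.

    The sidecar is ``<image>.json`` with a ``um_per_px`` key.
    """
    import imageio.v3 as iio

    path = Path(path)
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[..., :3]
    if um_per_px is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            um_per_px = float(json.loads(sidecar.read_text())["um_per_px"])
        else:
            raise ValueError("resolution not given and no sidecar JSON found")
    return AnnotatedSlide(pixels=img.astype(np.uint8), resolution_um_per_px=um_per_px)


def build_mask(
    slide: AnnotatedSlide,
    green_spec: HueSpec = GREEN_SPEC,
    red_spec: HueSpec = RED_SPEC,
    closing_radius_px: int = 3,
) -> RegionMask:
    """Inclusion mask: inside a green contour, not inside red, contours excluded."""
    hsv = rgb2hsv(slide.pixels)
    green = green_spec.select(hsv)
    if not green.any():
        raise NoTumourRegionError("no green contour pixels found")
    footprint = disk(closing_radius_px)
    green_closed = ndi.binary_closing(green, structure=footprint)
    green_filled = ndi.binary_fill_holes(green_closed)
    interior = green_filled & ~green_closed & ~green
    if not interior.any():
        raise NoTumourRegionError("no closed green contour found")

    red = red_spec.select(hsv)
    mask = interior.copy()
    if red.any():
        red_filled = ndi.binary_fill_holes(ndi.binary_closing(red, structure=footprint))
        if not (red_filled & interior).any():
            warnings.warn("red contour lies outside every green region; ignored", stacklevel=2)
        mask &= ~red_filled
    return RegionMask(mask, slide.resolution_um_per_px)


def orientation_angle(mask: RegionMask) -> float:
    """Major-axis angle in degrees of the equal-second-moment ellipse.

    Range (-90, 90], counter-clockwise positive with the image y-axis
    pointing down (i.e. the angle of the axis as drawn on screen).
    """
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ValueError("mask has no true pixels")
    if rows.size == 1:
        warnings.warn("single-pixel mask: orientation undefined, returning 0", stacklevel=2)
        return 0.0
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    # y is negated so the angle is measured counter-clockwise on screen
    theta = 0.5 * np.arctan2(-2.0 * mu11, mu20 - mu02)
    deg = np.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    return float(deg)


def rotate_and_crop(
    slide: AnnotatedSlide, mask: RegionMask
) -> tuple[AnnotatedSlide, RegionMask]:
    """Rotate so the major axis lies horizontally, then crop to content.

    The RGB raster is interpolated bilinearly, the mask nearest-neighbour;
    everything outside the mask is blacked out.
    """
    angle = orientation_angle(mask)
    if abs(angle) > 1e-6:
        # scipy rotates in the (row, col) plane; a positive on-screen angle
        # needs a rotation by -angle in array coordinates to level the axis
        img = ndi.rotate(slide.pixels, -angle, axes=(1, 0), reshape=True, order=1)
        m = ndi.rotate(
            mask.mask.astype(np.uint8), -angle, axes=(1, 0), reshape=True, order=0
        ).astype(bool)
    else:
        img = slide.pixels.copy()
        m = mask.mask.copy()
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    img = img[r0:r1, c0:c1].copy()
    m = m[r0:r1, c0:c1]
    img[~m] = 0
    out_slide = AnnotatedSlide(
        pixels=img,
        resolution_um_per_px=slide.resolution_um_per_px,
        magnification_tag=slide.magnification_tag,
    )
    return out_slide, RegionMask(m, slide.resolution_um_per_px)
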