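"""Core data containers shared by every pipeline stage.

Coordinates are expressed in micrometres with the origin at the top-left
corner of the (rotated, cropped) analysis frame, x running along columns
and y along rows.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: µm per pixel of the two supported bitmap export magnifications.
STANDARD_RESOLUTIONS = {"20x": 0.454, "10x": 0.908}


class NoTumourRegionError(ValueError):
    """Raised when an annotated slide contains no closed green contour."""


@dataclass
class AnnotatedSlide:
    """An RGB bitmap export with overlay contour annotations.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 raster.
    resolution_um_per_px
        Physical size of one pixel. The two standard export resolutions
        are 0.454 (20x) and 0.908 (10x) µm/px; other values are accepted
        with a warning.
    magnification_tag
        Optional ``"20x"`` / ``"10x"`` tag; inferred from the resolution
        when omitted and the resolution is standard.
    """

    pixels: np.ndarray
    resolution_um_per_px: float
    magnification_tag: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) RGB raster")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")
        std = {round(v, 6): k for k, v in STANDARD_RESOLUTIONS.items()}
        key = round(float(self.resolution_um_per_px), 6)
        if self.magnification_tag is None:
            self.magnification_tag = std.get(key)
        if key not in std:
            warnings.warn(
                f"non-standard resolution {self.resolution_um_per_px} µm/px "
                f"(standard: {sorted(std)})",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RegionMask:
    """Binary inclusion mask aligned to a slide raster."""

    mask: np.ndarray
    resolution_um_per_px: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")

    @property
    def included_area_mm2(self) -> float:
        """Area of the true pixels in mm²."""
        return float(self.mask.sum()) * self.resolution_um_per_px**2 / 1e6

    @property
    def frame_um(self) -> tuple[float, float]:
        """(width, height) of the raster in µm."""
        h, w = self.mask.shape
        return (w * self.resolution_um_per_px, h * self.resolution_um_per_px)


@dataclass
class CellPattern:
    """Planar point pattern of detected cell centroids.

    The observation window is, in order of preference: the explicit
    inclusion ``mask``, the rectangular ``window_um`` (width, height), or
    the bounding rectangle of the centroids.
    """

    centroids: np.ndarray
    resolution_um_per_px: float = STANDARD_RESOLUTIONS["10x"]
    mask: Optional[np.ndarray] = None
    window_um: Optional[tuple[float, float]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        if c.size == 0:
            c = np.empty((0, 2), dtype=float)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("centroids must be an (n, 2) array of (x_um, y_um)")
        self.centroids = c
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_cells(self) -> int:
        return int(self.centroids.shape[0])

    @property
    def frame_um(self) -> tuple[float, float]:
        """(width, height) of the analysis frame in µm."""
        if self.mask is not None:
            h, w = self.mask.shape
            return (w * self.resolution_um_per_px, h * self.resolution_um_per_px)
        if self.window_um is not None:
            return (float(self.window_um[0]), float(self.window_um[1]))
        if self.n_cells == 0:
            return (0.0, 0.0)
        span = self.centroids.max(axis=0)
        return (float(span[0]), float(span[1]))

    @property
    def area_mm2(self) -> float:
        """Observation-window area in mm² (mask area when a mask exists)."""
        if self.mask is not None:
            return float(self.mask.sum()) * self.resolution_um_per_px**2 / 1e6
        w, h = self.frame_um
        return w * h / 1e6

    @property
    def density_per_mm2(self) -> float:
        a = self.area_mm2
        return self.n_cells / a if a > 0 else 0.0

    def region_mask(self) -> Optional[RegionMask]:
        if self.mask is None:
            return None
        return RegionMask(self.mask, self.resolution_um_per_px)
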