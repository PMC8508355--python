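"""Detection of immunopositive (brown-stained) nuclei.

Pipeline: median + Gaussian smoothing, RGB thresholding of brown pixels
(the blue-channel upper bound is the only per-image parameter), box-blur
cleanup, isolated-pixel removal, hole filling, watershed splitting of
touching nuclei, and size filtering. Centroids are emitted in µm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .datatypes import CellPattern, RegionMask


@dataclass
class DetectionParams:
    """Tunable parameters of the nucleus detector.

    The fixed RGB bounds target the DAB chromogen (high red, red > green
    > blue); ``blue_upper`` is the per-image threshold — ``None`` selects
    it automatically by Otsu splitting of the blue channel within
    brown-candidate pixels.
    """

    median_kernel_px: int = 3
    gaussian_sigma: float = 0.5
    box_blur_kernel_px: int = 3
    r_min: int = 100
    r_max: int = 255
    g_min: int = 30
    g_max: int = 170
    b_min: int = 0
    blue_upper: Optional[int] = None
    min_nucleus_area_um2: float = 15.0
    max_nucleus_area_um2: float = 250.0
    watershed_min_separation_um: float = 3.0

    def __post_init__(self) -> None:
        for k in ("median_kernel_px", "box_blur_kernel_px"):
            if getattr(self, k) % 2 == 0:
                raise ValueError(f"{k} must be odd")
        if not self.min_nucleus_area_um2 < self.max_nucleus_area_um2:
            raise ValueError("min_nucleus_area_um2 must be < max_nucleus_area_um2")
        if self.blue_upper is not None and not 0 <= self.blue_upper <= 255:
            raise ValueError("blue_upper must be in [0, 255]")

    @classmethod
    def for_resolution(cls, um_per_px: float, **overrides) -> "DetectionParams":
        """Kernel sizes 5 px at 20x (0.454 µm/px), 3 px at 10x (0.908)."""
        k = 5 if um_per_px < 0.7 else 3
        return cls(median_kernel_px=k, box_blur_kernel_px=k, **overrides)


def smooth(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Per-channel median filter followed by a Gaussian filter."""
    k = params.median_kernel_px
    if k > min(image.shape[:2]):
        raise ValueError("median kernel larger than image")
    out = np.empty_like(image, dtype=float)
    for c in range(image.shape[2]):
        med = ndi.median_filter(image[..., c].astype(float), size=k)
        out[..., c] = ndi.gaussian_filter(med, sigma=params.gaussian_sigma)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def auto_blue_upper(image: np.ndarray, params: DetectionParams,
                    mask: Optional[np.ndarray] = None) -> int:
    """Per-image blue-channel upper bound via Otsu on brown candidates."""
    r, g, b = image[..., 0].astype(int), image[..., 1].astype(int), image[..., 2].astype(int)
    cand = (
        (r >= params.r_min) & (r <= params.r_max)
        & (g >= params.g_min) & (g <= params.g_max)
        & (b >= params.b_min)
    )
    if mask is not None:
        cand &= mask
    blues = b[cand]
    if blues.size < 64 or np.ptp(blues) < 2:
        return 140  # fallback default
    return int(threshold_otsu(blues.astype(np.uint8)))


def threshold_brown(image: np.ndarray, params: DetectionParams,
                    mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Binary raster of brown-shaded pixels inside the mask."""
    blue_upper = params.blue_upper
    if blue_upper is None:
        blue_upper = auto_blue_upper(image, params, mask)
    r, g, b = image[..., 0].astype(int), image[..., 1].astype(int), image[..., 2].astype(int)
    binary = (
        (r >= params.r_min) & (r <= params.r_max)
        & (g >= params.g_min) & (g <= params.g_max)
        & (b >= params.b_min) & (b <= blue_upper)
    )
    if mask is not None:
        binary &= mask
    return binary


def clean_and_fill(binary: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Box blur + re-binarise, drop isolated white pixels, fill holes."""
    k = params.box_blur_kernel_px
    blurred = ndi.uniform_filter(binary.astype(float), size=k) >= 0.5
    # a white pixel with zero white 8-neighbours is noise
    neigh = ndi.convolve(blurred.astype(int), np.ones((3, 3), int), mode="constant") - blurred
    blurred &= neigh > 0
    return ndi.binary_fill_holes(blurred)


def split_and_measure(binary: np.ndarray, params: DetectionParams,
                      resolution_um_per_px: float,
                      mask: Optional[np.ndarray] = None) -> CellPattern:
    """Watershed-split touching blobs, size-filter, emit centroids in µm."""
    res = resolution_um_per_px
    dist = ndi.distance_transform_edt(binary)
    min_sep_px = max(1, int(round(params.watershed_min_separation_um / res)))
    coords = peak_local_max(dist, min_distance=min_sep_px, labels=binary)
    markers = np.zeros_like(binary, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndi.label(markers > 0)  # merge coincident peaks
    labels = watershed(-dist, markers=markers, mask=binary)
    centroids = []
    px_area = res * res
    for sl, lab in zip(ndi.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        region = labels[sl] == lab
        area_um2 = region.sum() * px_area
        if not params.min_nucleus_area_um2 <= area_um2 <= params.max_nucleus_area_um2:
            continue
        rr, cc = np.nonzero(region)
        r_c = rr.mean() + sl[0].start
        c_c = cc.mean() + sl[1].start
        centroids.append((c_c * res, r_c * res))
    return CellPattern(
        centroids=np.asarray(centroids, dtype=float).reshape(-1, 2),
        resolution_um_per_px=res,
        mask=mask if mask is not None else np.ones_like(binary, dtype=bool),
    )


def detect_cells(image: np.ndarray, resolution_um_per_px: float,
                 params: Optional[DetectionParams] = None,
                 mask: Optional[np.ndarray] = None) -> CellPattern:
    """Full detection pipeline on an RGB raster."""
    if params is None:
        params = DetectionParams.for_resolution(resolution_um_per_px)
    smoothed = smooth(image, params)
    binary = threshold_brown(smoothed, params, mask)
    cleaned = clean_and_fill(binary, params)
    return split_and_measure(cleaned, params, resolution_um_per_px, mask)


def detect_slide(slide, region_mask: Optional[RegionMask] = None,
                 params: Optional[DetectionParams] = None) -> CellPattern:
    """Detect nuclei on an AnnotatedSlide, optionally within a RegionMask."""
    mask = region_mask.mask if region_mask is not None else None
    return detect_cells(slide.pixels, slide.resolution_um_per_px, params, mask)
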