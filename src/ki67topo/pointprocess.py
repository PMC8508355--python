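"""Stochastic-geometry descriptors: process intensity, Ripley's K and L.

K is estimated with translation edge correction on the bounding rectangle
of the observation window; the window measure |W| is the outlined mask
area when a mask exists, the rectangle area otherwise.
"""
from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import CellPattern

#: default radius ladder, µm: 5 to 50 in steps of 2.5 (19 values)
DEFAULT_RADII_UM = np.arange(5.0, 50.0 + 1e-9, 2.5)


@dataclass
class KEstimate:
    radii_um: np.ndarray
    K: np.ndarray
    L: np.ndarray
    intensity_per_mm2: float


def intensity(pattern: CellPattern) -> float:
    """Cells per mm² of observation window."""
    a = pattern.area_mm2
    if a <= 0:
        raise ValueError("observation window has zero area")
    return pattern.n_cells / a


def ripley_K(pattern: CellPattern, radii_um=None) -> KEstimate:
    """Translation-corrected Ripley K and L functions.

    ``K(r) = (|W| / n^2) * sum_{i != j, d_ij <= r} e_ij`` with
    ``e_ij = |W| / ((a - |dx|)(b - |dy|))`` for a bounding rectangle of
    sides (a, b). ``L(r) = sqrt(K(r) / pi)``. Units: µm².
    """
    radii = np.asarray(DEFAULT_RADII_UM if radii_um is None else radii_um, dtype=float)
    n = pattern.n_cells
    area_um2 = pattern.area_mm2 * 1e6
    if n < 2:
        warnings.warn("K undefined for n < 2 cells; returning zeros", stacklevel=2)
        z = np.zeros_like(radii)
        lam = n / pattern.area_mm2 if pattern.area_mm2 > 0 else 0.0
        return KEstimate(radii, z, z.copy(), lam)
    a, b = pattern.frame_um
    pts = pattern.centroids
    rmax = float(radii.max())
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=rmax, output_type="ndarray")
    if len(pairs):
        diffs = np.abs(pts[pairs[:, 0]] - pts[pairs[:, 1]])
        d = np.hypot(diffs[:, 0], diffs[:, 1])
        w = area_um2 / ((a - diffs[:, 0]) * (b - diffs[:, 1]))
        order = np.argsort(d)
        d, w = d[order], w[order]
        csum = np.concatenate([[0.0], np.cumsum(w)])
        counts = np.searchsorted(d, radii, side="right")
        # each unordered pair contributes twice to the i != j sum
        sums = 2.0 * csum[counts]
    else:
        sums = np.zeros_like(radii)
    K = area_um2 / n**2 * sums
    L = np.sqrt(K / np.pi)
    return KEstimate(radii, K, L, n / pattern.area_mm2)


def pointprocess_feature_names(radii_um=None) -> list[str]:
    radii = np.asarray(DEFAULT_RADII_UM if radii_um is None else radii_um, dtype=float)
    fmt = lambda r: f"{r:g}".replace(".", "p")
    names = ["pp_intensity"]
    names += [f"pp_K_{fmt(r)}" for r in radii]
    names += [f"pp_L_{fmt(r)}" for r in radii]
    return names


def pointprocess_feature_block(pattern: CellPattern, radii_um=None) -> "OrderedDict[str, float]":
    """Intensity + 19 K values + 19 L values = 39 features."""
    names = pointprocess_feature_names(radii_um)
    est = ripley_K(pattern, radii_um)
    vals = np.concatenate([[intensity(pattern)], est.K, est.L])
    return OrderedDict(zip(names, map(float, vals)))
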