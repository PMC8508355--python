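"""Windowed Shannon-entropy descriptors of the cell pattern.

The frame is partitioned into an axis-aligned grid of square windows
anchored at the frame origin. Only windows lying fully inside the frame
(and, when a mask exists, fully inside the included region) contribute.
The per-window cell counts define the event set; the entropy of their
empirical distribution is returned in bits.
"""
from __future__ import annotations

import warnings
from collections import OrderedDict

import numpy as np

from .datatypes import CellPattern

WINDOW_SIDES_UM = (20.0, 40.0, 80.0, 160.0, 320.0, 640.0)


def _qualifying_windows(pattern: CellPattern, side_um: float):
    """Boolean grid of fully-inside windows plus grid shape (nx, ny)."""
    w, h = pattern.frame_um
    nx = int(np.floor(w / side_um + 1e-9))
    ny = int(np.floor(h / side_um + 1e-9))
    if nx <= 0 or ny <= 0:
        return np.zeros((0, 0), dtype=bool)
    ok = np.ones((ny, nx), dtype=bool)
    if pattern.mask is not None:
        res = pattern.resolution_um_per_px
        m = pattern.mask
        # integral image of the inclusion mask for O(1) full-coverage tests
        ii = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
        ii[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
        for j in range(ny):
            r0 = int(np.floor(j * side_um / res))
            r1 = int(np.ceil((j + 1) * side_um / res))
            r1 = min(r1, m.shape[0])
            for i in range(nx):
                c0 = int(np.floor(i * side_um / res))
                c1 = int(np.ceil((i + 1) * side_um / res))
                c1 = min(c1, m.shape[1])
                total = ii[r1, c0] + ii[r0, c1]
                ok[j, i] = (ii[r1, c1] - total + ii[r0, c0]) == (r1 - r0) * (c1 - c0)
    return ok


def window_counts(pattern: CellPattern, side_um: float) -> np.ndarray:
    """Cell counts of the qualifying windows (multiset, flattened)."""
    ok = _qualifying_windows(pattern, side_um)
    if ok.size == 0:
        return np.zeros(0, dtype=int)
    ny, nx = ok.shape
    counts = np.zeros((ny, nx), dtype=int)
    if pattern.n_cells:
        ix = np.floor(pattern.centroids[:, 0] / side_um).astype(int)
        iy = np.floor(pattern.centroids[:, 1] / side_um).astype(int)
        keep = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(counts, (iy[keep], ix[keep]), 1)
    return counts[ok]


def window_entropy(pattern: CellPattern, side_um: float, base: float = 2.0) -> float:
    """Shannon entropy ``H = -sum_e p_e log(p_e)`` of window-count events."""
    counts = window_counts(pattern, side_um)
    if counts.size == 0:
        warnings.warn(
            f"no window of side {side_um} µm fits fully inside the frame; H set to 0",
            stacklevel=2,
        )
        return 0.0
    _, occ = np.unique(counts, return_counts=True)
    p = occ / occ.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def window_count_skewness(pattern: CellPattern, side_um: float) -> float:
    """Skewness of the per-window count distribution (variant descriptor,
    not part of the standard feature vector)."""
    from scipy import stats as sps

    counts = window_counts(pattern, side_um)
    if counts.size == 0 or np.ptp(counts) == 0:
        return 0.0
    return float(sps.skew(counts))


def entropy_feature_names(sides=WINDOW_SIDES_UM) -> list[str]:
    return [f"H_{int(round(s))}um" for s in sides]


def entropy_block(pattern: CellPattern, sides=WINDOW_SIDES_UM, base: float = 2.0):
    """One entropy per window side — 6 features by default."""
    out = OrderedDict()
    for s in sides:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[f"H_{int(round(s))}um"] = window_entropy(pattern, s, base=base)
    return out
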