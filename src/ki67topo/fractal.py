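"""Fractality descriptors of the cell pattern.

Box-counting dimension over a dyadic box ladder (10 µm up to 1100 µm) and
Higuchi fractal dimensions of the horizontal / vertical per-pixel-line
cell-count projections, plus their average: 4 features.
"""
from __future__ import annotations

import warnings
from collections import OrderedDict

import numpy as np

from .datatypes import CellPattern

MIN_BOX_UM = 10.0
MAX_BOX_UM = 1100.0
DEFAULT_KMAX = 8

FRACTAL_FEATURE_NAMES = [
    "frac_boxcount",
    "frac_higuchi_h",
    "frac_higuchi_v",
    "frac_higuchi_avg",
]


def box_ladder(min_box_um: float = MIN_BOX_UM, max_box_um: float = MAX_BOX_UM) -> np.ndarray:
    """Dyadic ladder of box sizes: min, 2*min, ... capped at max."""
    sizes = []
    s = float(min_box_um)
    while s <= max_box_um:
        sizes.append(s)
        s *= 2.0
    return np.asarray(sizes)


def boxcount_dimension(pattern: CellPattern, ladder: np.ndarray | None = None) -> float:
    """Box-counting dimension: least-squares slope of log N(s) vs log(1/s).

    Boxes are anchored at the frame origin; N(s) is the number of boxes
    containing at least one centroid.
    """
    if pattern.n_cells < 2:
        warnings.warn("box-counting undefined for n < 2 cells; returning 0", stacklevel=2)
        return 0.0
    ladder = box_ladder() if ladder is None else np.asarray(ladder, dtype=float)
    pts = pattern.centroids
    counts = []
    for s in ladder:
        idx = np.floor(pts / s).astype(np.int64)
        counts.append(len(np.unique(idx, axis=0)))
    x = np.log(1.0 / ladder)
    y = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def higuchi_projections(pattern: CellPattern) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel-column (horizontal) and per-pixel-row (vertical) cell counts."""
    res = pattern.resolution_um_per_px
    w, h = pattern.frame_um
    ncols = max(1, int(np.ceil(w / res)))
    nrows = max(1, int(np.ceil(h / res)))
    cols = np.zeros(ncols, dtype=float)
    rows = np.zeros(nrows, dtype=float)
    if pattern.n_cells:
        ic = np.clip(np.floor(pattern.centroids[:, 0] / res).astype(int), 0, ncols - 1)
        ir = np.clip(np.floor(pattern.centroids[:, 1] / res).astype(int), 0, nrows - 1)
        np.add.at(cols, ic, 1)
        np.add.at(rows, ir, 1)
    return cols, rows


def higuchi_fd(series, k_max: int = DEFAULT_KMAX) -> float:
    """Classical Higuchi fractal dimension of a 1-D series.

    For each lag k = 1..k_max and offset m = 1..k, the normalised curve
    length ``L_m(k)`` of the subsampled series is computed; the dimension
    is the slope of log mean L(k) versus log(1/k).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2 * k_max:
        raise ValueError(f"series of length {n} too short for k_max={k_max}")
    ks = np.arange(1, k_max + 1)
    lengths = np.empty(k_max)
    for ki, k in enumerate(ks):
        lm = []
        for m in range(k):
            sub = x[m::k]
            if sub.size < 2:
                continue
            raw = np.abs(np.diff(sub)).sum()
            norm = (n - 1) / (((n - m - 1) // k) * k)
            lm.append(raw * norm / k)
        lengths[ki] = np.mean(lm)
    valid = lengths > 0
    if valid.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(1.0 / ks[valid]), np.log(lengths[valid]), 1)[0]
    return float(slope)


def fractal_block(pattern: CellPattern, k_max: int = DEFAULT_KMAX):
    """The 4 fractality features."""
    out = OrderedDict()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["frac_boxcount"] = boxcount_dimension(pattern)
    cols, rows = higuchi_projections(pattern)
    try:
        fh = higuchi_fd(cols, k_max)
    except ValueError:
        fh = 0.0
    try:
        fv = higuchi_fd(rows, k_max)
    except ValueError:
        fv = 0.0
    out["frac_higuchi_h"] = fh
    out["frac_higuchi_v"] = fv
    out["frac_higuchi_avg"] = (fh + fv) / 2.0
    return out
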