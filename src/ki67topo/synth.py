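"""Synthetic data generation.

Seeded point-pattern generators with known spatial statistics, a
pseudo-IHC renderer producing outline-annotated RGB slides with ground
truth, and a labelled two-class cohort builder used to exercise the full
feature-extraction / selection / classification stack without any
external data.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import AnnotatedSlide, CellPattern

__all__ = ["gen_pattern", "IhcStyle", "render_ihc", "gen_cohort", "thomas_K"]


def thomas_K(r: np.ndarray, kappa_per_um2: float, sigma_um: float) -> np.ndarray:
    """Closed-form K function of a Thomas cluster process.

    ``K(r) = pi r^2 + (1/kappa) (1 - exp(-r^2 / (4 sigma^2)))`` with the
    parent intensity ``kappa`` in points per µm².
    """
    r = np.asarray(r, dtype=float)
    return np.pi * r**2 + (1.0 / kappa_per_um2) * (1.0 - np.exp(-(r**2) / (4.0 * sigma_um**2)))


def _csr(rng, window, intensity_per_mm2=None, n_points=None):
    w, h = window
    if n_points is None:
        lam = intensity_per_mm2 * (w * h / 1e6)
        n_points = rng.poisson(lam)
    pts = rng.uniform([0, 0], [w, h], size=(int(n_points), 2))
    return pts


def _thomas(rng, window, kappa_per_mm2, mu, sigma_um, n_points=None):
    w, h = window
    pad = 4.0 * sigma_um
    area_mm2 = (w + 2 * pad) * (h + 2 * pad) / 1e6
    pts_list = []
    # oversample parents until enough offspring land in the window
    target = n_points if n_points is not None else -1
    for _ in range(200):
        n_parents = rng.poisson(kappa_per_mm2 * area_mm2)
        parents = rng.uniform([-pad, -pad], [w + pad, h + pad], size=(n_parents, 2))
        n_off = rng.poisson(mu, size=n_parents)
        if n_off.sum() == 0:
            continue
        centres = np.repeat(parents, n_off, axis=0)
        pts = centres + rng.normal(0.0, sigma_um, size=centres.shape)
        inside = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        pts_list.append(pts[inside])
        total = sum(len(p) for p in pts_list)
        if target < 0 or total >= target:
            break
    pts = np.concatenate(pts_list) if pts_list else np.empty((0, 2))
    if target >= 0:
        if len(pts) < target:
            raise RuntimeError("Thomas sampler could not reach the requested point count")
        keep = rng.choice(len(pts), size=target, replace=False)
        pts = pts[np.sort(keep)]
    return pts


def _hardcore(rng, window, n_points, min_dist_um, max_attempts=1_000_000):
    from scipy.spatial import cKDTree

    w, h = window
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_points:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"hard-core dart throwing failed after {max_attempts} attempts "
                f"({len(pts)}/{n_points} placed)"
            )
        cand = rng.uniform([0, 0], [w, h])
        attempts += 1
        if pts:
            tree = cKDTree(np.asarray(pts))
            if tree.query_ball_point(cand, min_dist_um):
                continue
        pts.append(cand)
    return np.asarray(pts)


def _grid(window, nx, ny):
    w, h = window
    xs = (np.arange(nx) + 0.5) * w / nx
    ys = (np.arange(ny) + 0.5) * h / ny
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _line(window, n_points):
    w, h = window
    t = np.linspace(0.05, 0.95, n_points)
    return np.column_stack([t * w, np.full(n_points, h / 2.0)])


def _sierpinski(window, depth):
    """Vertices of the depth-th subdivision of the Sierpinski triangle."""
    w, h = window
    side = min(w, h)
    tri = np.array([[0.0, 0.0], [side, 0.0], [side / 2.0, side * math.sqrt(3) / 2.0]])
    tris = [tri]
    for _ in range(depth):
        nxt = []
        for t in tris:
            a, b, c = t
            ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
            nxt.extend([np.array([a, ab, ca]), np.array([ab, b, bc]), np.array([ca, bc, c])])
        tris = nxt
    pts = np.unique(np.round(np.concatenate(tris), 9), axis=0)
    return pts


def gen_pattern(
    kind: str,
    window_um: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
    resolution_um_per_px: float = 0.908,
    **params,
) -> CellPattern:
    """Generate a seeded synthetic cell pattern with attached ground truth.

    Kinds: ``csr`` (intensity_per_mm2 or n_points), ``thomas``
    (kappa_per_mm2, mu, sigma_um, optional n_points), ``hardcore``
    (n_points, min_dist_um), ``grid`` (nx, ny), ``line`` (n_points),
    ``sierpinski`` (depth).
    """
    rng = np.random.default_rng(seed)
    meta: dict = {"kind": kind, "seed": seed, "params": dict(params)}
    if kind == "csr":
        pts = _csr(rng, window_um, params.get("intensity_per_mm2"), params.get("n_points"))
        area = window_um[0] * window_um[1] / 1e6
        meta["true_intensity_per_mm2"] = (
            params.get("intensity_per_mm2")
            if params.get("intensity_per_mm2") is not None
            else params.get("n_points", 0) / area
        )
        meta["true_K"] = lambda r: np.pi * np.asarray(r, dtype=float) ** 2
    elif kind == "thomas":
        kappa = params["kappa_per_mm2"]
        mu, sigma = params["mu"], params["sigma_um"]
        pts = _thomas(rng, window_um, kappa, mu, sigma, params.get("n_points"))
        meta["true_intensity_per_mm2"] = kappa * mu
        meta["true_K"] = lambda r: thomas_K(r, kappa / 1e6, sigma)
    elif kind == "hardcore":
        pts = _hardcore(rng, window_um, params["n_points"], params["min_dist_um"],
                        params.get("max_attempts", 1_000_000))
    elif kind == "grid":
        pts = _grid(window_um, params["nx"], params["ny"])
    elif kind == "line":
        pts = _line(window_um, params["n_points"])
    elif kind == "sierpinski":
        pts = _sierpinski(window_um, params.get("depth", 7))
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return CellPattern(
        centroids=pts,
        resolution_um_per_px=resolution_um_per_px,
        window_um=window_um,
        meta=meta,
    )


@dataclass
class IhcStyle:
    """Rendering style controls emulating inter-centre stain variability."""

    background_rgb: tuple[int, int, int] = (235, 228, 238)
    background_noise: float = 6.0
    nucleus_radius_um: float = 3.5
    nucleus_radius_sd_um: float = 0.5
    brown_rgb: tuple[int, int, int] = (150, 90, 60)
    hue_jitter: float = 12.0
    n_negative_factor: float = 1.0  # haematoxylin-blue (negative) nuclei per positive
    negative_rgb: tuple[int, int, int] = (95, 105, 175)
    contour_margin_px: int = 12
    contour_width_px: int = 3
    green_rgb: tuple[int, int, int] = (0, 200, 0)
    red_rgb: tuple[int, int, int] = (230, 0, 0)
    red_boxes_um: tuple = ()  # sequence of (x0, y0, x1, y1) exclusion boxes


def _draw_disk(img, r_px, c_px, radius_px, colour, jitter, rng):
    from skimage.draw import disk

    rr, cc = disk((r_px, c_px), radius_px, shape=img.shape[:2])
    col = np.asarray(colour, dtype=float) + rng.normal(0, jitter, size=3)
    img[rr, cc] = np.clip(col, 0, 255)


def render_ihc(pattern: CellPattern, style: Optional[IhcStyle] = None, seed: int = 0):
    """Render a pattern as a pseudo-IHC annotated slide.

    Returns ``(slide, ground_truth)`` where ground_truth is a dict with
    the rendered centroid coordinates in the slide frame (µm), split into
    those inside/outside red exclusion boxes.
    """
    style = style or IhcStyle()
    rng = np.random.default_rng(seed)
    res = pattern.resolution_um_per_px
    w_um, h_um = pattern.frame_um
    margin = style.contour_margin_px
    W = int(math.ceil(w_um / res)) + 2 * margin
    H = int(math.ceil(h_um / res)) + 2 * margin
    img = np.empty((H, W, 3), dtype=float)
    img[...] = style.background_rgb
    img += rng.normal(0, style.background_noise, size=img.shape)

    # negative (blue) nuclei as detection distractors
    n_neg = int(round(style.n_negative_factor * pattern.n_cells))
    for _ in range(n_neg):
        r = margin + rng.uniform(0, h_um) / res
        c = margin + rng.uniform(0, w_um) / res
        rad = max(1.0, rng.normal(style.nucleus_radius_um, style.nucleus_radius_sd_um) / res)
        _draw_disk(img, r, c, rad, style.negative_rgb, style.hue_jitter, rng)

    # positive (brown) nuclei at the ground-truth centroids
    kept, excluded = [], []
    boxes = [tuple(b) for b in style.red_boxes_um]
    for x_um, y_um in pattern.centroids:
        in_red = any(b[0] <= x_um <= b[2] and b[1] <= y_um <= b[3] for b in boxes)
        r = margin + y_um / res
        c = margin + x_um / res
        rad = max(1.5, rng.normal(style.nucleus_radius_um, style.nucleus_radius_sd_um) / res)
        _draw_disk(img, r, c, rad, style.brown_rgb, style.hue_jitter, rng)
        (excluded if in_red else kept).append((x_um + margin * res, y_um + margin * res))

    img = np.clip(img, 0, 255).astype(np.uint8)

    # green rectangular contour around the tissue frame
    wdt = style.contour_width_px
    lo = margin - wdt - 1
    img[lo : lo + wdt, lo : W - lo, :] = style.green_rgb
    img[H - lo - wdt : H - lo, lo : W - lo, :] = style.green_rgb
    img[lo : H - lo, lo : lo + wdt, :] = style.green_rgb
    img[lo : H - lo, W - lo - wdt : W - lo, :] = style.green_rgb

    # red exclusion boxes (contour lines)
    for x0, y0, x1, y1 in boxes:
        r0, r1 = margin + int(y0 / res), margin + int(y1 / res)
        c0, c1 = margin + int(x0 / res), margin + int(x1 / res)
        img[r0 : r0 + wdt, c0:c1, :] = style.red_rgb
        img[r1 - wdt : r1, c0:c1, :] = style.red_rgb
        img[r0:r1, c0 : c0 + wdt, :] = style.red_rgb
        img[r0:r1, c1 - wdt : c1, :] = style.red_rgb

    slide = AnnotatedSlide(pixels=img, resolution_um_per_px=res)
    truth = {
        "centroids_um": np.asarray(kept, dtype=float).reshape(-1, 2),
        "excluded_um": np.asarray(excluded, dtype=float).reshape(-1, 2),
        "margin_px": margin,
    }
    return slide, truth


def gen_feature_dataset(
    kind: str = "planted",
    seed: int = 0,
    n_per_class: int = 24,
    n_features: int = 50,
    n_informative: int = 3,
    gap: float = 3.0,
    within_sd: float = 0.5,
):
    """Labelled feature matrix for selection benchmarks.

    ``planted``: the first ``n_informative`` features are complementary —
    each separates a different subgroup of the positive class from the
    negative class, so every informative feature is individually
    necessary. ``noise``: no class signal at all.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array(["GP"] * n_per_class + ["PP"] * n_per_class)
    x = rng.normal(size=(n, n_features))
    if kind == "planted":
        x[:, :n_informative] = rng.normal(0.0, within_sd, (n, n_informative))
        sub = np.arange(n_per_class) % n_informative
        for i, s in enumerate(sub):
            x[n_per_class + i, s] += gap
    elif kind != "noise":
        raise ValueError(f"unknown dataset kind {kind!r}")
    cols = [f"f{j:03d}" for j in range(n_features)]
    return pd.DataFrame(x, columns=cols), y


def gen_cohort(
    n_per_class: int,
    seed: int = 0,
    n_points: int = 350,
    window_um: tuple[float, float] = (1000.0, 1000.0),
    intensity_matched: bool = True,
    cluster_sigma_um: float = 25.0,
    cluster_kappa_per_mm2: float = 20.0,
    li_noise_sd: float = 2.0,
):
    """Build a labelled two-class synthetic cohort with full feature extraction.

    Good-prognosis (GP) samples are CSR patterns; poor-prognosis (PP)
    samples are Thomas cluster patterns. With ``intensity_matched`` the
    number of cells is fixed so counting-based baselines carry no class
    signal. Returns ``(features, metadata)`` DataFrames indexed by sample.
    """
    from .features import extract_features

    rng = np.random.default_rng(seed)
    rows, meta_rows, index = [], [], []
    for i in range(2 * n_per_class):
        label = "GP" if i < n_per_class else "PP"
        s = int(rng.integers(0, 2**31 - 1))
        n = n_points if intensity_matched else int(rng.integers(n_points // 2, 2 * n_points))
        if label == "GP":
            pat = gen_pattern("csr", window_um, seed=s, n_points=n)
        else:
            mu = n / (cluster_kappa_per_mm2 * window_um[0] * window_um[1] / 1e6)
            pat = gen_pattern(
                "thomas", window_um, seed=s,
                kappa_per_mm2=cluster_kappa_per_mm2, mu=mu,
                sigma_um=cluster_sigma_um, n_points=n,
            )
        feats = extract_features(pat)
        density = pat.density_per_mm2
        # pseudo labelling index: noisy monotone function of density
        li = max(0.1, 0.03 * density + rng.normal(0.0, li_noise_sd))
        rows.append(feats)
        meta_rows.append(
            {
                "label": label,
                "histology": rng.choice(["AC", "LCNEC"]),
                "ki67_li": li,
                "density_per_mm2": density,
                "n_cells": pat.n_cells,
                "seed": s,
            }
        )
        index.append(f"S{i:03d}")
    features = pd.DataFrame(rows, index=index)
    metadata = pd.DataFrame(meta_rows, index=index)
    return features, metadata
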