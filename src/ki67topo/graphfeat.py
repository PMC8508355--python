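"""Cell-graph topology features.

Proximity graphs connect every pair of cells whose Euclidean distance is
at or below a threshold (25, 50, 75 µm by default). Nine per-node metrics
are summarised by sixteen statistics; three whole-graph metrics are added,
giving 147 features per threshold and 441 in total.
"""
from __future__ import annotations

import warnings
from collections import OrderedDict

import networkx as nx
import numpy as np
from scipy import stats as sps
from scipy.spatial import cKDTree

from .datatypes import CellPattern

GRAPH_THRESHOLDS_UM = (25.0, 50.0, 75.0)

LOCAL_METRICS = (
    "degree",
    "clustering",
    "local_efficiency",
    "eigenvector",
    "closeness",
    "betweenness",
    "harmonic",
    "eccentricity",
    "pagerank",
)

GLOBAL_METRICS = ("density", "global_efficiency", "assortativity")

SUMMARY_STATS = (
    "amean",
    "gmean",
    "hmean",
    "std",
    "skew",
    "kurt",
    "range",
    "mode",
    "min",
    "max",
    "q1",
    "q2",
    "q3",
    "m2",
    "m3",
    "m4",
)


def build_graph(pattern: CellPattern, threshold_um: float) -> nx.Graph:
    """Proximity graph: edge (i, j) iff ``dist(i, j) <= threshold_um``."""
    g = nx.Graph(threshold_um=float(threshold_um))
    n = pattern.n_cells
    g.add_nodes_from(range(n))
    if n >= 2:
        tree = cKDTree(pattern.centroids)
        pairs = tree.query_pairs(r=float(threshold_um), output_type="ndarray")
        g.add_edges_from(map(tuple, pairs))
    return g


def _eigenvector_centrality(g: nx.Graph) -> np.ndarray:
    """Per-component principal-eigenvector centrality, L2-normalised.

    Computed by dense symmetric eigendecomposition per connected
    component; singleton components get 0.
    """
    vals = np.zeros(g.number_of_nodes())
    idx = {v: i for i, v in enumerate(g.nodes())}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        a = nx.to_numpy_array(g, nodelist=comp)
        w, v = np.linalg.eigh(a)
        vec = v[:, -1]
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)  # Perron vector is non-negative; kill sign noise
        vec /= np.linalg.norm(vec)
        for node, value in zip(comp, vec):
            vals[idx[node]] = value
    return vals


def _local_efficiency(g: nx.Graph) -> np.ndarray:
    vals = np.zeros(g.number_of_nodes())
    for i, v in enumerate(g.nodes()):
        nbrs = list(g[v])
        if len(nbrs) < 2:
            continue
        vals[i] = nx.global_efficiency(g.subgraph(nbrs))
    return vals


def local_metrics(g: nx.Graph) -> "OrderedDict[str, np.ndarray]":
    """Nine per-node metrics, each as an array ordered like ``g.nodes()``.

    Betweenness is the raw (unnormalised) shortest-path pair count;
    eccentricity is taken within each connected component; isolated nodes
    get 0 for everything except PageRank, which keeps its stationary mass.
    """
    nodes = list(g.nodes())
    n = len(nodes)
    out: "OrderedDict[str, np.ndarray]" = OrderedDict()
    if n == 0:
        for m in LOCAL_METRICS:
            out[m] = np.zeros(0)
        return out
    deg = dict(g.degree())
    out["degree"] = np.array([deg[v] for v in nodes], dtype=float)
    clus = nx.clustering(g)
    out["clustering"] = np.array([clus[v] for v in nodes], dtype=float)
    out["local_efficiency"] = _local_efficiency(g)
    out["eigenvector"] = _eigenvector_centrality(g)
    clo = nx.closeness_centrality(g)
    out["closeness"] = np.array([clo[v] for v in nodes], dtype=float)
    btw = nx.betweenness_centrality(g, normalized=False)
    out["betweenness"] = np.array([btw[v] for v in nodes], dtype=float)
    har = nx.harmonic_centrality(g)
    out["harmonic"] = np.array([har[v] for v in nodes], dtype=float)
    ecc = np.zeros(n)
    pos = {v: i for i, v in enumerate(nodes)}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            continue
        sub_ecc = nx.eccentricity(g.subgraph(comp))
        for v, e in sub_ecc.items():
            ecc[pos[v]] = e
    out["eccentricity"] = ecc
    pr = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=500)
    out["pagerank"] = np.array([pr[v] for v in nodes], dtype=float)
    return out


def global_metrics(g: nx.Graph) -> "OrderedDict[str, float]":
    """Edge density, global efficiency and degree assortativity.

    Graphs with fewer than two nodes yield zeros; an undefined
    assortativity (regular graph) is mapped to 0 by convention.
    """
    out: "OrderedDict[str, float]" = OrderedDict()
    n = g.number_of_nodes()
    if n < 2:
        for m in GLOBAL_METRICS:
            out[m] = 0.0
        return out
    out["density"] = nx.density(g)
    out["global_efficiency"] = nx.global_efficiency(g)
    if g.number_of_edges() == 0:
        out["assortativity"] = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = nx.degree_assortativity_coefficient(g)
        out["assortativity"] = 0.0 if not np.isfinite(r) else float(r)
    return out


def _mode(values: np.ndarray) -> float:
    """Most frequent value after rounding to 9 significant digits.

    Ties are broken toward the smallest value.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        mags = np.where(values != 0, np.floor(np.log10(np.abs(values))), 0.0)
    rounded = np.round(values / 10.0**mags, 8) * 10.0**mags
    uniq, counts = np.unique(rounded, return_counts=True)
    return float(uniq[counts == counts.max()].min())


def summarize(values) -> "OrderedDict[str, float]":
    """Sixteen summary statistics of a value list, in fixed order.

    Conventions (pinned for reproducibility): geometric and harmonic
    means are 0 when any value is <= 0; std uses ddof=1 (0 for n=1);
    skewness is the standardised third moment and kurtosis the excess
    kurtosis (both 0 for constant input); quartiles use linear
    interpolation (inclusive method); central moments are population
    moments.
    """
    values = np.asarray(values, dtype=float)
    out: "OrderedDict[str, float]" = OrderedDict()
    if values.size == 0:
        warnings.warn("summarize() on empty value list; returning zeros", stacklevel=2)
        for s in SUMMARY_STATS:
            out[s] = 0.0
        return out
    out["amean"] = float(values.mean())
    if values.min() > 0:
        out["gmean"] = float(sps.gmean(values))
        out["hmean"] = float(sps.hmean(values))
    else:
        out["gmean"] = 0.0
        out["hmean"] = 0.0
    out["std"] = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if np.ptp(values) == 0:
        out["skew"] = 0.0
        out["kurt"] = 0.0
    else:
        out["skew"] = float(sps.skew(values))
        out["kurt"] = float(sps.kurtosis(values))
    out["range"] = float(np.ptp(values))
    out["mode"] = _mode(values)
    out["min"] = float(values.min())
    out["max"] = float(values.max())
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    out["q1"], out["q2"], out["q3"] = float(q1), float(q2), float(q3)
    out["m2"] = float(sps.moment(values, 2))
    out["m3"] = float(sps.moment(values, 3))
    out["m4"] = float(sps.moment(values, 4))
    return out


def graph_feature_names(thresholds=GRAPH_THRESHOLDS_UM) -> list[str]:
    names = []
    for t in thresholds:
        ti = int(round(t))
        for metric in LOCAL_METRICS:
            for stat in SUMMARY_STATS:
                names.append(f"g{ti}_{metric}_{stat}")
        for metric in GLOBAL_METRICS:
            names.append(f"g{ti}_{metric}")
    return names


def graph_feature_block(
    pattern: CellPattern, thresholds=GRAPH_THRESHOLDS_UM
) -> "OrderedDict[str, float]":
    """All graph features over the configured thresholds (441 by default)."""
    out: "OrderedDict[str, float]" = OrderedDict()
    if pattern.n_cells == 0:
        warnings.warn("empty pattern: graph features set to 0", stacklevel=2)
    for t in thresholds:
        ti = int(round(t))
        g = build_graph(pattern, t)
        loc = local_metrics(g)
        for metric, vals in loc.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats = summarize(vals)
            for stat, v in stats.items():
                out[f"g{ti}_{metric}_{stat}"] = v
        for metric, v in global_metrics(g).items():
            out[f"g{ti}_{metric}"] = v
    return out


def eigcentrality_display_transform(values) -> np.ndarray:
    """Log2 shift used for centrality visualisation: ``log2(c) - min(log2(c))``."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("display transform requires strictly positive centralities")
    lv = np.log2(values)
    return lv - lv.min()
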