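"""Post-hoc feature statistics.

Pearson correlation against the labelling index and cell density,
Mann-Whitney histology-independence tests, Benjamini-Hochberg multiplicity
control (each analysis batch corrected separately), and the resulting
feature-set memberships.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

FDR_ALPHA = 0.05


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value (n - 2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance input: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def mannwhitney_test(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties), two-sided.

    Exact p when min(n_a, n_b) <= 8 and there are no ties; normal
    approximation with tie correction (and continuity correction)
    otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment: q_(i) = min_{j >= i} p_(j) m / j, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def feature_set_report(
    table: pd.DataFrame,
    ki67_li,
    density,
    histology,
    ranking: list[str] | None = None,
    top_k: int = 18,
    alpha: float = FDR_ALPHA,
) -> dict:
    """Per-feature membership in the three independence sets.

    A feature is "uncorrelated" with an index (or histology-independent)
    when its BH-adjusted p-value is >= alpha, i.e. not significant. Each
    batch of tests is corrected separately. ``table`` should already be
    the post-preliminary-filter feature set.
    """
    li = np.asarray(ki67_li, float)
    dens = np.asarray(density, float)
    hist = np.asarray(histology)
    hvals = np.unique(hist)
    if len(hvals) != 2:
        raise ValueError("histology must have exactly two levels")
    rows = []
    p_li, p_dens, p_hist = [], [], []
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pl = pearson_test(v, li) if np.ptp(v) > 0 else (np.nan, np.nan)
            _, pd_ = pearson_test(v, dens) if np.ptp(v) > 0 else (np.nan, np.nan)
        _, ph = mannwhitney_test(v[hist == hvals[0]], v[hist == hvals[1]])
        p_li.append(pl)
        p_dens.append(pd_)
        p_hist.append(ph)
    # undefined correlations (constant feature) are treated as uncorrelated
    q_li = benjamini_hochberg(np.nan_to_num(np.asarray(p_li), nan=1.0))
    q_dens = benjamini_hochberg(np.nan_to_num(np.asarray(p_dens), nan=1.0))
    q_hist = benjamini_hochberg(np.asarray(p_hist))
    uncorr_li = q_li >= alpha
    uncorr_dens = q_dens >= alpha
    hist_indep = q_hist >= alpha
    inter = uncorr_li & uncorr_dens & hist_indep
    for i, col in enumerate(table.columns):
        rows.append(
            {
                "feature": col,
                "p_li": p_li[i], "q_li": q_li[i], "uncorrelated_li": bool(uncorr_li[i]),
                "p_density": p_dens[i], "q_density": q_dens[i],
                "uncorrelated_density": bool(uncorr_dens[i]),
                "p_histology": p_hist[i], "q_histology": q_hist[i],
                "histology_independent": bool(hist_indep[i]),
                "in_intersection": bool(inter[i]),
            }
        )
    stats = pd.DataFrame(rows).set_index("feature")
    report = {
        "n_features": int(len(table.columns)),
        "n_uncorrelated_li": int(uncorr_li.sum()),
        "n_uncorrelated_density": int(uncorr_dens.sum()),
        "n_histology_independent": int(hist_indep.sum()),
        "n_uncorrelated_both": int((uncorr_li & uncorr_dens).sum()),
        "n_intersection": int(inter.sum()),
    }
    if ranking is not None:
        top = [f for f in ranking[:top_k] if f in stats.index]
        in_top = stats.loc[top, "in_intersection"]
        report["top_k"] = top_k
        report["n_top_in_intersection"] = int(in_top.sum())
        frac_all = inter.mean() if len(inter) else 0.0
        frac_top = in_top.mean() if len(top) else 0.0
        report["overrepresentation"] = float(frac_top / frac_all) if frac_all > 0 else float("nan")
    return {"per_feature": stats, "summary": report}
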