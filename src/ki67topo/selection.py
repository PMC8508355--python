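"""Three-stage feature selection.

1. Drop features constant across all samples (strict equality).
2. Drop the lower-variance member of every perfectly correlated pair
   (|Pearson r| = 1 within tolerance), processed in column order.
3. Neighbourhood-component feature weighting: regularisation selected by
   repeated 5-fold cross-validation over a lambda grid, final fit with
   L-BFGS, features below a 0.01 weight cut-off discarded.

The NCA objective (feature-weighting form) is

    F(w) = (1/n) sum_i p_i  -  lambda * sum_l w_l^2,
    p_ij proportional to exp(-sum_l w_l^2 |x_il - x_jl|)  (j != i),
    p_i = sum_{j: y_j = y_i} p_ij,

maximised over the raw weight vector w; reported weights are |w|.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

WEIGHT_CUTOFF = 0.01


@dataclass
class NCAResult:
    weights: pd.Series            # |w| per feature, input order
    lam: float
    ranking: list[str]            # features sorted by decreasing weight
    retained: list[str]           # ranking filtered at the cut-off
    converged: bool = True
    objective: float = float("nan")
    cv_losses: dict = field(default_factory=dict)


def drop_constant(table: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance (strictly constant) feature columns."""
    values = table.to_numpy()
    keep = ~(values == values[0:1, :]).all(axis=0) if len(table) else np.ones(table.shape[1], bool)
    return table.loc[:, keep]


def drop_perfectly_correlated(table: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    """For each |r| = 1 pair keep the higher-variance member.

    Pairs are scanned in column-index order so the cascade is
    deterministic; ties on variance keep the earlier column.
    """
    cols = list(table.columns)
    x = table.to_numpy(dtype=float)
    var = x.var(axis=0, ddof=1) if len(table) > 1 else np.zeros(x.shape[1])
    sd = np.sqrt(var)
    nz = sd > 0
    xs = np.zeros_like(x)
    xs[:, nz] = (x[:, nz] - x[:, nz].mean(axis=0)) / sd[nz]
    corr = xs.T @ xs / max(1, len(table) - 1)
    dropped = np.zeros(len(cols), dtype=bool)
    for i in range(len(cols)):
        if dropped[i]:
            continue
        for j in range(i + 1, len(cols)):
            if dropped[j] or not (nz[i] and nz[j]):
                continue
            if abs(abs(corr[i, j]) - 1.0) <= tol:
                if var[j] > var[i]:
                    dropped[i] = True
                    break
                dropped[j] = True
    return table.loc[:, [c for c, d in zip(cols, dropped) if not d]]


def preliminary_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Stages 1 + 2: constant filter then perfect-correlation filter."""
    return drop_perfectly_correlated(drop_constant(table))


def zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _objective_grad(w, diffs, same, lam):
    """Value and gradient of F at raw weights w.

    ``diffs``: (n, n, p) absolute coordinate differences; ``same``:
    (n, n) boolean same-class matrix with a False diagonal.
    """
    n = diffs.shape[0]
    w2 = w * w
    dist = diffs @ w2
    np.fill_diagonal(dist, np.inf)
    e = np.exp(-(dist - dist.min(axis=1, keepdims=True)))
    p = e / e.sum(axis=1, keepdims=True)
    p_i = (p * same).sum(axis=1)
    f = p_i.mean() - lam * w2.sum()
    t1 = np.einsum("ij,ijl->l", p * p_i[:, None], diffs)
    t2 = np.einsum("ij,ijl->l", p * same, diffs)
    grad = (2.0 * w / n) * (t1 - t2) - 2.0 * lam * w
    return f, grad


def _sample_grad(i, x, diffs_i, same_i, w, lam):
    """Stochastic gradient of sample i's contribution."""
    w2 = w * w
    dist = diffs_i @ w2
    dist[i] = np.inf
    e = np.exp(-(dist - dist.min()))
    p = e / e.sum()
    p_i = p[same_i].sum()
    t1 = (p * p_i) @ diffs_i
    t2 = p[same_i] @ diffs_i[same_i]
    return 2.0 * w * (t1 - t2) - 2.0 * lam * w


def _sgd_epochs_numpy(diffs, same, lam, epochs, init_step, perms):
    n, _, p = diffs.shape
    w = np.ones(p)
    for epoch in range(epochs):
        step = init_step / (1.0 + epoch)
        for i in perms[epoch]:
            w = w + step * _sample_grad(i, None, diffs[i], same[i], w, lam)
    return w


try:  # hot loop: JIT when numba is available, identical numpy fallback otherwise
    from numba import njit

    @njit(cache=True)
    def _sgd_epochs_jit(diffs, same, lam, epochs, init_step, perms):  # pragma: no cover
        n, _, p = diffs.shape
        w = np.ones(p)
        for epoch in range(epochs):
            step = init_step / (1.0 + epoch)
            for ii in range(n):
                i = perms[epoch, ii]
                w2 = w * w
                dist = diffs[i] @ w2
                dist[i] = np.inf
                dmin = np.inf
                for j in range(n):
                    if dist[j] < dmin:
                        dmin = dist[j]
                e = np.exp(-(dist - dmin))
                e[i] = 0.0
                psum = e.sum()
                prob = e / psum
                p_i = 0.0
                for j in range(n):
                    if same[i, j]:
                        p_i += prob[j]
                grad = np.zeros(p)
                for j in range(n):
                    coef = prob[j] * p_i - (prob[j] if same[i, j] else 0.0)
                    if coef != 0.0:
                        for l in range(p):
                            grad[l] += coef * diffs[i, j, l]
                w = w + step * (2.0 * w * grad - 2.0 * lam * w)
        return w

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def nca_fit(
    x: np.ndarray,
    y: np.ndarray,
    lam: float,
    solver: str = "lbfgs",
    max_iter: int = 30,
    seed: int = 0,
    init_step: float = 0.5,
):
    """Fit the feature-weighting objective; returns (|w|, converged, objective).

    ``x`` must already be z-scored. The SGD solver runs ``max_iter``
    epochs of per-sample updates with a decaying step (used for lambda
    tuning); L-BFGS is used for the final fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n, p = x.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    diffs = np.abs(x[:, None, :] - x[None, :, :])
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)
    w0 = np.ones(p)
    if solver == "lbfgs":
        # w = 0 is a stationary point of the objective and on wide data a
        # start at w0 = 1 can be driven straight into it by the penalty
        # term; a few geometrically shrinking starts avoid the saddle
        best = None
        for scale in (1.0, 0.3, 0.1, 0.03, 0.01):
            res = minimize(
                lambda w: tuple(-v for v in _objective_grad(w, diffs, same, lam)),
                scale * w0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        w, converged = best.x, bool(best.success)
        obj = -float(best.fun)
    elif solver == "sgd":
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(n) for _ in range(max_iter)])
        if _HAVE_NUMBA:
            w = _sgd_epochs_jit(diffs, same, float(lam), max_iter,
                                float(init_step), perms)
        else:
            w = _sgd_epochs_numpy(diffs, same, float(lam), max_iter,
                                  float(init_step), perms)
        converged = True
        obj, _ = _objective_grad(w, diffs, same, lam)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return np.abs(w), converged, obj


def _soft_classify(x_train, y_train, x_test, w):
    """Soft nearest-neighbour prediction under weighted L1 distances."""
    w2 = w * w
    preds = []
    classes = np.unique(y_train)
    for xt in x_test:
        dist = np.abs(x_train - xt) @ w2
        e = np.exp(-(dist - dist.min()))
        p = e / e.sum()
        scores = [p[y_train == c].sum() for c in classes]
        preds.append(classes[int(np.argmax(scores))])
    return np.asarray(preds)


def default_lambda_grid(n_samples: int, n_values: int = 20) -> np.ndarray:
    """20 values linearly spaced in [0, 8] / n_samples.

    The upper end is chosen so that the whole grid annihilates
    uninformative weights while staying below the collapse threshold of
    the objective: the leave-one-out gain of a perfect classifier is at
    most ~0.5, so any lambda with lambda * ||w*||^2 > 0.5 drives even a
    fully informative weight vector to zero. A narrower [0, 2] / n grid
    leaves pure-noise data under-regularised too often.
    """
    return np.linspace(0.0, 8.0, n_values) / n_samples


def _stratified_folds(y, n_folds, rng):
    folds = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(i)
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def nca_select(
    table: pd.DataFrame,
    labels,
    seed: int = 0,
    cv_reps: int = 100,
    n_folds: int = 5,
    lambda_grid=None,
    cutoff: float = WEIGHT_CUTOFF,
    sgd_iter: int = 30,
    se_rule: bool = True,
    se_factor: float = 3.0,
) -> NCAResult:
    """Lambda tuning by repeated CV (SGD fits) + final L-BFGS fit + cut-off.

    ``cv_reps`` defaults to the reference protocol's 100 repetitions;
    smaller values trade tuning variance for speed. With ``se_rule`` the
    largest lambda whose mean CV loss is within ``se_factor`` standard
    errors of the minimum is chosen (parsimony rule, the default);
    otherwise the plain minimum (ties toward the smaller lambda). The
    slack absorbs the sampling noise of the loss estimates, which is
    comparable to the spread of the per-lambda means when few CV
    repetitions are used.
    """
    y = np.asarray(labels)
    x = zscore(table.to_numpy(dtype=float))
    n = len(y)
    grid = default_lambda_grid(n) if lambda_grid is None else np.asarray(lambda_grid, float)
    rng = np.random.default_rng(seed)
    losses, loss_ses = {}, {}
    for lam in grid:
        errs = []
        for _ in range(cv_reps):
            folds = _stratified_folds(y, n_folds, rng)
            for k in range(n_folds):
                test = folds[k]
                if len(test) == 0:
                    continue
                train = np.setdiff1d(np.arange(n), test)
                w, _, _ = nca_fit(
                    x[train], y[train], lam, solver="sgd",
                    max_iter=sgd_iter, seed=int(rng.integers(2**31)),
                )
                pred = _soft_classify(x[train], y[train], x[test], w)
                errs.append(float(np.mean(pred != y[test])))
        errs = np.asarray(errs)
        losses[float(lam)] = float(errs.mean())
        loss_ses[float(lam)] = (
            float(errs.std(ddof=1) / np.sqrt(errs.size)) if errs.size > 1 else 0.0
        )
    best_lam = min(losses, key=lambda l: (losses[l], l))
    if se_rule:
        thr = losses[best_lam] + se_factor * loss_ses[best_lam]
        best_lam = max(l for l in losses if losses[l] <= thr)
    w, converged, obj = nca_fit(x, y, best_lam, solver="lbfgs")
    if not converged:
        warnings.warn("final L-BFGS fit did not fully converge; best iterate kept",
                      stacklevel=2)
    weights = pd.Series(w, index=table.columns)
    ranking = list(weights.sort_values(ascending=False, kind="stable").index)
    retained = [f for f in ranking if weights[f] >= cutoff]
    return NCAResult(
        weights=weights,
        lam=best_lam,
        ranking=ranking,
        retained=retained,
        converged=converged,
        objective=obj,
        cv_losses=losses,
    )


def select_features(
    table: pd.DataFrame, labels, seed: int = 0, cv_reps: int = 100, **kwargs
) -> tuple[pd.DataFrame, NCAResult]:
    """Full pipeline: constant -> perfect-correlation -> NCA."""
    filtered = preliminary_filter(table)
    result = nca_select(filtered, labels, seed=seed, cv_reps=cv_reps, **kwargs)
    return filtered, result
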