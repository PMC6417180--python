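"""Negative-binomial GLM machinery for two-group RNA-seq models.

Everything here is vectorized across genes for the shared two-column
design ``[intercept, group]`` with per-sample log offsets.  The NB
parameterization is ``Var(Y) = mu + alpha * mu^2`` (``alpha`` the
dispersion, ``1/alpha`` the gamma shape).

Provides median-of-ratios size factors, IRLS fitting, Cox-Reid adjusted
profile likelihoods for dispersion estimation, the parametric dispersion
trend ``alpha(mu) = a0 + a1/mu`` fit by gamma regression, and a trigamma
inverse used by the empirical-Bayes variance moderation of the weighted
linear-model engine.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special

_ETA_MIN = -30.0  # clamp for linear predictors of all-zero groups


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Genes with a zero in any sample drop out of the reference, the standard
    construction.  Falls back to library-size ratios if no gene is
    everywhere positive.
    """
    arr = np.asarray(counts, dtype=float)
    pos = (arr > 0).all(axis=1)
    if pos.sum() >= 1:
        logg = np.log(arr[pos])
        ref = logg.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logg - ref, axis=0))
    else:
        lib = arr.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples.

    ``y`` and ``mu`` are (G, n); ``alpha`` broadcasts over samples.
    """
    a = np.maximum(np.asarray(alpha, dtype=float), 1e-12)
    if a.ndim == 1:
        a = a[:, None]
    r = 1.0 / a
    mu = np.maximum(mu, 1e-12)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    x: np.ndarray,
    log_offsets: np.ndarray,
    alpha: np.ndarray | float,
    n_iter: int = 8,
    two_column: bool = True,
) -> dict[str, np.ndarray]:
    """IRLS fit of the NB GLM ``log mu = b0 + b1*x + offset`` per gene.

    Parameters
    ----------
    y : (G, n) counts
    x : (n,) group indicator (0/1); ignored when ``two_column`` is False
        (intercept-only null model).
    log_offsets : (n,) log size factors (or effective library sizes)
    alpha : per-gene dispersion, scalar or (G,)

    Returns a dict with ``beta`` (G, 2), ``mu`` (G, n), ``se1`` (G,) the
    Wald standard error of the group coefficient, and ``logdet`` (G,) the
    log-determinant of the weighted information matrix (for the Cox-Reid
    adjustment).  For the intercept-only model ``beta[:, 1]`` is 0.
    """
    G, n = y.shape
    a = np.broadcast_to(np.atleast_1d(np.asarray(alpha, dtype=float)), (G,))[:, None]
    off = np.broadcast_to(log_offsets, (G, n))
    # init from group means of offset-normalized counts
    norm = (y + 0.5) / np.exp(off)
    if two_column:
        m0 = norm[:, x == 0].mean(axis=1)
        m1 = norm[:, x == 1].mean(axis=1)
        b0 = np.log(np.maximum(m0, 1e-8))
        b1 = np.log(np.maximum(m1, 1e-8)) - b0
    else:
        b0 = np.log(np.maximum(norm.mean(axis=1), 1e-8))
        b1 = np.zeros(G)
    xg = x[None, :].astype(float)
    for _ in range(n_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * xg + off, _ETA_MIN, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        z = (eta - off) + (y - mu) / np.maximum(mu, 1e-12)
        if two_column:
            sw = w.sum(axis=1)
            swx = (w * xg).sum(axis=1)
            swxx = (w * xg * xg).sum(axis=1)
            r0 = (w * z).sum(axis=1)
            r1 = (w * xg * z).sum(axis=1)
            det = sw * swxx - swx * swx
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            b0 = (swxx * r0 - swx * r1) / det
            b1 = (sw * r1 - swx * r0) / det
        else:
            sw = w.sum(axis=1)
            b0 = (w * z).sum(axis=1) / np.maximum(sw, 1e-12)
    eta = np.clip(b0[:, None] + b1[:, None] * xg + off, _ETA_MIN, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    if two_column:
        swx = (w * xg).sum(axis=1)
        swxx = (w * xg * xg).sum(axis=1)
        det = np.maximum(sw * swxx - swx * swx, 1e-300)
        se1 = np.sqrt(np.maximum(sw / det, 0.0))
        logdet = np.log(det)
    else:
        se1 = np.full(G, np.nan)
        logdet = np.log(np.maximum(sw, 1e-300))
    return {
        "beta": np.column_stack([b0, b1]),
        "mu": mu,
        "se1": se1,
        "logdet": logdet,
    }


def cox_reid_apl(
    y: np.ndarray,
    x: np.ndarray,
    log_offsets: np.ndarray,
    alpha_grid: np.ndarray,
    two_column: bool = True,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood on a dispersion grid.

    Returns an (n_grid, G) array: for each grid dispersion the GLM is
    refit and ``loglik - 0.5 * logdet(X' W X)`` evaluated per gene.
    """
    out = np.empty((len(alpha_grid), y.shape[0]))
    for i, a in enumerate(alpha_grid):
        fit = fit_nb_glm(y, x, log_offsets, a, two_column=two_column)
        out[i] = nb_loglik(y, fit["mu"], np.full(y.shape[0], a)) - 0.5 * fit["logdet"]
    return out


def argmax_on_grid(obj: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-gene maximizer of (n_grid, G) objective with a quadratic refine.

    A parabola through the best grid point and its neighbours (in log-grid
    space) sharpens the estimate without further likelihood evaluations.
    """
    lg = np.log(grid)
    k = np.argmax(obj, axis=0)
    G = obj.shape[1]
    k_in = np.clip(k, 1, len(grid) - 2)
    y0 = obj[k_in - 1, np.arange(G)]
    y1 = obj[k_in, np.arange(G)]
    y2 = obj[k_in + 1, np.arange(G)]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = lg[1] - lg[0]
    refined = lg[k_in] + shift * step
    # keep pure grid answer at the boundaries
    refined = np.where((k == 0) | (k == len(grid) - 1), lg[k], refined)
    return np.exp(refined)


DEFAULT_GRID = np.exp(np.linspace(np.log(1e-5), np.log(10.0), 45))


def fit_dispersion_trend(
    base_mean: np.ndarray, disp: np.ndarray
) -> tuple[float, float]:
    """Parametric dispersion trend ``alpha(mu) = a0 + a1 / mu``.

    Iterated gamma-family regression of gene-wise dispersions on 1/mean,
    dropping ratio outliers between iterations.  Returns (a0, a1); raises
    ``RuntimeError`` when the fit degenerates (caller decides the
    fallback).
    """
    import statsmodels.api as sm

    keep = (base_mean > 0) & np.isfinite(disp) & (disp > 1e-7)
    if keep.sum() < 10:
        raise RuntimeError("too few genes to fit a dispersion trend")
    mu = base_mean[keep]
    d = disp[keep]
    a0, a1 = float(np.median(d)), 0.0
    for _ in range(8):
        X = np.column_stack([np.ones_like(mu), 1.0 / mu])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                d, X, family=sm.families.Gamma(link=sm.families.links.Identity())
            )
            try:
                res = model.fit(start_params=[max(a0, 1e-4), max(a1, 1e-4)])
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError("dispersion trend fit failed") from exc
        a0_new, a1_new = float(res.params[0]), float(res.params[1])
        if not np.isfinite(a0_new) or a0_new <= 0:
            raise RuntimeError("dispersion trend fit degenerated")
        pred = a0_new + a1_new / mu
        ratio = d / np.maximum(pred, 1e-12)
        inliers = (ratio > 1e-4) & (ratio < 15.0)
        converged = abs(a0_new - a0) < 1e-6 * abs(a0) + 1e-10
        a0, a1 = a0_new, max(a1_new, 0.0)
        if converged:
            break
        mu, d = mu[inliers], d[inliers]
        if len(mu) < 10:
            break
    return a0, a1


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (limma's construction)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)
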