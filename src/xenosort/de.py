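"""Three-engine consensus differential expression.

Three independent engines behind one contract (counts + two groups in,
one raw p per gene out):

* ``nb_wald`` — NB GLM with median-of-ratios size factors, Cox-Reid
  gene-wise dispersions shrunk toward a parametric trend (a log-normal
  prior, MAP estimate), Wald test on the group coefficient.
* ``nb_lrt`` — NB GLM with TMM effective library sizes, tagwise
  dispersions from an empirical-Bayes weighted Cox-Reid likelihood,
  likelihood-ratio test of the group coefficient (chi-square, 1 df).
* ``weighted_lm`` — log-CPM linear model with inverse mean-variance-trend
  precision weights and a moderated t-statistic via empirical-Bayes
  variance shrinkage.

Per engine, raw p-values receive a Sidak correction for the ``m``
comparisons tested within the model (identity at the default m=1), then a
Benjamini-Hochberg adjustment across genes; the consensus p per gene is
the median of the three corrected values, so a gene is significant at
``alpha`` exactly when at least two engines call it below ``alpha``.

Genes below the CPM floor in every group are removed before testing.
These are reimplementations of the published statistics of the standard
engines, not bindings; numerical agreement with any external package is
not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from . import nbglm
from .quantify import CountMatrix, cpm


@dataclass(frozen=True)
class DEParams:
    cpm_floor: float = 1.0
    alpha: float = 0.05
    sidak_m: int = 1  # comparisons within the model
    per_sample_filter: bool = False  # CPM floor per sample instead of group mean

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sidak_m < 1:
            raise ValueError("sidak_m must be >= 1")


# ---------------------------------------------------------------------------
# filtering and corrections


def cpm_filter(
    matrix: CountMatrix, cpm_floor: float = 1.0, per_sample: bool = False
) -> CountMatrix:
    """Discard genes below the CPM floor in *all* groups.

    Default reading: a gene survives iff its group-mean CPM reaches the
    floor in at least one group.  ``per_sample=True`` instead requires a
    single sample at or above the floor.
    """
    groups = pd.Series({s: matrix.group_of(s) for s in matrix.counts.columns})
    for g, cnt in groups.value_counts().items():
        if cnt == 0:
            raise ValueError(f"group {g!r} has no samples")
    cpm_mat = cpm(matrix.counts)
    if per_sample:
        keep = (cpm_mat >= cpm_floor).any(axis=1)
    else:
        group_means = cpm_mat.T.groupby(groups).mean().T
        keep = (group_means >= cpm_floor).any(axis=1)
    return CountMatrix(
        counts=matrix.counts.loc[keep],
        lengths=matrix.lengths.reindex(matrix.counts.index[keep]),
        groups=dict(matrix.groups),
    )


def sidak_correct(p: np.ndarray | float, m: int = 1) -> np.ndarray | float:
    """Sidak familywise correction: 1 - (1 - p)^m, clipped to [0, 1]."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.clip(1.0 - np.power(1.0 - np.asarray(p, dtype=float), m), 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# engine plumbing


def _two_group_design(
    counts: pd.DataFrame, groups: pd.Series | dict
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    groups = pd.Series(groups).reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    x = (groups == levels[1]).to_numpy().astype(float)
    n_a, n_b = int((x == 0).sum()), int((x == 1).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    return counts.to_numpy(dtype=float), x, levels


def _tmm_factors(counts: np.ndarray) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (30% M / 5% A trim)."""
    lib = counts.sum(axis=0)
    ref = int(np.argmin(np.abs(
        np.percentile(counts / lib, 75, axis=0) -
        np.median(np.percentile(counts / lib, 75, axis=0))
    )))
    f = np.ones(counts.shape[1])
    pr = counts[:, ref] / lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        pj = counts[:, j] / lib[j]
        ok = (pj > 0) & (pr > 0)
        if ok.sum() < 10:
            continue
        M = np.log2(pj[ok] / pr[ok])
        A = 0.5 * np.log2(pj[ok] * pr[ok])
        w = 1.0 / ((1 - pj[ok]) / (lib[j] * pj[ok]) + (1 - pr[ok]) / (lib[ref] * pr[ok]))
        keepM = (M >= np.quantile(M, 0.30)) & (M <= np.quantile(M, 0.70))
        keepA = (A >= np.quantile(A, 0.05)) & (A <= np.quantile(A, 0.95))
        keep = keepM & keepA
        if keep.sum() >= 5:
            f[j] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    return f / np.exp(np.mean(np.log(f)))


def _finalize_p(
    p: np.ndarray, counts: np.ndarray, index: pd.Index, name: str
) -> pd.Series:
    p = np.clip(np.where(np.isfinite(p), p, 1.0), 0.0, 1.0)
    p[counts.sum(axis=1) == 0] = 1.0  # defined degenerate output
    return pd.Series(p, index=index, name=name)


# ---------------------------------------------------------------------------
# engines


def de_engine_nb_wald(
    counts: pd.DataFrame, groups: pd.Series | dict
) -> pd.Series:
    """NB Wald engine: size factors, trended MAP dispersions, Wald test."""
    y, x, _ = _two_group_design(counts, groups)
    G, n = y.shape
    sf = nbglm.size_factors(y)
    off = np.log(sf)
    base_mean = (y / sf).mean(axis=1)

    apl = nbglm.cox_reid_apl(y, x, off, nbglm.DEFAULT_GRID)
    disp_gene = nbglm.argmax_on_grid(apl, nbglm.DEFAULT_GRID)
    try:
        a0, a1 = nbglm.fit_dispersion_trend(base_mean, disp_gene)
        trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    except RuntimeError:
        trend = np.full(G, max(float(np.median(disp_gene)), 1e-4))
    # log-normal prior width around the trend (spread beyond sampling noise)
    lr = np.log(np.maximum(disp_gene, 1e-8)) - np.log(np.maximum(trend, 1e-8))
    ok = np.isfinite(lr) & (base_mean > 0)
    s_lr = stats.median_abs_deviation(lr[ok], scale="normal") if ok.sum() > 2 else 1.0
    sampling_var = float(special.polygamma(1, (n - 2) / 2.0))
    prior_var = max(s_lr**2 - sampling_var, 0.25)
    log_trend = np.log(np.maximum(trend, 1e-10))
    penalty = (
        (np.log(nbglm.DEFAULT_GRID)[:, None] - log_trend[None, :]) ** 2
        / (2.0 * prior_var)
    )
    disp_map = nbglm.argmax_on_grid(apl - penalty, nbglm.DEFAULT_GRID)

    fit = nbglm.fit_nb_glm(y, x, off, disp_map)
    z = fit["beta"][:, 1] / np.maximum(fit["se1"], 1e-12)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return _finalize_p(p, y, counts.index, "nb_wald")


def de_engine_nb_lrt(
    counts: pd.DataFrame, groups: pd.Series | dict, prior_df: float = 10.0
) -> pd.Series:
    """NB LRT engine: TMM scaling, EB tagwise dispersions, chi-square LRT."""
    y, x, _ = _two_group_design(counts, groups)
    G, n = y.shape
    lib = y.sum(axis=0)
    eff = lib * _tmm_factors(y)
    off = np.log(eff / np.exp(np.mean(np.log(eff))))

    apl = nbglm.cox_reid_apl(y, x, off, nbglm.DEFAULT_GRID)
    common = apl.mean(axis=1)
    weight = prior_df / max(n - 2, 1)
    disp_tag = nbglm.argmax_on_grid(apl + weight * common[:, None], nbglm.DEFAULT_GRID)

    full = nbglm.fit_nb_glm(y, x, off, disp_tag)
    null = nbglm.fit_nb_glm(y, x, off, disp_tag, two_column=False)
    lr = 2.0 * (
        nbglm.nb_loglik(y, full["mu"], disp_tag)
        - nbglm.nb_loglik(y, null["mu"], disp_tag)
    )
    p = stats.chi2.sf(np.maximum(lr, 0.0), df=1)
    return _finalize_p(p, y, counts.index, "nb_lrt")


def de_engine_weighted_lm(
    counts: pd.DataFrame, groups: pd.Series | dict
) -> pd.Series:
    """Precision-weighted log-CPM engine with moderated t statistics."""
    y, x, _ = _two_group_design(counts, groups)
    G, n = y.shape
    lib = y.sum(axis=0)
    logcpm = np.log2((y + 0.5) / (lib + 1.0)[None, :] * 1e6)

    def wls(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        xg = x[None, :]
        sw = w.sum(axis=1)
        swx = (w * xg).sum(axis=1)
        swxx = (w * xg * xg).sum(axis=1)
        r0 = (w * logcpm).sum(axis=1)
        r1 = (w * xg * logcpm).sum(axis=1)
        det = np.maximum(sw * swxx - swx * swx, 1e-300)
        b0 = (swxx * r0 - swx * r1) / det
        b1 = (sw * r1 - swx * r0) / det
        fitted = b0[:, None] + b1[:, None] * xg
        rss = (w * (logcpm - fitted) ** 2).sum(axis=1)
        se_unit = np.sqrt(sw / det)  # SE of b1 per unit sigma
        return b1, fitted, rss, se_unit

    # pass 1: unweighted, to learn the mean-variance trend
    b1, fitted, rss, se_unit = wls(np.ones_like(logcpm))
    df_resid = n - 2
    s = np.sqrt(np.maximum(rss / df_resid, 0.0))
    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(s)
    ok = np.isfinite(sx) & np.isfinite(sy)
    lo = lowess(sy[ok], sx[ok], frac=0.5, return_sorted=True)
    lam = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(lam, lo[:, 0], lo[:, 1])
    w = 1.0 / np.maximum(pred_sqrt_sd, 1e-4) ** 4

    # pass 2: precision-weighted fit + EB variance moderation
    b1, fitted, rss, se_unit = wls(w)
    s2 = np.maximum(rss / df_resid, 1e-12)
    zlog = np.log(s2)
    e = zlog - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    evar = max(np.var(e, ddof=1) - special.polygamma(1, df_resid / 2.0), 0.0)
    if evar > 0:
        d0 = 2.0 * nbglm.trigamma_inverse(evar)
        s0_sq = np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    else:
        s2_post = np.full(G, np.exp(np.mean(e)))
        df_total = np.inf
    t = b1 / (np.sqrt(s2_post) * se_unit)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return _finalize_p(p, y, counts.index, "weighted_lm")


ENGINES = {
    "nb_wald": de_engine_nb_wald,
    "nb_lrt": de_engine_nb_lrt,
    "weighted_lm": de_engine_weighted_lm,
}


# ---------------------------------------------------------------------------
# consensus


def consensus(corrected: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Median-of-three consensus from per-engine corrected p-values.

    The median of three values is below ``alpha`` exactly when at least
    two of them are.  Genes with a missing engine value are flagged and
    excluded from significance calls.
    """
    if corrected.shape[1] != 3:
        raise ValueError("exactly three engine columns required")
    complete = corrected.notna().all(axis=1)
    cons = corrected.median(axis=1)
    out = pd.DataFrame(
        {
            "consensus_p": cons,
            "complete": complete,
            "significant": complete & (cons < alpha),
        }
    )
    out.loc[~complete, "consensus_p"] = np.nan
    return out


def run_consensus_de(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Full consensus procedure between two groups of a count matrix.

    Steps: CPM filter -> three engines -> Sidak(m) within engine -> BH
    across genes within engine -> median consensus -> significance at
    ``alpha``.  Returns one row per tested gene with every intermediate
    p-value, the log2 fold change of group_b over group_a (CPM scale,
    0.5 pseudocount), and the significance flag.
    """
    params = params or DEParams()
    samples = [s for s in matrix.counts.columns if matrix.group_of(s) in (group_a, group_b)]
    if not samples:
        raise ValueError(f"no samples in groups {group_a!r}/{group_b!r}")
    sub = CountMatrix(
        counts=matrix.counts[samples],
        lengths=matrix.lengths,
        groups={s: matrix.groups[s] for s in samples},
    )
    filtered = cpm_filter(sub, params.cpm_floor, params.per_sample_filter)
    counts = filtered.counts
    groups = pd.Series({s: filtered.group_of(s) for s in counts.columns})

    result = pd.DataFrame(index=counts.index)
    corrected = {}
    for name, engine in ENGINES.items():
        raw = engine(counts, groups)
        sid = pd.Series(sidak_correct(raw.values, params.sidak_m), index=raw.index)
        adj = pd.Series(bh_adjust(sid.values), index=raw.index)
        result[f"p_{name}"] = raw
        result[f"sidak_{name}"] = sid
        result[f"padj_{name}"] = adj
        corrected[name] = adj
    cons = consensus(pd.DataFrame(corrected), params.alpha)
    result["consensus_p"] = cons["consensus_p"]
    result["significant"] = cons["significant"]

    cpm_mat = cpm(counts)
    mean_a = cpm_mat[[s for s in samples if groups[s] == group_a]].mean(axis=1)
    mean_b = cpm_mat[[s for s in samples if groups[s] == group_b]].mean(axis=1)
    result["log2_fold_change"] = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    result["mean_cpm_a"] = mean_a
    result["mean_cpm_b"] = mean_b
    return result
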