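"""Sample-level profiling: gene filtering, variance stabilization, PCA,
and marker-panel expression matrices.

The PCA gene subset keeps genes with at least ``min_tpm`` TPM in at least
half the samples (both thresholds inclusive).  Counts are normalized by
median-of-ratios size factors and passed through the closed-form NB
variance-stabilizing transform under the parametric dispersion trend
``alpha(mu) = a0 + a1/mu``:

    f(x) = log2( (1 + a1 + 2*a0*x + 2*sqrt(a0*x*(1 + a1 + a0*x))) / (4*a0) )

which is strictly increasing, defined at x = 0, and asymptotically
log2-like, so count variance becomes approximately mean-independent before
the decomposition.  Marker panels (cell-type gene lists) are shipped as an
editable YAML config.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import nbglm


@dataclass(frozen=True)
class PCAGeneFilter:
    min_tpm: float = 5.0
    min_sample_fraction: float = 0.5  # inclusive

    def __post_init__(self) -> None:
        if self.min_tpm < 0:
            raise ValueError("min_tpm must be >= 0")
        if not 0.0 < self.min_sample_fraction <= 1.0:
            raise ValueError("min_sample_fraction must lie in (0, 1]")


def select_genes_for_pca(
    tpm_matrix: pd.DataFrame, gene_filter: PCAGeneFilter | None = None
) -> pd.Index:
    """Genes with TPM >= min_tpm in at least ceil(fraction * n) samples."""
    f = gene_filter or PCAGeneFilter()
    need = int(np.ceil(f.min_sample_fraction * tpm_matrix.shape[1]))
    n_pass = (tpm_matrix >= f.min_tpm).sum(axis=1)
    return tpm_matrix.index[n_pass >= need]


@dataclass
class VSTParams:
    """Fitted dispersion-trend coefficients and size factors."""

    a0: float  # asymptotic dispersion
    a1: float  # extra-Poisson term (alpha = a0 + a1/mu)
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def fit_vst(counts: pd.DataFrame) -> VSTParams:
    """Fit the dispersion trend from moment dispersions of normalized counts.

    Per-gene moment dispersions ``(var - mu) / mu^2`` are regressed on
    1/mean with a gamma-family fit; a degenerate fit falls back to the
    median positive dispersion with a warning (the transform then reduces
    to a shifted log).
    """
    sf = pd.Series(nbglm.size_factors(counts), index=counts.columns)
    norm = counts / sf
    mu = norm.mean(axis=1).to_numpy()
    var = norm.var(axis=1, ddof=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / mu**2
    try:
        a0, a1 = nbglm.fit_dispersion_trend(mu, disp)
    except RuntimeError:
        warnings.warn("dispersion trend fit degenerated; using median dispersion")
        pos = disp[np.isfinite(disp) & (disp > 0)]
        a0, a1 = (float(np.median(pos)) if len(pos) else 0.1), 0.0
    return VSTParams(a0=max(a0, 1e-8), a1=max(a1, 0.0), size_factors=sf)


def vst(counts: pd.DataFrame, params: VSTParams | None = None) -> pd.DataFrame:
    """Closed-form NB variance-stabilizing transform of normalized counts."""
    p = params or fit_vst(counts)
    x = (counts / p.size_factors).to_numpy(dtype=float)
    a0, a1 = p.a0, p.a1
    inner = (1.0 + a1 + 2.0 * a0 * x + 2.0 * np.sqrt(a0 * x * (1.0 + a1 + a0 * x)))
    out = np.log2(inner / (4.0 * a0))
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def pca(
    matrix: pd.DataFrame, genes: pd.Index | None = None, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on a (transformed) genes x samples matrix.

    Genes are centered; samples are the observations; components come from
    the singular value decomposition.  Returns (sample coordinates,
    variance-explained fractions).
    """
    sub = matrix.loc[genes] if genes is not None else matrix
    X = sub.T.to_numpy(dtype=float)  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=sub.columns, columns=cols),
        model.explained_variance_ratio_,
    )


def load_marker_panels(path: str | None = None) -> dict[str, list[str]]:
    """Marker panels from YAML; defaults to the shipped cell-type config."""
    if path is None:
        text = (
            importlib.resources.files("xenosort")
            .joinpath("data/marker_panels.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    panels = yaml.safe_load(text)
    return {str(k): [str(g) for g in v] for k, v in panels.items()}


def marker_matrix(
    tpm_matrix: pd.DataFrame, panels: dict[str, list[str]]
) -> tuple[pd.DataFrame, list[str]]:
    """log2(TPM+1) restricted to panel genes, ordered by panel definition.

    Genes absent from the matrix are reported back, not fatal.  The result
    has a (panel, gene) MultiIndex ready for heat-map plotting.
    """
    rows = []
    missing = []
    for panel, genes in panels.items():
        for g in genes:
            if g in tpm_matrix.index:
                rows.append((panel, g))
            else:
                missing.append(g)
    idx = pd.MultiIndex.from_tuples(rows, names=["panel", "gene"])
    vals = np.log2(tpm_matrix.loc[[g for _, g in rows]].to_numpy() + 1.0)
    return pd.DataFrame(vals, index=idx, columns=tpm_matrix.columns), missing
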