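"""Gene-level expression: overlap counting, CPM and TPM.

Fragments are counted to the gene whose exons their alignment interval
overlaps (any overlap of at least one base, half-open coordinates); a
fragment overlapping k > 1 genes contributes 1/k to each, and fragments
overlapping no exon are tallied in a ``__no_feature`` bucket.  Fractional
counts are resolved at matrix finalization by stochastic rounding with a
fixed seed, so the matrix holds integers and expectation is preserved.

The counter is a deliberately transparent stand-in for k-mer/EM
quantifiers: with single-isoform genes — the regime every synthetic test
here operates in — overlap counting and EM quantification coincide
conceptually.  Gene effective length is the exon-union length, with no
fragment-length correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sort import SpeciesCall
from .synthetic import Genome

NO_FEATURE = "__no_feature"


def _exon_union_length(exons: list[tuple[int, int]]) -> int:
    if not exons:
        return 0
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return sum(e - s for s, e in merged)


def gene_lengths(genome: Genome) -> pd.Series:
    """Exon-union length per annotated gene."""
    return pd.Series(
        {loc.gene_id: _exon_union_length(loc.exons) for loc in genome.loci if loc.exons},
        name="length",
    )


Annotation = dict[str, list[tuple[str, int, int]]]
"""Per-sequence exon annotation: seq_id -> [(gene_id, start, end), ...]."""


def genome_annotation(genome: Genome) -> Annotation:
    """Annotation dict for a synthetic genome (one gene per locus)."""
    return {
        loc.gene_id: [(loc.gene_id, s, e) for s, e in loc.exons]
        for loc in genome.loci
    }


def count_fragments(hits: list[tuple[str, int, int]], annotation: Annotation) -> pd.Series:
    """Fractional gene counts from (seq_id, start, end) alignment intervals.

    Each fragment contributes 1/k to each of the k genes whose exons its
    interval overlaps, or 1 to ``__no_feature`` when none do.
    """
    counts: dict[str, float] = {}
    for seq_id, start, end in hits:
        if seq_id not in annotation:
            raise ValueError(f"alignment references unknown locus {seq_id!r}")
        overlapping = sorted(
            {g for g, s, e in annotation[seq_id] if start < e and s < end}
        )
        if overlapping:
            w = 1.0 / len(overlapping)
            for g in overlapping:
                counts[g] = counts.get(g, 0.0) + w
        else:
            counts[NO_FEATURE] = counts.get(NO_FEATURE, 0.0) + 1.0
    return pd.Series(counts, dtype=float)


def count_genes(
    calls: list[SpeciesCall], genome: Genome, label: str = "graft"
) -> pd.Series:
    """Fractional gene counts for the fragments carrying a given label."""
    hits = []
    for c in calls:
        if c.label != label:
            continue
        hit = c.graft_hit if label == "graft" else c.host_hit
        if hit is not None:
            hits.append((hit.locus_id, hit.start, hit.end))
    return count_fragments(hits, genome_annotation(genome))


@dataclass
class CountMatrix:
    """Genes x samples integer counts with lengths and sample groups."""

    counts: pd.DataFrame
    lengths: pd.Series
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group: {missing}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_of(self, sample: str) -> str:
        return self.groups[sample]


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)


def build_count_matrix(
    sample_counts: dict[str, pd.Series],
    lengths: pd.Series,
    groups: dict[str, str],
    seed: int = 0,
    drop_no_feature: bool = True,
) -> CountMatrix:
    """Assemble per-sample fractional counts into an integer CountMatrix.

    Fractional values are resolved by stochastic rounding under ``seed``.
    """
    df = pd.DataFrame(sample_counts).fillna(0.0)
    df = df.reindex(sorted(df.index))
    if drop_no_feature:
        df = df.drop(index=[NO_FEATURE], errors="ignore")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(61,)))
    rounded = pd.DataFrame(
        _stochastic_round(df.values.astype(float), rng),
        index=df.index,
        columns=df.columns,
    )
    lengths = lengths.reindex(rounded.index)
    return CountMatrix(counts=rounded, lengths=lengths, groups=dict(groups))


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts * 1e6 / lib


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6.

    rate = count / length; TPM = rate * 1e6 / sum(rates) per sample.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"genes without a length: {missing[:5]}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene length: {bad[:5]}")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    out = rate * 1e6 / denom.replace(0, np.nan)
    return out.fillna(0.0)


def log2_tpm1(tpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1), the heat-map convention."""
    return np.log2(tpm_matrix + 1.0)
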