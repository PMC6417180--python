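"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: full unbanded
Smith-Waterman through Biopython's PairwiseAligner, brute-force
multiple-testing corrections, and a brute-force adapter suffix-prefix
scan.  They are slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

from xenosort.synthetic import revcomp


def biopython_aligner(match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    # PairwiseAligner scores the first gap base with open_gap_score and
    # subsequent bases with extend_gap_score, matching the package scheme.
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def oracle_best_hit(mate: str, genome, params) -> tuple[float, str] | None:
    """Best normalized local-alignment score of a mate over all loci and
    orientations, by full unbanded Smith-Waterman; None below theta."""
    aligner = biopython_aligner(
        params.match_score, params.mismatch_penalty,
        params.gap_open, params.gap_extend,
    )
    best = None
    for locus in genome.loci:
        for seq in (mate, revcomp(mate)):
            s = aligner.score(seq, locus.seq)
            if best is None or s > best[0]:
                best = (s, locus.gene_id)
    if best is None:
        return None
    norm = best[0] / (len(mate) * params.match_score)
    if norm < params.theta:
        return None
    return norm, best[1]


def oracle_fragment_scores(read, pair, params) -> dict[str, float | None]:
    """Fragment-level per-genome score by the unbanded oracle: mean of the
    mates' normalized scores when both clear theta on the same locus."""
    out: dict[str, float | None] = {}
    for name, genome in (("graft", pair.graft), ("host", pair.host)):
        h1 = oracle_best_hit(read.seq1, genome, params)
        h2 = oracle_best_hit(read.seq2, genome, params)
        if h1 is None or h2 is None or h1[1] != h2[1]:
            out[name] = None
        else:
            out[name] = (h1[0] + h2[0]) / 2.0
    return out


def oracle_label(scores: dict[str, float | None]) -> str:
    g, h = scores["graft"], scores["host"]
    if g is None and h is None:
        return "unaligned"
    if h is None:
        return "graft"
    if g is None:
        return "host"
    if g == h:
        return "ambiguous"
    return "graft" if g > h else "host"


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH by direct definition: adj_i = min over j >= rank(i) of
    min(1, m * p_(j) / j), computed with an explicit loop."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def brute_force_sidak(p: np.ndarray, m: int) -> np.ndarray:
    """Sidak by repeated multiplication of survival probabilities."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    for i, pi in enumerate(p):
        surv = 1.0
        for _ in range(m):
            surv *= 1.0 - pi
        out[i] = min(max(1.0 - surv, 0.0), 1.0)
    return out


def brute_force_trim(seq: str, adapters, min_overlap: int, mism_frac: float) -> int:
    """Longest adapter-prefix suffix match by exhaustive scan; returns the
    kept length."""
    best = len(seq)
    for adapter in adapters:
        for i in range(len(seq) - min_overlap + 1):
            overlap = len(seq) - i
            if overlap > len(adapter):
                continue
            mism = sum(a != b for a, b in zip(seq[i:], adapter[:overlap]))
            if mism <= int(mism_frac * overlap):
                best = min(best, i)
                break
    return best
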