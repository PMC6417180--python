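"""Dual-genome alignment scoring for species sorting.

Every retained fragment is scored against both the graft and the host
genome with a local alignment under a simple scheme (+1 match, -1 mismatch,
affine gaps -2 to open / -1 to extend) and the raw score is normalized by
the maximum attainable score, ``read_length * match_score``.  A normalized
score of 1.0 means a perfect full-length match; the species-sorting
threshold ("at least 90% of the maximum alignment") becomes
``normalized_score >= theta`` with ``theta = 0.90`` inclusive.

The search is exact-seed anchoring plus windowed Smith-Waterman: all exact
``seed_length``-mers shared between read and genome anchor candidate
diagonals, and a full local alignment is computed in a window of
``band_width`` bases around each anchored diagonal (numba-compiled).  An
unbanded Smith-Waterman over whole loci gives identical raw scores whenever
at least one exact seed survives on the optimal diagonal, which is the case
for essentially all reads at the divergences this pipeline targets; reads
with no surviving seed are reported as unaligned.

Both orientations are always tried; the reverse-complement hit is reported
with ``strand='-'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import Genome, GenomePair, ReadRecord, revcomp

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i


def encode(seq: str) -> np.ndarray:
    """Encode ACGT to 0..3 (other characters become a non-matching code)."""
    enc = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    # map unknowns to 4 so they mismatch everything
    return np.where(enc == 255, 4, enc).astype(np.int8)


@dataclass(frozen=True)
class AlignParams:
    match_score: int = 1
    mismatch_penalty: int = -1
    gap_open: int = -2  # score of the first base of a gap
    gap_extend: int = -1  # score of each further gap base
    band_width: int = 16
    theta: float = 0.90  # min normalized score, inclusive
    seed_length: int = 15
    max_insert: int = 1000  # mate concordance window, bases

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of one mate on one genome."""

    genome: str
    locus_id: str
    start: int  # 0-based on the locus
    end: int  # half-open
    raw_score: int
    normalized_score: float
    strand: str  # '+' forward, '-' reverse-complement


@dataclass(frozen=True)
class FragmentHit:
    """Concordant fragment-level alignment on one genome."""

    genome: str
    locus_id: str
    start: int  # union interval of the two mates
    end: int
    score: float  # mean of the mates' normalized scores
    hits: tuple[AlignmentHit, AlignmentHit]


@njit(cache=True)
def _sw_window(read, ref, match, mismatch, gap_open, gap_extend):
    """Local alignment of ``read`` against ``ref``; returns
    (best_score, ref_start, ref_end) with start propagated through the DP
    (no traceback needed)."""
    m = read.shape[0]
    w = ref.shape[0]
    neg = -(1 << 28)
    H = np.zeros(w + 1, dtype=np.int32)
    F = np.full(w + 1, neg, dtype=np.int32)  # gap consuming read bases
    SH = np.arange(w + 1, dtype=np.int32)  # ref start of path ending in H
    SF = np.zeros(w + 1, dtype=np.int32)
    best = 0
    best_end = 0
    best_start = 0
    for i in range(1, m + 1):
        diag = H[0]
        sdiag = SH[0]
        H[0] = 0
        SH[0] = 0
        E = neg  # gap consuming ref bases, scalar along the row
        SE = 0
        ri = read[i - 1]
        for j in range(1, w + 1):
            # F: vertical gap; H[j]/F[j] still hold the previous row here
            fo = H[j] + gap_open
            fe = F[j] + gap_extend
            if fo >= fe:
                F[j] = fo
                SF[j] = SH[j]
            else:
                F[j] = fe
                # SF[j] unchanged
            # E: horizontal gap; H[j-1] already belongs to the current row
            eo = H[j - 1] + gap_open
            ee = E + gap_extend
            if eo >= ee:
                E = eo
                SE = SH[j - 1]
            else:
                E = ee
            s = match if ri == ref[j - 1] else mismatch
            h = diag + s
            sh = sdiag
            if E > h:
                h = E
                sh = SE
            if F[j] > h:
                h = F[j]
                sh = SF[j]
            if h < 0:
                h = 0
                sh = j
            diag = H[j]
            sdiag = SH[j]
            H[j] = h
            SH[j] = sh
            if h > best:
                best = h
                best_end = j
                best_start = sh
    return best, best_start, best_end


def smith_waterman(read: str, ref: str, params: AlignParams | None = None
                   ) -> tuple[int, int, int]:
    """Unbanded local alignment of a read against an arbitrary reference.

    Returns (raw_score, ref_start, ref_end).  This is the same kernel the
    seeded search applies to its windows, exposed over a full sequence.
    """
    p = params or AlignParams()
    return _sw_window(
        encode(read), encode(ref),
        p.match_score, p.mismatch_penalty, p.gap_open, p.gap_extend,
    )


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    n = enc.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    win = sliding_window_view(enc.astype(np.int64), k)
    codes = win @ powers
    # windows containing a non-ACGT base get an out-of-range sentinel
    bad = sliding_window_view(enc, k).max(axis=1) > 3
    codes[bad] = -1
    return codes


class GenomeIndex:
    """Exact k-mer index over the loci of one genome."""

    def __init__(self, genome: Genome, seed_length: int):
        self.genome = genome
        self.k = seed_length
        self.encoded = [encode(loc.seq) for loc in genome.loci]
        index: dict[int, list[int]] = {}
        for li, enc in enumerate(self.encoded):
            for pos, code in enumerate(_kmer_codes(enc, seed_length)):
                if code >= 0:
                    index.setdefault(int(code), []).append((li << 32) | pos)
        self.index = {c: np.asarray(v, dtype=np.int64) for c, v in index.items()}


def _candidate_windows(
    codes: np.ndarray, index: GenomeIndex, read_len: int, band: int,
    max_clusters: int = 64,
) -> list[tuple[int, int, int]]:
    """Cluster seed hits into (locus, window_start, window_end) candidates."""
    by_locus: dict[int, list[int]] = {}
    get = index.index.get
    for i in range(codes.shape[0]):
        arr = get(int(codes[i]))
        if arr is None:
            continue
        for packed in arr:
            li = int(packed) >> 32
            pos = int(packed) & 0xFFFFFFFF
            by_locus.setdefault(li, []).append(pos - i)
    windows: list[tuple[int, int, int]] = []
    for li, diags in by_locus.items():
        diags.sort()
        ref_len = index.encoded[li].shape[0]
        lo = diags[0]
        hi = diags[0]
        for d in diags[1:]:
            if d - hi > band:
                windows.append((li, max(lo - band, 0),
                                min(hi + read_len + band, ref_len)))
                lo = d
            hi = d
        windows.append((li, max(lo - band, 0),
                        min(hi + read_len + band, ref_len)))
        if len(windows) > max_clusters:
            break
    return windows


def align_read(
    mate: str, index: GenomeIndex, params: AlignParams | None = None
) -> AlignmentHit | None:
    """Best-scoring hit of one mate on one genome, or None below theta.

    Both orientations are tried.  Ties between loci are broken toward the
    lowest locus index then the lowest start; forward strand wins an exact
    orientation tie.
    """
    p = params or AlignParams()
    if len(mate) < p.seed_length:
        warnings.warn(f"read shorter than seed_length={p.seed_length}; skipped")
        return None
    best: tuple[int, int, int, int, str] | None = None  # (-raw, li, start, end, strand)
    for strand, seq in (("+", mate), ("-", revcomp(mate))):
        enc = encode(seq)
        codes = _kmer_codes(enc, p.seed_length)
        for li, ws, we in _candidate_windows(codes, index, len(seq), p.band_width):
            raw, rs, re_ = _sw_window(
                enc, index.encoded[li][ws:we],
                p.match_score, p.mismatch_penalty, p.gap_open, p.gap_extend,
            )
            cand = (-raw, li, ws + rs, ws + re_, strand)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    raw = -best[0]
    norm = raw / (len(mate) * p.match_score)
    if norm < p.theta:
        return None
    return AlignmentHit(
        genome=index.genome.name,
        locus_id=index.genome.loci[best[1]].gene_id,
        start=best[2],
        end=best[3],
        raw_score=raw,
        normalized_score=norm,
        strand=best[4],
    )


class DualAligner:
    """Scores fragments against both genomes of a pair, with a result cache.

    The per-fragment result depends only on the fragment's sequences, so
    calibration sweeps that remix the same pools reuse cached calls.
    """

    def __init__(self, pair: GenomePair, params: AlignParams | None = None):
        self.pair = pair
        self.params = params or AlignParams()
        self.graft_index = GenomeIndex(pair.graft, self.params.seed_length)
        self.host_index = GenomeIndex(pair.host, self.params.seed_length)
        self._cache: dict[str, dict[str, FragmentHit | None]] = {}

    def _fragment_on(self, read: ReadRecord, index: GenomeIndex) -> FragmentHit | None:
        h1 = align_read(read.seq1, index, self.params)
        if h1 is None:
            return None
        h2 = align_read(read.seq2, index, self.params)
        if h2 is None:
            return None
        if h1.locus_id != h2.locus_id:
            return None  # discordant loci
        if h1.strand == h2.strand:
            return None  # mates must be head-to-head
        if abs(h1.start - h2.start) > self.params.max_insert:
            return None
        return FragmentHit(
            genome=index.genome.name,
            locus_id=h1.locus_id,
            start=min(h1.start, h2.start),
            end=max(h1.end, h2.end),
            score=(h1.normalized_score + h2.normalized_score) / 2.0,
            hits=(h1, h2),
        )

    def align_fragment(self, read: ReadRecord) -> dict[str, FragmentHit | None]:
        """Per-genome concordant fragment scores: {'graft': ..., 'host': ...}."""
        cached = self._cache.get(read.fid)
        if cached is not None:
            return cached
        result = {
            "graft": self._fragment_on(read, self.graft_index),
            "host": self._fragment_on(read, self.host_index),
        }
        self._cache[read.fid] = result
        return result
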