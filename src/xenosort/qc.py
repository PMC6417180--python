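"""Adapter trimming and read-retention filters.

The retention rules are strict inequalities: a fragment survives only if
every mate is longer than ``min_retained_length`` bases after trimming and
has a mean Phred quality strictly above ``min_mean_quality``.  Filtering is
fragment-level (both mates must pass) because downstream species assignment
operates on whole fragments; a mate-level mode is available via
``fragment_level=False``.

Adapter trimming removes the longest read suffix that matches a prefix of
any configured adapter, allowing a small mismatch fraction, mirroring the
behaviour of common 3'-adapter trimmers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ReadRecord

# Illumina TruSeq single-index adapters (read1 / read2).
TRUSEQ_ADAPTERS = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA",
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT",
)


@dataclass(frozen=True)
class QCParams:
    adapter_sequences: tuple[str, ...] = TRUSEQ_ADAPTERS
    min_retained_length: int = 50  # strict >
    min_mean_quality: float = 15.0  # strict >
    min_adapter_overlap: int = 3
    adapter_mismatch_fraction: float = 0.1
    fragment_level: bool = True

    def __post_init__(self) -> None:
        if self.min_retained_length < 0 or self.min_mean_quality < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QCReport:
    """Bookkeeping for one QC pass; categories partition the input."""

    input: int = 0
    trimmed: int = 0  # fragments with at least one trimmed base
    discarded_by_length: int = 0
    discarded_by_quality: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "trimmed": self.trimmed,
            "discarded_by_length": self.discarded_by_length,
            "discarded_by_quality": self.discarded_by_quality,
            "retained": self.retained,
        }


def _trim_point(seq: str, params: QCParams) -> int:
    """Length to keep after removing the longest adapter-matching suffix."""
    best = len(seq)
    for adapter in params.adapter_sequences:
        # i = candidate adapter start within the read; scan longest first
        lo = max(0, len(seq) - len(adapter))
        for i in range(lo, len(seq) - params.min_adapter_overlap + 1):
            overlap = len(seq) - i
            allowed = int(params.adapter_mismatch_fraction * overlap)
            mism = 0
            for a, b in zip(seq[i:], adapter):
                if a != b:
                    mism += 1
                    if mism > allowed:
                        break
            else:
                if i < best:
                    best = i
                break  # longest match for this adapter found
    return best


def trim_adapters(
    reads: list[ReadRecord], params: QCParams | None = None
) -> tuple[list[ReadRecord], int]:
    """Trim 3' adapter contamination from both mates of each fragment.

    Returns the trimmed reads and the number of fragments touched.
    Sequence and quality strings are cut together.
    """
    params = params or QCParams()
    out: list[ReadRecord] = []
    n_trimmed = 0
    for r in reads:
        k1 = _trim_point(r.seq1, params)
        k2 = _trim_point(r.seq2, params)
        if k1 < len(r.seq1) or k2 < len(r.seq2):
            n_trimmed += 1
            out.append(
                ReadRecord(r.fid, r.seq1[:k1], r.qual1[:k1], r.seq2[:k2], r.qual2[:k2], r.truth)
            )
        else:
            out.append(r)
    return out, n_trimmed


def mean_quality(qual: str) -> float:
    """Arithmetic mean Phred score of a Phred+33 quality string."""
    if not qual:
        return 0.0
    return float(np.mean(np.frombuffer(qual.encode(), dtype=np.uint8))) - 33.0


def filter_reads(
    reads: list[ReadRecord], params: QCParams | None = None
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the length and mean-quality retention filters.

    A mate passes iff ``len > min_retained_length`` and
    ``mean Phred > min_mean_quality`` (both strict).  With
    ``fragment_level=True`` (default) the fragment is retained iff both
    mates pass; length failures are counted before quality failures.
    """
    params = params or QCParams()
    report = QCReport(input=len(reads))
    kept: list[ReadRecord] = []
    for r in reads:
        lens_ok = [
            len(r.seq1) > params.min_retained_length,
            len(r.seq2) > params.min_retained_length,
        ]
        qual_ok = [
            mean_quality(r.qual1) > params.min_mean_quality,
            mean_quality(r.qual2) > params.min_mean_quality,
        ]
        if params.fragment_level:
            if not all(lens_ok):
                report.discarded_by_length += 1
                continue
            if not all(qual_ok):
                report.discarded_by_quality += 1
                continue
        else:
            if not any(lens_ok):
                report.discarded_by_length += 1
                continue
            if not any(l and q for l, q in zip(lens_ok, qual_ok)):
                report.discarded_by_quality += 1
                continue
        kept.append(r)
        report.retained += 1
    return kept, report


def run_qc(
    reads: list[ReadRecord], params: QCParams | None = None
) -> tuple[list[ReadRecord], QCReport]:
    """Trim adapters then filter; the composed per-sample QC step."""
    params = params or QCParams()
    trimmed, n_trimmed = trim_adapters(reads, params)
    kept, report = filter_reads(trimmed, params)
    report.trimmed = n_trimmed
    return kept, report
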