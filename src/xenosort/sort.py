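"""Species assignment from dual-genome fragment scores, and its evaluation.

A fragment with a concordant above-threshold alignment on exactly one
genome is assigned to that species; with hits on both genomes the higher
normalized score wins, and an exact tie (within ``tie_tolerance``, default
0) is called ambiguous; with no hit on either genome it is unaligned.

Evaluation against truth labels produces a confusion report with the false
sorting rates (host-truth fragments labeled graft and vice versa) and an
anatomy of the false positives: the fraction whose graft-side alignment
overlaps an annotated exon versus landing in non-exon sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignParams, DualAligner, FragmentHit
from .synthetic import Genome, GenomePair, ReadRecord

LABELS = ("graft", "host", "ambiguous", "unaligned")


@dataclass(frozen=True)
class SpeciesCall:
    fid: str
    label: str  # graft | host | ambiguous | unaligned
    graft_score: float | None
    host_score: float | None
    graft_hit: FragmentHit | None = None
    host_hit: FragmentHit | None = None

    @property
    def margin(self) -> float | None:
        if self.graft_score is None or self.host_score is None:
            return None
        return self.graft_score - self.host_score


def assign_species(
    fid: str,
    scores: dict[str, FragmentHit | None],
    tie_tolerance: float = 0.0,
) -> SpeciesCall:
    """Label one fragment from its per-genome scores."""
    g, h = scores.get("graft"), scores.get("host")
    gs = g.score if g is not None else None
    hs = h.score if h is not None else None
    if gs is None and hs is None:
        label = "unaligned"
    elif hs is None:
        label = "graft"
    elif gs is None:
        label = "host"
    elif abs(gs - hs) <= tie_tolerance:
        label = "ambiguous"
    else:
        label = "graft" if gs > hs else "host"
    return SpeciesCall(fid, label, gs, hs, g, h)


def sort_readset(
    fragments: list[ReadRecord],
    pair_or_aligner: GenomePair | DualAligner,
    params: AlignParams | None = None,
    tie_tolerance: float = 0.0,
) -> list[SpeciesCall]:
    """Assign every fragment to graft / host / ambiguous / unaligned.

    Accepts a prebuilt :class:`DualAligner` so repeated sorts of
    overlapping read sets (mixing sweeps, compensation) reuse the
    per-fragment cache.
    """
    aligner = (
        pair_or_aligner
        if isinstance(pair_or_aligner, DualAligner)
        else DualAligner(pair_or_aligner, params)
    )
    return [
        assign_species(r.fid, aligner.align_fragment(r), tie_tolerance)
        for r in fragments
    ]


def calls_table(calls: list[SpeciesCall]) -> pd.DataFrame:
    """Long-format call table (one row per fragment)."""
    rows = []
    for c in calls:
        g = c.graft_hit
        rows.append(
            {
                "fragment_id": c.fid,
                "label": c.label,
                "graft_score": c.graft_score,
                "host_score": c.host_score,
                "margin": c.margin,
                "graft_locus": g.locus_id if g else None,
                "graft_start": g.start if g else None,
                "graft_end": g.end if g else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fragment_id", "label", "graft_score", "host_score",
            "margin", "graft_locus", "graft_start", "graft_end",
        ],
    )


def partition_reads(
    fragments: list[ReadRecord], calls: list[SpeciesCall]
) -> dict[str, list[ReadRecord]]:
    """Split fragments by call label; the four lists partition the input."""
    by_fid = {c.fid: c.label for c in calls}
    out: dict[str, list[ReadRecord]] = {lab: [] for lab in LABELS}
    for r in fragments:
        out[by_fid[r.fid]].append(r)
    return out


@dataclass
class ConfusionReport:
    """Counts of calls per truth species, plus the derived rates.

    ``counts`` is indexed by truth species with one column per label.
    Rates with a zero denominator are NaN, never an error.
    """

    counts: pd.DataFrame

    @property
    def false_to_graft(self) -> float:
        return self._rate("host", "graft")

    @property
    def false_to_host(self) -> float:
        return self._rate("graft", "host")

    def ambiguous_rate(self, truth_species: str) -> float:
        return self._rate(truth_species, "ambiguous")

    def unaligned_rate(self, truth_species: str) -> float:
        return self._rate(truth_species, "unaligned")

    def _rate(self, truth_species: str, label: str) -> float:
        if truth_species not in self.counts.index:
            return float("nan")
        total = self.counts.loc[truth_species].sum()
        if total == 0:
            return float("nan")
        return float(self.counts.loc[truth_species, label] / total)

    def as_dict(self) -> dict[str, float]:
        return {
            "false_to_graft": self.false_to_graft,
            "false_to_host": self.false_to_host,
            "ambiguous_host": self.ambiguous_rate("host"),
            "ambiguous_graft": self.ambiguous_rate("graft"),
            "unaligned_host": self.unaligned_rate("host"),
            "unaligned_graft": self.unaligned_rate("graft"),
        }


def confusion(
    calls: list[SpeciesCall], fragments: list[ReadRecord]
) -> ConfusionReport:
    """Tabulate calls against truth labels (all fragments must carry truth)."""
    truth_by_fid = {}
    for r in fragments:
        if r.truth is None:
            raise ValueError(f"fragment {r.fid!r} has no truth label")
        truth_by_fid[r.fid] = r.truth.species
    counts = pd.DataFrame(
        0, index=pd.Index(["graft", "host"], name="truth"), columns=list(LABELS)
    )
    for c in calls:
        t = truth_by_fid[c.fid]
        counts.loc[t, c.label] += 1
    return ConfusionReport(counts)


@dataclass(frozen=True)
class FalsePositiveAnatomy:
    """Genic vs non-exon split of host-truth fragments falsely called graft."""

    n_false: int
    n_genic: int

    @property
    def genic_fraction(self) -> float:
        return self.n_genic / self.n_false if self.n_false else float("nan")

    @property
    def non_exon_fraction(self) -> float:
        return 1.0 - self.genic_fraction if self.n_false else float("nan")


def false_positive_anatomy(
    calls: list[SpeciesCall],
    fragments: list[ReadRecord],
    graft_genome: Genome,
) -> FalsePositiveAnatomy:
    """Classify false-positive graft calls by exon overlap of their hit.

    A false positive is genic when its graft-side alignment interval
    overlaps any annotated exon by at least one base (half-open intervals).
    """
    truth_by_fid = {r.fid: r.truth for r in fragments}
    n_false = 0
    n_genic = 0
    for c in calls:
        t = truth_by_fid.get(c.fid)
        if t is None or t.species != "host" or c.label != "graft":
            continue
        n_false += 1
        hit = c.graft_hit
        if hit is None:
            continue
        exons = graft_genome[hit.locus_id].exons
        if any(hit.start < e and s < hit.end for s, e in exons):
            n_genic += 1
    return FalsePositiveAnatomy(n_false=n_false, n_genic=n_genic)
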