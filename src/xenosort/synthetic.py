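"""Truth-labeled two-species transcriptome and read simulation.

Real xenograft sequencing mixes fragments from a human graft and a rat host
in one library.  This module builds a miniature stand-in for that situation:
a pair of orthologous "genomes" (one sequence record per gene locus) related
by a configurable substitution/indel divergence model, per-gene expression
profiles, and a paired-end short-read simulator with a base-error and
Phred-quality model.  Every simulated fragment carries a truth label
(species, gene, position) so that downstream sorting accuracy can be
measured exactly.

Two deliberate asymmetries between the genomes emulate annotation
divergence between species and make the genic/non-exon anatomy of false
positives observable:

* host exons extend into the flanking sequence beyond the graft exon
  (transcript-boundary differences, e.g. UTR length), and
* a fraction of loci are expressed and annotated only on the host side
  (genes with no annotated ortholog in the graft genome).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds reproduce
identical reads byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DivergenceSpec:
    """Substitution/indel divergence between the two genomes.

    snv_rate
        Per-site substitution probability in [0, 1].
    indel_rate
        Per-site indel event probability in [0, 1].
    mean_indel_len
        Mean indel length in bases (geometric distribution, >= 1).
    """

    snv_rate: float = 0.08
    indel_rate: float = 0.002
    mean_indel_len: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.snv_rate <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise ValueError("snv_rate and indel_rate must lie in [0, 1]")
        if self.mean_indel_len < 1.0:
            raise ValueError("mean_indel_len must be >= 1 base")


@dataclass
class Locus:
    """One gene locus: flanking sequence around a (possibly absent) exon.

    ``exons`` is a list of 0-based half-open intervals into ``seq``.  An
    empty list means the locus carries no annotated gene on this genome
    (the sequence still exists and reads can align to it).
    """

    gene_id: str
    seq: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.seq)):
                raise ValueError(
                    f"exon ({s}, {e}) outside locus {self.gene_id!r} "
                    f"of length {len(self.seq)}"
                )

    @property
    def transcript(self) -> str:
        return "".join(self.seq[s:e] for s, e in self.exons)

    def transcript_to_locus(self, tpos: int) -> int:
        """Map a transcript coordinate to a locus coordinate."""
        off = 0
        for s, e in self.exons:
            if tpos < off + (e - s):
                return s + (tpos - off)
            off += e - s
        raise IndexError(tpos)


@dataclass
class Genome:
    """A collection of gene loci for one species side."""

    name: str
    loci: list[Locus]

    def __post_init__(self) -> None:
        self._index = {loc.gene_id: loc for loc in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, gene_id: str) -> Locus:
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    @property
    def annotated_gene_ids(self) -> list[str]:
        return [loc.gene_id for loc in self.loci if loc.exons]


@dataclass
class GenomePair:
    """Two orthologous genomes (graft and host) plus their divergence model.

    ``graft`` and ``host`` are the *reference* genomes the aligner sees.
    ``graft_all`` and ``host_all`` hold every orthologous locus on each side
    (equal counts) with that side's expression annotation: loci listed in
    ``graft_transcribed`` / ``host_transcribed`` produce reads, whether or
    not the corresponding reference contains them.  The gap between the
    transcribed set and the reference models assembly/annotation
    incompleteness — the physical source of cross-species false sorting.
    """

    graft: Genome
    host: Genome
    graft_all: Genome
    host_all: Genome
    graft_transcribed: list[str]
    host_transcribed: list[str]
    divergence: DivergenceSpec
    seed: int


@dataclass(frozen=True)
class SimParams:
    """Read-simulation parameters.

    Defaults follow a standard paired-end 100 bp Illumina-style library:
    100 base mates from ~300 bp fragments, a small uniform substitution
    error rate, and per-base Phred qualities drawn from a truncated normal.
    """

    read_length: int = 100
    paired: bool = True
    base_error_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 5.0
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 30.0
    n_fragments: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must lie in [0, 1]")


@dataclass(frozen=True)
class Truth:
    """Ground-truth provenance of one simulated fragment."""

    species: str  # "graft" | "host"
    gene_id: str
    start: int  # 0-based fragment start on the source locus
    end: int  # locus coordinate one past the fragment end


@dataclass
class ReadRecord:
    """One sequenced fragment: two mates with qualities, optional truth."""

    fid: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    truth: Truth | None = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.fid!r}")


# ---------------------------------------------------------------------------
# genome pair generation


def _mutate(seq: np.ndarray, div: DivergenceSpec, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply SNVs then indels to an encoded sequence.

    Returns the derived sequence and a per-site coordinate map ``lift`` such
    that ``lift[i]`` is the derived-coordinate of source site ``i`` (sites
    deleted in the derived sequence map to the next surviving position, so
    interval liftover stays valid).
    """
    n = len(seq)
    out = seq.copy()
    # substitutions: add 1..3 mod 4 to guarantee a different base
    snv_mask = rng.random(n) < div.snv_rate
    shifts = rng.integers(1, 4, size=int(snv_mask.sum()))
    idx = np.flatnonzero(snv_mask)
    out[idx] = BASES[(np.searchsorted(BASES, out[idx]) + shifts) % 4]
    # decode to python list for indel editing
    if div.indel_rate > 0:
        pieces: list[np.ndarray] = []
        lift = np.empty(n + 1, dtype=np.int64)
        events = rng.random(n) < div.indel_rate
        is_ins = rng.random(n) < 0.5
        lengths = rng.geometric(1.0 / div.mean_indel_len, size=n)
        pos = 0  # derived coordinate
        i = 0
        while i < n:
            if events[i]:
                length = int(lengths[i])
                if is_ins[i]:
                    ins = BASES[rng.integers(0, 4, size=length)]
                    pieces.append(ins)
                    pieces.append(out[i : i + 1])
                    lift[i] = pos + length
                    pos += length + 1
                    i += 1
                else:
                    for j in range(i, min(i + length, n)):
                        lift[j] = pos
                    i = min(i + length, n)
                    continue
            else:
                pieces.append(out[i : i + 1])
                lift[i] = pos
                pos += 1
                i += 1
        lift[n] = pos
        derived = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
        return derived, lift
    lift = np.arange(n + 1, dtype=np.int64)
    return out, lift


def generate_genome_pair(
    n_genes: int,
    gene_length: int,
    divergence: DivergenceSpec | None = None,
    seed: int = 0,
    *,
    flank_length: int = 300,
    host_exon_extension: int = 150,
    rate_heterogeneity_sd: float = 1.0,
    host_missing_fraction: float = 0.02,
    missing_unannotated_fraction: float = 0.25,
    graft_missing_fraction: float = 0.005,
) -> GenomePair:
    """Generate an orthologous graft/host genome pair.

    Each locus is ``flank + exon + flank`` on the graft side; the host copy
    is derived by the divergence model, its exon lifted over through the
    indel map and extended ``host_exon_extension`` bases into each flank
    (transcript-boundary divergence between the species' annotations).
    Per-locus divergence is the global rate times a log-normal multiplier
    with ``rate_heterogeneity_sd`` on the log scale, the usual picture of
    evolutionary rate variation across genes: conserved genes diverge far
    less than the genome-wide average.

    Reference incompleteness, the physical source of false sorting, is
    modeled by three disjoint locus classes drawn at random:

    * ``host_missing_fraction`` of loci are transcribed by the host but
      absent from the host reference; their reads can only align to the
      graft reference.  Of these, ``missing_unannotated_fraction`` have an
      *unannotated* graft ortholog (sequence present, no exon record), so
      their falsely sorted reads land in non-exon graft sequence.
    * ``graft_missing_fraction`` of loci are transcribed by the graft but
      absent from the graft reference (the converse, rarer because graft
      assemblies are typically more complete).

    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_length < 1:
        raise ValueError("gene_length must be >= 1")
    div = divergence if divergence is not None else DivergenceSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))

    # disjoint locus classes: 0 shared, 1 host-missing/genic,
    # 2 host-missing/unannotated-ortholog, 3 graft-missing.
    # Class sizes are deterministic (the fractions are design parameters);
    # only their placement among loci is randomized.
    n1 = int(round(n_genes * host_missing_fraction * (1.0 - missing_unannotated_fraction)))
    n2 = int(round(n_genes * host_missing_fraction * missing_unannotated_fraction))
    n3 = int(round(n_genes * graft_missing_fraction))
    if n1 + n2 + n3 > n_genes:
        raise ValueError("missing-locus fractions exceed the locus count")
    cls = np.zeros(n_genes, dtype=np.int64)
    order = rng.permutation(n_genes)
    cls[order[:n1]] = 1
    cls[order[n1 : n1 + n2]] = 2
    cls[order[n1 + n2 : n1 + n2 + n3]] = 3
    rate_mult = np.exp(rng.normal(0.0, rate_heterogeneity_sd, size=n_genes))

    graft_ref: list[Locus] = []
    host_ref: list[Locus] = []
    graft_all: list[Locus] = []
    host_all: list[Locus] = []
    graft_transcribed: list[str] = []
    host_transcribed: list[str] = []
    locus_len = flank_length + gene_length + flank_length
    for g in range(n_genes):
        gid = f"gene{g:04d}"
        seq = BASES[rng.integers(0, 4, size=locus_len)]
        exon = (flank_length, flank_length + gene_length)
        m = float(rate_mult[g])
        local = DivergenceSpec(
            snv_rate=min(div.snv_rate * m, 0.75),
            indel_rate=min(div.indel_rate * m, 0.5),
            mean_indel_len=div.mean_indel_len,
        )
        hseq_arr, lift = _mutate(seq, local, rng)
        hs = int(lift[max(exon[0] - host_exon_extension, 0)])
        he = int(lift[min(exon[1] + host_exon_extension, locus_len)])
        he = max(he, hs + 1)
        gseq = seq.tobytes().decode()
        hseq = hseq_arr.tobytes().decode()

        c = int(cls[g])
        graft_annotated = c in (0, 1)  # class 2: unannotated ortholog
        graft_all.append(Locus(gid, gseq, [exon] if graft_annotated or c == 3 else []))
        host_all.append(Locus(gid, hseq, [(hs, he)]))
        if c != 3:
            graft_ref.append(Locus(gid, gseq, [exon] if graft_annotated else []))
        if c in (0, 3):
            host_ref.append(Locus(gid, hseq, [(hs, he)]))
        if c in (0, 1, 3):
            graft_transcribed.append(gid)
        host_transcribed.append(gid)
    return GenomePair(
        graft=Genome("graft", graft_ref),
        host=Genome("host", host_ref),
        graft_all=Genome("graft", graft_all),
        host_all=Genome("host", host_all),
        graft_transcribed=graft_transcribed,
        host_transcribed=host_transcribed,
        divergence=div,
        seed=seed,
    )


def simulate_sample(
    pair: GenomePair,
    side: str,
    n_fragments: int,
    seed: int,
    params: SimParams | None = None,
    *,
    profile: dict[str, float] | None = None,
    id_prefix: str | None = None,
) -> list[ReadRecord]:
    """Simulate one sample's reads from the transcribed loci of one side.

    Convenience wrapper: reads come from the side's *full* locus set
    (including loci missing from its alignment reference), with a
    log-normal expression profile drawn from ``seed`` unless supplied.
    """
    if side not in ("graft", "host"):
        raise ValueError("side must be 'graft' or 'host'")
    genome = pair.graft_all if side == "graft" else pair.host_all
    transcribed = pair.graft_transcribed if side == "graft" else pair.host_transcribed
    if profile is None:
        profile = random_expression_profile(transcribed, seed=seed)
    base = params or SimParams()
    sp = SimParams(
        read_length=base.read_length,
        paired=base.paired,
        base_error_rate=base.base_error_rate,
        quality_mean=base.quality_mean,
        quality_sd=base.quality_sd,
        fragment_length_mean=base.fragment_length_mean,
        fragment_length_sd=base.fragment_length_sd,
        n_fragments=n_fragments,
        seed=seed,
    )
    return simulate_reads(
        genome, profile, sp, species=side,
        id_prefix=id_prefix or f"{side}-s{seed}",
    )


# ---------------------------------------------------------------------------
# expression profiles and read simulation


def random_expression_profile(
    gene_ids: list[str], seed: int = 0, log_sd: float = 1.0
) -> dict[str, float]:
    """Log-normal relative abundances over ``gene_ids``, normalized to 1.

    A log-normal abundance distribution is the usual coarse description of
    bulk RNA-seq expression: a few dominant transcripts and a long tail.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,)))
    rho = np.exp(rng.normal(0.0, log_sd, size=len(gene_ids)))
    rho /= rho.sum()
    return dict(zip(gene_ids, rho.tolist()))


def _inject_errors(encoded: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return encoded
    mask = rng.random(encoded.shape) < rate
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out = encoded.copy()
    idx = np.flatnonzero(mask)
    out.flat[idx] = BASES[(np.searchsorted(BASES, out.flat[idx]) + shifts) % 4]
    return out


def _qualities(n: int, length: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(params.quality_mean, params.quality_sd, size=(n, length))
    return np.clip(np.rint(q), 2, 40).astype(np.uint8)


def simulate_reads(
    genome: Genome,
    profile: dict[str, float],
    params: SimParams,
    *,
    species: str | None = None,
    id_prefix: str | None = None,
) -> list[ReadRecord]:
    """Simulate truth-labeled paired-end reads from one genome side.

    Fragments pick their gene multinomially with probability proportional to
    abundance times effective transcript length, a fragment length from a
    truncated normal, a uniform start, then uniform substitution errors at
    ``base_error_rate`` per base.  Mate 1 reads the fragment 5' end forward;
    mate 2 reads the 3' end reverse-complemented.
    """
    species = species or genome.name
    id_prefix = id_prefix or species
    unknown = [g for g in profile if g not in genome or not genome[g].exons]
    if unknown:
        raise ValueError(f"profile references unannotated genes: {unknown[:5]}")
    genes = sorted(profile)
    tlens = np.array([len(genome[g].transcript) for g in genes])
    if np.any(tlens < params.read_length):
        short = [g for g, L in zip(genes, tlens) if L < params.read_length]
        raise ValueError(f"transcripts shorter than read_length: {short[:5]}")
    rho = np.array([profile[g] for g in genes], dtype=float)
    eff = np.maximum(tlens - params.fragment_length_mean + 1.0, 1.0)
    p = rho * eff
    p /= p.sum()

    ss = np.random.SeedSequence(params.seed, spawn_key=(31,))
    rng_gene, rng_frag, rng_err, rng_qual = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n = params.n_fragments
    gene_idx = rng_gene.choice(len(genes), size=n, p=p)
    flen = np.rint(
        rng_frag.normal(params.fragment_length_mean, params.fragment_length_sd, size=n)
    ).astype(np.int64)
    flen = np.clip(flen, params.read_length, tlens[gene_idx])
    starts = np.floor(rng_frag.random(n) * (tlens[gene_idx] - flen + 1)).astype(np.int64)

    L = params.read_length
    qual1 = _qualities(n, L, params, rng_qual)
    qual2 = _qualities(n, L, params, rng_qual)
    reads: list[ReadRecord] = []
    transcripts = {g: genome[g].transcript for g in genes}
    for i in range(n):
        g = genes[gene_idx[i]]
        t = transcripts[g]
        s, fl = int(starts[i]), int(flen[i])
        m1 = t[s : s + L]
        m2 = revcomp(t[s + fl - L : s + fl])
        enc1 = np.frombuffer(m1.encode(), dtype=np.uint8)
        enc2 = np.frombuffer(m2.encode(), dtype=np.uint8)
        enc1 = _inject_errors(enc1, params.base_error_rate, rng_err)
        enc2 = _inject_errors(enc2, params.base_error_rate, rng_err)
        locus = genome[g]
        lstart = locus.transcript_to_locus(s)
        lend = locus.transcript_to_locus(s + fl - 1) + 1
        reads.append(
            ReadRecord(
                fid=f"{id_prefix}:{i:07d}",
                seq1=enc1.tobytes().decode(),
                qual1=(qual1[i] + 33).tobytes().decode(),
                seq2=enc2.tobytes().decode(),
                qual2=(qual2[i] + 33).tobytes().decode(),
                truth=Truth(species=species, gene_id=g, start=lstart, end=lend),
            )
        )
    return reads


def mix_reads(
    graft_reads: list[ReadRecord],
    host_reads: list[ReadRecord],
    graft_fraction: float,
    total: int,
    seed: int = 0,
) -> list[ReadRecord]:
    """Mix graft and host read pools at a target graft fraction.

    Samples without replacement ``round(total * graft_fraction)`` graft
    fragments (round-half-even, numpy's default) and fills the remainder
    with host fragments; the output order is a deterministic shuffle.
    """
    if not 0.0 <= graft_fraction <= 1.0:
        raise ValueError("graft_fraction must lie in [0, 1]")
    n_graft = int(np.rint(total * graft_fraction))
    n_host = total - n_graft
    if n_graft > len(graft_reads):
        raise ValueError(f"need {n_graft} graft reads, have {len(graft_reads)}")
    if n_host > len(host_reads):
        raise ValueError(f"need {n_host} host reads, have {len(host_reads)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(41,)))
    gi = rng.choice(len(graft_reads), size=n_graft, replace=False)
    hi = rng.choice(len(host_reads), size=n_host, replace=False)
    mixture = [graft_reads[i] for i in gi] + [host_reads[i] for i in hi]
    order = rng.permutation(len(mixture))
    return [mixture[i] for i in order]
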