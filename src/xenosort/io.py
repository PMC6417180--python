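"""File formats: FASTA, paired FASTQ (Phred+33), GTF, truth-label TSV.

Coordinates are 0-based half-open in memory and 1-based inclusive in GTF,
the field's convention.  FASTQ parsing/writing goes through Biopython's
fast general iterator.
"""

from __future__ import annotations

import os
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthetic import Genome, Locus, ReadRecord, Truth


def write_fasta(genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for locus in genome.loci:
            fh.write(f">{locus.gene_id}\n")
            seq = locus.seq
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | os.PathLike, name: str = "genome") -> Genome:
    """Read a genome FASTA (one record per locus, no annotation)."""
    loci: list[Locus] = []
    gid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if gid is not None:
                    loci.append(Locus(gid, "".join(chunks)))
                gid, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if gid is not None:
        loci.append(Locus(gid, "".join(chunks)))
    return Genome(name, loci)


def write_gtf(genome: Genome, path: str | os.PathLike, source: str = "xenosort") -> None:
    """Write gene/exon features, 1-based inclusive ends."""
    with open(path, "w") as fh:
        for locus in genome.loci:
            if not locus.exons:
                continue
            gs = min(s for s, _ in locus.exons) + 1
            ge = max(e for _, e in locus.exons)
            attr = f'gene_id "{locus.gene_id}";'
            fh.write(
                f"{locus.gene_id}\t{source}\tgene\t{gs}\t{ge}\t.\t+\t.\t{attr}\n"
            )
            for s, e in locus.exons:
                fh.write(
                    f"{locus.gene_id}\t{source}\texon\t{s + 1}\t{e}\t.\t+\t.\t{attr}\n"
                )


def read_gtf_exons(path: str | os.PathLike) -> dict[str, list[tuple[str, int, int]]]:
    """Exon intervals per sequence, as (gene_id, start, end) 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    out: dict[str, list[tuple[str, int, int]]] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        out.setdefault(exon.seqid, []).append((gid, exon.start - 1, exon.end))
    return out


def apply_annotation(genome: Genome, exons: dict[str, list[tuple[str, int, int]]]) -> None:
    """Attach GTF exon intervals to the loci of a FASTA-loaded genome."""
    for locus in genome.loci:
        locus.exons = [(s, e) for _, s, e in exons.get(locus.gene_id, [])]


def write_fastq_pair(
    reads: list[ReadRecord], path1: str | os.PathLike, path2: str | os.PathLike
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.fid}/1\n{r.seq1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.fid}/2\n{r.seq2}\n+\n{r.qual2}\n")


def read_fastq_pair(
    path1: str | os.PathLike, path2: str | os.PathLike
) -> list[ReadRecord]:
    reads = []
    with open(path1) as f1, open(path2) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            fid = t1.split()[0].removesuffix("/1")
            reads.append(ReadRecord(fid, s1, q1, s2, q2))
    return reads


def write_sam(
    reads: list[ReadRecord],
    calls,
    genome: Genome,
    path: str | os.PathLike,
    species: str = "graft",
) -> None:
    """Minimal SAM for the fragments assigned to one species.

    One line per mate: QNAME FLAG RNAME POS MAPQ=255 CIGAR(full-length M)
    RNEXT=* PNEXT=0 TLEN=0 SEQ QUAL, plus ``AS:i`` (raw score), ``ZN:f``
    (normalized score) and ``ZS:A`` (species) tags.  Paired flags encode
    mate order and strand only.
    """
    by_fid = {c.fid: c for c in calls}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for locus in genome.loci:
            fh.write(f"@SQ\tSN:{locus.gene_id}\tLN:{len(locus.seq)}\n")
        for r in reads:
            c = by_fid.get(r.fid)
            if c is None or c.label != species:
                continue
            frag = c.graft_hit if species == "graft" else c.host_hit
            if frag is None:
                continue
            for mate_idx, (seq, qual, hit) in enumerate(
                ((r.seq1, r.qual1, frag.hits[0]), (r.seq2, r.qual2, frag.hits[1]))
            ):
                flag = 0x1 | 0x2 | (0x40 if mate_idx == 0 else 0x80)
                if hit.strand == "-":
                    flag |= 0x10
                fh.write(
                    f"{r.fid}\t{flag}\t{hit.locus_id}\t{hit.start + 1}\t255\t"
                    f"{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\t"
                    f"AS:i:{hit.raw_score}\tZN:f:{hit.normalized_score:.4f}\t"
                    f"ZS:A:{'g' if species == 'graft' else 'h'}\n"
                )


def write_truth(reads: list[ReadRecord], path: str | os.PathLike) -> None:
    """Truth-label sidecar TSV: fragment_id, species, gene_id, start (0-based)."""
    with open(path, "w") as fh:
        fh.write("fragment_id\tspecies\tgene_id\tstart\tend\n")
        for r in reads:
            if r.truth is None:
                continue
            t = r.truth
            fh.write(f"{r.fid}\t{t.species}\t{t.gene_id}\t{t.start}\t{t.end}\n")


def read_truth(path: str | os.PathLike) -> dict[str, Truth]:
    out: dict[str, Truth] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("fragment_id"):
            raise ValueError("truth TSV must start with a fragment_id header")
        for line in fh:
            fid, species, gene_id, start, end = line.rstrip("\n").split("\t")
            out[fid] = Truth(species, gene_id, int(start), int(end))
    return out


def attach_truth(reads: list[ReadRecord], truth: dict[str, Truth]) -> None:
    for r in reads:
        r.truth = truth.get(r.fid)


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
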