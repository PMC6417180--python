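"""End-to-end orchestration of the xenograft expression pipeline.

``run_all`` strings the stages together on synthetic data emulating the
study design: pre-transplant graft samples (pure), grafted-tissue samples
at two post-transplant timepoints (graft reads a small minority in host
background), species sorting, contamination compensation of the
pre-transplant samples, gene quantification of the graft-labeled reads,
two-way consensus differential expression, and PCA profiling.  Every stage
draws from one top-level seed, so a repeated run writes byte-identical
result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignParams, DualAligner
from .calibration import (
    CompensationParams,
    compensate_pre_transplant,
    estimate_graft_fraction,
)
from .de import DEParams, run_consensus_de
from .profiles import PCAGeneFilter, fit_vst, pca, select_genes_for_pca, vst
from .qc import QCParams, run_qc
from .quantify import build_count_matrix, count_genes, gene_lengths, tpm
from .sort import calls_table, confusion, sort_readset
from .synthetic import (
    DivergenceSpec,
    SimParams,
    generate_genome_pair,
    mix_reads,
    random_expression_profile,
    simulate_reads,
)


@dataclass(frozen=True)
class StudyDesign:
    """Synthetic study conditions mirroring the transplant experiment.

    Two pre-transplant samples and three samples at each post-transplant
    timepoint; graft reads make up about 5% of a grafted-tissue library.
    ``n_de_genes`` genes shift expression ``de_fold_change``-fold after
    transplantation (half up, half down).
    """

    n_genes: int = 200
    gene_length: int = 1500
    divergence: DivergenceSpec = field(default_factory=DivergenceSpec)
    n_pre: int = 2
    n_graft_2mo: int = 3
    n_graft_6mo: int = 3
    pre_fragments: int = 1500
    graft_fragments: int = 12000
    graft_fraction: float = 0.05
    background_fragments: int = 32000
    n_de_genes: int = 30
    de_fold_change: float = 4.0
    within_group_log_sd: float = 0.15


def group_profiles(
    gene_ids: list[str], design: StudyDesign, seed: int
) -> tuple[dict[str, dict[str, float]], list[str]]:
    """Per-group expression profiles with a known differential subset.

    Returns ({group: profile}, true_de_genes).  Post-transplant groups
    share the shifted profile; the 6-month group shifts a further (smaller)
    random subset to separate the timepoints.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(71,)))
    base = random_expression_profile(gene_ids, seed=seed)
    de_genes = sorted(
        rng.choice(gene_ids, size=min(design.n_de_genes, len(gene_ids)), replace=False)
    )
    shifted = dict(base)
    for i, g in enumerate(de_genes):
        fc = design.de_fold_change if i % 2 == 0 else 1.0 / design.de_fold_change
        shifted[g] = base[g] * fc
    total = sum(shifted.values())
    shifted = {g: v / total for g, v in shifted.items()}
    late = dict(shifted)
    late_genes = sorted(rng.choice(de_genes, size=max(len(de_genes) // 3, 1), replace=False))
    for g in late_genes:
        late[g] = shifted[g] * 2.0
    total = sum(late.values())
    late = {g: v / total for g, v in late.items()}
    return {"pre": base, "graft_2mo": shifted, "graft_6mo": late}, de_genes


def _sample_profile(
    profile: dict[str, float], log_sd: float, rng: np.random.Generator
) -> dict[str, float]:
    genes = sorted(profile)
    vals = np.array([profile[g] for g in genes])
    vals = vals * np.exp(rng.normal(0.0, log_sd, size=len(vals)))
    vals /= vals.sum()
    return dict(zip(genes, vals.tolist()))


def run_all(
    seed: int = 0,
    design: StudyDesign | None = None,
    align_params: AlignParams | None = None,
    de_params: DEParams | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, object]:
    """Run the full pipeline on synthetic data; optionally write TSVs.

    Returns a dict with the count matrix, expression matrices, species-
    sorting reports, DE tables, PCA coordinates and the truth inventory.
    """
    design = design or StudyDesign()
    ss = np.random.SeedSequence(seed, spawn_key=(101,))
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(64))

    pair = generate_genome_pair(
        design.n_genes, design.gene_length, design.divergence, seed=int(next(seeds))
    )
    aligner = DualAligner(pair, align_params)
    qc_params = QCParams()
    graft_genes = [g for g in pair.graft_transcribed if pair.graft_all[g].exons]
    profiles, true_de = group_profiles(graft_genes, design, seed=int(next(seeds)))
    prof_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(73,)))

    host_profile = random_expression_profile(pair.host_transcribed, seed=int(next(seeds)))

    def make_reads(genome, profile, n, sim_seed, species, prefix):
        params = SimParams(n_fragments=n, seed=int(sim_seed))
        return simulate_reads(genome, profile, params, species=species, id_prefix=prefix)

    # host background pool for compensation spiking (QC-passed)
    background = make_reads(
        pair.host_all, host_profile, design.background_fragments,
        next(seeds), "host", "bg",
    )
    background, _ = run_qc(background, qc_params)

    samples: dict[str, dict] = {}
    groups: dict[str, str] = {}
    layout = (
        [("pre", i, design.pre_fragments) for i in range(design.n_pre)]
        + [("graft_2mo", i, design.graft_fragments) for i in range(design.n_graft_2mo)]
        + [("graft_6mo", i, design.graft_fragments) for i in range(design.n_graft_6mo)]
    )
    for group, i, n_frag in layout:
        name = f"{group}_{i + 1}"
        groups[name] = group
        g_prof = _sample_profile(profiles[group], design.within_group_log_sd, prof_rng)
        if group == "pre":
            reads = make_reads(pair.graft_all, g_prof, n_frag, next(seeds), "graft", name)
        else:
            n_graft = int(np.rint(n_frag * design.graft_fraction))
            graft_reads = make_reads(
                pair.graft_all, g_prof, n_graft, next(seeds), "graft", f"{name}-g"
            )
            h_prof = _sample_profile(host_profile, design.within_group_log_sd, prof_rng)
            host_reads = make_reads(
                pair.host_all, h_prof, n_frag - n_graft, next(seeds), "host", f"{name}-h"
            )
            reads = mix_reads(
                graft_reads, host_reads, design.graft_fraction, n_frag,
                seed=int(next(seeds)),
            )
        reads, qc_report = run_qc(reads, qc_params)
        samples[name] = {"reads": reads, "qc": qc_report}

    # sort every sample; estimate the graft fraction from grafted tissue
    sort_reports = {}
    for name, d in samples.items():
        calls = sort_readset(d["reads"], aligner)
        d["calls"] = calls
        sort_reports[name] = confusion(calls, d["reads"]).as_dict()
    graft_samples = [n for n, g in groups.items() if g != "pre"]
    frac_estimates = {
        n: estimate_graft_fraction(samples[n]["calls"]) for n in graft_samples
    }
    measured_fraction = float(np.mean([frac_estimates[n] for n in graft_samples]))

    # contamination of the graft samples (truth-based, simulation only)
    def host_share(reads, calls):
        by_fid = {c.fid: c.label for c in calls}
        kept = [r for r in reads if by_fid[r.fid] == "graft"]
        if not kept:
            return float("nan")
        return sum(r.truth.species == "host" for r in kept) / len(kept)

    graft_contamination = float(
        np.mean([host_share(samples[n]["reads"], samples[n]["calls"]) for n in graft_samples])
    )

    # compensate pre-transplant samples at the measured graft fraction
    comp_results = {}
    for name, g in groups.items():
        if g != "pre":
            continue
        comp = compensate_pre_transplant(
            samples[name]["reads"],
            background,
            pair,
            CompensationParams(
                graft_fraction=measured_fraction,
                target_contamination=max(graft_contamination, 1e-6),
                seed=int(next(seeds)),
            ),
            aligner=aligner,
        )
        comp_results[name] = comp
        samples[name]["graft_calls"] = [c for c in comp.calls if c.label == "graft"]
    for name in graft_samples:
        samples[name]["graft_calls"] = [
            c for c in samples[name]["calls"] if c.label == "graft"
        ]

    # quantify graft-labeled reads on the graft annotation
    lengths = gene_lengths(pair.graft)
    per_sample_counts = {
        name: count_genes(d["graft_calls"], pair.graft, "graft")
        for name, d in samples.items()
    }
    matrix = build_count_matrix(
        per_sample_counts, lengths, groups, seed=int(next(seeds))
    )
    matrix.counts = matrix.counts.reindex(sorted(lengths.index)).fillna(0).astype(int)
    matrix.lengths = lengths.reindex(matrix.counts.index)

    # consensus DE for the two study contrasts
    de_params = de_params or DEParams()
    de_2mo = run_consensus_de(matrix, "pre", "graft_2mo", de_params)
    de_6mo = run_consensus_de(matrix, "graft_2mo", "graft_6mo", de_params)

    # profiling: TPM, gene subset, VST, PCA
    tpm_mat = tpm(matrix.counts, matrix.lengths)
    pca_genes = select_genes_for_pca(tpm_mat, PCAGeneFilter())
    vst_mat = vst(matrix.counts, fit_vst(matrix.counts))
    coords, var_explained = pca(vst_mat, pca_genes) if len(pca_genes) >= 2 else (
        pd.DataFrame(), np.array([]),
    )

    results: dict[str, object] = {
        "pair": pair,
        "aligner": aligner,
        "samples": samples,
        "groups": groups,
        "true_de_genes": true_de,
        "sort_reports": sort_reports,
        "graft_fraction_estimates": frac_estimates,
        "measured_graft_fraction": measured_fraction,
        "graft_contamination": graft_contamination,
        "compensation": comp_results,
        "count_matrix": matrix,
        "tpm": tpm_mat,
        "de_2mo_vs_pre": de_2mo,
        "de_6mo_vs_2mo": de_6mo,
        "pca_genes": pca_genes,
        "pca_coordinates": coords,
        "pca_variance_explained": var_explained,
    }
    if out_dir is not None:
        write_results(results, out_dir)
    return results


def write_results(results: dict[str, object], out_dir: str | Path) -> list[Path]:
    """Write the pipeline's result tables as deterministic TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.6g", **kw)
        written.append(path)

    matrix = results["count_matrix"]
    save(matrix.counts, "counts.tsv")
    save(results["tpm"], "tpm.tsv")
    save(results["de_2mo_vs_pre"], "de_2mo_vs_pre.tsv")
    save(results["de_6mo_vs_2mo"], "de_6mo_vs_2mo.tsv")
    save(pd.DataFrame(results["sort_reports"]).T, "sort_reports.tsv")
    coords = results["pca_coordinates"]
    if len(coords):
        save(coords, "pca_coordinates.tsv")
    calls_frames = []
    for name, d in results["samples"].items():
        t = calls_table(d["calls"])
        t.insert(0, "sample", name)
        calls_frames.append(t)
    save(pd.concat(calls_frames, ignore_index=True), "species_calls.tsv", index=False)
    return written
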