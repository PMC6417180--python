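# Methods

## Problem and overall design

Bulk RNA-seq of xenografted tissue (human neural stem cells grafted into a
rat host, in the motivating setting) yields one library containing
fragments from two species. Every analysis downstream — expression,
differential testing, cell-fate profiling — requires each fragment to be
attributed to its genome of origin first. `xenosort` implements that
attribution and everything that depends on it:

1. read QC (adapter trimming, length and quality retention),
2. dual-genome alignment scoring and species assignment,
3. simulation-driven calibration of the false-sorting rate,
4. compensation of pure pre-transplant samples so they carry the same
   sorting-error floor as grafted samples,
5. gene-level quantification (counts, CPM, TPM),
6. three-engine consensus differential expression,
7. variance-stabilized PCA and marker-panel matrices.

Because no suitable public raw dataset accompanies this design, the package
ships a first-class synthetic data module that generates truth-labeled
two-species reads with the statistical structure the analysis assumes. All
pipeline properties are validated against those truth labels.

## Species sorting

Each mate is scored against both genomes with a local alignment under
+1 match / −1 mismatch / affine gaps (−2 open, −1 per further base), and
the raw score is normalized by the maximum attainable score,
`read_length × match_score`. A fragment aligns to a genome when both mates
reach the threshold `theta = 0.90` (inclusive) on the same locus in
head-to-head orientation within `max_insert = 1000` bases; the fragment
score is the mean of the two mates' normalized scores. Assignment: one
qualifying genome → that species; two → the higher score, with an exact tie
(tolerance 0 by default) called *ambiguous*; none → *unaligned*. Ties are
deliberately left unassigned because a read that two genomes explain
equally well carries no species information.

The search is exact-seed anchoring (15-mer index) plus full
Smith–Waterman inside a window of `band_width = 16` bases around each
seeded diagonal, compiled with numba. This equals unbanded Smith–Waterman
over whole loci whenever at least one exact seed survives on the optimal
diagonal — essentially always at the divergences involved; a read with no
surviving seed is reported unaligned. The test suite keeps an independent
unbanded oracle (Biopython `PairwiseAligner` with verified identical gap
semantics) and checks ≥ 99% label agreement on 500 simulated fragments.

Alignment start positions are propagated through the dynamic program (no
traceback), giving the reference interval of every hit; that interval
drives both gene counting and the genic/non-exon anatomy of false
positives.

## Why false sorting happens in the model

If every read had a perfect home in its own reference, cross-species false
sorting would be structurally impossible at any divergence — the own-genome
score always wins. The generator therefore models the two real sources of
error:

* **Evolutionary rate variation.** Per-locus divergence is the global rate
  times a log-normal multiplier (sd = 1.0 on the log scale). Substitution
  rates genuinely vary by orders of magnitude across genes; conserved loci
  are the ones whose cross-species scores approach the threshold.
* **Reference incompleteness.** A fraction of transcribed loci are absent
  from their own side's reference: 2% of host loci (host assemblies and
  annotations are less complete), 0.5% of graft loci. Reads from these loci
  can only align cross-species; conserved ones clear `theta` and become
  false positives, the rest become unaligned. Of the host-missing loci, 25%
  have an *unannotated* graft ortholog (sequence present, no exon record),
  so their false positives land in non-exon graft sequence; host exons also
  extend 150 bases into the flanks beyond the graft exon (transcript-
  boundary divergence), so edge reads can land partly outside annotation.
  Together these produce the observed split of false positives between
  genic and non-exon regions.

Class sizes are deterministic (`round(n_genes × fraction)`); only the
placement of classes among loci and the rate multipliers are random. The
defaults (8% substitutions/site, 0.2% indel events/site of mean length 3)
describe a primate–rodent-like transcribed-sequence divergence; all are
arguments.

At these defaults the pipeline measures (seed 1, pooled over the
calibration sweep): ≈ 0.2% of host reads falsely sorted to graft with
≈ 0.8% ambiguous, ≈ 0.0–0.03% of graft reads falsely sorted to host with
≈ 1.2% ambiguous — the same regime as real human/rat sorting. Because only
a handful of loci are missing at desk scale, the realized false rate varies
substantially between genome-pair seeds; it is a property of the pair, as
it is of a real genome pair.

## What the generator does not model

Splicing isoforms, strand-specific protocols, GC and position bias,
duplicates, quality-correlated errors (base errors are uniform at 0.5% and
independent of the simulated Phred values, drawn from a truncated normal,
mean 35, sd 5), paralogy within a genome, and repetitive sequence. Passing
tests show the *sorting logic and its calibration machinery* behave as
designed under the stated error model; they do not certify performance on
real genomes, where paralogs and repeats add failure modes this model does
not contain.

## Calibration and compensation

The mixing sweep re-sorts pools mixed at graft fractions
{1, 5, 10, 25, 50}% (20 000 fragments per mixture at acceptance scale) and
tests flatness of the false-sorting rate against the fraction with a
binomial logistic trend test plus a two-proportion z-score for the extreme
pair. Species calls depend only on the fragment, not on the mixture it sits
in, so the implementation caches per-fragment calls and re-tallies per
mixture — exactly equivalent to sorting each mixture from scratch.

Compensation follows the spike-and-resort logic: the pure pre-transplant
reads are mixed into host background at the grafted sample's *measured*
graft fraction (default 5%), sorted, and the graft-labeled output replaces
the raw pre-transplant set. Both conditions then share the same
contamination floor rather than one being artificially clean; nothing is
subtracted and no graft read is fabricated. With
`target_contamination = 0`, spiking is skipped and only sorting losses
apply.

## Quantification

Fragments are counted to the gene whose exons their alignment interval
overlaps by ≥ 1 base (half-open coordinates); a fragment overlapping k
genes contributes 1/k to each; non-exon fragments go to `__no_feature`.
Fractional counts are resolved by stochastic rounding under a fixed seed
when the matrix is assembled, preserving expectations while keeping integer
counts. Gene effective length is the exon-union length with no
fragment-length correction. This transparent overlap counter stands in for
k-mer/EM quantifiers; with the single-isoform genes used throughout, the
two coincide conceptually, and no numerical agreement with any EM
quantifier is claimed. CPM = count × 1e6 / library size;
TPM = length-normalized rate × 1e6 / Σrates (columns sum to 1e6).

## Consensus differential expression

Genes below 1 CPM in all groups (group-mean reading; a per-sample variant
is a flag) are discarded. Three engines then test each gene, two-group
designs only, each refusing groups of fewer than two samples and returning
p = 1 for all-zero genes:

* **nb_wald** — NB GLM (log link, `Var = μ + αμ²`) with median-of-ratios
  size factors. Gene dispersions maximize the Cox–Reid adjusted profile
  likelihood on a 45-point log grid with parabolic refinement; a parametric
  trend `α(μ) = a0 + a1/μ` is fit by iterated gamma regression; gene
  dispersions are shrunk to the trend by a log-normal prior whose variance
  is the MAD² of log residuals minus the sampling variance
  `ψ₁((n−2)/2)`, floored at 0.25; the Wald statistic uses the information
  matrix at the MAP dispersion.
* **nb_lrt** — NB GLM with TMM effective library sizes (30%/5% trimmed
  mean of M-values). Tagwise dispersions maximize the gene's Cox–Reid
  likelihood plus `prior_df/(n−2)` times the genes' average likelihood
  (empirical-Bayes shrinkage toward the common value, prior_df = 10);
  the likelihood-ratio statistic against the intercept-only fit is referred
  to χ²(1).
* **weighted_lm** — log2-CPM (0.5 pseudocount) linear models. An unweighted
  pass learns the mean–variance trend (lowess of √sd on average
  log-count); observation weights are the predicted sd to the −4th power; a
  weighted pass plus empirical-Bayes variance moderation (scaled inverse
  χ² prior fit by moment matching on log variances, trigamma inversion)
  yields moderated t statistics on `d0 + n − 2` degrees of freedom.

These are reimplementations of the standard statistics at the level of
their published descriptions, not bindings to the reference packages, and
numerical agreement with those packages is not claimed. All three are
deterministic and calibrated: on null NB data (2 000 genes, 6+6) each
engine's raw p-values pass a Kolmogorov–Smirnov uniformity test at
α = 0.01, and label swaps leave p-values unchanged.

Per engine, raw p → Sidak `1−(1−p)^m` for the m comparisons within the
model (m = 1, the identity, for the single-contrast designs here; exposed
because the original correction's m is not recoverable) → BH across genes.
The consensus p is the median of the three corrected values — below α
exactly when at least two engines are — and significance is `consensus
p < 0.05`. This ordering (Sidak within engine, BH within engine, median
across engines) is the only one consistent with a per-engine
"Sidak/Benjamini–Hochberg corrected p".

## Profiling

PCA uses genes with ≥ 5 TPM in ≥ ⌈half the samples⌉ (both inclusive), on
counts normalized by size factors and transformed with the closed-form NB
variance-stabilizing transform under the fitted trend `α(μ) = a0 + a1/μ`:

    f(x) = log2( (1 + a1 + 2·a0·x + 2·√(a0·x·(1 + a1 + a0·x))) / (4·a0) )

strictly increasing, finite at 0, asymptotically log2. The trend is fit by
gamma regression of moment dispersions on 1/mean; a degenerate fit falls
back to a shifted log with a warning. Samples are observations; components
come from the SVD; variance-explained fractions are reported. Marker
panels (NSC, neuronal, astrocyte, oligodendrocyte, pluripotency, safety)
ship as an editable YAML and are rendered as log2(TPM+1) matrices.

## Numerical and degenerate-input choices

Linear predictors are clamped at e^−30 so all-zero groups stay finite;
2×2 weighted normal equations are solved in closed form per gene; grid
argmaxima are refined by a parabola in log-dispersion space and pinned at
grid boundaries; alignment tie-breaks are (lowest locus index, lowest
start, forward strand); mixture counts round half-even; empty call tables
yield NaN rates with zero denominators rather than errors.

## Problem sizes and determinism

Default study design: 200 genes × 1.5 kb (300-base flanks), 2
pre-transplant samples (1 500 fragments), 3+3 grafted samples (12 000
fragments at 5% graft), 32 000-fragment host background, 30 true DE genes
at 4-fold. A full `run-all` takes ~2.5 minutes on one core; the acceptance
script ~5 minutes; the test suite ~5 minutes. Every random draw descends
from one `numpy.random.SeedSequence` per entry point, and repeated runs
with one seed write byte-identical tables.

## Known limitations

Two-group DE designs only; no isoforms or EM multi-mapping resolution; no
probabilistic rescue of ambiguous reads; the aligner indexes gene-locus
references, not chromosome-scale genomes; false-sorting rates at desk
scale have high pair-to-pair variance because few loci drive them; the
weighted-lm engine's lowess trend can be unstable below ~100 genes.
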