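# Methods

`lncfruit` re-creates, as a tested library, the comparative-transcriptomics
workflow used to study lncRNAs in developing strawberry fruit: two genotypes
(FPR, red-fruited; FPW, white-fruited) sampled at three developmental stages
(green, turning, ripe) with three biological replicates each — 18 libraries.
This note records the models, the numerical choices, and what the synthetic
study does and does not emulate.

## lncRNA identification cascade

Assembled transcripts pass through six rules, in order:

1. **Redundancy removal.** Greedy longest-first clustering; a transcript
   joins the first representative sharing ≥ 95% of the shorter sequence's
   canonical 11-mers. This replaces CD-HIT's banded alignment identity with
   k-mer containment: the 95% threshold is preserved, the similarity measure
   differs (documented divergence; k-mers containing N never match).
2. **Expression.** Keep features with mean FPKM > 1 across all 18 samples
   and FPKM ≥ 1 in at least two samples. "Detected" is read as FPKM ≥ 1
   (ambiguous in the source protocol; recorded in the report header).
   FPKM_gs = counts_gs × 10⁹ / (length_g × total_s), total_s being the
   column sum of counts.
3. **Length / ORF.** Keep transcripts ≥ 200 bp whose longest complete ORF
   is ≤ 100 aa. ORFs are ATG→stop in the three forward frames only
   (strand-specific libraries; `both_strands=True` for unstranded data);
   length counts codons excluding the stop; 5′/3′-partial ORFs are ignored
   for determinism. Codons containing N are never a start or stop.
4. **Protein homology.** Remove any transcript with an NR or SwissProt hit
   (hit tables are inputs; BLAST itself is out of scope).
5. **Coding potential.** Remove transcripts any CPC/PLEK row flags as
   coding; transcripts those tools did not score fall back to a built-in
   heuristic: coding iff longest-ORF coverage (ORF nt incl. stop / length)
   ≥ 0.5, boundary inclusive. Explicit rows always override the heuristic.
6. **ncRNA families.** Remove transcripts with Rfam/Dfam/rRNA hits.

Every removal is logged (stage, id, reason) in a `FilterReport` whose stage
counts telescope; since rules 3–6 are pure predicates, the survivor set is
invariant under their permutation.

## Differential expression

Counts are normalized with median-of-ratios size factors (features positive
in all samples; factor_s = median of counts_gs/geomean_g). Note that
multiplying one library by c rescales all normalized counts by the common
constant c^(1/n) rather than leaving them bitwise identical — the estimator
is invariant when the correspondingly scaled factors are supplied.

Per pre-registered pairwise contrast (FPW1v2, FPW1v3, FPR1v2, FPR1v3, and
FPWk v FPRk for k=1..3) each feature gets a negative-binomial Wald test:

- group means m_A, m_B of normalized counts;
- dispersion α by method of moments within each group,
  α_g = (s²_g − m_g)/m_g², combined as max(α_A, α_B) so a quiet group never
  masks overdispersion, then moderated toward the across-feature median
  with fixed prior weight 1/3 (two pseudo-df against the ~4 residual df a
  3-vs-3 contrast leaves per feature) and floored at 10⁻⁸. Without the
  moderation the Wald null is visibly anti-conservative at n = 3
  (raw-p < 0.05 fraction ≈ 0.08–0.10); with it the fraction sits at
  0.04–0.06 across independent null simulations, with no loss of power on
  2-unit log2 effects. No trend fitting or shrinkage of fold changes is
  attempted (out of scope);
- log2FC = log2((m_B + 0.5)/(m_A + 0.5)); the delta-method standard error
  uses NB variance (m + αm²)/n per group; two-sided normal p-values;
  Benjamini–Hochberg adjustment across features.

A feature is differentially expressed iff |log2FC| > 1 and adjusted
p < 0.05. Replicate quality control reports Pearson r of log2(FPKM+1)
between all within-condition replicate pairs (constant rows dropped),
flagging pairs at r ≤ 0.9. qPCR validation uses 2^−ΔΔCt with the actin
reference: ΔCt = Ct_target − Ct_reference, ΔΔCt relative to a calibrator
condition.

## Target prediction

- **cis:** genome-anchored lncRNAs are paired with every gene whose locus
  lies within 10 kb of either flank (gap 0 for overlaps, strand-agnostic,
  the lncRNA's own gene excluded; nearest transcript per gene kept).
  De-novo transcripts without coordinates participate only in trans mode.
- **trans:** Pearson correlation of log2(FPKM+1) (configurable) across all
  18 samples between every lncRNA and every gene; pairs with |r| > 0.9 are
  reported with the sign retained, since lncRNAs may act as negative
  regulators; `signed=True` restricts to r > 0.9. Zero-variance features
  are excluded with a warning.
- `de_overlap` marks pairs whose two members are both DE in a contrast and
  tallies DE lncRNAs / DE targets / co-DE pairs per contrast.

## Co-expression network

Input is log2(FPKM+1), optionally reduced to the top-variance 5,000
features. Unsigned adjacency a_ij = |cor|^β; β is the smallest power in
1..12 whose connectivity distribution fits scale-free topology with signed
R² ≥ 0.8 (log-log regression over 10 connectivity bins, R² counted only
for negative slopes), else 6 with a warning. The grid stops at 12 because
with 18 samples the criterion can be met spuriously at very high powers,
which sharpen correlation noise into the network. Topological overlap is
the standard ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with unit
diagonal. Modules come from average-linkage clustering of 1−TOM with a
static cut: by default the merge height (of up to 1,000 candidates) that
maximizes the number of clusters of size ≥ 10, largest tied height — a
fixed fraction of the maximum merge height proved unusable because
average-linkage heights compress near the root. Dynamic tree cut is not
reproduced; the module count is therefore not comparable to any published
module count. Eigengenes are the first right singular vector over samples
of the standardized module matrix, sign-aligned with the mean profile;
module–trait association is Pearson r of eigengene versus the color score
(1 green, 2 white, 3 red) with a Student-t p on n−2 df.

## Regulatory network

miRNA target sites use the classic plant scoring scheme instead of an
external server: ungapped sliding alignment of the miRNA against each
transcript, per-position penalty from the miRNA 5′ end (mismatch 1.0, G:U
wobble 0.5, doubled at positions 2–13), site reported iff total ≤ 3.0.
Gaps and bulges are unsupported. PPI edges keep confidence ≥ 0.7 (raw
STRING 0–999 scores are rescaled on request). The tripartite network is a
typed multigraph (mRNA/lncRNA/miRNA nodes; ppi, mirna_target, lnc_target,
coexpression edges); duplicate (pair, type) edges collapse keeping the
maximum weight, self-loops are dropped, and unknown endpoints are an
error. Seed-gene sub-networks (the Fra a/PR10 analysis pattern) are the
induced subgraph on seeds plus all nodes within k hops (default 1),
edge-type-agnostic.

## Enrichment

Over-representation is the upper-tail hypergeometric P(X ≥ k) of a
selection of n genes against a term of K members in a universe of N, with
BH adjustment across terms. The universe defaults to features surviving
the expression filter. Gene-length bias correction (GOseq-style) is not
reproduced.

## Synthetic study

The generator (`lncfruit.simulate`) emits a complete toy study — genome,
GFF3, transcripts, miRNAs, counts, sample sheet, trait, evidence tables,
PPI edges, term map — plus `ground_truth.json`. Defaults, which are the
conditions under which all recovery claims are made: 2 chromosomes ×
2.8 Mb; 300 coding transcripts (planted 120–400-codon ORFs) and 100
lncRNAs (200–3,000 bp, rejection-sampled until the longest ORF is ≤ 100 aa
*and* ORF coverage < 0.5, so planted lncRNAs are genuinely ORF-poor); 10
redundant near-copies (length ≥ 500, 2% of positions substituted in one
contiguous block so ≥ 95% of 11-mers stay shared); 10 cis pairs placed at
exactly 5 kb from a coding locus (all other loci > 10 kb apart); 10 trans
pairs with latent correlation 0.95 enforced exactly in-sample by
orthogonalized construction; 4 modules of 25 genes at within-correlation
0.85, the first driven by the standardized color score; 15% DE features at
log2FC 2 in one random contrast; 15 miRNA sites embedded as exact reverse
complements (in 3′ UTRs of coding targets); NB counts with dispersion
0.05 and library sizes uniform in 0.8–1.2 M.

Latent structure is condition-aware: module factors carry 60% of their
variance at the genotype×stage level (40% replicate-level), trans latents
90%, and module factors are mutually orthogonalized in sample space —
with only six condition levels, unrelated condition profiles would
otherwise correlate by chance and blur the planted modules. Purely
per-sample factors were rejected because they destroy the within-condition
replicate correlation real libraries show; purely condition-level factors
were rejected because they make planted modules inseparable. Trans-pair
members are excluded from the independent DE pool (an independent shift
would decorrelate the pair); a quarter of the pairs instead receive one
shared shift, making them jointly DE. Baseline abundances are lognormal
(σ = 2.0 natural-log) around 200 (coding) / 60 (lncRNA) mean counts; 8% of
features are additionally forced below the FPKM filter. Every stage draws
from `default_rng([seed, stage])`, so runs are byte-identical per seed.

What the fixture does **not** emulate: splice isoforms, sequencing error,
positional read bias, GC effects, batch structure, unbalanced designs,
real secondary structure in miRNA targeting, or realistic genome repeat
content. Passing tests therefore demonstrate correctness of the pipeline's
logic and calibration of its statistics under an idealized NB world, not
performance on real libraries.

## Problem sizes

The default fixture (≈ 410 transcripts, 18 samples) runs the full
pipeline — simulate, identify, DE over seven contrasts, targets, modules,
network, enrichment — in well under a minute on one CPU; the test suite
and the reproduction script are sized accordingly (2,000-feature null for
calibration, 2,000 random pairs for the trans false-positive rate, five
seeds for module recovery).

## Known limitations

- The NB Wald stand-in is calibrated but unshrunk; its fold-change
  estimates are noisier than DESeq2's MAP estimates at low counts.
- k-mer containment can merge sequences a banded aligner would split when
  divergence is clustered, and vice versa for scattered divergence.
- The static TOM cut recovers well-separated modules; overlapping or
  nested modules need dynamic cutting, which is out of scope.
- cis prediction silently skips unanchored transcripts (warned once);
  there is no triplex or base-pairing mechanistic model behind either
  target mode.
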