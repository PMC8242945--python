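# Methods

This note documents the models, rules, parameters and numerical choices
behind each analysis stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Study design assumed by the pipeline

The pipeline targets an LPS-challenge design on clonal replicates: two
treatments (LPS injection, sham seawater control), two sampling timepoints
(1 h and 6 h), and n biological replicates per treatment. Each replicate is
a *clone pair* — tissue of the same individual sampled at both timepoints
within its treatment — and no individual appears in both treatments. The
default synthetic design has n = 6 individuals per treatment with one LPS
replicate missing at 6 h, giving 23 samples. Because treatments contain
disjoint individuals, differential expression is an unpaired two-group
comparison per timepoint; the clone structure is exploited only by the
individuality analysis.

## Receptor rule engine

Each PRR family is a predicate over the multiset of Pfam accessions on a
transcript plus a transmembrane flag:

| family | rule |
|---|---|
| TLR_like | TIR (PF01582) ∧ ≥1 Ig-like (PF00047) ∧ tm |
| TIR_only | TIR, failing the TLR_like rule |
| NLR_bona_fide | NACHT (PF05729) ∧ ≥1 LRR (PF13516) |
| NACHT_only | NACHT ∧ no LRR |
| GPCR_GPS_7TM | 7TM accession ∧ GPS (PF01825) |
| GPCR_7TM | 7TM accession |
| SRCR | PF00530 ∨ PF15494 |
| CTLD | PF00059 |

Decisions that were genuinely open:

* **"7TM" is structural, not a single Pfam family.** The default accession
  set {PF00001, PF00002, PF00003, PF10320, PF10328} covers the rhodopsin,
  secretin, metabotropic-glutamate and Srx/Srsx GPCR families and is
  override-able in the `Ruleset`.
* **Precedence.** Published repertoire tallies are non-overlapping without a
  stated resolution rule; here multi-family architectures resolve by the
  explicit order TLR_like > TIR_only > NLR_bona_fide > NACHT_only >
  GPCR_GPS_7TM > GPCR_7TM > SRCR > CTLD, configurable. Tests check
  equivalence against a brute-force rule checker that evaluates every rule
  independently.
* **E-value cutoff 1e-5** before any rule, matching the homology-search
  threshold conventionally used in this kind of annotation; configurable.
* **Whether a complete TLR-like call needs a transmembrane segment** is
  debatable for fragmented de novo assemblies; the default requires it
  (`tir_requires_tm=False` relaxes).
* Cytokine receptors have no shared diagnostic domain and require external
  proteome/pathway mapping; the engine does not call them.

Localization is membrane-bound iff a transmembrane segment was predicted;
secreted/cytosolic receptors cannot be distinguished from fragments, so the
membrane-bound count is a lower bound on truth in real data.

## Normalization

TPM is computed from counts and effective lengths; every column sums to 1e6
by construction. Between-sample factors use the trimmed mean of M-values
(Robinson & Oshlack 2010): reference column chosen by the 75th-percentile
count fraction closest to the mean; per-gene M (log2 relative abundance
ratio) and A (average log abundance) over genes positive in both libraries
(no pseudocounts — zero genes are excluded); double trimming of 30% from
each M tail and 5% from each A tail (average ranks, matching the reference
implementation's tie behavior); factor = 2 to the precision-weighted mean M
with delta-method weights; factors rescaled to geometric mean 1. Fewer than
10 surviving genes triggers an untrimmed fallback with a warning; a sample
sharing no positive genes with the reference is an error. An unweighted
mean is available (`weighted=False`); note the weighted factor is exactly
invariant to the composition and only approximately (≈1e-3) invariant to
rescaling a single library, because the weights depend on library size.

Factors are computed on **counts** and applied to the **TPM** matrix — the
convention of the Trinity downstream scripts this stage mirrors. The
result, TMM-normalized TPM, is the expression scale for all downstream
pattern analysis.

## Expression layers

Presence is `count > 0` on the raw (or RSEM expected) count matrix — any
positive expected count marks presence, including values in (0, 1). A gene
is constitutive iff present in all samples, not expressed iff present in
none, individual-specific otherwise; the partition is exhaustive and
exclusive by construction. The high-expression tier takes constitutive
genes with across-sample **mean** TMM-TPM > 10; a stricter per-sample mode
(`high_mode="all"`) is available since "above threshold" was ambiguous
between the two readings.

The immune-vs-other comparison reports
median(mean TMM-TPM of constitutive immune genes) /
median(constitutive non-immune). The ratio-of-medians estimator has a
sampling SE of roughly 5–7% when ~800 immune constitutive genes are
available (20,000 genes at default fractions); recovery of a planted boost
should be judged against that noise floor.

The individuality analysis quantifies "samples cluster by individual, not
timepoint": Jaccard distances between sample presence vectors over the
individual-specific gene set, average-linkage dendrogram (serialized as
Newick), and a pairing score = fraction of clone pairs that are mutual
nearest neighbors (ties within 1e-12 count as nearest). Significance comes
from permuting individual labels over samples:
p = (1 + #{permuted score ≥ observed}) / (1 + n_permutations), so p is
never 0 and is reproducible under a fixed seed. All-identical presence
vectors make the score undefined; the result is flagged tied with p = 1.
Note the combinatorial floor: with only k clone pairs a random permutation
preserves the pairing with probability 2^k·k!/(2k)!, which for k = 4 is
≈1%, so small designs cannot reach p < 0.01 on the score alone.

## Differential expression

The engine is a deliberately simple, fully documented NB Wald test — not a
re-implementation of any published DE package; the thresholds and the
downstream partition, not the engine, are the point.

* Counts are scaled by relative effective library size (column sum × TMM
  factor, normalized to geometric mean 1).
* Per-gene dispersion: method of moments on within-group mean/variance,
  var = μ + φμ², pooled across the two groups with (n−1) weights, floored
  at 1e-8; then shrunk 50/50 toward the 20%-trimmed mean dispersion of the
  gene's overall-expression decile. All-zero genes are excluded.
* log2FC = log2((μ_LPS + 0.5)/(μ_control + 0.5)) with pseudocount 0.5 so
  zeros stay finite; SE by the delta method from the NB variance function;
  two-sided p from the normal reference.
* Independent filtering (on by default, logged): all-zero genes and the
  bottom decile of base mean are excluded before Benjamini–Hochberg, which
  changes the BH denominator and therefore must be visible. One consequence
  worth knowing: if the expression background is artificially uniform, the
  bottom decile coincides with strongly down-regulated genes; with a
  realistic log-normal background the filter removes essentially only
  low-information genes.
* Significance: BH-adjusted p < 0.005 and |log2FC| ≥ 2, direction from the
  fold-change sign. Swapping group labels negates every log2FC and
  preserves p exactly.

On seeded null simulations (2,000 genes, 6 vs 6, dispersion 0.1, log-normal
means) the test is conservative at these thresholds — the fold-change
requirement dominates — and planted |log2FC| = 3 effects at μ = 100 are
detected with power above 0.9. Calibration was run once and frozen into the
acceptance suite.

## Consistent vs variable DEGs

"Regulated in a replicate" is not defined in qualitative descriptions of
replicate variability, so this module operationalizes it: treatment
replicate r supports a DEG when
log2((x_r + 1)/(control geometric mean + 1)) matches the DE direction with
magnitude ≥ `support_lfc` (default 1.0 — half the DEG fold-change
threshold; raising it can only lower support counts). The control geometric
mean is 0 when any control sample is 0.

DEGs are clustered on median-centered log2(TMM-TPM + 1) profiles across the
contrast's samples (Euclidean, complete linkage, tree cut at 40% of the
maximum merge height — the Trinity convention). Cluster ids are renumbered
by first appearance in lexicographic gene order, so the output is
independent of input order. Labels: a cluster is consistent iff its median
support exceeds half the treatment replicates, else variable; genes inherit
the cluster label. This single rule reproduces both canonical cases —
support 2 of 6 is variable, and support 3 of 6 (not *more* than half) is
also variable, while 3 of 5 is consistent. A per-gene labeling mode
(`mode="gene"`) exists because the cluster-vs-gene granularity is a
genuinely open choice; cluster mode is the default.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

* **Layers.** Genes are split constitutive / individual-specific / never
  expressed (default 0.40/0.40/0.20 — chosen so both expressed layers are
  well populated at the roughly half-expressed level seen in repertoire
  screens; the per-dataset constitutive fraction is not a quantity this
  generator claims to reproduce).
* **Baseline means** are log-normal (meanlog 4, sdlog 1 — a median around
  55 counts with a realistic right tail), floored at 20 for constitutive
  genes so that presence-in-all-samples is recoverable from observed
  counts: at μ = 20 and dispersion 0.2 a sampling zero has probability
  ≈3e-4 per sample, keeping one-way misclassification well under the 5%
  bound at 23 samples.
* **Structural zeros are exact zeros**, matching the presence/absence
  reading of repertoire heatmaps; sampling zeros can therefore only demote
  constitutive genes to individual-specific, never promote.
* **Carriage** of an individual-specific gene is decided per individual
  (probability 0.5), so both clones of a carrier agree regardless of
  timepoint. Carrier sets are clamped to be non-empty and to exclude at
  least one individual — a gene carried by everyone would genuinely be
  constitutive under the observed-count definition, which would break the
  one-way-error property by construction rather than by noise.
* **Response.** 200 responsive genes drawn from the constitutive layer;
  direction drawn once per gene (60% down / 40% up, reflecting
  predominantly downward LPS responses); responder individuals are a
  per-gene random subset of LPS individuals of size
  round(penetrance × n); a sequence of penetrances is cycled across genes
  to plant mixed designs. Means are multiplied by 2^(±3) only in LPS
  samples of responder individuals.
* **Immune flags** on 10% of genes; constitutive immune baselines get a
  ×1.35 boost so the median comparison has a planted truth.
* **Counts** are gamma-Poisson (NB) with variance μ + 0.2μ²; dispersion
  below 1e-9 degrades to Poisson. **Lengths** are log-normal (median 2 kb,
  sdlog 0.6, floored at 100).
* **Reproducibility.** Every stage draws from a named substream of the one
  seed (SeedSequence keyed by seed + stage label), so outputs are
  byte-identical across runs and stages can be reproduced independently.

What it does **not** emulate: multiple assembly fragments per gene,
read-level noise or mapping bias, microbiome contamination, correlated gene
modules, genotype-driven expression differences beyond carriage, or any
claim that real expression is log-normal-NB. Passing recovery tests
therefore shows the rules are implemented correctly and are recoverable
under their own assumptions — not that those assumptions hold in real
sponge data.

## Problem sizes used in tests

Layer recovery runs at the full default scale (20,000 genes × 23 samples);
DE calibration uses 50 null replicates of 2,000 genes at 6 vs 6; partition
recovery uses 4,000 genes with 200 mixed-penetrance responsive genes; the
individuality null uses 100 repetitions of 300-gene presence matrices with
99 permutations each. These sizes give the recovery and calibration
statistics comfortable margins over their thresholds while keeping the full
suite fast.

## Known limitations

* The NB Wald p-values rely on a normal reference and moment dispersions;
  they are meant for desk-scale planted-truth work, not as a drop-in for a
  production DE engine with shrunken estimators and outlier handling.
* The clone-pair pairing score ignores individuals with a single sample;
  designs with many dropouts lose power.
* The rule engine trusts its inputs (domain table + tm/signal flags); it
  does not run HMMER or judge domain-prediction quality.
* `constitutive_high` with the default mean mode can be driven by a few
  extreme samples; use `high_mode="all"` when that matters.
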