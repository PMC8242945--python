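# prrlayers

Layered immune-gene-expression analysis for bulk RNA-seq of marine sponges
(or any system with clone-pair replication), built around the three layers of
innate immune gene control seen in LPS-challenge experiments on the
breadcrumb sponge *Halichondria panicea*:

1. **constitutive expression** — genes detected (count > 0) in every sample;
2. **individual-specific expression** — genes whose presence tracks the
   sponge individual rather than treatment or timepoint;
3. **induced response** — genes differentially expressed after bacterial
   lipopolysaccharide (LPS) exposure, further split into *consistent* and
   *variable* by how many replicates actually respond.

The package is aimed at researchers analyzing non-model-organism immune
transcriptomes who want each analysis rule to be explicit, testable, and
re-runnable on synthetic data with planted ground truth.

## What it computes

**PRR repertoire screen** (`prrlayers.domains`). Pattern recognition
receptor families are called from Pfam domain architectures with an explicit
rule engine: TLR-like = TIR (PF01582) + ≥1 Ig-like (PF00047) + transmembrane
segment; bona fide NLR = NACHT (PF05729) + ≥1 LRR (PF13516); CTLD = PF00059;
SRCR = PF00530 or PF15494; 7TM GPCRs (configurable accession set), with or
without a GPS motif (PF01825). Multi-family architectures resolve by a fixed,
configurable precedence; hits with e-value > 1e-5 are ignored.

**Normalization** (`prrlayers.normalization`). TPM from counts and effective
lengths, with between-sample scaling by trimmed-mean-of-M-values (TMM)
factors computed on counts and applied to the TPM matrix:

    TPM[g,s] = 1e6 · (c[g,s]/ℓ[g]) / Σ_g' (c[g',s]/ℓ[g'])
    f[s] = 2^( Σ w_g M_g / Σ w_g ),  M_g = log2 of the sample/reference
           relative abundance ratio, doubly trimmed (30% M tails, 5% A tails)

**Expression layers** (`prrlayers.layers`). The constitutive /
individual-specific / not-expressed partition, the high-expression tier
(mean TMM-TPM > 10), the immune-vs-other constitutive median ratio, and an
individuality test: Jaccard distances between sample presence/absence
vectors, with a clone-pair mutual-nearest-neighbor score against a
label-permutation null.

**Differential expression** (`prrlayers.de`). A negative-binomial Wald test
per timepoint (LPS vs control), method-of-moments dispersions shrunk toward
an expression-decile trend, Benjamini–Hochberg FDR, and the study
thresholds FDR < 0.005 and |log2FC| ≥ 2, plus cross-timepoint overlap and
direction-consistency reporting.

**Consistent/variable partition** (`prrlayers.partition`). DEGs are
clustered on median-centered log2 profiles (Euclidean, complete linkage,
tree cut at 40% of the maximum merge height) and labeled *consistent* when
their cluster's median replicate support exceeds half the treatment
replicates, *variable* otherwise — a replicate supports a DEG when its
log2 ratio over the control geometric mean matches the DE direction by ≥ 1.

**Synthetic data** (`prrlayers.simulate`). Generates the full study design —
2 treatments × 2 timepoints × 6 individuals with clone pairs and one LPS
replicate missing at 6 h (23 samples) — with negative-binomial counts, a
planted constitutive core, per-individual gene repertoires, LPS-responsive
genes with configurable responder penetrance, and planted receptor
architectures, all recorded in a truth table.

## Worked example

```python
from prrlayers import (SimulationConfig, simulate_design, simulate_counts,
                       tmm_normalized_tpm, call_layers, layer_summary,
                       contrast_from_design, test_contrast)

cfg = SimulationConfig(n_genes=3000, seed=2, n_responsive=100)
design = simulate_design(cfg.n_individuals, cfg.dropout_samples)
exp = simulate_counts(cfg, design)
norm, factors = tmm_normalized_tpm(exp.counts, exp.lengths)
assignment = call_layers(exp.counts, norm)
print(layer_summary(assignment)["frac_of_all"])
de = test_contrast(exp.counts, factors, contrast_from_design(design, "t1h"))
print(int(de.significant.sum()), "DEGs at FDR<0.005, |log2FC|>=2")
```

prints (numbers from this exact run):

```
{'constitutive': 0.3943333333333333, 'individual_specific': 0.4056666666666667, 'not_expressed': 0.2}
109 DEGs at FDR<0.005, |log2FC|>=2
```

The layer fractions recover the planted 0.4 / 0.4 / 0.2 split up to sampling
zeros (a handful of constitutive genes drop to individual-specific; the
truth table says which). The 109 DEGs are the 100 planted responsive genes
minus those whose down-regulated mean is too low to clear the fold-change
threshold, plus individual-specific genes whose carriers happen to
concentrate in one treatment arm — the same individual-driven effect the
consistent/variable partition is designed to expose.

Or from the shell:

```
prrlayers run-all --seed 42 --outdir run42
```

writes every stage artifact (design, counts, receptor calls, TMM-TPM
matrix, layer table, DE tables, partition tables, Newick dendrogram) plus
`run_report.json` with layer fractions, receptor tallies, DEG counts per
direction, overlap fractions, the individuality p-value, and per-file
digests. Re-running with the same seed reproduces every file byte for byte.

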