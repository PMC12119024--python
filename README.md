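# gametiq

Crossover mapping and eQTL analysis from pooled single-nucleus RNA-seq of
recombinant haploid gametes.

## The problem

Every haploid gamete of an F1 hybrid is an independent recombinant genome.
Single-nucleus RNA-seq of a gamete pool (the motivating system is mature
*Arabidopsis* pollen from crosses sharing Col-0 as one parent) therefore
measures three things at once per nucleus: which F1 hybrid it came from,
where its meiotic crossovers happened, and its transcriptome. Linking the
inherited haplotype at each genomic bin to each gene's expression turns a
single sequencing library into an expression-QTL mapping population —
without growing a single segregant.

The catch is that the data are sparse and dirty: a few hundred
haplotype-informative marker UMIs per nucleus, ambient RNA that
contradicts the true haplotype, doublets, and extreme allele-specific
expression. `gametiq` implements the full inference chain:

1. **`gametiq.demux`** — assign each barcode to its F1 genotype of origin:
   EM over the observed alternate-allele SNP patterns, 25 bootstrap
   resamples, Phred-like confidence score `-log10(1 - p)`.
2. **`gametiq.markers`** — clean haplotype markers: 1MM-directional UMI
   dedup, 25 kb binning, SoupX-style ambient-background estimation and
   subtraction, masking of bins with > 9:1 pooled allele imbalance.
3. **`gametiq.rhmm`** — decode haplotypes with a rigid hidden Markov
   model: two haplotype states, each a chain of `R = 100` micro-states so
   that any path keeps adjacent crossovers ≥ 2.5 Mb apart (crossover
   interference as a hard constraint), with terminal rigidity `T = 4`
   allowing chromosome-end segments as short as 100 kb; symmetric Poisson
   emissions; forward–backward posteriors, per-boundary crossover
   probabilities with 95% credible intervals, and Viterbi tracks.
4. **`gametiq.qc`** — whitelist nuclei from genotyping and decoder fit
   metrics (random forest or Gaussian mixture on initial heuristic
   labels) and flag sperm+vegetative doublets with a
   DoubletFinder-style synthetic-doublet KNN score.
5. **`gametiq.eqtl`** — per (gene, bin) OLS with probabilistic haplotype
   regressors: `Exprs_x ~ Haplo_p1 + … + Haplo_pN + Geno_1 + … +
   Geno_{N-1} + PC_1 + PC_2`, likelihood-ratio test against the nested
   model, `LOD = Λ / (2 ln 10)`, Li–Ji effective-test Bonferroni plus
   gene-level Benjamini–Hochberg FDR, peak calling (LOD ≥ 3, FDR < 0.05,
   prominence ≥ 25%, ≥ 3 Mb apart) with 1.5-LOD-drop confidence
   intervals, cis/trans classification at a 2 Mb window, cell-type ×
   haplotype interaction scans, and latent-phenotype (5-PC) fine mapping
   of trans-hotspots.
6. **`gametiq.sim`** — a first-class simulator generating pools with known
   crossovers (hard minimum spacing), sparse ambient-contaminated
   markers (median 481 UMIs/nucleus), genotype mixes, sperm/vegetative
   expression programs with configurable cis/trans effects, and doublets
   — the ground truth that every stage is tested against.

## Worked example

Simulate a pool of 1,000 nuclei on a 30 Mb chromosome with 5% ambient
contamination and one cis-eQTL (+1.0 log2 units at bin 480), then run the
pipeline:

```python
import numpy as np
import pandas as pd
from gametiq import (
    SimConfig, EqtlEffect, simulate_truth_haplotypes, simulate_marker_matrix,
    mask_imbalanced_bins, correct_ambient, decode_nuclei, call_crossovers,
    simulate_expression, preprocess_expression, fit_bin_models,
    correct_multiple_testing, call_peaks, classify_peaks,
)

config = SimConfig(
    chromosome_lengths={"chr1": 30_000_000},
    n_nuclei=1_000,
    seed=0,
    ambient_fraction=0.05,
    eqtl_effects=[EqtlEffect(gene="GENE0042", chrom="chr1",
                             bin_index=480, effect_size=1.0)],
)
truth = simulate_truth_haplotypes(config)
markers = simulate_marker_matrix(truth, config)

markers = mask_imbalanced_bins(markers)
markers, background = correct_ambient(markers)
print(f"median ambient contamination: {np.median(background.rho):.3f}")

field = decode_nuclei(markers)
print(f"mean expected crossovers per nucleus: {field.expected_crossovers.mean():.2f}")
calls = call_crossovers(field)
print(f"crossover calls: {len(calls)}; median 95% CI width: "
      f"{(calls['ci_hi'] - calls['ci_lo']).median()/1e3:.0f} kb")

adata = preprocess_expression(simulate_expression(truth, config))
pheno = adata.var["eqtl_phenotype"].to_numpy()
Y = np.asarray(adata.layers["normalized"])[:, pheno]
genes = list(adata.var_names[pheno])
result = fit_bin_models(Y, genes, field, pcs=adata.obsm["X_pca"])
result = correct_multiple_testing(result, field)
print(f"tested {len(genes)} genes x {int(result.bin_mask.sum())} bins; "
      f"Meff = {result.meff:.1f}")
peaks = call_peaks(result)
coords = pd.DataFrame({"gene": genes, "chrom": "chr1",
                       "start": 480 * 25_000, "end": 480 * 25_000 + 2_000})
peaks = classify_peaks(peaks, coords)
print(peaks[["gene", "chrom", "bin", "lod", "ci_lo", "ci_hi", "class"]]
      .to_string(index=False))
```

Output:

```
median ambient contamination: 0.055
mean expected crossovers per nucleus: 1.30
crossover calls: 1165; median 95% CI width: 100 kb
tested 200 genes x 1200 bins; Meff = 54.0
    gene chrom  bin        lod    ci_lo    ci_hi class
GENE0042  chr1  476 124.814082 11825000 12050000   cis
```

Reading the numbers: the ambient estimate (0.055) recovers the simulated
5% contamination; 1.30 expected crossovers per nucleus matches the
configured 4.5 cM/Mb × 30 Mb = 1.35 genetic-map expectation; crossovers
are localized to a median 95% interval of 100 kb (4 bins). The scan tests
200 genes against 1,200 bins but, because neighbouring haplotype bins are
tightly linked, only ~54 effectively independent tests enter the
Bonferroni correction. The single called peak is the injected eQTL: its
1.5-LOD-drop interval (11.83–12.05 Mb) covers the causal bin
(12.00–12.025 Mb) and lies within 2 Mb of the gene, hence `cis`.

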