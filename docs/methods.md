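# Methods

`gametiq` analyses pooled single-nucleus RNA-seq of recombinant haploid
gametes (the motivating system is mature *Arabidopsis* pollen from F1
hybrids that share Col-0 as one parent). Each nucleus carries a haploid
recombinant genome; transcript reads that overlap parental variants act as
sparse haplotype markers, so a single experiment simultaneously measures
each gamete's genotype of origin, its crossover positions, and its
transcriptome. The pipeline has five inference stages plus a simulator;
this note records the models, the parameters that matter, and the design
choices made where the problem was genuinely open.

## Genotype demultiplexing (`demux`)

Pools mix gametes from N F1 hybrids. Because every nucleus shares the
reference parent, only positions where a barcode's UMIs support the
alternate allele by *strict* majority are informative of the parent-2
accession; reference-majority and tied positions are discarded (a reference
majority is fully explained by reference-parent inheritance). The
observation per barcode is the resulting SNP presence pattern, not the UMI
counts themselves.

Genotypes are assigned with a mixture model fit by EM with fractional
assignment. Per barcode and genotype g, the likelihood of each observed
alt-majority position is `1 - e` if g carries the alternate allele there
and `e` otherwise. `e` (default 0.05, configurable) absorbs ambient
contamination and rare mis-calls; the value is a free parameter chosen to
be robust to moderate ambient levels without washing out signal. Starting
from equal genotype priors, the M-step re-estimates priors from mean
responsibilities; convergence is declared when the L1 change of the prior
vector drops below 0.01 (the dataset-level reading of "total change in
probability"; a per-barcode reading is the documented alternative), or
after 1,000 iterations.

Confidence comes from 25 bootstrap resamples of each barcode's informative
positions (with replacement), with genotype priors frozen at their
converged values for stability. The assignment is the argmax of the mean
bootstrap posterior; its mean probability is Phred-scaled,
`-log10(1 - p)`, with p capped at `1 - 1/(2 * n_boot * n_positions + 2)`
so that scores stay finite at saturation.

## Marker cleaning (`markers`)

Markers are deduplicated with the 1MM directional UMI network method
(directed edge a→b when Hamming distance is 1 and
`count(a) >= 2*count(b) - 1`; groups collapse to the highest-count root).
Groups whose reads disagree on the supported haplotype are discarded.
Deduplicated markers carry their group's read count so that re-running
dedup on its own output is a no-op. Markers are positioned by their
leftmost aligned base and accumulated into non-overlapping 25 kb bins per
barcode and channel (reference parent vs parent 2).

Ambient contamination is corrected SoupX-style. The pooled per-(bin,
channel) marker fractions form the background profile. Per barcode, a 1 Mb
sliding window (advanced in 25 kb steps; each bin judged by the window
centred on it — the step size is unstated in the source method, so the
finest grid was chosen) calls the window-majority channel foreground. The
contamination level is rho = observed background-channel markers divided by
the markers expected in those channels were the barcode pure ambient; only
windows holding >= 5 markers contribute (an added stability guard). The
corrected matrix subtracts `rho * profile * barcode_total` and clips at
zero; corrected counts stay real-valued and are rounded only at emission
evaluation in the decoder.

Bins with a pooled channel imbalance strictly greater than 9:1 are masked
(extreme allele-specific expression distorts haplotype calling). The mask
is computed on raw pooled counts, before ambient correction (the order is
unstated in the source; raw counts avoid feedback from the correction).
A bin with one empty channel is masked only when the other holds >= 10
markers; with fewer there is no evidence of imbalance.

## Rigid HMM haplotype decoding (`rhmm`)

Crossover interference strongly suppresses crossovers closer than ~2.5 Mb
in *Arabidopsis*. The decoder encodes this structurally: each of the two
haplotype macro-states is a chain of R = 100 micro-states (rigidity). A
haplotype switch enters micro-state 1 of the other chain and must advance
one micro-state per 25 kb bin until reaching the final "free" state, the
only state from which switching (probability s) or staying (1 - s) is
possible. Every path therefore keeps adjacent switches >= R bins = 2.5 Mb
apart — a hard constraint, not a prior. Interference does not suppress
crossovers near chromosome ends, so paths may start at micro-state
R - T + 1 or later and terminate at micro-state T or later
(terminal rigidity T = 4), allowing terminal segments as short as
T bins = 100 kb. This micro-state realization is what provably yields the
two printed guarantees; the initial distribution is uniform over the 2T
allowed entry states.

The switch probability is initialized from the genome-wide recombination
rate: 4.5 cM/Mb = 0.045 crossovers/Mb, times 0.025 Mb per bin, gives
s = 1.125e-3 per free bin. No rigidity correction is applied to s — at
these rates the correction is second-order.

Emissions are a symmetric Poisson pair: in a state's foreground channel the
bin count is Poisson(lambda_fg), in the background channel
Poisson(lambda_bg), with channels swapped between the two macro-states.
Emission means are per-nucleus method-of-moments estimates — lambda_fg is
the mean larger channel count over non-empty unmasked bins, lambda_bg the
mean smaller count, floored at 0.01*lambda_fg — rather than Baum–Welch
refits, for determinism and stability at the typical ~480-marker depth.
Masked bins emit with probability 1, so their posterior is interpolated
purely through the transition structure. Non-integer ambient-corrected
counts are rounded to the nearest integer at evaluation.

Inference uses scaled forward–backward over the sparse transition
structure (O(R) per bin). The per-bin posterior of parent-2 inheritance
sums the parent-2 chain's micro-states; the crossover probability at each
bin boundary is the posterior mass flowing through the two switch
transitions, and their sum is the expected crossover count. Viterbi uses
the same recursion in log space with ties broken toward staying.

Crossover calls segment the boundary-probability series at a valley
threshold of 0.05 (unstated in the source; small enough to keep genuine
event mass together) and keep events with total mass >= 0.5. The point
estimate is the mass-weighted mean boundary; the 95% credible interval is
the smallest contiguous boundary window holding >= 95% of the event's
mass, widened by half a bin on each side because a switch resolved to the
boundary of bins b and b+1 places the crossover anywhere between the two
bin midpoints.

Per-nucleus fit metrics: the HMM score is the Phred-scaled fraction of
markers agreeing with the discretized track,
`-log10(1 - accuracy + 1/(2*markers))`; the HMM uncertainty is
`log10(sum_b |posterior_b - discretized_b| + 1e-6)` — a per-bin sum, which
makes the conventional quality threshold of 2.5 sensible at a ~5,000-bin
genome (the genomic-integral reading would shift it by log10 of the bin
size).

## Nucleus quality control (`qc`)

Initial labels: in pooled (multi-genotype) runs, positives are barcodes
whose genotyping probability exceeds the 25th percentile within their
assigned genotype (negatives are the rest — the source states only the
positive rule); in single-genotype runs, positives satisfy
(HMM score > 4 or HMM uncertainty < 2.5) and log10 markers >= 2.5. A
classifier generalizes the labels: a random forest (200 trees, sklearn
defaults otherwise) on the four metrics in pooled mode, or a 2-component
Gaussian mixture on (HMM score, HMM uncertainty) in single mode, the
high-quality component being the one with the higher mean HMM score.
Whitelist = predicted probability > 0.5.

Expression doublets are detected DoubletFinder-style: initial clusters from
a Gaussian mixture on PC scores; synthetic doublets (25% of the pool size)
are sums of random cross-cluster barcode pairs, depth-normalized and
projected into the PCA basis fit on real barcodes; the doublet score is the
fraction of a barcode's k = 10 nearest neighbours that are synthetic — a
probability rather than a rank cutoff, thresholded at 0.5. Same-type
doublets are invisible to this method by construction; the simulator's
ground truth distinguishes cross-type doublets for exactly this reason.

## eQTL mapping (`eqtl`)

Counts are filtered (genes in >= 10 barcodes for PCA; genes detected in
>= 5% of nuclei, inclusive, as eQTL phenotypes), depth-normalized to
10,000 and log2(1 + x)-transformed (scale and pseudocount are fixed,
configurable conventions; the source states only "normalized by sequencing
depth and log2 transformed"). PCs are computed once on the full
whitelisted matrix and reused as covariates across scans.

For gene x and bin p the full model is

    Exprs_x ~ Haplo_p1 + ... + Haplo_pN + Geno_1 + ... + Geno_{N-1} + PC_1 + PC_2

with Haplo_pn the posterior parent-2 probability at p zeroed outside
genotype n (N = 1 collapses to a single haplotype regressor). The nested
model drops the haplotype block; the LRT statistic is
`Lambda = n * ln(RSS_nested / RSS_full)` with a chi-square reference on the
number of retained haplotype regressors, and `LOD = Lambda / (2 ln 10)`.
The scan is computed by residualizing phenotypes and haplotype regressors
against the shared covariates once (Frisch–Waugh–Lovell) and doing a small
QR per bin; it reproduces statsmodels OLS to machine precision (tested) at
a fraction of the cost. Rank-deficient bins drop the offending regressors.

Multiple testing follows one consistent reading of a two-stage scheme:
the Li–Ji effective number of tests Meff (eigenvalues of the bin–bin
correlation matrix of the haplotype posteriors;
`Meff = sum 1(lam>=1) + frac(lam)`; computed via the smaller Gram matrix
when nuclei are fewer than bins; near-integer eigenvalues are snapped
before the floor, which is discontinuous there) Bonferroni-corrects p
within the scan, then Benjamini–Hochberg across genes on each gene's
minimum adjusted p gives the gene-level FDR.

Peaks are local LOD maxima with topographic prominence >= 25% of the
gene's top LOD and >= 3 Mb apart, retained when LOD >= 3, the peak bin's
adjusted p < 0.05 and the gene FDR < 0.05; plateau maxima take the
leftmost bin. The confidence interval is the contiguous bin run with
LOD >= peak - 1.5, in nt. A peak is cis when its CI lies on the gene's
chromosome and intersects the gene extended by 2 Mb (inclusive at the
boundary); otherwise trans.

Cell types are soft probabilities from a 2-component Gaussian mixture on
PC scores (sperm vs vegetative nuclei in the motivating system). The
interaction scan replaces the haplotype block with CT_t x Haplo_p for each
type while controlling for cell type and PCs; the overall LRT drops all
interactions, and cell-type-specific calls use per-interaction-coefficient
t-tests (chosen over per-genotype LRTs, which the source leaves
unspecified), converted to LOD-scale profiles (t^2 / (2 ln 10)) so the
standard peak caller applies per type.

Trans-hotspot fine mapping filters nuclei (classifier probability > 0.95,
doublet probability < 0.05, sperm probability > 0.95, log10 markers > 2.5)
and genes (trans peak CI covering the hotspot, no cis peak anywhere),
computes 5 principal components of the filtered normalized matrix, and
scans each component against all bins with the remaining components as
covariates — the joint-model reading of "a nested model where the tested
component was excluded"; the independent-scan alternative is the documented
other reading. The strongest component's peak and its 1.5-LOD-drop CI
localize the hotspot.

## Simulator (`sim`)

The generator emulates the statistical structure the inference assumes,
with ground truth for every latent quantity. Defaults are the study
conditions: 25 kb bins, 4.5 cM/Mb, a 2.5 Mb hard interference floor, and a
median of 481 marker UMIs per nucleus.

- **Haplotypes.** Per nucleus and chromosome the crossover count is
  Poisson with mean rate x length / 100; positions are uniform and
  rejection-resampled until adjacent events clear the spacing floor
  (matching the decoder's hard constraint exactly, rather than a gamma
  renewal process — the acceptance guarantees need the constraint exact).
  Infeasible counts on short chromosomes are reduced with a warning. A bin
  takes the haplotype at its midpoint.
- **Markers.** Per-nucleus totals are negative binomial (gamma–Poisson,
  dispersion r = 2 — a free parameter; empirical depths are overdispersed)
  with the mean set to `median_target * r / gamma.ppf(0.5, r)` so the
  realized median matches the configured 481. Markers land in bins
  proportional to a density profile (uniform by default; real marker
  density tracks expression and collapses in centromeres). Each marker
  reports its bin's true haplotype with probability 1 - ambient_fraction,
  else a draw from the pool-wide per-bin haplotype frequencies — the same
  background model the correction assumes.
- **Allele counts.** A nucleus emits alternate-allele UMIs at panel
  positions its genotype carries *and* whose bin is parent-2 inherited;
  an ambient fraction of UMIs is redrawn from pool-wide allele
  frequencies.
- **Expression.** Poisson-lognormal counts: per-gene baseline log2 means,
  a cell-type program (40 genes shifted by 2 log2 units, split between the
  two types) so types separate in PC space, configured eQTL effects
  shifting log2 means of parent-2 carriers at the causal bin, per-nucleus
  lognormal depth (mean 2,000 UMIs) and 0.25 log2 units of biological
  noise. These magnitudes are free parameters chosen to resemble sparse
  snRNA-seq.
- **Doublets.** Random pairs merged under one barcode (expression and
  allele counts summed, markers unioned); cross-cell-type pairs are
  tracked separately because only they are detectable from expression.

What the simulator does *not* emulate: read-level errors, UMI collisions,
position-level marker clustering within bins, batch effects, empirical
cell-type imbalance beyond the configured proportions, and genotype-
dependent recombination landscapes. Passing recovery tests therefore shows
the inference is correct under its own model assumptions at desk scale,
not that those assumptions hold in any particular real library.

## Problem sizes and numerical choices

Tests and the acceptance script run on one 30 Mb chromosome (1,200 bins)
with 120–2,000 nuclei, 20 hotspot replicates at 800 nuclei x 80 genes, and
a null scan of 500 genes x 1,000 nuclei — sizes chosen so the full suite
completes in about a minute while keeping every statistical check
well-powered. Forward–backward is scaled (not log-space) with per-bin
emission normalization; posteriors, boundary probabilities and Viterbi
paths are invariant to that normalization. Exhaustive legal-path
enumeration verifies the recursions to 1e-9 on all instances with <= 8
bins and R <= 3. Viterbi ties break toward no switch. Degenerate inputs
(markerless nuclei, constant haplotype bins, empty genotypes, single
clusters) are flagged or dropped rather than fatal wherever the
surrounding computation can proceed.

## Known limitations

Haploid two-state decoding only (no heterozygous or polyploid states, no
gene conversion); no kinship/mixed-model correction in the eQTL scan; the
ambient correction assumes a single pool-wide background; per-nucleus
emission moments can be noisy below ~100 markers (such nuclei are
typically removed by QC); and the whitelisting thresholds are tuned to the
metric scales above, not re-estimated per dataset.
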