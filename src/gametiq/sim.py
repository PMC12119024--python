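"""Synthetic pooled-gamete snRNA-seq generator with known ground truth.

Emulates the statistical structure the inference pipeline assumes: pools of
recombinant haploid nuclei from N F1 hybrids sharing one reference parent,
each nucleus a mosaic of the two parental haplotypes with crossovers subject
to hard interference (minimum spacing), sparse haplotype markers with
ambient contamination, sperm/vegetative expression programs with cis/trans
eQTL effects, and barcode-collision doublets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad
from scipy.stats import gamma as gamma_dist

from .config import CM_PER_MORGAN, EqtlEffect, SimConfig
from .demux import AlleleCountTable, VariantPanel
from .markers import BinGrid, MarkerMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimTruth:
    """Ground truth of one simulated pool.

    ``haplotype[i, b]`` is 0 (reference parent) or 1 (parent 2) for barcode
    ``i`` at genome-wide bin ``b`` (a bin takes the haplotype at its
    midpoint); ``crossovers`` lists (barcode, chrom, position) events;
    adjacent crossovers on one chromosome are >= ``min_co_spacing`` apart.
    """

    barcodes: list[str]
    grid: BinGrid
    haplotype: np.ndarray  # (n_nuclei, n_bins) int8
    crossovers: pd.DataFrame  # columns barcode, chrom, position
    genotype: np.ndarray  # (n_nuclei,) int
    celltype: np.ndarray  # (n_nuclei,) object (labels)
    doublet: np.ndarray  # (n_nuclei,) bool
    doublet_cross_type: np.ndarray | None = None  # True where the merged pair mixed cell types
    effects: list[EqtlEffect] = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.barcodes)


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


# ---------------------------------------------------------------------------
# Truth haplotypes
# ---------------------------------------------------------------------------


def _place_crossovers(
    rng: np.random.Generator, length: int, n_co: int, spacing: int, max_tries: int = 200
) -> np.ndarray:
    """Uniform positions rejection-resampled to honour the spacing floor."""
    while n_co > 0:
        if (n_co - 1) * spacing >= length:
            logger.warning(
                "chromosome of %d nt cannot hold %d crossovers at %d nt "
                "spacing; reducing",
                length,
                n_co,
                spacing,
            )
            n_co -= 1
            continue
        for _ in range(max_tries):
            pos = np.sort(rng.uniform(0, length, size=n_co))
            if n_co == 1 or (np.diff(pos) >= spacing).all():
                return pos
        n_co -= 1  # spacing nearly infeasible at this count
        logger.warning("crossover placement failed; retrying with %d", n_co)
    return np.empty(0)


def simulate_truth_haplotypes(config: SimConfig) -> SimTruth:
    """Draw recombinant haplotypes for a pool of haploid nuclei.

    Per nucleus and chromosome, the crossover count is Poisson with mean
    ``recomb_rate[cM/Mb] x length[Mb] / 100``; positions are uniform,
    rejection-resampled until adjacent events are >= ``min_co_spacing``
    apart. The haplotype track starts in a random phase and alternates at
    each crossover. Genotypes and cell types are assigned independently.
    """
    rng = _rng(config, 1)
    grid = BinGrid(dict(config.chromosome_lengths), config.bin_size)
    n = config.n_nuclei
    barcodes = [f"BC{i:05d}" for i in range(n)]
    haplotype = np.zeros((n, grid.total_bins), dtype=np.int8)
    offsets = grid.offsets()
    co_rows: list[tuple[str, str, float]] = []

    for chrom in grid.chromosomes:
        length = grid.chromosome_lengths[chrom]
        mean_co = config.recomb_rate * (length / 1e6) / CM_PER_MORGAN
        n_bins = grid.n_bins(chrom)
        mids = np.minimum(
            np.arange(n_bins) * config.bin_size + config.bin_size / 2, length - 0.5
        )
        counts = rng.poisson(mean_co, size=n)
        phases = rng.integers(0, 2, size=n)
        for i in range(n):
            pos = _place_crossovers(
                rng, length, int(counts[i]), config.min_co_spacing
            )
            # haplotype at a midpoint = phase + number of crossovers left of it
            flips = np.searchsorted(pos, mids)
            haplotype[i, offsets[chrom] : offsets[chrom] + n_bins] = (
                phases[i] + flips
            ) % 2
            for p in pos:
                co_rows.append((barcodes[i], chrom, float(p)))

    genotype = rng.integers(0, config.n_genotypes, size=n)
    ct_names = list(config.celltype_proportions)
    ct_probs = np.array([config.celltype_proportions[c] for c in ct_names])
    celltype = rng.choice(ct_names, size=n, p=ct_probs)
    return SimTruth(
        barcodes=barcodes,
        grid=grid,
        haplotype=haplotype,
        crossovers=pd.DataFrame(co_rows, columns=["barcode", "chrom", "position"]),
        genotype=genotype,
        celltype=celltype,
        doublet=np.zeros(n, dtype=bool),
        effects=list(config.eqtl_effects),
    )


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------


def _depth_mean_for_median(median: float, dispersion: float) -> float:
    """Negative-binomial mean whose distribution has roughly this median.

    A gamma-Poisson mixture inherits (approximately) the median of its gamma
    mixing distribution, which for shape ``r`` and mean ``mu`` sits at
    ``mu * gamma.ppf(0.5, r) / r``; invert that factor.
    """
    return median * dispersion / gamma_dist.ppf(0.5, dispersion)


def simulate_marker_matrix(
    truth: SimTruth,
    config: SimConfig,
    density_profile: np.ndarray | None = None,
) -> MarkerMatrix:
    """Draw sparse binned haplotype-marker counts for each nucleus.

    Per-nucleus totals are negative binomial (median ~= the configured
    marker depth; marker counts in real pools are overdispersed). Markers
    land in bins proportional to ``density_profile`` (uniform by default;
    real marker density tracks gene expression and collapses in
    centromeres). Each marker reports its bin's true haplotype with
    probability ``1 - ambient_fraction``; otherwise its haplotype is drawn
    from the pool-wide per-bin haplotype frequencies (the ambient
    background).
    """
    rng = _rng(config, 2)
    grid = truth.grid
    n, n_bins = truth.n_nuclei, grid.total_bins
    if density_profile is None:
        density_profile = np.ones(n_bins)
    density_profile = np.asarray(density_profile, dtype=float)
    if density_profile.shape != (n_bins,) or (density_profile < 0).any():
        raise ValueError("density_profile must be non-negative, one weight per bin")
    if density_profile.sum() <= 0:
        raise ValueError("density_profile is all zero")
    p_bins = density_profile / density_profile.sum()

    r = config.marker_depth_dispersion
    mu = _depth_mean_for_median(config.marker_depth_median, r)
    lam = rng.gamma(shape=r, scale=mu / r, size=n)
    depths = rng.poisson(lam)

    # pool-wide background: per-bin frequency of the parent-2 haplotype
    bg_p2 = truth.haplotype.mean(axis=0)  # (n_bins,)

    per_bin = rng.multinomial(depths, p_bins)  # (n, n_bins)
    amb = rng.binomial(per_bin, config.ambient_fraction)
    native = per_bin - amb
    amb_p2 = rng.binomial(amb, bg_p2[None, :])
    hap = truth.haplotype
    counts = np.empty((n, n_bins, 2), dtype=float)
    counts[:, :, 1] = native * (hap == 1) + amb_p2
    counts[:, :, 0] = native * (hap == 0) + (amb - amb_p2)
    return MarkerMatrix(counts=counts, barcodes=list(truth.barcodes), grid=grid)


# ---------------------------------------------------------------------------
# Allele counts (demultiplexing input)
# ---------------------------------------------------------------------------


def random_variant_panel(
    grid: BinGrid,
    n_genotypes: int,
    n_positions: int,
    carrier_prob: float = 0.5,
    seed: int = 0,
    genotype_names: list[str] | None = None,
) -> VariantPanel:
    """A synthetic parent-2 variant panel on the bin grid.

    Positions are uniform over the genome; each genotype carries each
    alternate allele independently with ``carrier_prob`` (positions with no
    carrier are re-drawn, mirroring a panel restricted to sites that
    distinguish at least one accession from the reference parent).
    """
    rng = np.random.default_rng(seed)
    if genotype_names is None:
        genotype_names = [f"G{g}" for g in range(n_genotypes)]
    chroms = grid.chromosomes
    lengths = np.array([grid.chromosome_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    carriers = np.zeros((n_positions, n_genotypes), dtype=bool)
    seen: set[tuple[str, int]] = set()
    bases = np.array(list("ACGT"))
    j = 0
    while j < n_positions:
        ci = rng.choice(len(chroms), p=probs)
        pos = int(rng.integers(0, grid.chromosome_lengths[chroms[ci]]))
        if (chroms[ci], pos) in seen:
            continue
        row_carriers = rng.random(n_genotypes) < carrier_prob
        if not row_carriers.any():
            continue
        seen.add((chroms[ci], pos))
        ref, alt = rng.choice(bases, size=2, replace=False)
        rows.append((chroms[ci], pos, ref, alt))
        carriers[j] = row_carriers
        j += 1
    positions = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    order = positions.sort_values(["chrom", "pos"]).index.to_numpy()
    return VariantPanel(
        positions=positions.loc[order].reset_index(drop=True),
        carrier_matrix=carriers[order],
        genotype_names=genotype_names,
    )


def simulate_allele_counts(
    truth: SimTruth,
    panel: VariantPanel,
    config: SimConfig,
    mean_umis_per_position: float = 0.5,
) -> AlleleCountTable:
    """Emulate an allele counter's per-barcode ref/alt UMI table.

    A nucleus emits alt UMIs at panel positions where its genotype carries
    the alternate allele *and* the position's bin was inherited from
    parent 2; elsewhere it emits ref UMIs. An ``ambient_fraction`` of UMIs
    is replaced by draws from the pool-wide allele frequency at the
    position.
    """
    if panel.n_positions == 0:
        raise ValueError("empty variant panel")
    rng = _rng(config, 3)
    grid = truth.grid
    offsets = grid.offsets()
    pos_bins = np.array(
        [
            offsets[c] + p // grid.bin_size
            for c, p in zip(panel.positions["chrom"], panel.positions["pos"])
        ]
    )
    n, m = truth.n_nuclei, panel.n_positions
    carriers = panel.carrier_matrix  # (m, N)

    # per-position truth: nucleus emits alt iff carrier AND parent-2 bin
    hap_at_pos = truth.haplotype[:, pos_bins]  # (n, m)
    is_alt = carriers.T[truth.genotype] & (hap_at_pos == 1)  # (n, m) bool
    pool_alt_freq = is_alt.mean(axis=0)  # (m,)

    umis = rng.poisson(mean_umis_per_position, size=(n, m))
    amb = rng.binomial(umis, config.ambient_fraction)
    native = umis - amb
    alt = np.where(is_alt, native, 0) + rng.binomial(amb, pool_alt_freq[None, :])
    ref = umis - alt
    return AlleleCountTable(
        ref=sp.csr_matrix(ref),
        alt=sp.csr_matrix(alt),
        barcodes=list(truth.barcodes),
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(truth: SimTruth, config: SimConfig) -> ad.AnnData:
    """Draw a barcode x gene UMI count matrix with configured eQTL effects.

    Each gene has a baseline log2 mean expression fraction; a subset of
    genes forms a cell-type program (shifted by ``celltype_program_log2fc``
    in the first cell type) so that sperm and vegetative nuclei separate in
    PC space. For each configured effect, nuclei carrying the parent-2
    haplotype at the causal bin (and matching the effect's genotype/cell
    type restriction) have the gene's log2 mean shifted by the effect size.
    Counts are Poisson-lognormal: per-nucleus depth x 2**(log2 mean +
    normal noise).
    """
    rng = _rng(config, 4)
    n, g = truth.n_nuclei, config.n_genes
    genes = [f"GENE{j:04d}" for j in range(g)]
    gene_index = {name: j for j, name in enumerate(genes)}
    offsets = truth.grid.offsets()

    base = rng.normal(0.0, 1.0, size=g)  # log2 relative expression
    ct_names = list(config.celltype_proportions)
    program = np.zeros((len(ct_names), g))
    prog_genes = rng.choice(g, size=min(config.celltype_program_genes, g), replace=False)
    half = len(prog_genes) // 2
    # first cell type up-regulates half the program, second the other half
    program[0, prog_genes[:half]] = config.celltype_program_log2fc
    if len(ct_names) > 1:
        program[1, prog_genes[half:]] = config.celltype_program_log2fc
    ct_idx = np.array([ct_names.index(c) for c in truth.celltype])

    log2_mean = base[None, :] + program[ct_idx]  # (n, g)
    for eff in truth.effects:
        if eff.gene not in gene_index:
            raise ValueError(f"effect on unknown gene {eff.gene}")
        j = gene_index[eff.gene]
        b = offsets[eff.chrom] + eff.bin_index
        affected = truth.haplotype[:, b] == 1
        if eff.genotypes is not None:
            affected &= np.isin(truth.genotype, list(eff.genotypes))
        if eff.celltype is not None:
            affected &= truth.celltype == eff.celltype
        log2_mean[affected, j] += eff.effect_size

    noise = rng.normal(0.0, config.expression_noise_sd, size=(n, g))
    rel = 2.0 ** (log2_mean + noise)
    rel /= rel.sum(axis=1, keepdims=True)
    depth = rng.lognormal(
        np.log(config.mean_expression_depth), 0.3, size=n
    )
    counts = rng.poisson(depth[:, None] * rel)

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.float32)),
        obs=pd.DataFrame(
            {
                "genotype": truth.genotype,
                "celltype": truth.celltype,
                "doublet": truth.doublet,
            },
            index=truth.barcodes,
        ),
        var=pd.DataFrame(index=genes),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


def inject_artifacts(
    expr: ad.AnnData,
    markers: MarkerMatrix,
    counts: AlleleCountTable | None,
    truth: SimTruth,
    config: SimConfig,
) -> tuple[ad.AnnData, MarkerMatrix, AlleleCountTable | None, SimTruth]:
    """Replace random barcode pairs with doublets.

    ``doublet_fraction`` of the final barcodes are doublets: a pair of
    nuclei merged under one barcode — expression and allele counts are the
    pair's sums, markers the union. The first member's barcode is kept and
    the second member is removed from the pool.
    """
    if config.doublet_fraction == 0:
        return expr, markers, counts, truth
    rng = _rng(config, 5)
    n = truth.n_nuclei
    n_dbl = int(round(config.doublet_fraction * n / (1 + config.doublet_fraction)))
    if n_dbl == 0:
        return expr, markers, counts, truth
    picks = rng.choice(n, size=2 * n_dbl, replace=False)
    hosts, partners = picks[:n_dbl], picks[n_dbl:]

    X = expr.layers["counts"].toarray()
    X[hosts] += X[partners]
    mk = markers.counts.copy()
    mk[hosts] += mk[partners]
    keep = np.setdiff1d(np.arange(n), partners)

    doublet = truth.doublet.copy()
    doublet[hosts] = True
    cross = np.zeros(n, dtype=bool)
    cross[hosts] = truth.celltype[hosts] != truth.celltype[partners]
    new_truth = SimTruth(
        barcodes=[truth.barcodes[i] for i in keep],
        grid=truth.grid,
        haplotype=truth.haplotype[keep],
        crossovers=truth.crossovers[
            truth.crossovers["barcode"].isin({truth.barcodes[i] for i in keep})
        ].reset_index(drop=True),
        genotype=truth.genotype[keep],
        celltype=truth.celltype[keep],
        doublet=doublet[keep],
        doublet_cross_type=cross[keep],
        effects=list(truth.effects),
    )
    new_expr = ad.AnnData(
        X=sp.csr_matrix(X[keep]),
        obs=expr.obs.iloc[keep].assign(doublet=doublet[keep]),
        var=expr.var.copy(),
    )
    new_expr.layers["counts"] = new_expr.X.copy()
    new_markers = MarkerMatrix(
        counts=mk[keep],
        barcodes=new_truth.barcodes,
        grid=markers.grid,
        bin_mask=markers.bin_mask.copy(),
    )
    new_counts = counts
    if counts is not None:
        ref = counts.ref.toarray()
        alt = counts.alt.toarray()
        ref[hosts] += ref[partners]
        alt[hosts] += alt[partners]
        new_counts = AlleleCountTable(
            ref=sp.csr_matrix(ref[keep]),
            alt=sp.csr_matrix(alt[keep]),
            barcodes=new_truth.barcodes,
        )
    return new_expr, new_markers, new_counts, new_truth
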