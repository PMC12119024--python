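"""Probabilistic-haplotype eQTL mapping.

For each gene x and 25 kb bin p, expression is modelled by ordinary least
squares::

    Exprs_x ~ Haplo_p1 + ... + Haplo_pN + Geno_1 + ... + Geno_{N-1} + PC_1 + ... + PC_M

where ``Haplo_pn`` is the posterior probability of parent-2 inheritance at
bin p (zeroed for nuclei not of genotype n), ``Geno_n`` are genotype
dummies and ``PC_i`` expression principal components. The haplotype block
is tested with a likelihood-ratio test against the nested model without it;
LRT statistics convert to LOD scores (LOD = LRT / (2 ln 10)). Multiple
testing across bins uses the Li-Ji effective number of independent
haplotypes for Bonferroni correction, then Benjamini-Hochberg FDR across
genes; peaks are called on per-gene LOD profiles with a 1.5-LOD-drop
confidence interval and classified cis/trans by a 2 Mb window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad
from scipy import signal, stats
from scipy.linalg import solve_triangular
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .markers import BinGrid
from .rhmm import HaplotypeField

logger = logging.getLogger(__name__)

TWO_LN10 = 2.0 * np.log(10.0)


# ---------------------------------------------------------------------------
# Expression preprocessing
# ---------------------------------------------------------------------------


def normalize_counts(counts: np.ndarray, scale: float = 10_000.0) -> np.ndarray:
    """Depth-normalize and log2-transform: ``log2(1 + c * scale / total)``."""
    counts = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    totals = counts.sum(axis=1, keepdims=True)
    totals = np.maximum(totals, 1.0)
    return np.log2(1.0 + counts * scale / totals)


def preprocess_expression(
    adata: ad.AnnData,
    min_barcodes: int = 10,
    min_cell_fraction: float = 0.05,
    n_pcs: int = 10,
    scale: float = 10_000.0,
    seed: int = 0,
) -> ad.AnnData:
    """Filter, normalize and embed a barcode x gene count matrix.

    Genes detected in fewer than ``min_barcodes`` barcodes are removed
    before normalization and PCA; genes detected in at least
    ``min_cell_fraction`` of nuclei (inclusive) are additionally flagged in
    ``var['eqtl_phenotype']`` as usable eQTL phenotypes. Adds a
    ``normalized`` layer, ``obsm['X_pca']`` and the fitted PCA model in
    ``uns['pca_model']``.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty expression matrix")
    counts = adata.layers.get("counts", adata.X)
    counts = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    detected = (counts > 0).sum(axis=0)
    keep = detected >= min_barcodes
    out = adata[:, keep].copy()
    counts = counts[:, keep]
    out.layers["counts"] = sp.csr_matrix(counts)
    out.layers["normalized"] = normalize_counts(counts, scale=scale)
    out.var["eqtl_phenotype"] = (counts > 0).mean(axis=0) >= min_cell_fraction

    n_pcs = min(n_pcs, out.n_obs - 1, out.n_vars - 1)
    pca = PCA(n_components=n_pcs, random_state=seed)
    out.obsm["X_pca"] = pca.fit_transform(out.layers["normalized"])
    out.uns["pca_model"] = pca
    return out


def assign_celltypes(
    adata: ad.AnnData, n_pcs: int = 2, seed: int = 0
) -> np.ndarray:
    """Soft cell-type probabilities from a 2-component Gaussian mixture.

    Fit on the first ``n_pcs`` PC scores; component order is fixed by mean
    PC1 (descending) so results are reproducible. Stores the (n, 2) matrix
    in ``obsm['celltype_prob']`` and returns it.
    """
    pcs = adata.obsm["X_pca"][:, :n_pcs]
    gmm = GaussianMixture(n_components=2, random_state=seed).fit(pcs)
    order = np.argsort(-gmm.means_[:, 0])
    probs = gmm.predict_proba(pcs)[:, order]
    adata.obsm["celltype_prob"] = probs
    return probs


# ---------------------------------------------------------------------------
# Bin-wise linear models
# ---------------------------------------------------------------------------


@dataclass
class EqtlResult:
    """Per (gene, bin) association statistics for one scan."""

    genes: list[str]
    grid: BinGrid
    lrt: np.ndarray  # (G, B)
    lod: np.ndarray  # (G, B)
    p: np.ndarray  # (G, B)
    df: np.ndarray  # (B,) haplotype regressors retained per bin
    bin_mask: np.ndarray  # (B,) bins actually tested
    coef: np.ndarray | None = None  # (N, G, B) per-genotype haplotype betas
    coef_p: np.ndarray | None = None  # (N, G, B)
    genotype_names: list[str] | None = None
    meff: float | None = None
    p_adj: np.ndarray | None = None  # (G, B)
    gene_fdr: np.ndarray | None = None  # (G,)

    def to_frame(self) -> pd.DataFrame:
        table = self.grid.table()
        recs = []
        for gi, gene in enumerate(self.genes):
            df = table.copy()
            df["gene"] = gene
            df["lrt"] = self.lrt[gi]
            df["lod"] = self.lod[gi]
            df["p"] = self.p[gi]
            if self.p_adj is not None:
                df["p_adj"] = self.p_adj[gi]
            recs.append(df[self.bin_mask])
        return pd.concat(recs, ignore_index=True)


def _residualize(Qz: np.ndarray, M: np.ndarray) -> np.ndarray:
    return M - Qz @ (Qz.T @ M)


def _orthonormal(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of Z (rank-revealing)."""
    q, r = np.linalg.qr(Z)
    keep = np.abs(np.diag(r)) > 1e-9 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def fit_bin_models(
    Y: np.ndarray,
    genes: list[str],
    haplotypes: HaplotypeField | np.ndarray,
    grid: BinGrid | None = None,
    genotype: np.ndarray | None = None,
    n_genotypes: int | None = None,
    genotype_names: list[str] | None = None,
    pcs: np.ndarray | None = None,
    n_pcs: int = 2,
    bin_mask: np.ndarray | None = None,
    interactions: np.ndarray | None = None,
) -> EqtlResult:
    """OLS scan of every (gene, bin) pair with a haplotype-block LRT.

    ``Y`` is the (nuclei x genes) log2 expression phenotype matrix,
    ``haplotypes`` the posterior parent-2 probabilities (nuclei x bins).
    Covariates (intercept, genotype dummies, the first ``n_pcs`` PCs) are
    projected out of phenotypes and haplotype regressors once
    (Frisch-Waugh-Lovell); each bin then needs only a small QR. With
    ``interactions`` (nuclei x T cell-type probabilities), the per-bin
    regressors become ``CT_t x Haplo_p`` instead of genotype-split
    haplotypes. Rank-deficient bins (constant haplotype, missing genotype)
    drop the offending regressors; a bin with no usable regressor gets
    LRT = 0.

    The LRT against the nested model without the haplotype block is
    ``n * ln(RSS_nested / RSS_full)`` with a chi-square reference on the
    number of retained regressors; ``LOD = LRT / (2 ln 10)``.
    """
    if isinstance(haplotypes, HaplotypeField):
        H = haplotypes.posterior
        grid = haplotypes.grid
    else:
        H = np.asarray(haplotypes)
        if grid is None:
            raise ValueError("grid required when haplotypes is an array")
    Y = np.asarray(Y, dtype=float)
    n, G = Y.shape
    B = H.shape[1]
    if bin_mask is None:
        bin_mask = np.ones(B, dtype=bool)

    if interactions is not None:
        T = interactions.shape[1]
        groups = interactions  # (n, T) soft weights
        names = genotype_names or [f"CT{t}" for t in range(T)]
        Zparts = [np.ones((n, 1)), interactions[:, : T - 1]]
    elif genotype is not None and (n_genotypes or genotype.max() + 1) > 1:
        N = int(n_genotypes or genotype.max() + 1)
        onehot = np.zeros((n, N))
        onehot[np.arange(n), genotype] = 1.0
        groups = onehot
        names = genotype_names or [f"G{g}" for g in range(N)]
        Zparts = [np.ones((n, 1)), onehot[:, : N - 1]]
    else:
        groups = np.ones((n, 1))
        names = genotype_names or ["all"]
        Zparts = [np.ones((n, 1))]
    if pcs is not None and n_pcs > 0:
        Zparts.append(np.asarray(pcs)[:, :n_pcs])
    Z = np.hstack(Zparts)
    Qz = _orthonormal(Z)
    k0 = Qz.shape[1]

    Yres = _residualize(Qz, Y)
    RSS0 = (Yres**2).sum(axis=0)
    ok_gene = RSS0 > 1e-12
    N = groups.shape[1]

    lrt = np.zeros((G, B))
    dfs = np.zeros(B, dtype=int)
    coef = np.full((N, G, B), np.nan)
    coef_p = np.full((N, G, B), np.nan)

    norm_tol = 1e-8 * np.sqrt(n)
    for b in np.flatnonzero(bin_mask):
        X = groups * H[:, b][:, None]  # (n, N)
        Xres = _residualize(Qz, X)
        norms = np.linalg.norm(Xres, axis=0)
        keep = norms > norm_tol
        k = int(keep.sum())
        dfs[b] = k
        if k == 0:
            continue
        q, r = np.linalg.qr(Xres[:, keep])
        C = q.T @ Yres  # (k, G)
        RSS1 = np.maximum(RSS0 - (C**2).sum(axis=0), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(ok_gene, n * np.log(RSS0 / RSS1), 0.0)
        lrt[:, b] = np.maximum(lam, 0.0)
        # per-regressor coefficients and t-tests
        beta = solve_triangular(r, C)  # (k, G)
        rinv = solve_triangular(r, np.eye(k))
        var_unit = (rinv**2).sum(axis=1)  # diag (X'X)^-1
        dof = max(n - k0 - k, 1)
        sigma2 = RSS1 / dof
        se = np.sqrt(var_unit[:, None] * sigma2[None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        coef[keep, :, b] = beta
        coef_p[keep, :, b] = pvals

    lod = lrt / TWO_LN10
    p = np.ones((G, B))
    tested = bin_mask & (dfs > 0)
    p[:, tested] = stats.chi2.sf(lrt[:, tested], dfs[tested][None, :])
    return EqtlResult(
        genes=list(genes),
        grid=grid,
        lrt=lrt,
        lod=lod,
        p=p,
        df=dfs,
        bin_mask=np.asarray(bin_mask, bool),
        coef=coef,
        coef_p=coef_p,
        genotype_names=list(names),
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def li_ji_meff(H: np.ndarray) -> float:
    """Li-Ji effective number of independent tests among haplotype bins.

    From the eigenvalues ``lam_i`` of the bin-bin correlation matrix:
    ``Meff = sum_i [ 1(lam_i >= 1) + (lam_i - floor(lam_i)) ]``. Constant
    bins carry no test and are excluded. When nuclei are fewer than bins the
    spectrum is computed from the smaller Gram matrix (the nonzero
    eigenvalues coincide; zero eigenvalues contribute nothing).
    """
    H = np.asarray(H, dtype=float)
    sd = H.std(axis=0)
    Hn = H[:, sd > 0]
    n, m = Hn.shape
    if m == 0:
        return 0.0
    Z = (Hn - Hn.mean(axis=0)) / (Hn.std(axis=0) * np.sqrt(n))
    if n < m:
        gram = Z @ Z.T
    else:
        gram = Z.T @ Z
    lam = np.clip(np.linalg.eigvalsh(gram), 0.0, None)
    # the floor is discontinuous at integers: snap eigenvalues that are
    # integer up to numerical error, or a 7.999... eigenvalue would
    # contribute a spurious fractional part of ~1
    near = np.rint(lam)
    lam = np.where(np.abs(lam - near) < 1e-8 * max(len(lam), 1), near, lam)
    meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return meff


def correct_multiple_testing(
    result: EqtlResult, haplotypes: HaplotypeField | np.ndarray
) -> EqtlResult:
    """Meff-Bonferroni within the scan, then BH FDR across genes.

    Adjusted p per (gene, bin) is ``min(1, p * Meff)``; each gene's minimum
    adjusted p enters a Benjamini-Hochberg correction across genes, giving
    the gene-level FDR used for significance calls.
    """
    H = (
        haplotypes.posterior
        if isinstance(haplotypes, HaplotypeField)
        else np.asarray(haplotypes)
    )
    meff = li_ji_meff(H[:, result.bin_mask])
    result.meff = meff
    result.p_adj = np.minimum(result.p * max(meff, 1.0), 1.0)
    min_adj = result.p_adj[:, result.bin_mask].min(axis=1)
    _, fdr, _, _ = multipletests(min_adj, method="fdr_bh")
    result.gene_fdr = fdr
    return result


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "gene",
    "chrom",
    "bin",
    "position",
    "lod",
    "ci_lo",
    "ci_hi",
    "celltype",
]


def call_peaks(
    result: EqtlResult,
    lod_min: float = 3.0,
    fdr: float = 0.05,
    prominence_frac: float = 0.25,
    min_distance: int = 3_000_000,
    lod_drop: float = 1.5,
    celltype: str = "all",
    lod_override: np.ndarray | None = None,
) -> pd.DataFrame:
    """Call per-gene eQTL peaks on the LOD profiles.

    Local maxima with topographic prominence >= ``prominence_frac`` of the
    gene's highest LOD and >= ``min_distance`` apart are retained when peak
    LOD >= ``lod_min``, the peak bin's Meff-adjusted p < ``fdr`` and the
    gene-level FDR < ``fdr``. The confidence interval is the maximal
    contiguous bin run around the peak with LOD >= peak - ``lod_drop``,
    reported in nt. Requires :func:`correct_multiple_testing` first.
    """
    if result.p_adj is None or result.gene_fdr is None:
        raise ValueError("run correct_multiple_testing before peak calling")
    grid = result.grid
    offsets = grid.offsets()
    dist_bins = max(1, int(round(min_distance / grid.bin_size)))
    lods = lod_override if lod_override is not None else result.lod
    rows = []
    for gi, gene in enumerate(result.genes):
        profile = np.where(result.bin_mask, lods[gi], 0.0)
        top = profile.max()
        if top < lod_min or result.gene_fdr[gi] >= fdr:
            continue
        prom = prominence_frac * top
        for chrom in grid.chromosomes:
            off, nb = offsets[chrom], grid.n_bins(chrom)
            prof = profile[off : off + nb]
            padded = np.r_[-1e30, prof, -1e30]
            peaks, _ = signal.find_peaks(
                padded, prominence=prom, distance=dist_bins
            )
            for pk in peaks - 1:
                # plateau maxima take the leftmost bin
                while pk > 0 and prof[pk - 1] == prof[pk]:
                    pk -= 1
                if prof[pk] < lod_min:
                    continue
                if result.p_adj[gi, off + pk] >= fdr:
                    continue
                lo = pk
                while lo > 0 and prof[lo - 1] >= prof[pk] - lod_drop:
                    lo -= 1
                hi = pk
                while hi < nb - 1 and prof[hi + 1] >= prof[pk] - lod_drop:
                    hi += 1
                rows.append(
                    (
                        gene,
                        chrom,
                        pk,
                        (pk + 0.5) * grid.bin_size,
                        float(prof[pk]),
                        lo * grid.bin_size,
                        min((hi + 1) * grid.bin_size, grid.chromosome_lengths[chrom]),
                        celltype,
                    )
                )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def classify_peaks(
    peaks: pd.DataFrame, gene_coords: pd.DataFrame, cis_window: int = 2_000_000
) -> pd.DataFrame:
    """Label peaks cis or trans from gene coordinates.

    A peak is cis when its confidence interval lies on the gene's chromosome
    and intersects ``[gene_start - cis_window, gene_end + cis_window]``
    (inclusive at the boundary); everything else is trans.
    """
    coords = gene_coords.set_index("gene")
    missing = set(peaks["gene"]) - set(coords.index)
    if missing:
        raise ValueError(f"unknown gene coordinates: {sorted(missing)[:5]}")
    out = peaks.copy()
    classes = []
    for _, row in out.iterrows():
        g = coords.loc[row["gene"]]
        same = g["chrom"] == row["chrom"]
        cis = same and (
            row["ci_hi"] >= g["start"] - cis_window
            and row["ci_lo"] <= g["end"] + cis_window
        )
        classes.append("cis" if cis else "trans")
    out["class"] = classes
    return out


# ---------------------------------------------------------------------------
# Cell-type interaction scan
# ---------------------------------------------------------------------------


def celltype_scan(
    Y: np.ndarray,
    genes: list[str],
    haplotypes: HaplotypeField,
    celltype_probs: np.ndarray,
    celltype_names: list[str] | None = None,
    pcs: np.ndarray | None = None,
    n_pcs: int = 2,
    bin_mask: np.ndarray | None = None,
    **peak_kwargs,
) -> tuple[EqtlResult, pd.DataFrame]:
    """eQTL scan with cell-type x haplotype interaction regressors.

    The model replaces the haplotype block with ``CT_t x Haplo_p`` for each
    cell type t while controlling for cell type (T-1 soft dummies) and PCs;
    the overall LRT drops all interaction terms. Peaks are called on the
    overall profile and, per cell type, on profiles built from the
    per-interaction-coefficient t statistics (``t^2 / (2 ln 10)``), so a
    cell-type-restricted effect surfaces under its own label.
    """
    T = celltype_probs.shape[1]
    if celltype_names is None:
        celltype_names = [f"CT{t}" for t in range(T)]
    active = celltype_probs.sum(axis=0) > 1e-9
    if active.sum() < T:
        logger.warning("cell type(s) absent; collapsing to present types")
        celltype_probs = celltype_probs[:, active]
        celltype_names = [c for c, a in zip(celltype_names, active) if a]
        T = celltype_probs.shape[1]
    result = fit_bin_models(
        Y,
        genes,
        haplotypes,
        pcs=pcs,
        n_pcs=n_pcs,
        bin_mask=bin_mask,
        interactions=celltype_probs,
        genotype_names=celltype_names,
    )
    result = correct_multiple_testing(result, haplotypes)
    peaks = [call_peaks(result, celltype="all", **peak_kwargs)]
    for t, name in enumerate(celltype_names):
        with np.errstate(invalid="ignore"):
            z2 = stats.norm.isf(np.clip(result.coef_p[t] / 2, 1e-300, 1.0)) ** 2
        lod_t = np.nan_to_num(z2) / TWO_LN10
        peaks.append(
            call_peaks(result, celltype=name, lod_override=lod_t, **peak_kwargs)
        )
    return result, pd.concat(peaks, ignore_index=True)


# ---------------------------------------------------------------------------
# Trans-hotspot fine mapping with latent phenotypes
# ---------------------------------------------------------------------------


def finemap_hotspot(
    adata: ad.AnnData,
    haplotypes: HaplotypeField,
    qc: pd.DataFrame,
    peaks: pd.DataFrame,
    hotspot: tuple[str, float],
    n_components: int = 5,
    min_nuclei: int = 50,
    min_genes: int = 10,
    sperm_prob: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Fine-map a trans-eQTL hotspot with latent expression phenotypes.

    Nuclei are filtered to confident singleton, non-artefact sperm nuclei
    (classifier probability > 0.95, doublet probability < 0.05, sperm
    probability > 0.95) with > 2.5 log10 markers; genes are filtered to
    those with a trans peak whose CI covers the hotspot and no cis peak.
    The filtered normalized matrix is decomposed into ``n_components``
    principal components; each component is scanned against all bins as a
    phenotype with the remaining components as covariates, and the
    strongest component's peak and 1.5-LOD-drop CI localize the hotspot.

    Returns a dict with the nucleus/gene filters, per-component results and
    the top component's peak (chrom, bin, position, ci_lo, ci_hi, lod).
    """
    chrom, pos = hotspot
    qc = qc.set_index("barcode").loc[adata.obs_names]
    keep_n = (
        (qc["classifier_prob"] > 0.95)
        & (qc["doublet_prob"] < 0.05)
        & (qc["log10_markers"] > 2.5)
    ).to_numpy()
    if sperm_prob is not None:
        keep_n &= np.asarray(sperm_prob) > 0.95

    at_hotspot = (
        (peaks["chrom"] == chrom)
        & (peaks["ci_lo"] <= pos)
        & (peaks["ci_hi"] >= pos)
        & (peaks["class"] == "trans")
    )
    trans_genes = set(peaks.loc[at_hotspot, "gene"])
    cis_genes = set(peaks.loc[peaks["class"] == "cis", "gene"])
    genes = sorted(trans_genes - cis_genes)
    if keep_n.sum() < min_nuclei:
        raise ValueError(f"only {keep_n.sum()} nuclei pass the hotspot filters")
    if len(genes) < min_genes:
        raise ValueError(f"only {len(genes)} genes pass the hotspot filters")

    sub = adata[keep_n, genes]
    Y = np.asarray(sub.layers["normalized"])
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(Y)

    Hsub = HaplotypeField(
        posterior=haplotypes.posterior[keep_n],
        viterbi=haplotypes.viterbi[keep_n],
        boundary_prob=haplotypes.boundary_prob[keep_n],
        expected_crossovers=haplotypes.expected_crossovers[keep_n],
        barcodes=[b for b, k in zip(haplotypes.barcodes, keep_n) if k],
        grid=haplotypes.grid,
    )
    results = []
    best = None
    for k in range(n_components):
        others = np.delete(scores, k, axis=1)
        res = fit_bin_models(
            scores[:, [k]],
            [f"PC{k + 1}"],
            Hsub,
            pcs=others,
            n_pcs=others.shape[1],
        )
        res = correct_multiple_testing(res, Hsub)
        results.append(res)
        top_lod = res.lod[0].max()
        if best is None or top_lod > best[0]:
            best = (top_lod, k, res)

    top_lod, k, res = best
    grid = haplotypes.grid
    offsets = grid.offsets()
    b = int(res.lod[0].argmax())
    # locate chromosome and 1.5-LOD-drop CI around the top bin
    for c in grid.chromosomes:
        off, nb = offsets[c], grid.n_bins(c)
        if off <= b < off + nb:
            prof = res.lod[0, off : off + nb]
            pk = b - off
            lo = pk
            while lo > 0 and prof[lo - 1] >= prof[pk] - 1.5:
                lo -= 1
            hi = pk
            while hi < nb - 1 and prof[hi + 1] >= prof[pk] - 1.5:
                hi += 1
            peak = {
                "component": k + 1,
                "chrom": c,
                "bin": pk,
                "position": (pk + 0.5) * grid.bin_size,
                "ci_lo": lo * grid.bin_size,
                "ci_hi": min((hi + 1) * grid.bin_size, grid.chromosome_lengths[c]),
                "lod": float(top_lod),
            }
            break
    return {
        "n_nuclei": int(keep_n.sum()),
        "genes": genes,
        "components": results,
        "peak": peak,
        "nucleus_filter": keep_n,
    }
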