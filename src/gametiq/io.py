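"""Readers and writers for the pipeline's on-disk formats.

Variant panels travel as VCF (one sample column per parent-2 accession,
haploid GT); allele counts and expression matrices as MatrixMarket with
barcode/feature TSVs; markers, haplotype posteriors, crossover calls, QC
and eQTL tables as TSV; the bin grid and mask as BED.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io as sio
import anndata as ad

from .demux import AlleleCountTable, VariantPanel
from .markers import BinGrid, MarkerMatrix
from .rhmm import HaplotypeField


# -- VCF panels -------------------------------------------------------------


def write_panel_vcf(panel: VariantPanel, path: str) -> None:
    """Write a variant panel as a minimal VCF with haploid genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = panel.positions["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(panel.genotype_names)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, (_, row) in enumerate(panel.positions.iterrows()):
            gts = "\t".join(
                "1" if panel.carrier_matrix[j, g] else "0"
                for g in range(panel.n_genotypes)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos'] + 1}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_panel_vcf(path: str) -> VariantPanel:
    """Read a variant panel from VCF (biallelic records only)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    names = list(vcf.samples)
    rows, carriers = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        rows.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        gts = rec.genotypes  # [[allele, ...phased], ...]
        carriers.append([g[0] == 1 for g in gts])
    return VariantPanel(
        positions=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]),
        carrier_matrix=np.array(carriers, dtype=bool),
        genotype_names=names,
    )


# -- allele counts ----------------------------------------------------------


def write_allele_counts(counts: AlleleCountTable, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    sio.mmwrite(os.path.join(outdir, "ref.mtx"), counts.ref)
    sio.mmwrite(os.path.join(outdir, "alt.mtx"), counts.alt)
    pd.Series(counts.barcodes).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )


def read_allele_counts(outdir: str) -> AlleleCountTable:
    ref = sp.csr_matrix(sio.mmread(os.path.join(outdir, "ref.mtx")))
    alt = sp.csr_matrix(sio.mmread(os.path.join(outdir, "alt.mtx")))
    barcodes = (
        pd.read_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", header=None)[0]
        .astype(str)
        .tolist()
    )
    return AlleleCountTable(ref=ref, alt=alt, barcodes=barcodes)


# -- expression -------------------------------------------------------------


def write_expression(adata: ad.AnnData, outdir: str) -> None:
    """MatrixMarket + barcodes.tsv + features.tsv (CellRanger-style layout)."""
    os.makedirs(outdir, exist_ok=True)
    X = adata.layers.get("counts", adata.X)
    X = sp.csr_matrix(X)
    sio.mmwrite(os.path.join(outdir, "matrix.mtx"), X.T)  # features x barcodes
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", index=False, header=False
    )


def read_expression(outdir: str) -> ad.AnnData:
    X = sp.csr_matrix(sio.mmread(os.path.join(outdir, "matrix.mtx"))).T
    barcodes = (
        pd.read_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", header=None)[0]
        .astype(str)
        .tolist()
    )
    features = (
        pd.read_csv(os.path.join(outdir, "features.tsv"), sep="\t", header=None)[0]
        .astype(str)
        .tolist()
    )
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=features),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


# -- markers ----------------------------------------------------------------


def write_marker_matrix(matrix: MarkerMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_matrix(
    path: str, grid: BinGrid, barcodes: list[str] | None = None
) -> MarkerMatrix:
    from .markers import CHANNELS

    df = pd.read_csv(path, sep="\t")
    if barcodes is None:
        barcodes = sorted(df["barcode"].unique())
    bc_index = {b: i for i, b in enumerate(barcodes)}
    offsets = grid.offsets()
    counts = np.zeros((len(barcodes), grid.total_bins, 2))
    i = df["barcode"].map(bc_index).to_numpy()
    b = df["chrom"].map(offsets).to_numpy() + df["bin"].to_numpy()
    c = df["channel"].map({name: k for k, name in enumerate(CHANNELS)}).to_numpy()
    np.add.at(counts, (i, b, c), df["count"].to_numpy())
    return MarkerMatrix(counts=counts, barcodes=list(barcodes), grid=grid)


def write_bin_bed(grid: BinGrid, mask: np.ndarray, path: str) -> None:
    table = grid.table()
    table["usable"] = np.asarray(mask, dtype=int)
    table[["chrom", "start", "end", "usable"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# -- haplotype field --------------------------------------------------------


def write_haplotype_field(field: HaplotypeField, path: str) -> None:
    """Per-(barcode, bin) posterior / Viterbi / boundary probability TSV."""
    table = field.grid.table()
    n, B = field.posterior.shape
    df = pd.DataFrame(
        {
            "barcode": np.repeat(field.barcodes, B),
            "chrom": np.tile(table["chrom"].to_numpy(), n),
            "bin": np.tile(table["bin"].to_numpy(), n),
            "posterior_p2": field.posterior.ravel(),
            "viterbi": field.viterbi.ravel(),
            "boundary_prob": field.boundary_prob.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_field(path: str, grid: BinGrid) -> HaplotypeField:
    df = pd.read_csv(path, sep="\t")
    barcodes = list(dict.fromkeys(df["barcode"]))
    n, B = len(barcodes), grid.total_bins
    posterior = df["posterior_p2"].to_numpy().reshape(n, B)
    viterbi = df["viterbi"].to_numpy().reshape(n, B).astype(np.int8)
    boundary = df["boundary_prob"].to_numpy().reshape(n, B)
    return HaplotypeField(
        posterior=posterior,
        viterbi=viterbi,
        boundary_prob=boundary,
        expected_crossovers=boundary.sum(axis=1),
        barcodes=barcodes,
        grid=grid,
    )


def write_truth(truth, outdir: str) -> None:
    """Ground-truth tables of a simulation (haplotypes, crossovers, labels)."""
    os.makedirs(outdir, exist_ok=True)
    truth.crossovers.to_csv(
        os.path.join(outdir, "true_crossovers.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {
            "barcode": truth.barcodes,
            "genotype": truth.genotype,
            "celltype": truth.celltype,
            "doublet": truth.doublet,
        }
    ).to_csv(os.path.join(outdir, "true_labels.tsv"), sep="\t", index=False)
    table = truth.grid.table()
    n, B = truth.haplotype.shape
    pd.DataFrame(
        {
            "barcode": np.repeat(truth.barcodes, B),
            "chrom": np.tile(table["chrom"].to_numpy(), n),
            "bin": np.tile(table["bin"].to_numpy(), n),
            "haplotype": truth.haplotype.ravel(),
        }
    ).to_csv(os.path.join(outdir, "true_haplotypes.tsv"), sep="\t", index=False)
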