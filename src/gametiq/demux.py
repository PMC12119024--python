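"""Genotype demultiplexing of pooled recombinant haploid nuclei.

Each nucleus in the pool derives from one of N F1 hybrids sharing a common
reference parent. Positions where a barcode's reads support the alternate
allele by strict majority are informative of the parent-2 accession; a
mixture model over genotypes is fit by expectation maximization with
fractional assignment, and per-barcode confidence is estimated by
bootstrapping the informative positions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass
class VariantPanel:
    """Alternate-allele fingerprints of the parent-2 genotypes.

    ``positions`` has columns (chrom, pos, ref, alt) — biallelic variants at
    reference coordinates; ``carrier_matrix[j, g]`` is True when genotype
    ``g`` carries the alternate allele at position ``j``.
    """

    positions: pd.DataFrame
    carrier_matrix: np.ndarray  # (n_positions, n_genotypes) bool
    genotype_names: list[str]

    def __post_init__(self) -> None:
        if len(self.positions) != self.carrier_matrix.shape[0]:
            raise ValueError("positions/carrier_matrix length mismatch")
        if self.carrier_matrix.shape[1] != len(self.genotype_names):
            raise ValueError("carrier_matrix/genotype_names mismatch")
        keys = self.positions[["chrom", "pos"]]
        if keys.duplicated().any():
            raise ValueError("duplicate positions in panel")
        if self.carrier_matrix.any(axis=1).sum() < self.carrier_matrix.shape[0]:
            raise ValueError("every retained position needs >= 1 carrier")

    @property
    def n_genotypes(self) -> int:
        return self.carrier_matrix.shape[1]

    @property
    def n_positions(self) -> int:
        return self.carrier_matrix.shape[0]


@dataclass
class AlleleCountTable:
    """Sparse per-(barcode, panel position) ref/alt UMI counts."""

    ref: sp.csr_matrix  # (n_barcodes, n_positions)
    alt: sp.csr_matrix
    barcodes: list[str]

    def __post_init__(self) -> None:
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref/alt shape mismatch")
        if self.ref.shape[0] != len(self.barcodes):
            raise ValueError("barcode count mismatch")
        if (self.ref.data < 0).any() or (self.alt.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_barcodes(self) -> int:
        return self.ref.shape[0]


@dataclass
class GenotypePosterior:
    """Per-barcode genotype responsibilities with bootstrap confidence."""

    barcodes: list[str]
    genotype_names: list[str]
    point: np.ndarray  # (n_barcodes, N) EM responsibilities
    bootstrap_mean: np.ndarray  # (n_barcodes, N)
    assignment: np.ndarray  # (n_barcodes,) argmax of bootstrap_mean
    score: np.ndarray  # (n_barcodes,) Phred-like confidence
    n_informative: np.ndarray  # (n_barcodes,) int
    priors: np.ndarray  # (N,) converged genotype priors

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.bootstrap_mean,
            columns=[f"p_{g}" for g in self.genotype_names],
        )
        df.insert(0, "barcode", self.barcodes)
        df["assignment"] = [self.genotype_names[a] for a in self.assignment]
        df["score"] = self.score
        df["n_informative"] = self.n_informative
        return df


def select_informative_positions(counts: AlleleCountTable) -> sp.csr_matrix:
    """Per-barcode indicator of positions with a strict alt-UMI majority.

    Positions where the reference allele wins (or ties) are dropped: a
    reference majority is explained by inheritance from the shared reference
    parent and carries no information about the parent-2 accession.
    Returns a boolean CSR matrix (barcode x position).
    """
    informative = counts.alt > counts.ref
    return informative.tocsr()


def _log_likelihood_matrix(
    informative: sp.csr_matrix, panel: VariantPanel, error_rate: float
) -> np.ndarray:
    """Per-(barcode, genotype) log-likelihood of the observed alt pattern.

    Each observed alt-majority position contributes log(1 - e) if the
    genotype carries the alt allele there, log(e) otherwise. Counts beyond
    the majority call are not used — the observation is the SNP pattern.
    """
    if panel.n_positions == 0:
        raise ValueError("empty variant panel")
    carriers = panel.carrier_matrix.astype(float)
    contrib = np.log1p(-error_rate) * carriers + np.log(error_rate) * (1 - carriers)
    return informative.astype(float) @ contrib  # (n_barcodes, N)


def em_assign_genotypes(
    informative: sp.csr_matrix,
    panel: VariantPanel,
    error_rate: float = 0.05,
    max_iter: int = 1000,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional genotype assignment by expectation maximization.

    Starting from equal priors, the E-step computes per-barcode genotype
    responsibilities proportional to ``prior_g * likelihood_g``; the M-step
    re-estimates priors as the mean responsibility. Iteration stops when the
    L1 change of the prior vector falls below ``tol`` (the dataset-level
    "total change in probability") or after ``max_iter`` iterations.

    Returns ``(responsibilities, priors)``. Barcodes with no informative
    positions receive the prior as posterior (uniform likelihood) and are
    logged.
    """
    loglik = _log_likelihood_matrix(informative, panel, error_rate)
    n_empty = int((np.asarray(informative.sum(axis=1)).ravel() == 0).sum())
    if n_empty:
        logger.info("%d barcodes have no informative positions", n_empty)
    n_g = panel.n_genotypes
    priors = np.full(n_g, 1.0 / n_g)
    for _ in range(max_iter):
        resp = _responsibilities(loglik, priors)
        new_priors = resp.mean(axis=0)
        delta = np.abs(new_priors - priors).sum()
        priors = new_priors
        if delta < tol:
            break
    return _responsibilities(loglik, priors), priors


def _responsibilities(loglik: np.ndarray, priors: np.ndarray) -> np.ndarray:
    log_post = loglik + np.log(np.clip(priors, 1e-300, None))
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    return post / post.sum(axis=1, keepdims=True)


def bootstrap_genotype(
    counts: AlleleCountTable,
    panel: VariantPanel,
    n_boot: int = 25,
    error_rate: float = 0.05,
    max_iter: int = 1000,
    tol: float = 0.01,
    seed: int = 0,
) -> GenotypePosterior:
    """Full demultiplexing: EM point estimate plus bootstrap confidence.

    Per barcode, the informative positions are resampled with replacement
    ``n_boot`` times and the posterior recomputed under the genotype priors
    fixed at their full-data converged values; the assignment is the argmax
    of the mean bootstrap posterior and its mean probability feeds the
    Phred-like score. Barcodes without informative positions get a uniform
    posterior and score 0.
    """
    rng = np.random.default_rng(seed)
    informative = select_informative_positions(counts)
    point, priors = em_assign_genotypes(
        informative, panel, error_rate=error_rate, max_iter=max_iter, tol=tol
    )
    n_bc, n_g = point.shape
    carriers = panel.carrier_matrix.astype(float)
    contrib = np.log1p(-error_rate) * carriers + np.log(error_rate) * (1 - carriers)
    log_priors = np.log(np.clip(priors, 1e-300, None))

    boot_mean = np.zeros((n_bc, n_g))
    n_informative = np.asarray(informative.sum(axis=1)).ravel().astype(int)
    indptr, indices = informative.indptr, informative.indices
    for i in range(n_bc):
        pos = indices[indptr[i] : indptr[i + 1]]
        k = len(pos)
        if k == 0:
            boot_mean[i] = 1.0 / n_g
            continue
        # n_boot resamples at once: (n_boot, k) draws -> summed log contribs
        draws = rng.integers(0, k, size=(n_boot, k))
        ll = contrib[pos[draws]].sum(axis=1) + log_priors  # (n_boot, N)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        p /= p.sum(axis=1, keepdims=True)
        boot_mean[i] = p.mean(axis=0)

    assignment = boot_mean.argmax(axis=1)
    assigned_p = boot_mean[np.arange(n_bc), assignment]
    cap = 1.0 / (2.0 * n_boot * np.maximum(n_informative, 1) + 2.0)
    score = phred_score(np.minimum(assigned_p, 1.0 - cap))
    score[n_informative == 0] = 0.0
    return GenotypePosterior(
        barcodes=list(counts.barcodes),
        genotype_names=list(panel.genotype_names),
        point=point,
        bootstrap_mean=boot_mean,
        assignment=assignment,
        score=score,
        n_informative=n_informative,
        priors=priors,
    )


def phred_score(p: float | np.ndarray) -> np.ndarray:
    """Phred-like scaling of a probability: ``-log10(1 - p)``."""
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("probability outside [0, 1]")
    with np.errstate(divide="ignore"):
        return -np.log10(1.0 - arr)
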