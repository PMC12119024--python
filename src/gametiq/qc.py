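"""Nucleus whitelisting and doublet detection.

High-quality nuclei are separated from artefacts (doublets, ambient-heavy
or near-empty barcodes) using genotyping confidence, marker depth and the
decoder's fit metrics. Heuristic initial labels train a classifier whose
predicted probability gives the final whitelist; expression doublets are
flagged by comparing each barcode's neighbourhood in PC space against
synthetic cross-cluster doublets.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import anndata as ad
from sklearn.ensemble import RandomForestClassifier
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

POOLED_FEATURES = ["log10_markers", "genotype_score", "hmm_score", "hmm_uncertainty"]
SINGLE_FEATURES = ["hmm_score", "hmm_uncertainty"]


def initial_quality_labels(qc: pd.DataFrame, mode: str) -> np.ndarray:
    """Heuristic positive/negative labels for whitelist training.

    ``mode='pooled'`` (multi-genotype pools): positive where the genotyping
    probability exceeds the 25th percentile within the barcode's assigned
    genotype. ``mode='single'`` (one genotype, no genotyping score):
    positive where (hmm_score > 4 or hmm_uncertainty < 2.5) and
    log10_markers >= 2.5.
    """
    if mode == "pooled":
        for col in ("genotype_prob", "assignment"):
            if col not in qc:
                raise ValueError(f"pooled mode requires metric '{col}'")
        labels = np.zeros(len(qc), dtype=bool)
        for _, idx in qc.groupby("assignment").groups.items():
            probs = qc.loc[idx, "genotype_prob"]
            labels[qc.index.get_indexer(idx)] = probs > probs.quantile(0.25)
        return labels
    if mode == "single":
        for col in ("hmm_score", "hmm_uncertainty", "log10_markers"):
            if col not in qc:
                raise ValueError(f"single mode requires metric '{col}'")
        good_fit = (qc["hmm_score"] > 4) | (qc["hmm_uncertainty"] < 2.5)
        return (good_fit & (qc["log10_markers"] >= 2.5)).to_numpy()
    raise ValueError(f"unknown mode {mode!r}")


def fit_whitelist_classifier(
    qc: pd.DataFrame,
    labels: np.ndarray,
    mode: str,
    threshold: float = 0.5,
    n_trees: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Train the whitelist classifier on initial labels and score barcodes.

    Pooled mode fits a random forest on four metrics (log10 markers,
    genotyping score, HMM score, HMM uncertainty); single mode fits a
    2-component multivariate Gaussian mixture on (HMM score, HMM
    uncertainty), taking the component with the higher mean HMM score as
    high-quality. Returns ``qc`` with ``classifier_prob`` and ``pass``
    columns added.
    """
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("initial labels contain a single class")
    if min(n_pos, n_neg) < 20:
        logger.warning(
            "few labeled examples per class (%d/%d); classifier may be unstable",
            n_pos,
            n_neg,
        )
    out = qc.copy()
    if mode == "pooled":
        feats = out[POOLED_FEATURES].to_numpy()
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(feats, labels)
        prob = clf.predict_proba(feats)[:, list(clf.classes_).index(True)]
    elif mode == "single":
        feats = out[SINGLE_FEATURES].to_numpy()
        # labels seed the component means; EM then refines on all barcodes
        means_init = np.vstack([feats[labels].mean(axis=0), feats[~labels].mean(axis=0)])
        gmm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            means_init=means_init,
            random_state=seed,
        ).fit(feats)
        good = int(np.argmax(gmm.means_[:, SINGLE_FEATURES.index("hmm_score")]))
        prob = gmm.predict_proba(feats)[:, good]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["classifier_prob"] = prob
    out["pass"] = prob > threshold
    return out


def detect_expression_doublets(
    adata: ad.AnnData,
    k: int = 10,
    synth_fraction: float = 0.25,
    n_clusters: int = 2,
    threshold: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Score barcodes by proximity to synthetic cross-cluster doublets.

    Requires a normalized layer and PCA (see
    :func:`gametiq.eqtl.preprocess_expression`). Initial clusters are a
    Gaussian mixture over PC scores; synthetic doublets are depth-normalized
    sums of random cross-cluster barcode pairs, projected into the PCA basis
    fit on real barcodes. The doublet probability is the fraction of each
    barcode's ``k`` nearest neighbours (in PC space, over real + synthetic
    points) that are synthetic. Barcodes above ``threshold`` should be
    removed.
    """
    from .eqtl import normalize_counts  # local import to avoid cycle at import time

    if "X_pca" not in adata.obsm:
        raise ValueError("run preprocess_expression first (PCA missing)")
    rng = np.random.default_rng(seed)
    pcs = adata.obsm["X_pca"]
    n = adata.n_obs
    n_synth = int(round(synth_fraction * n))
    if n_synth == 0:
        return np.zeros(n)

    gmm = GaussianMixture(n_components=n_clusters, random_state=seed).fit(pcs)
    clusters = gmm.predict(pcs)
    if len(np.unique(clusters)) < 2:
        logger.warning("single expression cluster; doublet detection skipped")
        return np.zeros(n)

    counts = adata.layers["counts"]
    counts = counts.toarray() if hasattr(counts, "toarray") else np.asarray(counts)
    pairs = np.empty((n_synth, 2), dtype=int)
    cluster_ids = np.unique(clusters)
    for s in range(n_synth):
        ca, cb = rng.choice(cluster_ids, size=2, replace=False)
        pairs[s, 0] = rng.choice(np.flatnonzero(clusters == ca))
        pairs[s, 1] = rng.choice(np.flatnonzero(clusters == cb))
    synth_counts = counts[pairs[:, 0]] + counts[pairs[:, 1]]
    synth_norm = normalize_counts(synth_counts)
    # project into the PCA basis fit on real barcodes
    pca = adata.uns["pca_model"]
    synth_pcs = pca.transform(synth_norm)

    all_pcs = np.vstack([pcs, synth_pcs])
    is_synth = np.r_[np.zeros(n, dtype=bool), np.ones(n_synth, dtype=bool)]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(all_pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = idx[:, 1:]  # drop self
    return is_synth[neigh].mean(axis=1)


def build_qc_table(
    barcodes: list[str],
    marker_totals: np.ndarray,
    hmm_score: np.ndarray,
    hmm_uncertainty: np.ndarray,
    genotype_prob: np.ndarray | None = None,
    assignment: np.ndarray | None = None,
    genotype_score: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-barcode QC metric table."""
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "log10_markers": np.log10(np.maximum(marker_totals, 1)),
            "hmm_score": hmm_score,
            "hmm_uncertainty": hmm_uncertainty,
        }
    )
    if genotype_prob is not None:
        df["genotype_prob"] = genotype_prob
    if assignment is not None:
        df["assignment"] = assignment
    if genotype_score is not None:
        df["genotype_score"] = genotype_score
    return df
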