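"""Independent reference computations used to check the implementation.

These deliberately avoid the package's own algorithms: the HMM oracle
enumerates every legal micro-state path; the Bayes oracle computes a
single-barcode genotype posterior directly.
"""
from __future__ import annotations


import numpy as np
from scipy.stats import poisson


def enumerate_rhmm_posteriors(
    rigidity: int,
    terminal_rigidity: int,
    switch_prob: float,
    counts: np.ndarray,
    mask: np.ndarray,
    lam_fg: float,
    lam_bg: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact posteriors/boundary probabilities/Viterbi track by brute force.

    Recursively enumerates every legal micro-state path (legal transitions
    only: advance, stay at the free state, or switch from it; start
    micro-index >= R - T, end micro-index >= T - 1), accumulating each
    path's probability explicitly. Only feasible for a handful of bins.
    """
    n = counts.shape[0]
    R, T, s = rigidity, terminal_rigidity, switch_prob

    emit = np.ones((n, 2))
    for t in range(n):
        if not mask[t]:
            continue
        c = np.rint(counts[t])
        for h in (0, 1):
            fg, bg = (c[1], c[0]) if h == 1 else (c[0], c[1])
            emit[t, h] = poisson.pmf(fg, lam_fg) * poisson.pmf(bg, lam_bg)

    total = 0.0
    post = np.zeros(n)
    bnd = np.zeros(max(n - 1, 0))
    best = {"w": -1.0, "path": None}

    def successors(h: int, i: int):
        if i < R - 1:
            yield h, i + 1, 1.0
        else:
            yield h, R - 1, 1.0 - s
            yield 1 - h, 0, s

    def walk(t: int, h: int, i: int, w: float, path: list[int]) -> None:
        nonlocal total
        path.append(h)
        if t == n - 1:
            if i >= T - 1 and w > 0:
                total += w
                arr = np.array(path)
                post[arr == 1] += w
                if n > 1:
                    bnd[np.array(path[:-1]) != np.array(path[1:])] += w
                if w > best["w"]:
                    best["w"], best["path"] = w, list(path)
        else:
            for h2, j, p in successors(h, i):
                w2 = w * p * emit[t + 1, h2]
                if w2 > 0:
                    walk(t + 1, h2, j, w2, path)
        path.pop()

    for h in (0, 1):
        for i in range(R - T, R):
            w0 = (1.0 / (2 * T)) * emit[0, h]
            if w0 > 0:
                walk(0, h, i, w0, [])

    viterbi = np.array(best["path"], dtype=np.int8)
    return post / total, bnd / total, viterbi


def bayes_genotype_posterior(
    observed_positions: list[int],
    carrier_matrix: np.ndarray,
    error_rate: float,
    priors: np.ndarray | None = None,
) -> np.ndarray:
    """Direct Bayes posterior over genotypes for one barcode."""
    n_g = carrier_matrix.shape[1]
    if priors is None:
        priors = np.full(n_g, 1.0 / n_g)
    lik = np.ones(n_g)
    for pos in observed_positions:
        lik *= np.where(carrier_matrix[pos], 1.0 - error_rate, error_rate)
    post = priors * lik
    return post / post.sum()
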