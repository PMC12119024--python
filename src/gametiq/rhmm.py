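"""Rigid hidden Markov model for haploid haplotype decoding.

The decoder assigns each 25 kb bin of a gamete's genome to one of the two
parental haplotypes from sparse binned marker counts. Crossover
interference is encoded structurally: each haplotype macro-state is a chain
of ``rigidity`` micro-states, and after a haplotype switch the path must
traverse the whole chain (one micro-state per bin) before the next switch
is possible — so adjacent crossovers in any path are at least
``rigidity * bin_size`` apart (2.5 Mb at defaults). Because meiotic
interference does not suppress crossovers near chromosome ends, paths may
enter and exit a chain part-way at the termini, controlled by
``terminal_rigidity``: terminal haplotype segments may be as short as
``terminal_rigidity * bin_size`` (100 kb at defaults).

Emissions are a symmetric pair of Poissons: in the bin's foreground channel
(the haplotype the state represents) counts follow ``Poisson(lambda_fg)``,
in the other channel ``Poisson(lambda_bg)``, with the channels swapped
between the two macro-states. Masked bins emit with probability 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import RhmmConfig
from .markers import BinGrid, MarkerMatrix

__all__ = [
    "RigidHmm",
    "HaplotypeField",
    "CrossoverCall",
    "build_rhmm",
    "estimate_emissions",
    "decode_nuclei",
    "call_crossovers",
    "nucleus_fit_metrics",
]


@dataclass
class HaplotypeField:
    """Per-barcode, per-bin posterior haplotype probabilities.

    ``posterior[i, b]`` is P(bin ``b`` of barcode ``i`` inherited from
    parent 2); ``viterbi[i, b]`` the maximum-likelihood discrete track;
    ``boundary_prob[i, b]`` the posterior probability of a crossover between
    bins ``b`` and ``b+1`` (0 at each chromosome's last bin); and
    ``expected_crossovers`` the per-barcode sum of boundary probabilities.
    """

    posterior: np.ndarray  # (n_barcodes, n_bins)
    viterbi: np.ndarray  # (n_barcodes, n_bins) int8
    boundary_prob: np.ndarray  # (n_barcodes, n_bins)
    expected_crossovers: np.ndarray  # (n_barcodes,)
    barcodes: list[str]
    grid: BinGrid
    lambda_fg: np.ndarray = field(default=None)  # type: ignore[assignment]
    lambda_bg: np.ndarray = field(default=None)  # type: ignore[assignment]
    decoded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.decoded is None:
            self.decoded = np.ones(len(self.barcodes), dtype=bool)


@dataclass
class CrossoverCall:
    """One crossover event with its 95% posterior-credible interval (nt)."""

    barcode: str
    chrom: str
    position: float  # mass-weighted point estimate
    ci_lo: float
    ci_hi: float
    mass: float  # total posterior mass of the event


class RigidHmm:
    """Rigid HMM for one chromosome (``n_bins`` bins).

    States are (haplotype h in {0, 1}, micro-index i in 0..R-1). Transitions:
    i < R-1 advances deterministically to i+1; i = R-1 ("free" state) stays
    with probability ``1 - switch_prob`` or switches to the other
    haplotype's micro-index 0 with probability ``switch_prob``. Paths start
    uniformly over micro-indices >= R - T and may terminate at micro-indices
    >= T - 1, which yields the terminal-segment guarantee.
    """

    def __init__(self, config: RhmmConfig, n_bins: int):
        if n_bins < config.terminal_rigidity:
            raise ValueError(
                f"chromosome has {n_bins} bins < terminal rigidity "
                f"{config.terminal_rigidity}"
            )
        self.config = config
        self.n_bins = n_bins
        self.R = config.rigidity
        self.T = config.terminal_rigidity
        self.s = config.switch_prob
        R, T = self.R, self.T
        self.init = np.zeros(R)
        self.init[R - T :] = 1.0 / (2 * T)  # per haplotype; x2 haplotypes
        self.endw = np.zeros(R)
        self.endw[T - 1 :] = 1.0

    # -- emissions ---------------------------------------------------------

    def _log_emissions(
        self,
        counts: np.ndarray,
        mask: np.ndarray,
        lam_fg: float,
        lam_bg: float,
    ) -> np.ndarray:
        """(n_bins, 2) log emission likelihood per haplotype macro-state.

        Corrected (non-integer) counts are rounded to the nearest integer
        before Poisson evaluation. Each bin's pair is shifted by its max so
        downstream recursions stay in a safe numeric range; posteriors,
        boundary probabilities and Viterbi paths are invariant to the shift.
        """
        c = np.rint(np.asarray(counts, dtype=float))  # (n_bins, 2)
        lams = np.array([[lam_fg, lam_bg], [lam_bg, lam_fg]])  # h=0 fg=ch0
        # log Poisson pmf: c*log(lam) - lam - log(c!)
        with np.errstate(divide="ignore"):
            ll = (
                c[:, None, :] * np.log(lams)[None, :, :]
                - lams[None, :, :]
                - gammaln(c + 1.0)[:, None, :]
            ).sum(axis=2)
        ll[~mask] = 0.0
        ll -= ll.max(axis=1, keepdims=True)
        return ll  # (n_bins, 2) for h in {0, 1}

    # -- forward-backward --------------------------------------------------

    def forward_backward(
        self,
        counts: np.ndarray,
        mask: np.ndarray,
        lam_fg: float,
        lam_bg: float,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior P(parent 2) per bin and crossover probability per boundary.

        Scaled forward-backward over the sparse rigid transition structure;
        returns ``(posterior, boundary_prob)`` with shapes (n_bins,) and
        (n_bins - 1,).
        """
        e = np.exp(self._log_emissions(counts, mask, lam_fg, lam_bg))
        n, R, s = self.n_bins, self.R, self.s

        alpha = np.empty((n, 2, R))
        scales = np.empty(n)
        a = self.init[None, :] * e[0][:, None]
        scales[0] = a.sum()
        alpha[0] = a / scales[0]
        for t in range(1, n):
            prev = alpha[t - 1]
            new = np.zeros((2, R))
            if R > 1:
                new[:, 1:] = prev[:, :-1]
                new[:, -1] += prev[:, -1] * (1 - s)
                new[0, 0] = prev[1, -1] * s
                new[1, 0] = prev[0, -1] * s
            else:
                new[0, 0] = prev[0, 0] * (1 - s) + prev[1, 0] * s
                new[1, 0] = prev[1, 0] * (1 - s) + prev[0, 0] * s
            new *= e[t][:, None]
            scales[t] = new.sum()
            alpha[t] = new / scales[t]

        beta = np.empty((n, 2, R))
        beta[-1] = self.endw[None, :]
        for t in range(n - 2, -1, -1):
            nxt = beta[t + 1] * e[t + 1][:, None]  # (2, R)
            new = np.zeros((2, R))
            if R > 1:
                new[:, :-1] = nxt[:, 1:]
                new[:, -1] = (1 - s) * nxt[:, -1]
                new[0, -1] += s * nxt[1, 0]
                new[1, -1] += s * nxt[0, 0]
            else:
                new[0, 0] = (1 - s) * nxt[0, 0] + s * nxt[1, 0]
                new[1, 0] = (1 - s) * nxt[1, 0] + s * nxt[0, 0]
            beta[t] = new / scales[t + 1]

        gamma = alpha * beta  # (n, 2, R)
        norm = gamma.sum(axis=(1, 2), keepdims=True)
        gamma /= norm
        posterior = gamma[:, 1, :].sum(axis=1)

        # boundary switch probability: posterior mass flowing through the two
        # switch transitions (h, R-1) -> (1-h, 0), normalized like gamma
        e_next = e[1:]  # (n-1, 2)
        b_next = beta[1:, :, 0]  # (n-1, 2)
        a_free = alpha[:-1, :, R - 1]  # (n-1, 2)
        flux = (
            a_free[:, 0] * s * e_next[:, 1] * b_next[:, 1]
            + a_free[:, 1] * s * e_next[:, 0] * b_next[:, 0]
        ) / scales[1:]
        # normalize by total transition mass (equals gamma normalization)
        boundary = flux / norm[:-1, 0, 0]
        return posterior, np.clip(boundary, 0.0, 1.0)

    # -- viterbi -----------------------------------------------------------

    def viterbi(
        self,
        counts: np.ndarray,
        mask: np.ndarray,
        lam_fg: float,
        lam_bg: float,
    ) -> np.ndarray:
        """Maximum-likelihood haplotype track (0/1 per bin).

        The returned path's switches obey the rigidity constraints by
        construction. Ties are broken toward staying in the current
        haplotype.
        """
        loge = self._log_emissions(counts, mask, lam_fg, lam_bg)
        n, R, s = self.n_bins, self.R, self.s
        log_s, log_stay = np.log(s), np.log1p(-s)
        NEG = -np.inf

        with np.errstate(divide="ignore"):
            log_init = np.log(self.init)
            log_endw = np.log(self.endw)

        delta = np.empty((2, R))
        delta[:] = log_init[None, :] + loge[0][:, None]
        # back-pointers: 0 = advance/enter (deterministic), 1 = stay at free state
        from_stay = np.zeros((n, 2), dtype=bool)  # choice at free state only
        for t in range(1, n):
            new = np.full((2, R), NEG)
            if R > 1:
                if R > 2:
                    new[:, 1:-1] = delta[:, :-2]
                # free state: advance from R-2 vs stay at R-1
                adv = delta[:, R - 2]
                stay = delta[:, R - 1] + log_stay
                from_stay[t] = stay >= adv
                new[:, R - 1] = np.maximum(adv, stay)
                new[0, 0] = delta[1, R - 1] + log_s
                new[1, 0] = delta[0, R - 1] + log_s
            else:
                stay0 = delta[0, 0] + log_stay
                sw0 = delta[1, 0] + log_s
                stay1 = delta[1, 0] + log_stay
                sw1 = delta[0, 0] + log_s
                from_stay[t, 0] = stay0 >= sw0
                from_stay[t, 1] = stay1 >= sw1
                new[0, 0] = max(stay0, sw0)
                new[1, 0] = max(stay1, sw1)
            delta = new + loge[t][:, None]

        final = delta + log_endw[None, :]
        h, i = np.unravel_index(np.argmax(final), final.shape)
        track = np.empty(n, dtype=np.int8)
        track[-1] = h
        for t in range(n - 1, 0, -1):
            if R > 1:
                if i == 0:
                    h = 1 - h
                    i = R - 1
                elif i == R - 1 and from_stay[t, h]:
                    i = R - 1
                else:
                    i -= 1
            else:
                if not from_stay[t, h]:
                    h = 1 - h
            track[t - 1] = h
        return track


def build_rhmm(config: RhmmConfig, chrom_n_bins: int) -> RigidHmm:
    """Construct the rigid HMM for a chromosome of ``chrom_n_bins`` bins."""
    return RigidHmm(config, chrom_n_bins)


def estimate_emissions(
    counts: np.ndarray, mask: np.ndarray, bg_floor_frac: float = 0.01
) -> tuple[float, float]:
    """Method-of-moments per-nucleus Poisson emission means.

    Over non-empty unmasked bins, ``lambda_fg`` is the mean of the larger
    channel count and ``lambda_bg`` the mean of the smaller, floored at
    ``bg_floor_frac * lambda_fg`` to keep the likelihood non-degenerate.
    """
    c = np.asarray(counts, dtype=float)[mask]
    nonempty = c.sum(axis=1) > 0
    if not nonempty.any():
        raise ValueError("nucleus has no markers in unmasked bins")
    c = c[nonempty]
    lam_fg = float(c.max(axis=1).mean())
    lam_bg = float(c.min(axis=1).mean())
    lam_bg = max(lam_bg, bg_floor_frac * lam_fg)
    return lam_fg, lam_bg


def decode_nuclei(
    matrix: MarkerMatrix, config: RhmmConfig | None = None
) -> HaplotypeField:
    """Decode every nucleus of a MarkerMatrix chromosome by chromosome.

    Nuclei without any markers in unmasked bins are skipped (posterior 0.5
    everywhere, flagged in ``decoded``).
    """
    if config is None:
        config = RhmmConfig(bin_size=matrix.grid.bin_size)
    n_bc, n_bins = matrix.n_barcodes, matrix.n_bins
    posterior = np.full((n_bc, n_bins), 0.5)
    viterbi = np.zeros((n_bc, n_bins), dtype=np.int8)
    boundary = np.zeros((n_bc, n_bins))
    lam_fg = np.full(n_bc, np.nan)
    lam_bg = np.full(n_bc, np.nan)
    decoded = np.ones(n_bc, dtype=bool)

    models = {
        chrom: build_rhmm(config, matrix.grid.n_bins(chrom))
        for chrom in matrix.grid.chromosomes
    }
    for i in range(n_bc):
        try:
            fg, bg = estimate_emissions(
                matrix.counts[i], matrix.bin_mask, config.bg_floor_frac
            )
        except ValueError:
            decoded[i] = False
            continue
        lam_fg[i], lam_bg[i] = fg, bg
        for chrom, model in models.items():
            sl = matrix.chrom_slice(chrom)
            c = matrix.counts[i, sl]
            m = matrix.bin_mask[sl]
            post, bnd = model.forward_backward(c, m, fg, bg)
            posterior[i, sl] = post
            boundary[i, sl.start : sl.start + model.n_bins - 1] = bnd
            viterbi[i, sl] = model.viterbi(c, m, fg, bg)

    return HaplotypeField(
        posterior=posterior,
        viterbi=viterbi,
        boundary_prob=boundary,
        expected_crossovers=boundary.sum(axis=1),
        barcodes=list(matrix.barcodes),
        grid=matrix.grid,
        lambda_fg=lam_fg,
        lambda_bg=lam_bg,
        decoded=decoded,
    )


def call_crossovers(
    field: HaplotypeField,
    level: float = 0.95,
    min_mass: float = 0.5,
    valley: float = 0.05,
) -> pd.DataFrame:
    """Segment boundary probabilities into crossover calls with credible CIs.

    Contiguous runs of boundary probability >= ``valley`` form candidate
    events; events with total posterior mass >= ``min_mass`` are reported
    with a mass-weighted point estimate and the smallest contiguous boundary
    interval holding >= ``level`` of the event's mass, in nt. Because a
    switch at the boundary of bins b and b+1 places the crossover anywhere
    between the two bin midpoints, the interval is widened by half a bin on
    each side.
    """
    grid = field.grid
    offsets = grid.offsets()
    rows: list[CrossoverCall] = []
    for i, bc in enumerate(field.barcodes):
        if not field.decoded[i]:
            continue
        for chrom in grid.chromosomes:
            off = offsets[chrom]
            nb = grid.n_bins(chrom)
            probs = field.boundary_prob[i, off : off + nb - 1]
            # boundary b sits between bins b and b+1 -> position (b+1)*bin_size
            pos = (np.arange(nb - 1) + 1.0) * grid.bin_size
            above = probs >= valley
            if not above.any():
                continue
            edges = np.flatnonzero(np.diff(above.astype(int)))
            starts = np.r_[0 if above[0] else [], edges[~above[edges]] + 1].astype(int)
            ends = np.r_[edges[above[edges]], (nb - 2) if above[-1] else []].astype(int)
            for s0, e0 in zip(starts, ends):
                seg_p = probs[s0 : e0 + 1]
                mass = seg_p.sum()
                if mass < min_mass:
                    continue
                seg_pos = pos[s0 : e0 + 1]
                point = float((seg_p * seg_pos).sum() / mass)
                lo_i, hi_i = _smallest_mass_interval(seg_p, level)
                half = grid.bin_size / 2
                rows.append(
                    CrossoverCall(
                        barcode=bc,
                        chrom=chrom,
                        position=point,
                        ci_lo=max(float(seg_pos[lo_i]) - half, 0.0),
                        ci_hi=min(
                            float(seg_pos[hi_i]) + half,
                            float(grid.chromosome_lengths[chrom]),
                        ),
                        mass=float(mass),
                    )
                )
    return pd.DataFrame(
        [(c.barcode, c.chrom, c.ci_lo, c.position, c.ci_hi, c.mass) for c in rows],
        columns=["barcode", "chrom", "ci_lo", "position", "ci_hi", "mass"],
    )


def _smallest_mass_interval(p: np.ndarray, level: float) -> tuple[int, int]:
    """Indices of the shortest contiguous window holding >= level of sum(p)."""
    target = level * p.sum()
    n = len(p)
    best = (0, n - 1)
    best_len = n
    j = 0
    acc = 0.0
    for i in range(n):
        if j < i:
            j, acc = i, 0.0
        while j < n and acc < target:
            acc += p[j]
            j += 1
        if acc >= target and (j - i) < best_len:
            best, best_len = (i, j - 1), j - i
        acc -= p[i]
    return best


def nucleus_fit_metrics(
    posterior: np.ndarray,
    counts: np.ndarray,
    mask: np.ndarray,
) -> tuple[float, float]:
    """Per-nucleus decode-fit metrics ``(hmm_score, hmm_uncertainty)``.

    The HMM score is the fraction of markers (in unmasked bins) whose
    channel agrees with the discretized haplotype track, Phred-scaled with a
    finite-sample cap: ``-log10(1 - accuracy + 1/(2 * total markers))``. The
    uncertainty score is the log10 area between the posterior and its
    discretization: ``log10(sum_b |posterior_b - discretized_b| + 1e-6)``.
    """
    c = np.asarray(counts, dtype=float)[mask]
    post = np.asarray(posterior, dtype=float)[mask]
    total = c.sum()
    if total <= 0:
        raise ValueError("nucleus has no markers in unmasked bins")
    disc = (post > 0.5).astype(float)
    agree = np.where(disc == 1, c[:, 1], c[:, 0]).sum()
    accuracy = agree / total
    eps = 1.0 / (2.0 * total)
    hmm_score = float(-np.log10(1.0 - accuracy + eps))
    hmm_uncertainty = float(np.log10(np.abs(post - disc).sum() + 1e-6))
    return hmm_score, hmm_uncertainty
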