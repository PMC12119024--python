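"""Haplotype-marker processing: UMI deduplication, 25 kb binning,
ambient-contamination correction and allele-specific-expression bin masking.

A "marker" is a deduplicated RNA fragment whose alleles identify which
parental haplotype a genomic interval was inherited from. Markers are
binned into non-overlapping 25 kb bins per barcode and channel
(channel 0 = reference parent, channel 1 = parent 2).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("ref_parent", "parent2")


@dataclass
class BinGrid:
    """Non-overlapping half-open bins tiling each chromosome."""

    chromosome_lengths: dict[str, int]
    bin_size: int = 25_000

    def n_bins(self, chrom: str) -> int:
        return -(-self.chromosome_lengths[chrom] // self.bin_size)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chromosome_lengths)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chromosomes)

    def offsets(self) -> dict[str, int]:
        """Start index of each chromosome in the genome-wide bin vector."""
        out, acc = {}, 0
        for c in self.chromosomes:
            out[c] = acc
            acc += self.n_bins(c)
        return out

    def table(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            length = self.chromosome_lengths[chrom]
            for b in range(self.n_bins(chrom)):
                rows.append(
                    (chrom, b, b * self.bin_size, min((b + 1) * self.bin_size, length))
                )
        return pd.DataFrame(rows, columns=["chrom", "bin", "start", "end"])

    def bin_of(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chromosome_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size


@dataclass
class MarkerMatrix:
    """Barcode x bin x channel marker counts with a usable-bin mask.

    ``counts[i, b, c]`` is the (possibly ambient-corrected, hence float)
    number of markers for barcode ``i`` in genome-wide bin ``b`` supporting
    channel ``c``. ``bin_mask[b]`` is True where the bin is usable
    downstream; masked bins contribute no emissions to the decoder.
    """

    counts: np.ndarray  # (n_barcodes, n_bins, 2)
    barcodes: list[str]
    grid: BinGrid
    bin_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_mask is None:
            self.bin_mask = np.ones(self.counts.shape[1], dtype=bool)
        if self.counts.shape != (len(self.barcodes), self.grid.total_bins, 2):
            raise ValueError("counts shape inconsistent with barcodes/grid")

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def chrom_slice(self, chrom: str) -> slice:
        start = self.grid.offsets()[chrom]
        return slice(start, start + self.grid.n_bins(chrom))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (barcode, chrom, bin, channel, count) for TSV export."""
        table = self.grid.table()
        i, b, c = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "barcode": [self.barcodes[j] for j in i],
                "chrom": table["chrom"].to_numpy()[b],
                "bin": table["bin"].to_numpy()[b],
                "channel": [CHANNELS[j] for j in c],
                "count": self.counts[i, b, c],
            }
        )


@dataclass
class BackgroundProfile:
    """Pooled ambient-marker profile and per-barcode contamination levels.

    ``profile[b, c]`` is the fraction of all pooled markers falling in bin
    ``b``, channel ``c`` (sums to 1 over bins x channels); ``rho[i]`` is
    barcode ``i``'s estimated ambient contamination fraction in [0, 1].
    """

    profile: np.ndarray  # (n_bins, 2)
    rho: np.ndarray  # (n_barcodes,)
    flagged: np.ndarray  # (n_barcodes,) True where rho undefined -> 0


# ---------------------------------------------------------------------------
# UMI deduplication (1MM directional)
# ---------------------------------------------------------------------------


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return mism == 1


def dedup_umis(
    observations: list[tuple[str, int, str, int]] | pd.DataFrame,
) -> pd.DataFrame:
    """Collapse PCR duplicates with the 1MM directional UMI network method.

    ``observations`` rows are ``(barcode, position, umi, haplotype)`` with one
    row per read (duplicate rows = duplicate reads of one molecule).
    Within each (barcode, position) group a directed edge a -> b is drawn when
    the UMIs differ at exactly one base and ``count(a) >= 2 * count(b) - 1``;
    each resulting group collapses to its root (highest-count) UMI. Groups
    whose member reads disagree on the supported haplotype are discarded.

    Returns a frame with one row per retained marker molecule:
    (barcode, position, umi, haplotype, reads) — ``reads`` is the group's
    total read count, so re-running dedup on its own output is a no-op. An
    optional ``reads`` column on the input supplies per-row read weights.
    """
    if isinstance(observations, pd.DataFrame):
        cols = ["barcode", "position", "umi", "haplotype"]
        if "reads" in observations:
            cols.append("reads")
        df = observations[cols].copy()
    else:
        df = pd.DataFrame(
            observations, columns=["barcode", "position", "umi", "haplotype"]
        )
    if "reads" not in df:
        df["reads"] = 1
    if len(df) == 0:
        return df.iloc[0:0]

    out_rows: list[tuple[str, int, str, int, int]] = []
    grouped = df.groupby(["barcode", "position"], sort=False)
    for (bc, pos), grp in grouped:
        # read counts and haplotype votes per UMI
        counts = grp.groupby("umi")["reads"].sum()
        haps = grp.groupby("umi")["haplotype"].agg(lambda s: set(s))
        umis = list(counts.sort_values(ascending=False).index)
        parent = {u: u for u in umis}

        def find(u: str) -> str:
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        # directional expansion from high-count roots
        for i, a in enumerate(umis):
            for b in umis[i + 1 :]:
                if counts[a] >= 2 * counts[b] - 1 and _hamming1(a, b):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        # root with the higher count wins
                        if counts[ra] >= counts[rb]:
                            parent[rb] = ra
                        else:
                            parent[ra] = rb
        groups: dict[str, list[str]] = {}
        for u in umis:
            groups.setdefault(find(u), []).append(u)
        for root, members in groups.items():
            support: set[int] = set()
            for u in members:
                support |= haps[u]
            if len(support) == 1:
                out_rows.append(
                    (bc, pos, root, support.pop(), int(sum(counts[u] for u in members)))
                )
            # disagreeing groups are dropped entirely
    return pd.DataFrame(
        out_rows, columns=["barcode", "position", "umi", "haplotype", "reads"]
    )


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_markers(
    markers: pd.DataFrame,
    grid: BinGrid,
    barcodes: list[str] | None = None,
) -> MarkerMatrix:
    """Accumulate deduplicated markers into a barcode x bin x channel matrix.

    ``markers`` needs columns (barcode, chrom, position, haplotype) with
    haplotype in {0, 1} and position the leftmost aligned base (0-based).
    """
    if barcodes is None:
        barcodes = sorted(markers["barcode"].unique()) if len(markers) else []
    bc_index = {b: i for i, b in enumerate(barcodes)}
    counts = np.zeros((len(barcodes), grid.total_bins, 2), dtype=float)
    offsets = grid.offsets()
    for chrom, grp in markers.groupby("chrom", sort=False) if len(markers) else []:
        length = grid.chromosome_lengths[chrom]
        pos = grp["position"].to_numpy()
        if (pos < 0).any() or (pos >= length).any():
            raise ValueError(f"marker position outside chromosome {chrom}")
        b = offsets[chrom] + pos // grid.bin_size
        i = grp["barcode"].map(bc_index).to_numpy()
        c = grp["haplotype"].to_numpy()
        np.add.at(counts, (i, b, c), 1.0)
    return MarkerMatrix(counts=counts, barcodes=list(barcodes), grid=grid)


# ---------------------------------------------------------------------------
# Ambient (SoupX-like) correction
# ---------------------------------------------------------------------------


def correct_ambient(
    matrix: MarkerMatrix,
    window: int = 1_000_000,
    min_window_markers: int = 5,
) -> tuple[MarkerMatrix, BackgroundProfile]:
    """Estimate and subtract ambient-RNA marker contamination per barcode.

    The pooled per-(bin, channel) marker fractions across all barcodes form
    the background profile. For each barcode, a sliding window (1 Mb,
    advanced bin-by-bin, each bin judged by the window centred on it) decides
    which channel is locally foreground (window majority) and which is
    background. The contamination level is::

        rho = observed background markers / expected background markers

    where the expectation assumes the barcode's total marker count were drawn
    entirely from the background profile, restricted to the channels called
    background. Only bins whose window holds at least ``min_window_markers``
    markers contribute to the estimate. The corrected matrix subtracts
    ``rho * profile * barcode_total`` from every (bin, channel), clipped at 0.
    """
    counts = matrix.counts
    pooled = counts.sum(axis=0)  # (n_bins, 2)
    total_pooled = pooled.sum()
    if total_pooled <= 0:
        raise ValueError("cannot estimate a background profile without markers")
    profile = pooled / total_pooled

    n_bc, n_bins, _ = counts.shape
    half = max(1, window // (2 * matrix.grid.bin_size))

    # per-chromosome window sums via cumulative sums
    bc_totals = counts.sum(axis=(1, 2))
    obs = np.zeros(n_bc)
    exp_frac = np.zeros(n_bc)
    for chrom in matrix.grid.chromosomes:
        sl = matrix.chrom_slice(chrom)
        sub = counts[:, sl, :]  # (n_bc, m, 2)
        m = sub.shape[1]
        cs = np.concatenate(
            [np.zeros((n_bc, 1, 2)), np.cumsum(sub, axis=1)], axis=1
        )
        lo = np.maximum(np.arange(m) - half, 0)
        hi = np.minimum(np.arange(m) + half + 1, m)
        win = cs[:, hi, :] - cs[:, lo, :]  # (n_bc, m, 2) window channel sums
        fg = (win[..., 1] > win[..., 0]).astype(int)  # fg channel per (bc, bin)
        # ties: treat channel 0 as foreground (no background evidence either way)
        win_tot = win.sum(axis=2)
        usable = win_tot >= min_window_markers
        bg = 1 - fg
        bg_obs = np.take_along_axis(sub, bg[..., None], axis=2)[..., 0]
        prof_sub = profile[sl, :]
        bg_prof = prof_sub[np.arange(m)[None, :], bg]  # (n_bc, m)
        obs += np.where(usable, bg_obs, 0.0).sum(axis=1)
        exp_frac += np.where(usable, bg_prof, 0.0).sum(axis=1)

    expected = exp_frac * bc_totals
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(expected > 0, obs / expected, 0.0)
    rho = np.clip(rho, 0.0, 1.0)
    zero = bc_totals == 0
    rho[zero] = 0.0
    flagged = zero.copy()

    corrected = np.clip(
        counts - rho[:, None, None] * profile[None, :, :] * bc_totals[:, None, None],
        0.0,
        None,
    )
    out = MarkerMatrix(
        counts=corrected,
        barcodes=list(matrix.barcodes),
        grid=matrix.grid,
        bin_mask=matrix.bin_mask.copy(),
    )
    return out, BackgroundProfile(profile=profile, rho=rho, flagged=flagged)


# ---------------------------------------------------------------------------
# Extreme allele-specific-expression masking
# ---------------------------------------------------------------------------


def mask_imbalanced_bins(
    matrix: MarkerMatrix, max_ratio: float = 9.0, min_total: int = 10
) -> MarkerMatrix:
    """Mask bins with a pooled channel imbalance strictly greater than 9:1.

    Extreme allele-specific expression makes one haplotype's markers dominate
    a bin across all nuclei, which distorts haplotype calling; such bins are
    excluded from downstream likelihoods. A bin where one channel has zero
    pooled markers is masked only if the other has at least ``min_total``
    (otherwise there is too little evidence to judge imbalance).
    """
    pooled = matrix.counts.sum(axis=0)  # (n_bins, 2)
    hi = pooled.max(axis=1)
    lo = pooled.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
    imbalanced = np.where(lo > 0, ratio > max_ratio, hi >= min_total)
    imbalanced &= hi > 0
    mask = matrix.bin_mask & ~imbalanced
    return MarkerMatrix(
        counts=matrix.counts.copy(),
        barcodes=list(matrix.barcodes),
        grid=matrix.grid,
        bin_mask=mask,
    )
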