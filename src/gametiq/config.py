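"""Configuration objects for simulation and haplotype decoding.

All genomic coordinates are 0-based, half-open. Bin ``b`` of a chromosome
covers ``[b * bin_size, (b + 1) * bin_size)``; the last bin may be partial.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Conversion between recombination rate in cM/Mb and expected crossovers:
#: 1 cM = 0.01 crossovers per meiosis, so rate[cM/Mb] * length[Mb] / 100
#: is the expected crossover count on a chromosome.
CM_PER_MORGAN = 100.0

DEFAULT_BIN_SIZE = 25_000
DEFAULT_RECOMB_RATE = 4.5  # cM/Mb, Arabidopsis male meiosis scale
DEFAULT_MIN_CO_SPACING = 2_500_000  # nt, crossover interference floor


@dataclass
class EqtlEffect:
    """A ground-truth expression QTL injected by the simulator.

    Parameters
    ----------
    gene : str
        Target gene name.
    chrom : str
        Chromosome of the causal bin.
    bin_index : int
        Causal 25 kb bin (0-based) on ``chrom``. Nuclei inheriting the
        parent-2 haplotype at this bin have their log2 expression mean
        shifted by ``effect_size``.
    effect_size : float
        Shift in log2 units.
    genotypes : set[int] | None
        Restrict the effect to these genotype indices (None = all).
    celltype : str | None
        Restrict the effect to one cell type label (None = all).
    """

    gene: str
    chrom: str
    bin_index: int
    effect_size: float
    genotypes: set[int] | None = None
    celltype: str | None = None


@dataclass
class SimConfig:
    """Study conditions for the synthetic pooled-gamete generator.

    Defaults mirror the conditions the inference pipeline is built for:
    25 kb bins, a 4.5 cM/Mb recombination rate with a 2.5 Mb interference
    floor, and a median of 481 haplotype-informative marker UMIs per nucleus.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000}
    )
    bin_size: int = DEFAULT_BIN_SIZE
    n_genotypes: int = 1
    n_nuclei: int = 500
    recomb_rate: float = DEFAULT_RECOMB_RATE
    min_co_spacing: int = DEFAULT_MIN_CO_SPACING
    marker_depth_median: float = 481.0
    marker_depth_dispersion: float = 2.0
    ambient_fraction: float = 0.0
    doublet_fraction: float = 0.0
    celltype_proportions: dict[str, float] = field(
        default_factory=lambda: {"sperm": 0.75, "vegetative": 0.25}
    )
    n_genes: int = 200
    mean_expression_depth: float = 2_000.0
    expression_noise_sd: float = 0.25
    celltype_program_genes: int = 40
    celltype_program_log2fc: float = 2.0
    eqtl_effects: list[EqtlEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.min_co_spacing < self.bin_size:
            raise ValueError("min_co_spacing must be >= bin_size")
        if not 0.0 <= self.ambient_fraction <= 1.0:
            raise ValueError("ambient_fraction must be in [0, 1]")
        if not 0.0 <= self.doublet_fraction < 0.5:
            raise ValueError("doublet_fraction must be in [0, 0.5)")
        total = sum(self.celltype_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("celltype_proportions must sum to 1")
        if any(p < 0 for p in self.celltype_proportions.values()):
            raise ValueError("celltype_proportions must be non-negative")
        if any(length <= 0 for length in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    def n_bins(self, chrom: str) -> int:
        """Number of 25 kb bins tiling ``chrom`` (last bin may be partial)."""
        length = self.chromosome_lengths[chrom]
        return -(-length // self.bin_size)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chromosome_lengths)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        effects = [
            EqtlEffect(
                **{
                    **e,
                    "genotypes": set(e["genotypes"])
                    if e.get("genotypes") is not None
                    else None,
                }
            )
            for e in raw.pop("eqtl_effects", [])
        ]
        return cls(eqtl_effects=effects, **raw)


@dataclass
class RhmmConfig:
    """Parameters of the rigid HMM used for haplotype decoding.

    ``rigidity`` chains of identical-haplotype micro-states enforce a hard
    minimum of ``rigidity`` bins (2.5 Mb at defaults) between internal
    haplotype switches; ``terminal_rigidity`` lets paths enter/exit a chain
    part-way at chromosome ends so terminal segments may be as short as
    ``terminal_rigidity`` bins (100 kb at defaults). ``switch_prob`` is the
    per-free-bin switch probability, initialized from the genome-wide
    recombination rate: 4.5 cM/Mb = 0.045 CO/Mb, times 0.025 Mb/bin.
    """

    rigidity: int = 100
    terminal_rigidity: int = 4
    bin_size: int = DEFAULT_BIN_SIZE
    init_recomb_rate: float = DEFAULT_RECOMB_RATE
    switch_prob: float | None = None
    bg_floor_frac: float = 0.01  # lambda_bg floored at this fraction of lambda_fg

    def __post_init__(self) -> None:
        if self.rigidity < 1:
            raise ValueError("rigidity must be >= 1")
        if not 1 <= self.terminal_rigidity <= self.rigidity:
            raise ValueError("terminal_rigidity must be in [1, rigidity]")
        if self.switch_prob is None:
            self.switch_prob = (
                self.init_recomb_rate / CM_PER_MORGAN * self.bin_size / 1e6
            )
        if not 0.0 < self.switch_prob < 1.0:
            raise ValueError("switch_prob must be in (0, 1)")

    def replace(self, **kwargs: Any) -> "RhmmConfig":
        return dataclasses.replace(self, **kwargs)
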