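"""Configuration objects for the synthetic-data generators.

Each config is a plain dataclass with validation in ``__post_init__``;
invalid proportions or degenerate designs raise ``ConfigError`` at
construction time, before any simulation work happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


DENISOVAN = "DENISOVAN"
NEANDERTHAL = "NEANDERTHAL"
NONARCHAIC = "NONARCHAIC"
AMBIGUOUS = "AMBIGUOUS"

ARCHAIC_ANCESTRIES = (DENISOVAN, NEANDERTHAL)


@dataclass
class CohortConfig:
    """Design of a phased diploid cohort with labelled archaic tracts.

    ``ancestry_mix`` gives the expected fraction of each haplotype's genome
    covered by tracts of each archaic ancestry (defaults emulate a Papuan
    cohort: ~4% Denisovan, ~2.5% Neanderthal).  ``miaf_spectrum`` is a
    discrete distribution over introgressed-allele counts, realised through
    the carrier counts of shared tracts; ``None`` selects a 1/i spectrum
    truncated to counts 2..n_chromosomes//2.  Non-archaic derived alleles
    follow a neutral 1/i spectrum over counts 1..n_chromosomes-1.
    """

    n_individuals: int = 56
    n_sites: int = 2000
    chrom: str = "1"
    chrom_length: int = 10_000_000
    tract_mean_len: float = 50_000.0
    ancestry_mix: dict = field(
        default_factory=lambda: {DENISOVAN: 0.04, NEANDERTHAL: 0.025}
    )
    archaic_site_fraction: float = 0.25
    dual_site_fraction: float = 0.08
    dual_tie_fraction: float = 0.25
    miaf_spectrum: dict | None = None
    outgroup_leak_rate: float = 0.0
    archaic_background_leak: float = 0.0
    ancestral_missing_rate: float = 0.0
    ancestral_mismatch_rate: float = 0.0
    seed: int = 0

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigError("need at least 2 individuals")
        if self.n_sites < 1 or self.chrom_length < 1000:
            raise ConfigError("degenerate cohort size")
        mix = self.ancestry_mix
        if set(mix) - set(ARCHAIC_ANCESTRIES):
            raise ConfigError(f"ancestry_mix keys must be in {ARCHAIC_ANCESTRIES}")
        props = [
            self.archaic_site_fraction,
            self.dual_site_fraction,
            self.dual_tie_fraction,
            self.outgroup_leak_rate,
            self.archaic_background_leak,
            self.ancestral_missing_rate,
            self.ancestral_mismatch_rate,
            *mix.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ConfigError("all proportions must lie in [0, 1]")
        if sum(mix.values()) > 1.0:
            raise ConfigError("ancestry_mix proportions must sum to <= 1")
        if self.miaf_spectrum is not None:
            if not self.miaf_spectrum:
                raise ConfigError("miaf_spectrum must be non-empty")
            if any(
                k < 1 or k > self.n_chromosomes or w < 0
                for k, w in self.miaf_spectrum.items()
            ):
                raise ConfigError("miaf_spectrum keys must be valid allele counts")


@dataclass
class EpigenomeConfig:
    """Design of per-cell-type 15-state segmentations and gene annotations.

    ``planted_or`` maps ``(state, tissue)`` to the odds ratio by which
    archaic variants are concentrated in that state within the cell types of
    that tissue, relative to control variants; a tissue of ``None`` plants
    the effect in every cell type.  All other states follow the baseline
    genome-wide state frequencies in both groups.
    """

    cell_types: dict = field(
        default_factory=lambda: {
            "E033": "Blood & T-cell",
            "E034": "Blood & T-cell",
            "E029": "HSC & B-cell",
            "E032": "HSC & B-cell",
            "E003": "ESC",
            "E066": "Other",
        }
    )
    planted_or: dict = field(default_factory=dict)
    baseline_state_probs: dict | None = None
    n_genes: int = 60
    n_go_terms: int = 25
    n_eqtls: int = 40
    eqtl_swap_fraction: float = 0.1
    n_bstat_intervals: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise ConfigError("need at least one cell type")
        for (state, _tissue), oddsratio in self.planted_or.items():
            from ..states import normalize_state

            normalize_state(state)  # raises for unknown labels
            if oddsratio <= 0:
                raise ConfigError("planted odds ratios must be positive")


@dataclass
class MotifConfig:
    """Design of a PFM library, a genome, and planted allelic disruptions."""

    n_motifs: int = 8
    # widths >= 10 keep even an all-A/T consensus window rarer than 1e-5
    # under the background, so planted matches can pass the threshold
    width_range: tuple = (10, 14)
    n_duplicated_tfs: int = 2
    genome_length: int = 60_000
    n_planted: int = 20
    n_neutral_snps: int = 0
    sharpness: float = 40.0
    background: dict = field(
        default_factory=lambda: {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.width_range
        if lo < 4 or hi > 20 or lo > hi:
            raise ConfigError("motif widths must lie within 4..20")
        if abs(sum(self.background.values()) - 1.0) > 1e-9:
            raise ConfigError("background must sum to 1")


@dataclass
class ReporterConfig:
    """Design of qPCR plates for an allelic reporter assay.

    Ct values are generated as ``Ct = intercept - log_E(quantity) + noise``;
    ``fold_changes`` maps construct id to the true archaic/non-archaic
    expression ratio.
    """

    constructs: tuple = ("oligo1", "oligo2", "oligo3", "oligo4", "oligo5")
    cell_lines: tuple = ("LCL1", "LCL2")
    n_transfection_reps: int = 3
    n_technical_reps: int = 3
    n_dilutions: int = 4
    efficiency: dict | float = 2.0
    fold_changes: dict = field(default_factory=dict)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.constructs) < 2:
            raise ConfigError("need at least 2 constructs")
        if self.n_transfection_reps < 3 or self.n_technical_reps < 1:
            raise ConfigError("need >= 3 transfection replicates")
        if self.n_dilutions < 3:
            raise ConfigError("need >= 3 dilution points")
        effs = (
            self.efficiency.values()
            if isinstance(self.efficiency, dict)
            else [self.efficiency]
        )
        if any(e <= 1.0 for e in effs):
            raise ConfigError("amplification efficiency must exceed 1")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ConfigError("fold changes must be positive")

    def efficiency_of(self, construct: str) -> float:
        if isinstance(self.efficiency, dict):
            return self.efficiency[construct]
        return float(self.efficiency)
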