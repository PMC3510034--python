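"""Simulation configuration.

A single frozen dataclass holds every tunable of the synthetic-data
generators so that one seed fully determines all emitted files.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic iCLIP / RNA-seq study.

    Lengths are nucleotide means of per-gene sampling distributions,
    rates are expected crosslink events per nucleotide (at the median
    expression level), and ``interaction_effect`` is the log2 shift
    planted in the null-genotype x treatment-B cell of the count design.
    """

    n_genes: int = 500
    n_targets: int = 50

    # gene architecture (mean segment lengths, nt)
    utr5_len: int = 150
    orf_len: int = 1200
    intron_len: int = 800
    utr3_len: int = 600
    intergenic_len: int = 500
    decoy_fraction: float = 0.1  # fraction of genes with an antisense ncRNA decoy

    # motif planting
    motif: str = "TGTT"
    sites_per_target: int = 5

    # iCLIP library
    wt_target_rate: float = 0.1      # crosslinks / nt of target 3'UTR (wildtype)
    background_rate: float = 0.002   # crosslinks / nt anywhere in a gene
    pcr_dup_rate: float = 0.15
    n_replicates_iclip: int = 2

    # expression
    fpkm_log_mean: float = 2.5
    fpkm_log_sd: float = 0.8
    reads_per_fpkm: float = 10.0     # normalized reads per FPKM unit (expression filter)

    # 2x2 count experiment
    interaction_effect: float = 2.0  # log2 units
    n_interaction_genes: int = 25
    dispersion: float = 0.1          # NB dispersion (Poisson when 0)
    n_replicates_counts: int = 3
    count_depth: float = 20.0        # mean counts per FPKM unit

    # term sets
    n_terms: int = 60
    term_size: int = 25
    enriched_term_fraction: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_targets <= self.n_genes:
            raise ValueError("n_targets must lie in [0, n_genes]")
        if not 0 <= self.n_interaction_genes <= self.n_targets:
            raise ValueError("n_interaction_genes must lie in [0, n_targets]")
        for name in ("wt_target_rate", "background_rate", "fpkm_log_sd",
                     "dispersion", "reads_per_fpkm", "count_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.pcr_dup_rate <= 1.0:
            raise ValueError("pcr_dup_rate must lie in [0, 1]")
        if not 0.0 <= self.enriched_term_fraction <= 1.0:
            raise ValueError("enriched_term_fraction must lie in [0, 1]")
        if self.term_size <= 0:
            raise ValueError("term_size must be positive")
        if self.term_size > self.n_genes:
            raise ValueError("term_size must not exceed n_genes")
        if not set(self.motif) <= set("ACGT") or not self.motif:
            raise ValueError("motif must be a non-empty ACGT string")


def study_scale_config(seed: int = 0) -> SimConfig:
    """Configuration at the scale of the mouse-brain study.

    14,288 expressed genes of which 2,000 are planted binding targets;
    term sets are larger and more numerous so that walk-down enrichment
    in rank groups of 357 genes is well resolved.
    """
    return SimConfig(
        n_genes=14288,
        n_targets=2000,
        n_interaction_genes=500,
        n_terms=120,
        term_size=40,
        seed=seed,
    )
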