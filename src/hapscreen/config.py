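"""Simulation configuration.

All knobs of the synthetic RNA-seq generator live here so a run is fully
described by one object (and one YAML block on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["SimConfig"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic 2-group RNA-seq experiment.

    The defaults describe a desk-scale bulk RNA-seq screen with two
    replicates per condition: gene mean expression is log-normal,
    counts are negative binomial with variance ``mu + dispersion * mu**2``,
    a fraction ``pi1`` of genes carries a planted log2 fold change of
    magnitude ``effect_log2fc`` with random sign, and gene sets may be
    planted as enriched for those genes.

    Attributes
    ----------
    n_genes:
        Number of genes simulated.
    n_per_group:
        Replicates per condition (the study design here is 2 vs 2).
    baseline_mean_log_mu, baseline_mean_log_sigma:
        Natural-log location/scale of the log-normal prior on gene mean counts.
    dispersion:
        Negative-binomial dispersion; variance = mean + dispersion * mean^2.
    pi1:
        Fraction of genes planted as differentially expressed.
    effect_log2fc:
        Absolute log2 fold change of planted genes (sign drawn at random).
    library_size_cv:
        Coefficient of variation of per-sample library-size factors.
    n_sets, set_size:
        Gene-set collection geometry.
    n_enriched_sets:
        How many sets are planted as enriched (flagged "immunological").
    enrichment_rho:
        Relative odds that a member of an enriched set is DE; 1 = none.
    rrna_fraction:
        Fraction of genes flagged as ribosomal RNA (exercises the filter).
    seed:
        RNG seed; same config (incl. seed) gives bitwise-identical output.
    """

    n_genes: int = 10_000
    n_per_group: int = 2
    baseline_mean_log_mu: float = 4.0
    baseline_mean_log_sigma: float = 1.0
    dispersion: float = 0.1
    pi1: float = 0.1
    effect_log2fc: float = 2.0
    library_size_cv: float = 0.1
    n_sets: int = 20
    set_size: int = 100
    n_enriched_sets: int = 1
    enrichment_rho: float = 5.0
    rrna_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(field: str, why: str) -> ValueError:
            return ValueError(f"invalid SimConfig.{field}: {why}")

        if self.n_genes < 1:
            raise bad("n_genes", "must be a positive integer")
        if self.n_per_group < 1:
            raise bad("n_per_group", "must be a positive integer")
        if self.baseline_mean_log_sigma < 0:
            raise bad("baseline_mean_log_sigma", "must be nonnegative")
        if self.dispersion <= 0:
            raise bad("dispersion", "must be strictly positive")
        if not 0.0 <= self.pi1 <= 1.0:
            raise bad("pi1", "must lie in [0, 1]")
        if self.pi1 > 0 and self.pi1 * self.n_genes < 1:
            raise bad("pi1", "pi1 * n_genes must be >= 1 when pi1 > 0")
        if self.effect_log2fc <= 0:
            raise bad("effect_log2fc", "must be strictly positive")
        if self.library_size_cv < 0:
            raise bad("library_size_cv", "must be nonnegative")
        if self.n_sets < 0:
            raise bad("n_sets", "must be nonnegative")
        if self.set_size < 1:
            raise bad("set_size", "must be a positive integer")
        if self.set_size > self.n_genes:
            raise bad("set_size", "must not exceed n_genes")
        if self.n_enriched_sets < 0 or self.n_enriched_sets > self.n_sets:
            raise bad("n_enriched_sets", "must lie in [0, n_sets]")
        if self.enrichment_rho < 1:
            raise bad("enrichment_rho", "must be >= 1")
        if not 0.0 <= self.rrna_fraction < 1.0:
            raise bad("rrna_fraction", "must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)
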