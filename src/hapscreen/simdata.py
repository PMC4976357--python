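"""Synthetic data generation.

The experiment this pipeline analyses — a 2-vs-2 bulk RNA-seq comparison of
CRISPR-edited haplotype cell lines against unedited controls — is emulated
here: negative-binomial counts with log-normal gene means, a planted fraction
of differentially expressed genes, gene-set collections with optional planted
enrichment, qPCR Ct tables with planted fold changes, and toy amplicon
sequences carrying three SNPs for the guide-design stage.

Every generator is a pure function of its config/seed: the same seed yields
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .enrich import GeneSetCollection
from .guides import Amplicon, Snp
from .matrix import CountMatrix
from .summaries import CtTable

__all__ = [
    "SimulationTruth",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_ct_table",
    "simulate_amplicon",
]

TREATED = "treated"
CONTROL = "control"

# distinct RNG stream keys so each generator call has its own stream
_STREAM_COUNTS = 0
_STREAM_SETS = 1


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment, for parameter-recovery checks."""

    de_genes: set[str]
    signed_log2fc: dict[str, float]
    enriched_sets: set[str] = field(default_factory=set)
    rrna_genes: set[str] = field(default_factory=set)


def _gene_ids(n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"gene_{i:0{width}d}" for i in range(n)]


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a seeded 2-group negative-binomial count matrix.

    Gene mean expression is log-normal; a Bernoulli(``pi1``) subset of genes
    receives a log2 fold change of ``+-effect_log2fc`` (random sign) applied
    to the treated group; per-sample library-size factors are log-normal with
    coefficient of variation ``library_size_cv``; counts are negative binomial
    with variance ``mu + dispersion * mu**2``.

    Returns the matrix together with a :class:`SimulationTruth` recording
    every planted quantity.
    """
    rng = np.random.default_rng([_STREAM_COUNTS, config.seed])
    n = config.n_genes
    genes = _gene_ids(n)

    log_mu = rng.normal(config.baseline_mean_log_mu, config.baseline_mean_log_sigma, n)
    mu = np.exp(log_mu)

    de_mask = rng.random(n) < config.pi1
    signs = rng.choice([-1.0, 1.0], size=n)
    lfc = np.where(de_mask, signs * config.effect_log2fc, 0.0)

    sample_ids = [f"{TREATED}_{i + 1}" for i in range(config.n_per_group)] + [
        f"{CONTROL}_{i + 1}" for i in range(config.n_per_group)
    ]
    group_of = {s: (TREATED if s.startswith(TREATED) else CONTROL) for s in sample_ids}

    if config.library_size_cv > 0:
        sig2 = np.log1p(config.library_size_cv**2)
        lib = rng.lognormal(mean=-sig2 / 2, sigma=np.sqrt(sig2), size=len(sample_ids))
    else:
        lib = np.ones(len(sample_ids))

    # per-gene, per-sample NB mean: treated columns carry the fold change
    fold = 2.0**lfc
    mean_mat = np.empty((n, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        base = mu * fold if group_of[s] == TREATED else mu
        mean_mat[:, j] = base * lib[j]

    r = 1.0 / config.dispersion  # NB size parameter
    p = r / (r + mean_mat)
    counts = rng.negative_binomial(r, p).astype(np.int64)

    rrna = rng.random(n) < config.rrna_fraction

    matrix = CountMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        group_of=group_of,
        counts=counts,
        rrna_flags=rrna,
    )
    truth = SimulationTruth(
        de_genes={g for g, m in zip(genes, de_mask) if m},
        signed_log2fc={g: float(v) for g, v, m in zip(genes, lfc, de_mask) if m},
        rrna_genes={g for g, m in zip(genes, rrna) if m},
    )
    return matrix, truth


def simulate_gene_sets(config: SimConfig, truth: SimulationTruth) -> GeneSetCollection:
    """Draw a gene-set collection, planting enrichment in ``n_enriched_sets``.

    Members of an enriched set are sampled with the odds of being a planted DE
    gene multiplied by ``enrichment_rho``; the other sets are uniform draws
    from the gene universe. Enriched sets are flagged ``"immunological"`` so
    the off-target screen has a planted signal to find; the rest are flagged
    ``"background"``. Names of enriched sets are recorded in
    ``truth.enriched_sets``.
    """
    rng = np.random.default_rng([_STREAM_SETS, config.seed])
    genes = np.array(_gene_ids(config.n_genes))
    de = np.isin(genes, sorted(truth.de_genes))

    sets: dict[str, set[str]] = {}
    flags: dict[str, str] = {}
    enriched_names: set[str] = set()
    width = len(str(max(config.n_sets - 1, 1)))
    for k in range(config.n_sets):
        name = f"set_{k:0{width}d}"
        if k < config.n_enriched_sets and config.enrichment_rho > 1:
            w = np.where(de, config.enrichment_rho, 1.0)
            members = rng.choice(genes, size=config.set_size, replace=False, p=w / w.sum())
            flags[name] = "immunological"
            enriched_names.add(name)
        else:
            members = rng.choice(genes, size=config.set_size, replace=False)
            flags[name] = "background"
        sets[name] = set(members.tolist())

    truth.enriched_sets = enriched_names
    return GeneSetCollection(universe=set(genes.tolist()), sets=sets, flags=flags)


def simulate_ct_table(
    n_samples: int,
    seed: int,
    fold_changes: dict[str, float] | None = None,
    noise_sd: float = 0.02,
    baseline_delta_ct: float = 5.0,
) -> CtTable:
    """Draw a plausible qPCR Ct table with optional planted fold changes.

    The reference gene cycles around 20; the target sits ``baseline_delta_ct``
    cycles above it, shifted down by log2(fold) in samples with a planted fold
    change relative to the calibrator (the first sample, whose fold is 1 by
    construction). Gaussian noise of ``noise_sd`` cycles is added to the
    target Ct.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1}" for i in range(n_samples)]
    calibrator = samples[0]
    folds = dict.fromkeys(samples, 1.0)
    if fold_changes:
        unknown = set(fold_changes) - set(samples)
        if unknown:
            raise ValueError(f"fold change for unknown sample(s): {sorted(unknown)}")
        if calibrator in fold_changes and fold_changes[calibrator] != 1.0:
            raise ValueError("calibrator fold change must be 1")
        folds.update(fold_changes)

    ct_ref = {s: float(rng.normal(20.0, 0.5)) for s in samples}
    ct_target = {
        s: float(
            ct_ref[s]
            + baseline_delta_ct
            - np.log2(folds[s])
            + rng.normal(0.0, noise_sd)
        )
        for s in samples
    }
    return CtTable(
        samples=samples, ct_target=ct_target, ct_reference=ct_ref, calibrator=calibrator
    )


def simulate_amplicon(
    length: int = 400,
    seed: int = 0,
    labels: tuple[str, str, str] = ("rs4073(-251)", "rs2227307(+396)", "rs2227306(+781)"),
) -> Amplicon:
    """Draw a toy amplicon with three SNPs, emulating the IL-8 target region.

    SNPs are placed near 1/4, 1/2 and 3/4 of the sequence with jitter; the
    default labels carry the IL-8 promoter-relative aliases as display strings
    only — coordinates are amplicon-local, 0-based.
    """
    if length < 60:
        raise ValueError("length must be >= 60 to place three spaced SNPs")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    jitter = length // 20
    positions = sorted(
        int(np.clip(round(length * f) + rng.integers(-jitter, jitter + 1), 1, length - 2))
        for f in (0.25, 0.5, 0.75)
    )
    if len(set(positions)) != 3:
        positions = [length // 4, length // 2, 3 * length // 4]
    snps = []
    for pos, label in zip(positions, labels):
        ref = seq[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snps.append(Snp(position=pos, ref=ref, alt=alt, label=label))
    return Amplicon(sequence=seq, snps=snps)
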