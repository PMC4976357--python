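"""Gene-set over-representation and the off-target screening argument.

The putative gene list extracted at a liberal FDR level is, in expectation, a
mixture: a fraction ``pi_list`` of truly differentially expressed genes
diluted with background. If some pathway is enriched among the truly DE
genes, it remains enriched (diluted but detectable) in the putative list —
this is what lets a low-replicate screen argue that *no* immune pathway was
perturbed: run over-representation on the putative list and check whether any
immune-flagged set passes the significance cutoff (default alpha = 1e-4,
deliberately liberal so absence of a hit is meaningful).

The test is the one-sided hypergeometric upper tail (Fisher), exact for
desk-scale universes. No multiple-testing correction is applied across sets
by default, matching the fixed-alpha screening logic; Benjamini-Hochberg is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "ScreenVerdict",
    "fisher_enrichment",
    "enrich_all",
    "propagate_expectation",
    "offtarget_screen",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a stated gene universe, with optional flags."""

    universe: set[str]
    sets: dict[str, set[str]]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has members outside the universe: {sorted(extra)[:5]}"
                )


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    odds_ratio: float


@dataclass
class ScreenVerdict:
    """Outcome of the off-target pathway screen at a fixed alpha."""

    alpha: float
    significant: list[EnrichmentRow]
    significant_by_flag: dict[str, list[EnrichmentRow]]
    clean: bool


def fisher_enrichment(
    gene_list: set[str] | list[str], gene_set: set[str], universe: set[str], set_name: str = ""
) -> EnrichmentRow:
    """One-sided hypergeometric over-representation of ``gene_set`` in ``gene_list``.

    P(X >= overlap) where X is the overlap of a uniform draw of
    ``len(gene_list)`` genes from the universe with the set. Exact upper-tail
    computation (scipy's hypergeometric survival function).
    """
    if not universe:
        raise ValueError("empty gene universe")
    glist = set(gene_list)
    offenders = sorted(glist - universe)
    if offenders:
        raise ValueError(f"gene list members outside the universe: {offenders[:10]}")
    offenders = sorted(set(gene_set) - universe)
    if offenders:
        raise ValueError(f"gene set members outside the universe: {offenders[:10]}")

    m = len(universe)
    big_k = len(gene_set)
    n = len(glist)
    k = len(glist & set(gene_set))
    p = float(stats.hypergeom.sf(k - 1, m, big_k, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)

    # conditional odds ratio from the 2x2 table; inf when a margin cell is empty
    a, b = k, big_k - k
    c, d = n - k, m - big_k - (n - k)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentRow(
        set_name=set_name,
        overlap=k,
        set_size=big_k,
        list_size=n,
        universe_size=m,
        p_value=p,
        odds_ratio=odds,
    )


def enrich_all(
    gene_list: set[str] | list[str],
    collection: GeneSetCollection,
    alpha: float = 1e-4,
    bh_correct: bool = False,
) -> list[EnrichmentRow]:
    """Over-representation of every set in the collection, sorted by p.

    With ``bh_correct`` the p-values are Benjamini-Hochberg adjusted before
    they are compared with alpha downstream (stored in place of the raw p).
    """
    rows = [
        fisher_enrichment(gene_list, members, collection.universe, set_name=name)
        for name, members in collection.sets.items()
    ]
    if bh_correct and rows:
        ps = np.array([r.p_value for r in rows])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, i in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, ps[i] * m / rank)
            adj[i] = running
        for r, q in zip(rows, adj):
            r.p_value = float(q)
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def propagate_expectation(
    pi_list: float, de_overlap_rate: float, background_rate: float
) -> float:
    """Expected set-overlap rate of a diluted list.

    A putative list at FDR level q is modeled as ``pi_list = 1 - q`` truly DE
    genes (overlapping the set at ``de_overlap_rate``) mixed with background
    genes (overlapping at ``background_rate``):

        expected rate = pi_list * de_overlap_rate + (1 - pi_list) * background_rate

    Used to predict whether enrichment among the truly DE genes remains
    detectable in the diluted list before running the screen.
    """
    if not 0.0 < pi_list <= 1.0:
        raise ValueError("pi_list must lie in (0, 1]")
    for name, rate in (("de_overlap_rate", de_overlap_rate), ("background_rate", background_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return pi_list * de_overlap_rate + (1.0 - pi_list) * background_rate


def offtarget_screen(
    results: list[EnrichmentRow],
    flags: dict[str, str],
    alpha: float = 1e-4,
    immune_flag: str = "immunological",
) -> ScreenVerdict:
    """Partition significant sets by flag; "clean" iff no immune set is significant.

    Every set in ``results`` must have a flag. Significance is ``p < alpha``
    (strict, matching a "p-value below alpha" criterion).
    """
    missing = [r.set_name for r in results if r.set_name not in flags]
    if missing:
        raise ValueError(f"no flag for set(s): {missing}")
    significant = [r for r in results if r.p_value < alpha]
    by_flag: dict[str, list[EnrichmentRow]] = {}
    for r in significant:
        by_flag.setdefault(flags[r.set_name], []).append(r)
    clean = not by_flag.get(immune_flag)
    return ScreenVerdict(
        alpha=alpha, significant=significant, significant_by_flag=by_flag, clean=clean
    )
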