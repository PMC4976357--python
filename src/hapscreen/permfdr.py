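"""Permutation-based FDR estimation for low-replicate differential expression.

With only two replicates per condition, per-gene inference is hopeless, but
the *spectrum* of two-sample T statistics still carries information. The
procedure:

1. Compute a classical pooled-variance two-sample t per gene, by default on
   log2(count + 1).
2. Enumerate every balanced relabeling of the samples that mixes the groups
   (for a 2-vs-2 design these are exactly the two partitions pairing one
   treated sample with one control in each pseudo-group), excluding the
   observed labeling and identifying label swaps.
3. At each observed |T| cutoff, estimate the false discovery rate as the mean
   permutation exceedance count divided by the observed exceedance count,
   clipped to [0, 1] and made monotone non-increasing in the cutoff.
4. Extract the "putative set" at a deliberately liberal level (0.5): a list
   expected to contain the nominal fraction of true positives, usable as a
   diluted random sample of the truly differentially expressed genes in
   downstream enrichment arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .matrix import CountMatrix

__all__ = [
    "DEResult",
    "PermutationScheme",
    "compute_t_statistics",
    "enumerate_balanced_permutations",
    "estimate_fdr_curve",
    "extract_putative_set",
    "run_differential_expression",
]


@dataclass
class PermutationScheme:
    """Balanced sample-to-group relabelings, observed labeling excluded."""

    partitions: list[dict[str, str]]
    includes_observed: bool = False

    def __len__(self) -> int:
        return len(self.partitions)


@dataclass
class DEResult:
    """Observed statistics, permutation spectra and the estimated FDR curve.

    ``thresholds`` is the descending grid of distinct observed |T| values;
    ``fdr_curve`` is aligned with it, clipped to [0, 1] and monotone
    non-increasing in the cutoff. ``putative_set`` is filled once
    :func:`extract_putative_set` has been applied at ``level``.
    """

    gene_ids: list[str]
    t_obs: dict[str, float]
    thresholds: np.ndarray
    obs_exceedance: np.ndarray
    perm_exceedance_mean: np.ndarray
    fdr_curve: np.ndarray
    raw_ratio: np.ndarray
    n_permutations: int
    transform: str
    level: float | None = None
    putative_set: list[str] = field(default_factory=list)


def _transform(counts: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(counts.astype(float) + 1.0)
    if transform == "raw":
        return counts.astype(float)
    raise ValueError(f"unknown transform {transform!r}")


def _t_stats(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, epsilon: float) -> np.ndarray:
    """Vectorized pooled-variance two-sample t over matrix rows.

    Rows with zero pooled variance (and zero epsilon) get statistic 0.
    """
    a, b = x[:, idx1], x[:, idx2]
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    ss1 = ((a - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((b - m2[:, None]) ** 2).sum(axis=1)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2) * np.sqrt(1.0 / n1 + 1.0 / n2) + epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def _group_indices(matrix: CountMatrix, labeling: dict[str, str]) -> tuple[np.ndarray, np.ndarray, str, str]:
    groups = sorted(set(labeling.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    idx1 = np.array([j for j, s in enumerate(matrix.sample_ids) if labeling[s] == g1])
    idx2 = np.array([j for j, s in enumerate(matrix.sample_ids) if labeling[s] == g2])
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs >= 2 samples for a pooled-variance t")
    return idx1, idx2, g1, g2


def compute_t_statistics(
    matrix: CountMatrix,
    labeling: dict[str, str] | None = None,
    transform: str = "log2p1",
    epsilon: float = 0.0,
) -> dict[str, float]:
    """Classical two-sample pooled-variance t per gene.

    ``labeling`` defaults to the matrix's own group assignment. The statistic
    is computed on log2(count + 1) by default (``transform="raw"`` for raw
    counts); genes with zero pooled variance get statistic 0 unless a
    stabilizing ``epsilon`` is added to the denominator.
    """
    labeling = dict(matrix.group_of) if labeling is None else labeling
    idx1, idx2, _, _ = _group_indices(matrix, labeling)
    x = _transform(matrix.counts, transform)
    t = _t_stats(x, idx1, idx2, epsilon)
    return {g: float(v) for g, v in zip(matrix.gene_ids, t)}


def enumerate_balanced_permutations(
    sample_ids: list[str], group_of: dict[str, str]
) -> PermutationScheme:
    """All group-size-preserving relabelings, excluding the observed one.

    A relabeling assigns ``n1`` samples to the first group label and the rest
    to the second. When group sizes are equal, swapping the two labels yields
    the same partition of samples and is counted once (canonicalized by
    keeping the first sample in its observed group's label). For a 2-vs-2
    design the scheme is exactly the two "mixed" partitions pairing one
    sample of each original group.
    """
    groups = sorted(set(group_of[s] for s in sample_ids))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    members1 = frozenset(s for s in sample_ids if group_of[s] == g1)
    n1 = len(members1)
    balanced = n1 == len(sample_ids) - n1
    anchor = sample_ids[0]

    partitions: list[dict[str, str]] = []
    for combo in combinations(sample_ids, n1):
        new1 = frozenset(combo)
        if balanced:
            # canonical form: the anchor sample keeps its observed label
            if (anchor in new1) != (anchor in members1):
                continue
        if new1 == members1:
            continue  # observed labeling
        partitions.append({s: (g1 if s in new1 else g2) for s in sample_ids})
    if not partitions:
        raise ValueError("group sizes admit no balanced relabeling besides the observed one")
    return PermutationScheme(partitions=partitions)


def estimate_fdr_curve(
    t_obs: dict[str, float],
    scheme: PermutationScheme,
    matrix: CountMatrix,
    transform: str = "log2p1",
    epsilon: float = 0.0,
) -> DEResult:
    """Estimate FDR at every observed |T| cutoff from the permutation spectra.

    At cutoff t the raw estimate is the mean, over the relabelings in
    ``scheme``, of the number of genes whose permuted |T| reaches t, divided
    by the number of genes whose observed |T| reaches t. Ratios are clipped
    to [0, 1] and monotonized into a q-value-style curve: the reported FDR at
    cutoff t is the minimum raw ratio over all cutoffs at most as stringent,
    which makes the curve non-increasing in the cutoff.
    """
    if len(scheme) == 0:
        raise ValueError("permutation scheme is empty")
    abs_obs = np.abs(np.array([t_obs[g] for g in matrix.gene_ids]))
    thresholds = np.unique(abs_obs)[::-1]  # descending

    sorted_obs = np.sort(abs_obs)
    n = len(abs_obs)
    obs_exc = n - np.searchsorted(sorted_obs, thresholds, side="left")

    x = _transform(matrix.counts, transform)
    perm_exc = np.zeros(len(thresholds))
    for labeling in scheme.partitions:
        idx1, idx2, _, _ = _group_indices(matrix, labeling)
        tp = np.sort(np.abs(_t_stats(x, idx1, idx2, epsilon)))
        perm_exc += n - np.searchsorted(tp, thresholds, side="left")
    perm_exc /= len(scheme)

    keep = obs_exc > 0  # cutoffs with no observed exceedance cannot be ratioed
    thresholds, obs_exc, perm_exc = thresholds[keep], obs_exc[keep], perm_exc[keep]

    raw = np.clip(perm_exc / obs_exc, 0.0, 1.0)
    # suffix minimum on the descending grid = min over less-stringent cutoffs
    fdr = np.minimum.accumulate(raw[::-1])[::-1]

    return DEResult(
        gene_ids=list(matrix.gene_ids),
        t_obs=dict(t_obs),
        thresholds=thresholds,
        obs_exceedance=obs_exc,
        perm_exceedance_mean=perm_exc,
        fdr_curve=fdr,
        raw_ratio=raw,
        n_permutations=len(scheme),
        transform=transform,
    )


def extract_putative_set(result: DEResult, level: float) -> list[str]:
    """Genes passing the least stringent cutoff whose estimated FDR <= level.

    May be empty. Also records ``level`` and the list on ``result``.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    qualifying = np.flatnonzero(result.fdr_curve <= level)
    result.level = level
    if qualifying.size == 0:
        result.putative_set = []
        return []
    t_star = result.thresholds[qualifying].min()
    genes = [g for g in result.gene_ids if abs(result.t_obs[g]) >= t_star]
    result.putative_set = genes
    return genes


def run_differential_expression(
    matrix: CountMatrix,
    level: float = 0.5,
    transform: str = "log2p1",
    epsilon: float = 0.0,
) -> DEResult:
    """Full screen on one two-group matrix: t spectrum, FDR curve, putative set."""
    t_obs = compute_t_statistics(matrix, transform=transform, epsilon=epsilon)
    scheme = enumerate_balanced_permutations(matrix.sample_ids, matrix.group_of)
    result = estimate_fdr_curve(t_obs, scheme, matrix, transform=transform, epsilon=epsilon)
    extract_putative_set(result, level)
    return result
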