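"""Permutation-FDR machinery against brute-force oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

from hapscreen import (
    SimConfig,
    compute_t_statistics,
    enumerate_balanced_permutations,
    estimate_fdr_curve,
    extract_putative_set,
    run_differential_expression,
    simulate_counts,
)
from hapscreen.matrix import CountMatrix


def _pooled_t(group1, group2):
    """Straight-line pooled-variance two-sample t (oracle helper)."""
    n1, n2 = len(group1), len(group2)
    m1, m2 = sum(group1) / n1, sum(group2) / n2
    ss = sum((v - m1) ** 2 for v in group1) + sum((v - m2) ** 2 for v in group2)
    sp2 = ss / (n1 + n2 - 2)
    denom = math.sqrt(sp2) * math.sqrt(1 / n1 + 1 / n2)
    return 0.0 if denom == 0 else (m1 - m2) / denom


def _brute_force_fdr(counts, labelings):
    """Exhaustive spectrum-ratio FDR over explicit relabelings (oracle).

    ``counts`` is a list of per-gene value-lists (already on the analysis
    scale); ``labelings`` is [(obs_g1_idx, obs_g2_idx), (perm1...), ...] with
    the observed labeling first.
    """
    (o1, o2), *perms = labelings
    t_obs = [abs(_pooled_t([row[i] for i in o1], [row[i] for i in o2])) for row in counts]
    cutoffs = sorted(set(t_obs), reverse=True)
    curve = []
    for c in cutoffs:
        obs = sum(1 for t in t_obs if t >= c)
        pm = 0.0
        for p1, p2 in perms:
            tp = [abs(_pooled_t([row[i] for i in p1], [row[i] for i in p2])) for row in counts]
            pm += sum(1 for t in tp if t >= c)
        pm /= len(perms)
        curve.append(min(max(pm / obs, 0.0), 1.0))
    # monotonize: minimum over cutoffs at most as stringent
    out = curve[:]
    for i in range(len(out) - 2, -1, -1):
        out[i] = min(out[i], out[i + 1])
    return cutoffs, curve, out, t_obs


class TestTStatistics:
    def test_worked_example(self):
        m = CountMatrix(
            gene_ids=["g"],
            sample_ids=["a1", "a2", "b1", "b2"],
            group_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            counts=np.array([[10, 12, 20, 22]]),
        )
        t = compute_t_statistics(m, transform="raw")
        assert abs(t["g"]) == pytest.approx(10 / math.sqrt(2), abs=1e-9)

    def test_degenerate_variance_is_zero_not_nan(self, tiny_matrix):
        t = compute_t_statistics(tiny_matrix, transform="raw")
        assert t["g1"] == 0.0  # constant gene

    def test_equal_group_means_zero(self):
        m = CountMatrix(
            gene_ids=["g"],
            sample_ids=["a1", "a2", "b1", "b2"],
            group_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            counts=np.array([[7, 9, 9, 7]]),
        )
        assert compute_t_statistics(m, transform="raw")["g"] == 0.0

    def test_epsilon_stabilizer_shrinks_large_t(self, tiny_matrix):
        t0 = compute_t_statistics(tiny_matrix, transform="raw")
        t1 = compute_t_statistics(tiny_matrix, transform="raw", epsilon=1.0)
        assert abs(t1["g0"]) < abs(t0["g0"])

    def test_small_group_rejected(self):
        m = CountMatrix(
            gene_ids=["g"],
            sample_ids=["a1", "b1", "b2"],
            group_of={"a1": "A", "b1": "B", "b2": "B"},
            counts=np.array([[1, 2, 3]]),
        )
        with pytest.raises(ValueError, match=">= 2 samples"):
            compute_t_statistics(m)


class TestEnumeration:
    def test_two_vs_two_gives_the_two_mixed_partitions(self):
        samples = ["t1", "t2", "c1", "c2"]
        groups = {"t1": "T", "t2": "T", "c1": "C", "c2": "C"}
        scheme = enumerate_balanced_permutations(samples, groups)
        assert len(scheme) == 2
        splits = {
            frozenset(frozenset(s for s in samples if lab[s] == g) for g in ("T", "C"))
            for lab in scheme.partitions
        }
        expected = {
            frozenset([frozenset({"t1", "c1"}), frozenset({"t2", "c2"})]),
            frozenset([frozenset({"t1", "c2"}), frozenset({"t2", "c1"})]),
        }
        assert splits == expected

    def test_three_vs_three_count_matches_brute_force(self):
        samples = [f"s{i}" for i in range(6)]
        groups = {s: ("A" if i < 3 else "B") for i, s in enumerate(samples)}
        scheme = enumerate_balanced_permutations(samples, groups)
        # brute force over label vectors: distinct sample partitions, observed excluded
        seen = set()
        for combo in combinations(samples, 3):
            part = frozenset([frozenset(combo), frozenset(set(samples) - set(combo))])
            seen.add(part)
        observed = frozenset(
            [frozenset(samples[:3]), frozenset(samples[3:])]
        )
        assert len(scheme) == len(seen - {observed}) == 9

    def test_preserves_group_sizes(self):
        samples = ["a", "b", "c", "d", "e"]
        groups = {"a": "X", "b": "X", "c": "Y", "d": "Y", "e": "Y"}
        scheme = enumerate_balanced_permutations(samples, groups)
        for lab in scheme.partitions:
            assert sum(1 for s in samples if lab[s] == "X") == 2

    def test_no_alternative_relabeling_errors(self):
        with pytest.raises(ValueError, match="no balanced relabeling"):
            enumerate_balanced_permutations(["a", "b"], {"a": "X", "b": "Y"})


class TestFdrCurve:
    def test_tiny_instance_matches_exhaustive_enumeration(self, tiny_matrix):
        t_obs = compute_t_statistics(tiny_matrix, transform="raw")
        scheme = enumerate_balanced_permutations(tiny_matrix.sample_ids, tiny_matrix.group_of)
        result = estimate_fdr_curve(t_obs, scheme, tiny_matrix, transform="raw")

        labelings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        rows = [list(map(float, r)) for r in tiny_matrix.counts]
        cutoffs, raw, fdr, _ = _brute_force_fdr(rows, labelings)
        assert np.allclose(result.thresholds, cutoffs)
        assert np.allclose(result.raw_ratio, raw)
        assert np.allclose(result.fdr_curve, fdr)

    def test_pure_null_spectra_give_fdr_one(self):
        # permuted spectra identical to observed at every cutoff => ratio 1
        m = CountMatrix(
            gene_ids=["g0", "g1"],
            sample_ids=["a1", "a2", "b1", "b2"],
            group_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            counts=np.array([[5, 5, 5, 5], [9, 9, 9, 9]]),
        )
        t_obs = compute_t_statistics(m, transform="raw")
        scheme = enumerate_balanced_permutations(m.sample_ids, m.group_of)
        result = estimate_fdr_curve(t_obs, scheme, m, transform="raw")
        assert np.allclose(result.fdr_curve, 1.0)

    def test_curve_is_monotone_and_clipped(self):
        matrix, _ = simulate_counts(SimConfig(n_genes=500, seed=21))
        result = run_differential_expression(matrix)
        assert ((result.fdr_curve >= 0) & (result.fdr_curve <= 1)).all()
        # descending cutoff grid: FDR non-decreasing along it
        assert (np.diff(result.fdr_curve) >= -1e-12).all()

    def test_column_permutation_invariance(self):
        matrix, _ = simulate_counts(SimConfig(n_genes=300, seed=8))
        perm = [2, 0, 3, 1]
        shuffled = CountMatrix(
            gene_ids=list(matrix.gene_ids),
            sample_ids=[matrix.sample_ids[j] for j in perm],
            group_of=dict(matrix.group_of),
            counts=matrix.counts[:, perm],
        )
        r1 = run_differential_expression(matrix)
        r2 = run_differential_expression(shuffled)
        assert np.allclose(r1.thresholds, r2.thresholds)
        assert np.allclose(r1.fdr_curve, r2.fdr_curve)
        assert r1.putative_set == r2.putative_set


class TestPutativeSet:
    def test_level_validation(self, tiny_matrix):
        result = run_differential_expression(tiny_matrix, transform="raw")
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="level"):
                extract_putative_set(result, bad)

    def test_unreachable_level_gives_empty_list(self):
        m = CountMatrix(
            gene_ids=["g0", "g1"],
            sample_ids=["a1", "a2", "b1", "b2"],
            group_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            counts=np.array([[5, 5, 5, 5], [9, 9, 9, 9]]),
        )
        result = run_differential_expression(m, transform="raw")
        assert extract_putative_set(result, 0.01) == []

    def test_matches_straight_line_reimplementation(self):
        matrix, _ = simulate_counts(SimConfig(n_genes=300, pi1=0.1, seed=17))
        result = run_differential_expression(matrix, level=0.5)

        rows = [np.log2(matrix.counts[i].astype(float) + 1).tolist() for i in range(300)]
        labelings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        cutoffs, _, fdr, t_obs = _brute_force_fdr(rows, labelings)
        qualifying = [c for c, q in zip(cutoffs, fdr) if q <= 0.5]
        expected = []
        if qualifying:
            t_star = min(qualifying)
            expected = [g for g, t in zip(matrix.gene_ids, t_obs) if t >= t_star]
        assert result.putative_set == expected

    def test_pure_null_lists_typically_near_empty(self):
        """With nothing planted, the typical run yields a (near-)empty list.

        The size distribution is heavy-tailed with only two permutations, so
        the median — not the mean — captures typical behavior.
        """
        sizes = []
        for seed in range(15):
            matrix, _ = simulate_counts(SimConfig(n_genes=1000, pi1=0.0, seed=seed))
            result = run_differential_expression(matrix, level=0.5)
            sizes.append(len(result.putative_set))
        assert np.median(sizes) < 10  # < 1% of genes in the typical run
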