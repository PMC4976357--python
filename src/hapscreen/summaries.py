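"""Descriptive summaries: clustering, Venn overlaps, qPCR fold changes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "CtTable",
    "Dendrogram",
    "hierarchical_cluster",
    "venn_counts",
    "ddct_fold_change",
]


@dataclass
class CtTable:
    """qPCR threshold-cycle values for a target and a reference gene."""

    samples: list[str]
    ct_target: dict[str, float]
    ct_reference: dict[str, float]
    calibrator: str

    def __post_init__(self) -> None:
        if self.calibrator not in self.samples:
            raise ValueError(f"calibrator {self.calibrator!r} not among samples")
        for s in self.samples:
            for name, table in (("target", self.ct_target), ("reference", self.ct_reference)):
                if s not in table:
                    raise ValueError(f"missing {name} Ct for sample {s!r}")
                if not np.isfinite(table[s]):
                    raise ValueError(f"non-finite {name} Ct for sample {s!r}")


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over labeled leaves.

    ``merges`` follows the scipy linkage convention: row i merges clusters
    ``a`` and ``b`` (ids < n are leaves, id n+i is the cluster formed at row
    i) at the given height.
    """

    merges: np.ndarray  # (n-1, 4) linkage matrix
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("merge matrix must have n-1 rows for n leaves")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        inner = f"({walk(root.left, root.dist)},{walk(root.right, root.dist)})"
        return inner + ";"


def hierarchical_cluster(
    data: np.ndarray, labels: list[str], linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of the rows of ``data`` with Euclidean distance.

    ``linkage`` may be "average" (default), "complete" or "single". The
    result is deterministic for a given input order; with all pairwise
    distances distinct the tree topology is invariant to input order.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need at least two items (rows) to cluster")
    if len(labels) != data.shape[0]:
        raise ValueError("labels length must match number of rows")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains missing or non-finite values")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    merges = hierarchy.linkage(pdist(data, metric="euclidean"), method=linkage)
    return Dendrogram(merges=merges, labels=list(labels))


def venn_counts(list_a, list_b) -> tuple[int, int, int]:
    """Exact two-set partition counts: (only in A, only in B, in both)."""
    a, b = set(list_a), set(list_b)
    both = len(a & b)
    return (len(a) - both, len(b) - both, both)


def ddct_fold_change(table: CtTable) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    fold(s) = 2^-[(Ct_target,s - Ct_ref,s) - (Ct_target,cal - Ct_ref,cal)];
    the calibrator's own fold is exactly 1.
    """
    cal_delta = table.ct_target[table.calibrator] - table.ct_reference[table.calibrator]
    out: dict[str, float] = {}
    for s in table.samples:
        delta = table.ct_target[s] - table.ct_reference[s]
        out[s] = float(2.0 ** (-(delta - cal_delta)))
    out[table.calibrator] = 1.0
    return out
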