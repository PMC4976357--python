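"""Gene-by-sample count matrix container.

The central in-memory object of the pipeline: integer counts, ordered gene and
sample identifiers, a group label per sample and an optional per-gene rRNA
flag (stand-in for sequence-level rRNA identification, which happens upstream
of quantification in a real pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Integer expression counts (genes x samples) with sample group labels.

    Parameters
    ----------
    gene_ids:
        Ordered, unique gene identifiers (row labels).
    sample_ids:
        Ordered, unique sample identifiers (column labels).
    group_of:
        Mapping from sample id to group label; every sample must be present.
    counts:
        Nonnegative integer array of shape ``(len(gene_ids), len(sample_ids))``.
    rrna_flags:
        Optional boolean array per gene marking ribosomal RNA genes.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    group_of: dict[str, str]
    counts: np.ndarray
    rrna_flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.rrna_flags is not None:
            self.rrna_flags = np.asarray(self.rrna_flags, dtype=bool)
            if self.rrna_flags.shape != (len(self.gene_ids),):
                raise ValueError("rrna_flags length must equal number of genes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            group_of=dict(self.group_of),
            counts=self.counts[idx, :].copy(),
            rrna_flags=None if self.rrna_flags is None else self.rrna_flags[idx].copy(),
        )

    def select_groups(self, groups: list[str]) -> "CountMatrix":
        """Column-subset to the samples belonging to the given groups."""
        keep = [s for s in self.sample_ids if self.group_of[s] in groups]
        idx = [self.sample_ids.index(s) for s in keep]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=keep,
            group_of={s: self.group_of[s] for s in keep},
            counts=self.counts[:, idx].copy(),
            rrna_flags=None if self.rrna_flags is None else self.rrna_flags.copy(),
        )
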