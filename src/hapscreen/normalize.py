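"""Count-matrix normalization.

Emulates the contract of read-resampling normalization pipelines: drop
ribosomal RNA genes, then equalize sequencing depth across samples by random
subsampling of counts so every sample has exactly the same total. Subsampling
is without replacement (multivariate hypergeometric), mimicking the random
removal of individual reads; binomial thinning is available as an option but
does not give exactly equal totals.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import CountMatrix

__all__ = ["filter_rrna", "equalize_depth"]


def filter_rrna(matrix: CountMatrix) -> CountMatrix:
    """Remove genes flagged as ribosomal RNA, preserving row order.

    If the matrix carries no flags this is a no-op with a warning (there is
    nothing to filter on).
    """
    if matrix.rrna_flags is None:
        warnings.warn("matrix has no rRNA flags; filter_rrna is a no-op", stacklevel=2)
        return matrix
    return matrix.subset_genes(~matrix.rrna_flags)


def equalize_depth(
    matrix: CountMatrix,
    seed: int,
    method: str = "hypergeometric",
    target: int | None = None,
) -> CountMatrix:
    """Downsample every sample to an equal total count.

    With the default ``hypergeometric`` method each column is a
    without-replacement subsample of its reads: the new column is a
    multivariate hypergeometric draw with the original gene counts as
    category sizes, so column totals equal ``target`` (default: the minimum
    original column total) exactly and no gene can exceed its original count.
    ``binomial`` thins each count independently with probability
    ``target / total``; totals are then equal only in expectation.
    """
    totals = matrix.column_totals()
    zero = [s for s, t in zip(matrix.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"cannot equalize depth: zero-total sample(s) {zero}")
    if method not in ("hypergeometric", "binomial"):
        raise ValueError(f"unknown method {method!r}")
    tgt = int(totals.min()) if target is None else int(target)
    if tgt < 0 or tgt > totals.min():
        raise ValueError("target must lie in [0, min column total]")

    rng = np.random.default_rng(seed)
    out = np.empty_like(matrix.counts)
    for j in range(matrix.n_samples):
        col = matrix.counts[:, j]
        if totals[j] == tgt:
            out[:, j] = col
        elif method == "hypergeometric":
            out[:, j] = rng.multivariate_hypergeometric(col, tgt, method="marginals")
        else:
            out[:, j] = rng.binomial(col, tgt / totals[j])
    return CountMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        group_of=dict(matrix.group_of),
        counts=out,
        rrna_flags=None if matrix.rrna_flags is None else matrix.rrna_flags.copy(),
    )
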