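#!/usr/bin/env python
"""Normalize each contrast: drop rRNA-flagged genes, equalize depth.

After filtering, every sample is randomly downsampled (without replacement)
to the smallest library so all columns carry exactly the same number of
counts — the low-level contract of read-resampling normalization pipelines.
Writes results/norm/<contrast>/.
"""

from pathlib import Path

from hapscreen import equalize_depth, filter_rrna, io

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for contrast_dir in sorted((BASE / "sim").glob("*_vs_control")):
        name = contrast_dir.name
        matrix = io.read_counts(
            contrast_dir / "sim.counts.tsv",
            contrast_dir / "sim.samples.tsv",
            contrast_dir / "sim.rrna.txt",
        )
        before = matrix.column_totals()
        matrix = filter_rrna(matrix)
        matrix = equalize_depth(matrix, seed=0)
        out = BASE / "norm" / name
        out.mkdir(parents=True, exist_ok=True)
        io.write_counts(matrix, out / "norm")
        print(
            f"{name}: {matrix.n_genes} genes kept; totals "
            f"{before.min()}..{before.max()} -> {int(matrix.column_totals()[0])} (all equal)"
        )


if __name__ == "__main__":
    main()
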