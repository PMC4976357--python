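#!/usr/bin/env python
"""Descriptive wrap-up: clustering, Venn overlap of the two lists, qPCR folds.

Clusters the samples of each contrast (Euclidean distance, average linkage,
log2 scale, restricted to the putative genes) and writes Newick trees;
counts the overlap between the two contrasts' putative lists; and computes
2^-ddCt relative expression from the simulated Ct table. Writes
results/report/.
"""

import json
from pathlib import Path

import numpy as np

from hapscreen import ddct_fold_change, hierarchical_cluster, io, venn_counts

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = BASE / "report"
    out.mkdir(parents=True, exist_ok=True)
    lists = {}
    for contrast_dir in sorted((BASE / "de").glob("*_vs_control")):
        name = contrast_dir.name
        genes = [g for g in (contrast_dir / "putative.txt").read_text().split()]
        lists[name] = genes
        matrix = io.read_counts(
            BASE / "norm" / name / "norm.counts.tsv", BASE / "norm" / name / "norm.samples.tsv"
        )
        wanted = set(genes)
        sub = matrix.subset_genes(np.array([g in wanted for g in matrix.gene_ids]))
        data = np.log2(sub.counts.T.astype(float) + 1.0)
        dend = hierarchical_cluster(data, sub.sample_ids)
        (out / f"{name}.samples.nwk").write_text(dend.to_newick() + "\n")
        print(f"{name}: clustered {sub.n_samples} samples on {sub.n_genes} putative genes; "
              f"tree -> {name}.samples.nwk")

    (a_name, a), (b_name, b) = sorted(lists.items())
    only_a, only_b, both = venn_counts(a, b)
    print(f"Venn of putative lists: {a_name} only {only_a}, {b_name} only {only_b}, shared {both}")

    table = io.read_ct_table(BASE / "sim" / "ct_table.tsv")
    folds = ddct_fold_change(table)
    print("ddCt fold changes vs calibrator "
          + ", ".join(f"{s}={f:.2f}" for s, f in folds.items()))

    (out / "report.json").write_text(json.dumps({
        "venn": {"only_a": only_a, "only_b": only_b, "both": both,
                 "lists": [a_name, b_name]},
        "ddct_fold_change": {s: round(f, 3) for s, f in folds.items()},
    }, indent=1))


if __name__ == "__main__":
    main()
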