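#!/usr/bin/env python
"""Generate the synthetic study: two edited-line contrasts vs control.

Emulates a 2-replicate-per-condition RNA-seq design: two "haplotype" lines
(each simulated as its own treated-vs-control contrast) with negative-binomial
counts, a planted fraction of DE genes, a gene-set collection with one planted
immune-flagged enriched set, a toy three-SNP amplicon for the guide-design
stage and a qPCR Ct table. Writes everything as plain text under
results/sim/<contrast>/.
"""

from pathlib import Path

from hapscreen import SimConfig, io, simulate_amplicon, simulate_counts, simulate_ct_table, simulate_gene_sets

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

# the two contrasts emulate the two edited lines; seeds differ, design identical
CONTRASTS = {"hap1_vs_control": 101, "hap2_vs_control": 202}


def main() -> None:
    for name, seed in CONTRASTS.items():
        cfg = SimConfig(seed=seed)
        out = OUT / name
        out.mkdir(parents=True, exist_ok=True)
        matrix, truth = simulate_counts(cfg)
        sets = simulate_gene_sets(cfg, truth)
        io.write_counts(matrix, out / "sim")
        io.write_gmt(sets, out / "sim.gmt")
        io.write_flags(sets.flags, out / "sim.flags.tsv")
        io.write_truth(truth, out / "sim.truth.json")
        print(
            f"{name}: {cfg.n_genes} genes x {matrix.n_samples} samples, "
            f"{len(truth.de_genes)} planted DE, {len(truth.rrna_genes)} rRNA-flagged, "
            f"enriched set(s): {sorted(truth.enriched_sets)}"
        )

    amp = simulate_amplicon(seed=7)
    io.write_amplicon(amp, OUT / "amplicon.fasta", OUT / "amplicon.snps.tsv")
    print(f"amplicon: {len(amp.sequence)} bp, SNPs at {[s.position for s in amp.snps]}")

    ct = simulate_ct_table(n_samples=6, seed=7, fold_changes={"s4": 4.0, "s5": 2.0})
    io.write_ct_table(ct, OUT / "ct_table.tsv")
    print("qPCR Ct table: 6 samples, folds 4 and 2 planted in s4/s5")


if __name__ == "__main__":
    main()
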