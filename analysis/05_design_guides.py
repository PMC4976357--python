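#!/usr/bin/env python
"""Guide design on the toy amplicon + the published IL-8 insert arithmetic.

Scans the simulated three-SNP amplicon for NGG PAM sites on both strands,
selects guide pairs cutting strictly inside the (SNP1, SNP3) interval and
covering SNP2, builds BbsI cloning oligos for the best pair, and constructs
HDR templates for the reference haplotype and the single-SNP-swap haplotype
(the ATC-vs-ATT analogue). Also rebuilds the two published IL-8 guide-insert
oligos from their protospacers and verifies the reverse-complement round
trips. Writes results/guides/.
"""

from pathlib import Path

from hapscreen import build_hdr_template, build_insert_oligos, io, scan_pams, select_flanking_pair
from hapscreen.il8 import PUBLISHED_INSERTS

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    amp = io.read_amplicon(BASE / "sim" / "amplicon.fasta", BASE / "sim" / "amplicon.snps.tsv")
    candidates = scan_pams(amp)
    pairs = select_flanking_pair(candidates, amp.snps)
    s1, s2, s3 = amp.snps
    print(f"amplicon {len(amp.sequence)} bp; SNPs {s1.label}@{s1.position}, "
          f"{s2.label}@{s2.position}, {s3.label}@{s3.position}")
    print(f"{len(candidates)} PAM candidates; {len(pairs)} qualifying flanking pairs")

    out = BASE / "guides"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pairs.tsv", "w") as fh:
        fh.write("rank\tg1_protospacer\tg1_strand\tg1_cut\tg2_protospacer\tg2_strand\tg2_cut\texcised_length\n")
        for i, p in enumerate(pairs):
            fh.write(f"{i + 1}\t{p.g1.protospacer}\t{p.g1.strand}\t{p.g1.cut_site}\t"
                     f"{p.g2.protospacer}\t{p.g2.strand}\t{p.g2.cut_site}\t{p.excised_length}\n")

    records = []
    if pairs:
        best = pairs[0]
        print(f"best pair cuts at {best.g1.cut_site} and {best.g2.cut_site} "
              f"(excises {best.excised_length} bp covering {s2.label})")
        for tag, guide in (("gRNA1", best.g1), ("gRNA2", best.g2)):
            oligos = build_insert_oligos(guide.protospacer)
            records += [(f"{tag}_forward_oligo", oligos.forward), (f"{tag}_reverse_oligo", oligos.reverse)]
            print(f"  {tag} ({guide.strand}): forward {oligos.forward}, reverse {oligos.reverse}")

    ref_hap = "".join(s.ref for s in amp.snps)
    alt3_hap = ref_hap[:2] + amp.snps[2].alt
    for hap in (ref_hap, alt3_hap):
        records.append((f"hdr_template_{hap}", build_hdr_template(amp, hap)))
    diff = [i for i, (a, b) in enumerate(zip(records[-2][1], records[-1][1])) if a != b]
    print(f"HDR templates {ref_hap} vs {alt3_hap} differ only at position(s) {diff} "
          f"(SNP3 at {s3.position})")

    with open(out / "oligos_and_templates.fasta", "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")

    print("published IL-8 inserts:")
    for insert in PUBLISHED_INSERTS:
        pair = build_insert_oligos(insert.protospacer, forward_adapter=insert.forward_adapter)
        ok = pair.forward == insert.forward_oligo and pair.reverse == insert.reverse_oligo
        print(f"  {insert.name}: {len(pair.forward)} nt forward / {len(pair.reverse)} nt reverse, "
              f"round-trip {'OK' if ok else 'MISMATCH'}")


if __name__ == "__main__":
    main()
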