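"""Published IL-8 editing design inputs.

The guide-insert oligos used to clone the two IL-8-targeting sgRNAs into the
BbsI-digested pX330 vector, as published for the haplotype-edited HEK293T
lines, plus the headline transcriptome numbers of that screen. The insert 1
forward oligo was synthesized with a 5-nt 5' prefix (CAACC) rather than the
canonical 4-nt CACC overhang; both reverse oligos follow the AAAC scheme, so
the protospacers are recovered by stripping the printed prefixes.

These constants are *inputs* (published sequences and counts), not outputs of
this package.
"""

from __future__ import annotations

from .guides import revcomp

__all__ = [
    "PUBLISHED_INSERTS",
    "GuideInsert",
    "IL8_SNP_ALIASES",
    "N_PUTATIVE_ATC_TTC",
    "N_PUTATIVE_ATT_TTC",
    "N_TRANSCRIPTS",
    "FDR_LEVEL",
    "ENRICHMENT_ALPHA",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class GuideInsert:
    """One published guide insert: printed oligos and their adapter split."""

    name: str
    forward_oligo: str
    reverse_oligo: str
    forward_adapter: str
    reverse_adapter: str

    @property
    def protospacer(self) -> str:
        return self.forward_oligo[len(self.forward_adapter) :]

    def check_round_trip(self) -> bool:
        """Reverse oligo minus its adapter must be the protospacer's revcomp."""
        return self.reverse_oligo[len(self.reverse_adapter) :] == revcomp(self.protospacer)


PUBLISHED_INSERTS: list[GuideInsert] = [
    GuideInsert(
        name="guide_insert_1",
        forward_oligo="CAACCGATTATTTGGAGACTATGGAAGG",
        reverse_oligo="AAACCCTTCCATAGTCTCCAAATAATC",
        forward_adapter="CAACC",
        reverse_adapter="AAAC",
    ),
    GuideInsert(
        name="guide_insert_2",
        forward_oligo="CACCCCACTCTAGTACTATATCTGTCA",
        reverse_oligo="AAACTGACAGATATAGTACTAGAGTGG",
        forward_adapter="CACC",
        reverse_adapter="AAAC",
    ),
]

# IL-8 SNP aliases: rs number and promoter-relative position
IL8_SNP_ALIASES = (("rs4073", "-251"), ("rs2227307", "+396"), ("rs2227306", "+781"))

# headline numbers of the published screen (putative-list sizes at FDR 0.5,
# transcripts quantified, significance cutoff of the pathway screen)
N_PUTATIVE_ATC_TTC = 986
N_PUTATIVE_ATT_TTC = 217
N_TRANSCRIPTS = 34_917
FDR_LEVEL = 0.5
ENRICHMENT_ALPHA = 1e-4
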