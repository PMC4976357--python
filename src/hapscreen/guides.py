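"""CRISPR guide design arithmetic for haplotype editing.

Covers the design workflow for replacing a SNP-bearing region by
homology-directed repair: scan an amplicon for SpCas9 NGG PAM sites on both
strands, pick a guide pair whose cut sites flank the middle SNP — the first
guide cutting strictly downstream of the first SNP and the second strictly
upstream of the third — build the Golden-Gate cloning oligos with the BbsI
overhangs of the pX330 vector (CACC on the top strand, AAAC on the bottom),
and build repair templates with the desired haplotype alleles substituted.

Coordinates are 0-based half-open throughout; a cut site is the integer
junction 3 bp 5' of the PAM (blunt SpCas9 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Snp",
    "Amplicon",
    "GuideCandidate",
    "GuidePair",
    "OligoPair",
    "revcomp",
    "scan_pams",
    "select_flanking_pair",
    "build_insert_oligos",
    "build_hdr_template",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
FORWARD_ADAPTER = "CACC"  # BbsI top-strand overhang of digested pX330
REVERSE_ADAPTER = "AAAC"  # BbsI bottom-strand overhang


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T string."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(f"non-ACGT character {base!r} at position {i}")


@dataclass(frozen=True)
class Snp:
    """A biallelic variant on the amplicon; label is display-only."""

    position: int
    ref: str
    alt: str
    label: str


@dataclass
class Amplicon:
    """Target region sequence with its ordered SNPs."""

    sequence: str
    snps: list[Snp]

    def __post_init__(self) -> None:
        _check_dna(self.sequence)
        last = -1
        for snp in self.snps:
            if not 0 <= snp.position < len(self.sequence):
                raise ValueError(f"SNP {snp.label}: position {snp.position} outside sequence")
            if snp.position <= last:
                raise ValueError("SNP positions must be strictly increasing")
            last = snp.position
            if self.sequence[snp.position] != snp.ref:
                raise ValueError(
                    f"SNP {snp.label}: ref allele {snp.ref} does not match sequence "
                    f"base {self.sequence[snp.position]} at {snp.position}"
                )


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer + NGG PAM occurrence on one strand of the amplicon.

    ``protospacer_interval`` and ``pam_interval`` are half-open intervals in
    amplicon coordinates; ``cut_site`` is the junction coordinate of the
    blunt cut, 3 bp 5' of the PAM on the candidate's strand.
    """

    protospacer: str
    strand: str
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    cut_site: int


@dataclass(frozen=True)
class GuidePair:
    """Two candidates whose cuts excise an interval of the amplicon."""

    g1: GuideCandidate
    g2: GuideCandidate

    @property
    def excised_interval(self) -> tuple[int, int]:
        return (self.g1.cut_site, self.g2.cut_site)

    @property
    def excised_length(self) -> int:
        return self.g2.cut_site - self.g1.cut_site


@dataclass(frozen=True)
class OligoPair:
    """Annealed Golden-Gate cloning oligos for one guide insert."""

    forward: str
    reverse: str


def scan_pams(amplicon: Amplicon, protospacer_length: int = 20) -> list[GuideCandidate]:
    """All NGG protospacer candidates on both strands.

    Forward strand: PAM at [p, p+3) wherever sequence[p+1:p+3] == "GG", with
    the protospacer immediately 5' at [p-L, p). Reverse strand: a CCN on the
    forward sequence at [q, q+3) is an NGG PAM on the reverse strand, with the
    protospacer at [q+3, q+3+L) (reverse-complemented). Only sites with room
    for a full protospacer are returned, ordered by position.
    """
    if protospacer_length < 1:
        raise ValueError("protospacer_length must be >= 1")
    seq = amplicon.sequence
    _check_dna(seq)
    length = len(seq)
    if length < protospacer_length + 3:
        raise ValueError("sequence shorter than protospacer + PAM")
    out: list[GuideCandidate] = []
    for p in range(length - 2):
        if seq[p + 1 : p + 3] == "GG" and p - protospacer_length >= 0:
            out.append(
                GuideCandidate(
                    protospacer=seq[p - protospacer_length : p],
                    strand="+",
                    protospacer_interval=(p - protospacer_length, p),
                    pam_interval=(p, p + 3),
                    cut_site=p - 3,
                )
            )
        if seq[p : p + 2] == "CC" and p + 3 + protospacer_length <= length:
            out.append(
                GuideCandidate(
                    protospacer=revcomp(seq[p + 3 : p + 3 + protospacer_length]),
                    strand="-",
                    protospacer_interval=(p + 3, p + 3 + protospacer_length),
                    pam_interval=(p, p + 3),
                    cut_site=p + 6,
                )
            )
    return out


def select_flanking_pair(
    candidates: list[GuideCandidate], snps: list[Snp]
) -> list[GuidePair]:
    """Guide pairs whose cuts fall strictly inside the (SNP1, SNP3) interval.

    Requires at least three ordered SNPs. A pair (g1, g2) qualifies when
    g1 cuts strictly downstream of the first SNP, g2 strictly upstream of the
    third, and g1's cut precedes g2's. If any qualifying pair's excised
    interval covers the middle SNP, only covering pairs are returned. Pairs
    are ranked by excised length (shortest sufficient excision first), ties
    by coordinates.
    """
    if len(snps) < 3:
        raise ValueError("need at least three ordered SNPs")
    if not candidates:
        raise ValueError("no guide candidates supplied")
    first, middle, third = snps[0], snps[1], snps[2]
    pairs = [
        GuidePair(g1, g2)
        for g1 in candidates
        for g2 in candidates
        if g1.cut_site > first.position
        and g2.cut_site < third.position
        and g1.cut_site < g2.cut_site
    ]
    covering = [
        p for p in pairs if p.g1.cut_site <= middle.position < p.g2.cut_site
    ]
    if covering:
        pairs = covering
    elif not pairs:
        import warnings

        warnings.warn("no guide pair satisfies the flanking constraints", stacklevel=2)
        return []
    pairs.sort(key=lambda p: (p.excised_length, p.g1.cut_site, p.g2.cut_site))
    return pairs


def build_insert_oligos(
    protospacer: str,
    forward_adapter: str = FORWARD_ADAPTER,
    reverse_adapter: str = REVERSE_ADAPTER,
    g_prepend: bool = False,
) -> OligoPair:
    """Cloning oligos for one guide insert: adapters + protospacer.

    forward = forward_adapter + protospacer, reverse = reverse_adapter +
    reverse-complement(protospacer); annealed they leave the BbsI-compatible
    4-nt overhangs. ``g_prepend`` adds a 5' G to the protospacer for U6
    transcription initiation (off by default).
    """
    if not protospacer:
        raise ValueError("empty protospacer")
    _check_dna(protospacer)
    if g_prepend and not protospacer.startswith("G"):
        protospacer = "G" + protospacer
    return OligoPair(
        forward=forward_adapter + protospacer,
        reverse=reverse_adapter + revcomp(protospacer),
    )


def build_hdr_template(amplicon: Amplicon, haplotype: str | dict[str, str]) -> str:
    """Repair-template sequence with the requested alleles substituted.

    ``haplotype`` is either a string of alleles aligned with the amplicon's
    SNPs in order (e.g. "ATC") or a mapping from SNP label to allele. Each
    allele must equal the ref or alt of its SNP; all other positions are
    returned unchanged.
    """
    if isinstance(haplotype, str):
        if len(haplotype) != len(amplicon.snps):
            raise ValueError(
                f"haplotype string length {len(haplotype)} != {len(amplicon.snps)} SNPs"
            )
        wanted = dict(zip((s.label for s in amplicon.snps), haplotype))
    else:
        wanted = dict(haplotype)
        unknown = set(wanted) - {s.label for s in amplicon.snps}
        if unknown:
            raise ValueError(f"unknown SNP label(s): {sorted(unknown)}")
    seq = list(amplicon.sequence)
    for snp in amplicon.snps:
        if snp.label not in wanted:
            continue
        allele = wanted[snp.label]
        if allele not in (snp.ref, snp.alt):
            raise ValueError(
                f"allele {allele!r} at SNP {snp.label} is neither ref "
                f"({snp.ref}) nor alt ({snp.alt})"
            )
        seq[snp.position] = allele
    return "".join(seq)
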