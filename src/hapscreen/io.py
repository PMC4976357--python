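"""Plain-text readers and writers for the pipeline's on-disk formats.

Counts travel as tab-delimited text (first column gene id, header row of
sample ids) with a two-column samples file (sample_id, group) and an optional
one-id-per-line rRNA flag file; gene sets as GMT; simulation truth as JSON;
amplicons as FASTA with a small SNP table (position, ref, alt, label).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrich import GeneSetCollection
from .guides import Amplicon, Snp
from .matrix import CountMatrix
from .summaries import CtTable

__all__ = [
    "write_counts",
    "read_counts",
    "write_gmt",
    "read_gmt",
    "read_flags",
    "write_flags",
    "write_truth",
    "read_truth",
    "write_amplicon",
    "read_amplicon",
    "write_ct_table",
    "read_ct_table",
]


def write_counts(matrix: CountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.counts.tsv``, ``<prefix>.samples.tsv`` and, when flags
    are present, ``<prefix>.rrna.txt``."""
    prefix = Path(prefix)
    matrix.to_frame().to_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": [matrix.group_of[s] for s in matrix.sample_ids]}
    ).to_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index=False)
    if matrix.rrna_flags is not None:
        flagged = [g for g, f in zip(matrix.gene_ids, matrix.rrna_flags) if f]
        prefix.with_suffix(".rrna.txt").write_text("\n".join(flagged) + ("\n" if flagged else ""))


def read_counts(
    counts_path: str | Path, samples_path: str | Path, rrna_path: str | Path | None = None
) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    group_of = dict(zip(samples["sample_id"], samples["group"]))
    rrna = None
    if rrna_path is not None and Path(rrna_path).exists():
        flagged = set(Path(rrna_path).read_text().split())
        rrna = np.array([g in flagged for g in df.index])
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        group_of={str(k): str(v) for k, v in group_of.items()},
        counts=df.to_numpy(),
        rrna_flags=rrna,
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.flags.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file; the universe defaults to the union of all members.

    When an explicit universe (the analysis background, e.g. all quantified
    genes) is supplied, set members outside it are dropped — enrichment is
    only defined over the background. The GMT description field is kept as
    the set's flag when non-empty.
    """
    sets: dict[str, set[str]] = {}
    flags: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, members = fields[0], fields[1], fields[2:]
        sets[name] = set(members)
        if desc:
            flags[name] = desc
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    else:
        sets = {name: members & universe for name, members in sets.items()}
    return GeneSetCollection(universe=universe, sets=sets, flags=flags)


def write_flags(flags: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(flags):
            fh.write(f"{name}\t{flags[name]}\n")


def read_flags(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            name, label = line.split("\t")
            out[name] = label
    return out


def write_truth(truth, path: str | Path) -> None:
    payload = {
        "de_genes": sorted(truth.de_genes),
        "signed_log2fc": dict(sorted(truth.signed_log2fc.items())),
        "enriched_sets": sorted(truth.enriched_sets),
        "rrna_genes": sorted(truth.rrna_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path):
    from .simdata import SimulationTruth

    d = json.loads(Path(path).read_text())
    return SimulationTruth(
        de_genes=set(d["de_genes"]),
        signed_log2fc=d["signed_log2fc"],
        enriched_sets=set(d["enriched_sets"]),
        rrna_genes=set(d["rrna_genes"]),
    )


def write_amplicon(amplicon: Amplicon, fasta_path: str | Path, snp_path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(amplicon.sequence), id="amplicon", description="")],
        str(fasta_path),
        "fasta",
    )
    pd.DataFrame(
        [(s.position, s.ref, s.alt, s.label) for s in amplicon.snps],
        columns=["position", "ref", "alt", "label"],
    ).to_csv(snp_path, sep="\t", index=False)


def read_amplicon(fasta_path: str | Path, snp_path: str | Path) -> Amplicon:
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    snps = [
        Snp(position=int(r.position), ref=str(r.ref), alt=str(r.alt), label=str(r.label))
        for r in pd.read_csv(snp_path, sep="\t").itertuples(index=False)
    ]
    return Amplicon(sequence=str(records[0].seq).upper(), snps=snps)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": table.samples,
            "ct_target": [table.ct_target[s] for s in table.samples],
            "ct_reference": [table.ct_reference[s] for s in table.samples],
            "calibrator": [int(s == table.calibrator) for s in table.samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    calibrators = df.loc[df["calibrator"] == 1, "sample_id"].tolist()
    if len(calibrators) != 1:
        raise ValueError("Ct table must designate exactly one calibrator")
    return CtTable(
        samples=df["sample_id"].tolist(),
        ct_target=dict(zip(df["sample_id"], df["ct_target"])),
        ct_reference=dict(zip(df["sample_id"], df["ct_reference"])),
        calibrator=calibrators[0],
    )
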