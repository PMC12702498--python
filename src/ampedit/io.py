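"""File format helpers: FASTA/FASTQ via Biopython, tables via pandas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import Read
from .refs import AmpliconRef, GuideSite


def write_fasta(refs: list[AmpliconRef], path: str | Path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in refs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[AmpliconRef]:
    return [
        AmpliconRef(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fastq(reads: list[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    return [
        Read(
            name=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_guides_tsv(path: str | Path, amplicon_id: str | None = None) -> list[GuideSite]:
    """Guide table with columns: role, spacer, strand, start, pam."""
    df = pd.read_csv(path, sep="\t")
    return [
        GuideSite(
            role=row.role, spacer=row.spacer, strand=row.strand,
            start=int(row.start), pam=row.pam, amplicon_id=amplicon_id,
        )
        for row in df.itertuples()
    ]


def write_guides_tsv(guides: list[GuideSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"role": g.role, "spacer": g.spacer, "strand": g.strand,
             "start": g.start, "pam": g.pam}
            for g in guides
        ]
    ).to_csv(path, sep="\t", index=False)
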