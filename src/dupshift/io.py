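"""FASTA and TSV I/O.

FASTA headers follow the grammar ``>geneID|transcriptID|species|role`` with
role one of ``original``, ``derived``, ``outgroup`` or empty.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import GeneRecord, InvalidInputError


def write_fasta(genes: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for k, cds in enumerate(g.transcripts):
                fh.write(f">{g.gene_id}|{g.gene_id}.t{k}|{g.species}|{g.role}\n")
                for i in range(0, len(cds), 60):
                    fh.write(cds[i : i + 60] + "\n")


def read_fasta(path) -> list[GeneRecord]:
    """Parse a FASTA with the package header grammar into gene records."""
    genes: dict[str, GeneRecord] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 3:
            raise InvalidInputError(
                f"header {rec.id!r} does not match geneID|transcriptID|species|role"
            )
        gene_id, _tid, species = fields[0], fields[1], fields[2]
        role = fields[3] if len(fields) > 3 else ""
        if gene_id not in genes:
            genes[gene_id] = GeneRecord(
                gene_id=gene_id, species=species, transcripts=[], role=role
            )
            order.append(gene_id)
        genes[gene_id].transcripts.append(str(rec.seq).upper())
    return [genes[g] for g in order]


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"positions": str, "sizes": str})


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
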