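"""Genome records and plain-text I/O helpers.

Proteomes are stored one FASTA file per genome with headers of the form
``<genome_id>|<protein_id>``.  Tabular artifacts use a pinned TSV dialect:
header row, tab delimiter, UTF-8, '.' decimal separator, no quoting, so
that repeated runs diff byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical metadata column order.
METADATA_COLUMNS = (
    "genome_id",
    "domain",
    "phylum",
    "family",
    "genome_length_bp",
    "n_cds",
    "ecosystem_category",
    "host_associated",
    "respiration_mode",
    "trophic_mode",
    "completeness",
    "contamination",
    "has_rrna",
    "n_trna",
)


@dataclass
class GenomeRecord:
    """One genome: an ordered protein set plus its metadata row."""

    genome_id: str
    proteins: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)


def write_proteome(genome: GenomeRecord, path: str | Path) -> None:
    """Write a genome's proteins as FASTA with ``genome|protein`` headers."""
    records = [
        SeqRecord(Seq(seq), id=f"{genome.genome_id}|{pid}", description="")
        for pid, seq in genome.proteins.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_proteome(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read a per-genome protein FASTA written by :func:`write_proteome`.

    When the header has no ``|`` separator the genome id falls back to the
    file stem (or the explicit ``genome_id`` argument).
    """
    path = Path(path)
    gid = genome_id or path.stem
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            hg, pid = header.split("|", 1)
            if genome_id is None:
                gid = hg
        else:
            pid = header
        proteins[pid] = str(rec.seq).upper()
    return GenomeRecord(genome_id=gid, proteins=proteins)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame in the pinned TSV dialect."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a metadata table, validating the required columns are present."""
    df = read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    return df
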