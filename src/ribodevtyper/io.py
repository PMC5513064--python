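"""Thin FASTA/FASTQ/TSV IO helpers (Biopython- and pandas-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence} (order preserved)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, uppercase sequence); malformed records raise with index."""
    index = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq).upper()
            index += 1
    except ValueError as exc:  # SeqIO raises ValueError on malformed records
        raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, seq) pairs as FASTQ with constant quality 'I'."""
    with open(path, "w") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
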