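"""Sequence and table io: format-sniffed FASTA/FASTQ plus TSV helpers.

Sequence parsing is delegated to Biopython's SeqIO behind a thin
sniffing layer (first byte '>' vs '@'); sequences are uppercased and
qualities ignored.  All tables are tab-separated UTF-8 with '.'
decimals so that pipeline outputs diff cleanly.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

__all__ = [
    "sniff_format",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_table",
    "write_table",
]


def sniff_format(path: str | Path) -> str:
    """'fasta' or 'fastq' from the first byte; empty files -> 'empty'."""
    with open(path, "rb") as fh:
        first = fh.read(1)
    if not first:
        return "empty"
    if first == b">":
        return "fasta"
    if first == b"@":
        return "fastq"
    raise ValueError(f"{path}: unrecognised sequence format "
                     f"(first byte {first!r})")


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, uppercased sequence) from a FASTA or FASTQ file."""
    fmt = sniff_format(path)
    if fmt == "empty":
        warnings.warn(f"{path}: empty sequence file", stacklevel=2)
        return
    for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {i + 1} ({rec.id}) is empty")
        yield rec.id, seq


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_fastq(path: str | Path, records: list[tuple[str, str]],
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path,
                index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
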