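"""File-format helpers: FASTA via Biopython, TSV tables with the package's
coordinate convention (0-based half-open in memory, 1-based inclusive on
disk), UTF-8 throughout."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_records",
    "read_records",
    "write_truth",
    "read_truth",
]

_COORD_COLS = ("start", "end", "cds_start", "cds_end")


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} mapping."""
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def _to_disk(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _COORD_COLS:
        if col.endswith("start") and col in out.columns:
            out[col] = out[col] + 1          # 1-based inclusive start
    return out


def _from_disk(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _COORD_COLS:
        if col.endswith("start") and col in out.columns:
            out[col] = out[col] - 1
    return out


def write_records(records: pd.DataFrame, path) -> None:
    """Write a record/hit table as TSV with 1-based inclusive coordinates."""
    _to_disk(records).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_records(path) -> pd.DataFrame:
    """Read a TSV record table back to 0-based half-open coordinates."""
    return _from_disk(pd.read_csv(path, sep="\t", encoding="utf-8"))


def write_truth(truth: pd.DataFrame, path) -> None:
    write_records(truth, path)


def read_truth(path) -> pd.DataFrame:
    return read_records(path)
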