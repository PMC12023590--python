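"""Reading and writing of the flat-file formats used across the pipeline.

Sequences travel as FASTA (Biopython-backed, wrapped at 80 columns), all
tables as TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter


def read_fasta(path: str | Path) -> dict[str, str]:
    """Return an id -> uppercase sequence mapping, preserving file order."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                descriptions: Mapping[str, str] | None = None) -> None:
    """Write sequences as FASTA wrapped at 80 columns."""
    records = [
        SeqRecord(Seq(seq), id=name,
                  description=(descriptions or {}).get(name, ""))
        for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=80)
        writer.write_file(records)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Entity x sample matrix with entity ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
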