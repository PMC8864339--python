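"""Format plumbing: FASTA/FASTQ via Biopython, TSV with metadata headers.

Every TSV writer can prepend ``#``-prefixed metadata lines (tool version,
seed, config hash) so outputs are self-describing; the reader skips them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLOAT_FORMAT = "%.10g"


def write_fasta(records: Iterable, path) -> None:
    recs = []
    for r in records:
        if isinstance(r, SeqRecord):
            recs.append(r)
        else:  # (name, sequence) pair
            name, seq = r
            recs.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fastq")


def read_fastq(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tsv_metadata(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ": " in body:
                key, value = body.split(": ", 1)
                meta[key] = value
    return meta
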