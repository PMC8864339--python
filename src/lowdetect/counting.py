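"""Per-sample, per-locus unique-read counting.

"Mapped uniquely" is operationalized two ways: from SAM/BAM alignments
(primary, mapped records with MAPQ above a threshold) or alignment-free
(each read assigned to the locus with the strictly greatest canonical
k-mer overlap; ties and zero-overlap reads discarded as non-unique).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .errors import FormatError, ParameterError
from .kmers import DEFAULT_K, build_kmer_set, iter_canonical_kmers, _seq_of
from .simulate import ReferencePanel

DEFAULT_MAPQ_MIN = 20


@dataclass
class CountMatrix:
    """Samples x loci unique-read counts.

    Wraps an integer DataFrame indexed by sample id with locus-name
    columns; ``provenance`` records how the counts were produced
    (``sam``, ``kmer_assign``, ``simulated`` or ``file``).
    """

    df: pd.DataFrame
    provenance: str = "file"

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise ParameterError("counts must be nonnegative")
        self.df = self.df.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def locus_names(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path, metadata: dict | None = None) -> None:
        from .io import write_tsv

        write_tsv(self.df.reset_index(names="sample_id"), path, metadata=metadata)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        from .io import read_tsv

        df = read_tsv(path).set_index("sample_id")
        return cls(df, provenance="file")

    @classmethod
    def from_rows(cls, rows: dict[str, pd.Series], provenance: str) -> "CountMatrix":
        df = pd.DataFrame({sid: s for sid, s in rows.items()}).T
        df.index.name = None
        return cls(df, provenance=provenance)


def counts_from_sam(sam_path, panel: ReferencePanel, mapq_min: int = DEFAULT_MAPQ_MIN) -> pd.Series:
    """Per-locus unique-read counts for one sample from a SAM/BAM file.

    Counts primary, mapped records with MAPQ >= ``mapq_min``; unmapped,
    secondary, supplementary and sub-threshold records are excluded.
    Reference names in the file must all belong to the panel.
    """
    sam_path = str(sam_path)
    mode = "rb" if sam_path.endswith(".bam") else "r"
    counts = pd.Series(0, index=panel.locus_names, dtype=int)
    with pysam.AlignmentFile(sam_path, mode, check_sq=False) as fh:
        refs = set(fh.references or ())
        unknown = sorted(refs - set(panel.locus_names))
        if unknown:
            raise ParameterError(f"SAM references not in panel: {unknown}")
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            counts[rec.reference_name] += 1
    return counts


def assign_by_kmer(reads: Iterable, panel: ReferencePanel, k: int = DEFAULT_K) -> pd.Series:
    """Alignment-free per-locus counts by strict-maximum k-mer overlap.

    Each read goes to the locus sharing the strictly greatest number of
    canonical k-mers with it; ties and reads with no overlap at all are
    discarded as non-uniquely assignable.
    """
    locus_kmers = {l.name: build_kmer_set([l.sequence], k).kmers for l in panel.loci}
    counts = pd.Series(0, index=panel.locus_names, dtype=int)
    for read in reads:
        seq = _seq_of(read)
        if len(seq) < k:
            continue
        read_kmers = set(iter_canonical_kmers(seq, k))
        overlaps = {name: len(read_kmers & km) for name, km in locus_kmers.items()}
        best = max(overlaps.values())
        if best == 0:
            continue
        winners = [name for name, v in overlaps.items() if v == best]
        if len(winners) == 1:
            counts[winners[0]] += 1
    return counts
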