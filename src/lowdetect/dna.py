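"""Small DNA string utilities used throughout the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, base-wise)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Strand-collapsed representation; well defined for odd k, where no
    k-mer can equal its own reverse complement.
    """
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_acgt(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)
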