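"""W-primer specificity screening against the Z gametologue.

W-specific primers must mismatch the Z gametologue in at least two
positions so that PCR amplifies the W copy only. Comparison is ungapped
on pre-aligned gametologue regions; mismatches are counted over the whole
primer, and ambiguous (non-ACGT) bases always count as mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .dna import revcomp
from .errors import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_PRIMER_LENGTH = 20
DEFAULT_MIN_MISMATCHES = 2
DEFAULT_TARGET_PRODUCT = 550
DEFAULT_TOLERANCE = 50

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class PrimerCandidate:
    locus: str
    strand: str  # 'forward' or 'reverse'
    start: int  # 0-based offset of the window on the W amplicon
    length: int
    sequence: str
    mismatches_vs_Z: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ParameterError("sequence length must equal the length field")
        if self.mismatches_vs_Z > self.length:
            raise ParameterError("mismatch count cannot exceed primer length")


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_length: int

    def __post_init__(self) -> None:
        if self.product_length <= 0:
            raise ParameterError("product_length must be positive")


def count_mismatches(a: str, b: str) -> int:
    """Ungapped Hamming distance, case-insensitive.

    Positions where either base is outside A/C/G/T count as mismatches
    regardless of equality.
    """
    if len(a) != len(b):
        raise ParameterError(f"sequences differ in length ({len(a)} vs {len(b)})")
    a = a.upper()
    b = b.upper()
    return sum(1 for x, y in zip(a, b) if x != y or x not in _ACGT or y not in _ACGT)


def screen_w_primers(
    w_seq: str,
    z_seq: str,
    primer_len: int = DEFAULT_PRIMER_LENGTH,
    min_mismatches: int = DEFAULT_MIN_MISMATCHES,
    target_product: int = DEFAULT_TARGET_PRODUCT,
    tolerance: int = DEFAULT_TOLERANCE,
    locus: str = "W",
) -> list[PrimerPair]:
    """Enumerate W primer pairs that discriminate the Z gametologue.

    Slides ``primer_len`` windows over both strands of the W amplicon,
    keeps windows with >= ``min_mismatches`` vs the aligned Z window, and
    pairs forward/reverse survivors whose implied product length lies
    within ``target_product`` +/- ``tolerance``.
    """
    if len(w_seq) != len(z_seq):
        raise ParameterError("W and Z gametologue regions must be pre-aligned (equal length)")
    if primer_len <= 0 or primer_len > len(w_seq):
        raise ParameterError("invalid primer length")
    w_seq = w_seq.upper()
    z_seq = z_seq.upper()

    # window mismatch counts are strand-independent: reverse-complementing
    # both windows preserves the Hamming distance
    survivors: list[tuple[int, int]] = []  # (start, mismatches)
    for i in range(len(w_seq) - primer_len + 1):
        mm = count_mismatches(w_seq[i : i + primer_len], z_seq[i : i + primer_len])
        if mm >= min_mismatches:
            survivors.append((i, mm))
    if not survivors:
        logger.info("no primer window reaches %d mismatches vs Z", min_mismatches)
        return []

    pairs: list[PrimerPair] = []
    for fs, fmm in survivors:
        for rs, rmm in survivors:
            product = rs + primer_len - fs  # forward 5' to reverse 5' span
            if product <= primer_len:
                continue
            if abs(product - target_product) > tolerance:
                continue
            fwd = PrimerCandidate(
                locus=locus,
                strand="forward",
                start=fs,
                length=primer_len,
                sequence=w_seq[fs : fs + primer_len],
                mismatches_vs_Z=fmm,
            )
            rev = PrimerCandidate(
                locus=locus,
                strand="reverse",
                start=rs,
                length=primer_len,
                sequence=revcomp(w_seq[rs : rs + primer_len]),
                mismatches_vs_Z=rmm,
            )
            pairs.append(PrimerPair(forward=fwd, reverse=rev, product_length=product))
    return pairs


def pairs_to_frame(pairs: list[PrimerPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        for cand in (p.forward, p.reverse):
            rows.append(
                {
                    "strand": cand.strand,
                    "start": cand.start,
                    "sequence": cand.sequence,
                    "mismatches_vs_Z": cand.mismatches_vs_Z,
                    "product_length": p.product_length,
                }
            )
    return pd.DataFrame(rows, columns=["strand", "start", "sequence", "mismatches_vs_Z", "product_length"])
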