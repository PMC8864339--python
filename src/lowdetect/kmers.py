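"""Female-specific read identification by canonical k-mer subtraction.

Candidate W-linked sequence is discovered by comparing female reads
against the k-mer content of male reads: a female read whose k-mers are
largely present in the male set is shared (autosomal or Z-linked) and
removed; the survivors are assembled into unitigs. k-mers are
strand-collapsed (canonical) so library strandedness does not matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqRecord import SeqRecord

from .dna import canonical, revcomp
from .errors import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_K = 25
_VALID = frozenset("ACGT")


def _seq_of(read) -> str:
    if isinstance(read, SeqRecord):
        return str(read.seq).upper()
    return str(read).upper()


def _id_of(read, fallback: str) -> str:
    if isinstance(read, SeqRecord):
        return read.id
    return fallback


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ParameterError("k must be odd (canonical form is ill-defined for palindromes)")
    if not 11 <= k <= 31:
        raise ParameterError("k must lie in [11, 31]")


def iter_canonical_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers of the valid (A/C/G/T-only) windows of a sequence."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if _VALID.issuperset(window):
            yield canonical(window)


@dataclass
class KmerSet:
    """A strand-collapsed k-mer store built from a read set."""

    k: int = DEFAULT_K
    kmers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        _check_k(self.k)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer.upper()) in self.kmers

    def add_sequence(self, seq: str) -> None:
        self.kmers.update(iter_canonical_kmers(seq, self.k))


def build_kmer_set(reads: Iterable, k: int = DEFAULT_K) -> KmerSet:
    """Collect the canonical k-mers of every read.

    Reads containing non-ACGT bases contribute only their valid windows;
    an empty stream yields an empty set.
    """
    ks = KmerSet(k=k)
    for read in reads:
        ks.add_sequence(_seq_of(read))
    return ks


@dataclass
class SubtractionResult:
    """Partition of female reads into male-shared and female-specific."""

    specific_reads: list
    shared_reads: list
    per_read_shared_fraction: dict[str, float]

    @property
    def n_input(self) -> int:
        return len(self.specific_reads) + len(self.shared_reads)


def shared_fraction(seq: str, male_kmers: KmerSet) -> float:
    """Fraction of a read's canonical k-mers present in the male set.

    Returns 1.0 for reads too short to contain a single k-mer (they carry
    no evidence of specificity and are removed, the conservative choice).
    """
    total = 0
    hit = 0
    for kmer in iter_canonical_kmers(seq, male_kmers.k):
        total += 1
        if kmer in male_kmers.kmers:
            hit += 1
    if total == 0:
        return 1.0
    return hit / total


def subtract_reads(
    female_reads: Iterable,
    male_kmers: KmerSet,
    shared_threshold: float = 0.5,
) -> SubtractionResult:
    """Remove female reads shared with the male k-mer set.

    A read is classified shared iff the fraction of its canonical k-mers
    found in ``male_kmers`` is >= ``shared_threshold``; the remainder are
    candidate W-linked (female-specific) reads.
    """
    if not 0.0 < shared_threshold <= 1.0:
        raise ParameterError("shared_threshold must lie in (0, 1]")
    specific: list = []
    shared: list = []
    fractions: dict[str, float] = {}
    for i, read in enumerate(female_reads):
        seq = _seq_of(read)
        rid = _id_of(read, f"read_{i}")
        if len(seq) < male_kmers.k:
            logger.warning("read %s shorter than k=%d; routed to shared", rid, male_kmers.k)
            frac = 1.0
        else:
            frac = shared_fraction(seq, male_kmers)
        fractions[rid] = frac
        (shared if frac >= shared_threshold else specific).append(read)
    return SubtractionResult(specific, shared, fractions)


# ---------------------------------------------------------------------------
# unitig construction


def _oriented_kmer(node: str, forward: bool) -> str:
    return node if forward else revcomp(node)


def _forward_extensions(okmer: str, kmers: set[str]) -> list[str]:
    suffix = okmer[1:]
    return [suffix + b for b in "ACGT" if canonical(suffix + b) in kmers]


def _backward_extensions(okmer: str, kmers: set[str]) -> list[str]:
    prefix = okmer[:-1]
    return [b + prefix for b in "ACGT" if canonical(b + prefix) in kmers]


def _walk(start: str, kmers: set[str], visited: set[str]) -> str:
    """Maximal non-branching path through ``start`` (oriented walk)."""
    # forward
    path = [start]
    current = start
    while True:
        nxt = _forward_extensions(current, kmers)
        if len(nxt) != 1:
            break
        nxt_k = nxt[0]
        if len(_backward_extensions(nxt_k, kmers)) != 1:
            break
        if canonical(nxt_k) in visited or canonical(nxt_k) == canonical(start):
            break  # already consumed, or a cycle closing on the start
        path.append(nxt_k)
        visited.add(canonical(nxt_k))
        current = nxt_k
    # backward
    current = start
    head: list[str] = []
    while True:
        prv = _backward_extensions(current, kmers)
        if len(prv) != 1:
            break
        prv_k = prv[0]
        if len(_forward_extensions(prv_k, kmers)) != 1:
            break
        if canonical(prv_k) in visited or canonical(prv_k) == canonical(start):
            break
        head.append(prv_k)
        visited.add(canonical(prv_k))
        current = prv_k
    path = head[::-1] + path
    seq = path[0] + "".join(p[-1] for p in path[1:])
    return seq


def build_unitigs(
    specific_reads: Iterable, k: int = DEFAULT_K, min_count: int = 1
) -> list[tuple[str, str]]:
    """Assemble maximal non-branching paths of the canonical de Bruijn graph.

    Returns ``(name, sequence)`` pairs with sequences in canonical
    orientation (lexicographic minimum of the unitig and its reverse
    complement), sorted, so output is deterministic. Only paths of length
    >= k (i.e. at least one k-mer) are emitted. ``min_count`` > 1 drops
    k-mers observed fewer times than that — low-abundance k-mers on
    deeply covered amplicons are almost always sequencing errors and
    would otherwise fragment the graph.
    """
    _check_k(k)
    if min_count > 1:
        tally: dict[str, int] = {}
        for read in specific_reads:
            for kmer in iter_canonical_kmers(_seq_of(read), k):
                tally[kmer] = tally.get(kmer, 0) + 1
        ks = KmerSet(k=k, kmers={km for km, c in tally.items() if c >= min_count})
    else:
        ks = build_kmer_set(specific_reads, k)
    if not ks.kmers:
        logger.warning("no k-mers in input; emitting no unitigs")
        return []
    visited: set[str] = set()
    unitigs: list[str] = []
    for node in sorted(ks.kmers):
        if node in visited:
            continue
        visited.add(node)
        seq = _walk(node, ks.kmers, visited)
        unitigs.append(min(seq, revcomp(seq)))
    unitigs.sort()
    return [(f"unitig_{i + 1}", seq) for i, seq in enumerate(unitigs)]
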