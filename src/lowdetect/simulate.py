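"""Synthetic cohorts, amplicon panels, counts and reads.

Emulates a targeted assay for mosaic loss of the W chromosome (LOW) in
wild birds: one autosomal, one Z-linked and one W-linked ~550 bp amplicon
per species, PCR-amplified and sequenced per female. Copy numbers are in
chromosome copies (autosome = 2; Z = 1 in females; W = 1 - f in females
carrying a mosaic-loss fraction f of blood cells lacking the W).

Two species presets mirror the field designs the assay was built for:

* ``booby`` (blue-footed booby, *Sula nebouxii*): 61 females in four age
  bands — 13 nestlings–fledglings (0–1 y), 19 young adults (2–7 y),
  10 middle-aged adults (8–11 y), 19 old adults (12–18 y).
* ``frigatebird`` (magnificent frigatebird, *Fregata magnificens*):
  41 females — 12 nestlings of one month and 29 adults of 6–30 y.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import BASES, is_acgt
from .errors import ParameterError

AUTOSOMAL = "autosomal"
Z = "Z"
W = "W"
CHROM_CLASSES = (AUTOSOMAL, Z, W)

AMPLICON_LENGTH = 550
READ_LENGTH = 75

#: group label used as the one-copy calibration anchor in both designs
CALIBRATION_GROUP = "nestling"

# age bands (years, inclusive) and group sizes of the two field designs
BOOBY_GROUPS = {
    "nestling": (13, 0.0, 1.0),
    "young": (19, 2.0, 7.0),
    "middle": (10, 8.0, 11.0),
    "old": (19, 12.0, 18.0),
}
FRIGATEBIRD_GROUPS = {
    "nestling": (12, 1.0 / 12.0, 1.0 / 12.0),
    "adult": (29, 6.0, 30.0),
}

# marker gene names used by the two species presets (W listed as the
# gametologue of the Z marker so primer screening has a paired target)
_PRESET_MARKERS = {
    "booby": {"autosomal": "NCK2", "Z": "VCAN", "W": "RICTOR"},
    "frigatebird": {"autosomal": "NCK2", "Z": "DMRT1", "W": "APC1"},
}


@dataclass(frozen=True)
class AmpliconLocus:
    """A single PCR amplicon target."""

    name: str
    chrom_class: str
    sequence: str
    gametologue_of: str | None = None

    def __post_init__(self) -> None:
        if self.chrom_class not in CHROM_CLASSES:
            raise ParameterError(f"unknown chrom_class {self.chrom_class!r}")
        if not is_acgt(self.sequence):
            raise ParameterError(f"locus {self.name}: sequence must be A/C/G/T only")
        if self.gametologue_of is not None and self.chrom_class == AUTOSOMAL:
            raise ParameterError("gametologue links are only valid on W or Z loci")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferencePanel:
    """One autosomal, one Z and one W amplicon for a species."""

    species: str
    loci: tuple[AmpliconLocus, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ParameterError("locus names must be unique")
        classes = {l.chrom_class for l in self.loci}
        if set(CHROM_CLASSES) - classes:
            missing = sorted(set(CHROM_CLASSES) - classes)
            raise ParameterError(f"panel must cover all classes; missing {missing}")

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> AmpliconLocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def by_class(self, chrom_class: str) -> AmpliconLocus:
        """The (single) locus of a class; first match if several."""
        for l in self.loci:
            if l.chrom_class == chrom_class:
                return l
        raise KeyError(chrom_class)

    def to_records(self) -> list[SeqRecord]:
        return [
            SeqRecord(Seq(l.sequence), id=l.name, description=f"class={l.chrom_class}")
            for l in self.loci
        ]


@dataclass(frozen=True)
class Sample:
    """One sampled female (or male, for the subtraction stage)."""

    id: str
    species: str
    sex: str  # 'F' or 'M'
    age_years: float
    group: str = ""
    loss_fraction: float = 0.0  # fraction of blood cells lacking the W
    depth_factor: float = 1.0  # per-sample depth multiplier

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ParameterError(f"sex must be F or M, got {self.sex!r}")
        if self.age_years < 0:
            raise ParameterError("age_years must be nonnegative")
        if not 0.0 <= self.loss_fraction <= 1.0:
            raise ParameterError("loss_fraction must lie in [0, 1]")
        if self.sex == "M" and self.loss_fraction != 0.0:
            raise ParameterError("males carry no W; loss_fraction must be 0")
        if self.depth_factor <= 0:
            raise ParameterError("depth_factor must be positive")


@dataclass(frozen=True)
class Cohort:
    """The set of samples analysed together under one design."""

    samples: tuple[Sample, ...]
    design: str

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ParameterError("sample ids must be unique")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def groups(self) -> dict[str, str]:
        """Mapping sample id -> age-group label."""
        return {s.id: s.group for s in self.samples}

    def ages(self) -> dict[str, float]:
        return {s.id: s.age_years for s in self.samples}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.id for s in self.samples],
                "species": [s.species for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "age_years": [s.age_years for s in self.samples],
                "group": [s.group for s in self.samples],
                "loss_fraction": [s.loss_fraction for s in self.samples],
            }
        )


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the count and read simulators.

    mean_depth is the expected number of unique reads for the autosomal
    locus per sample; with a two-copy autosome and single-copy Z and W
    this puts the expected per-sample total near 2 * mean_depth.
    Variance of counts is mu + mu^2 / dispersion (negative binomial);
    per-sample depth varies log-normally with coefficient of variation
    depth_cv.
    """

    mean_depth: float = 92_789.0
    depth_cv: float = 0.124
    efficiency: Mapping[str, float] | None = None
    dispersion: float = 30.0
    error_rate: float = 0.001
    read_length: int = READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        if self.depth_cv < 0:
            raise ParameterError("depth_cv must be >= 0")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be > 0")
        if not 0.0 <= self.error_rate < 0.25:
            raise ParameterError("error_rate must lie in [0, 0.25)")
        if self.efficiency is not None and any(e <= 0 for e in self.efficiency.values()):
            raise ParameterError("all efficiencies must be > 0")

    def locus_efficiency(self, name: str) -> float:
        if self.efficiency is None:
            return 1.0
        return float(self.efficiency.get(name, 1.0))


def default_params(design: str, seed: int = 0) -> SimulationParams:
    """Simulation parameters matching the sequencing scale of a design.

    Unique-read yields per sample: booby 185,578 (sd 22,995) and
    frigatebird 821,199 (sd 156,573); mean_depth is half the total
    (autosome carries two of the four expected locus copies in females)
    and depth_cv the reported sd/mean.
    """
    if design == "booby":
        return SimulationParams(mean_depth=92_789.0, depth_cv=0.124, seed=seed)
    if design == "frigatebird":
        return SimulationParams(mean_depth=410_600.0, depth_cv=0.191, seed=seed)
    raise ParameterError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# reference panel


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _diverge(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute each base independently with probability `divergence`."""
    out = list(seq)
    hits = rng.random(len(seq)) < divergence
    for i in np.flatnonzero(hits):
        alternatives = [b for b in BASES if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def make_reference(
    species: str,
    seed: int = 0,
    divergence: float = 0.1,
    amplicon_length: int = AMPLICON_LENGTH,
) -> ReferencePanel:
    """Build a three-locus amplicon panel for a species preset.

    The W amplicon is derived from the Z amplicon by independent per-base
    substitution with probability ``divergence`` (a gametologue pair);
    the autosomal amplicon is independent random sequence.
    """
    if not 0.0 <= divergence < 0.25:
        raise ParameterError("divergence must lie in [0, 0.25)")
    markers = _PRESET_MARKERS.get(species, {"autosomal": "AUTO", "Z": "GENE_Z", "W": "GENE_W"})
    rng = np.random.default_rng([seed, zlib.crc32(species.encode()) & 0x7FFFFFFF])
    auto_seq = _random_seq(rng, amplicon_length)
    z_seq = _random_seq(rng, amplicon_length)
    w_seq = _diverge(rng, z_seq, divergence)
    return ReferencePanel(
        species=species,
        loci=(
            AmpliconLocus(markers["autosomal"], AUTOSOMAL, auto_seq),
            AmpliconLocus(markers["Z"], Z, z_seq, gametologue_of=markers["W"]),
            AmpliconLocus(markers["W"], W, w_seq, gametologue_of=markers["Z"]),
        ),
    )


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    design: str,
    loss_profile: Mapping[str, float] | None = None,
    seed: int = 0,
) -> Cohort:
    """Construct a cohort of females under a species design preset.

    Ages are drawn uniformly within each printed band (individual ages are
    not published); loss fractions are assigned per group from
    ``loss_profile`` (default: no loss anywhere).
    """
    if design == "booby":
        groups = BOOBY_GROUPS
    elif design == "frigatebird":
        groups = FRIGATEBIRD_GROUPS
    else:
        raise ParameterError(f"unknown design {design!r}")
    profile = dict(loss_profile or {})
    unknown = set(profile) - set(groups)
    if unknown:
        raise ParameterError(f"loss_profile names unknown groups: {sorted(unknown)}")
    if any(not 0.0 <= f <= 1.0 for f in profile.values()):
        raise ParameterError("loss fractions must lie in [0, 1]")

    rng = np.random.default_rng([seed, zlib.crc32(design.encode()) & 0x7FFFFFFF])
    samples: list[Sample] = []
    i = 0
    for group, (n, lo, hi) in groups.items():
        f = float(profile.get(group, 0.0))
        for _ in range(n):
            i += 1
            age = lo if lo == hi else float(rng.uniform(lo, hi))
            samples.append(
                Sample(
                    id=f"{design}_{i:03d}",
                    species=design,
                    sex="F",
                    age_years=age,
                    group=group,
                    loss_fraction=f,
                )
            )
    return Cohort(samples=tuple(samples), design=design)


# ---------------------------------------------------------------------------
# counts


def _copy_number(locus: AmpliconLocus, sample: Sample) -> float:
    """Chromosome copies of a locus in a sample's blood."""
    if locus.chrom_class == AUTOSOMAL:
        return 2.0
    if locus.chrom_class == Z:
        return 1.0 if sample.sex == "F" else 2.0
    # W
    return (1.0 - sample.loss_fraction) if sample.sex == "F" else 0.0


def _depth_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Log-normal multipliers with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with mean mu, variance mu + mu^2/size_param."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if np.any(pos):
        p = size_param / (size_param + mu[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate_counts(cohort: Cohort, panel: ReferencePanel, params: SimulationParams):
    """Simulate the per-sample x per-locus unique-read count matrix.

    Count_il ~ NB(mean mu_il, variance mu_il + mu_il^2/dispersion) with
    mu_il = D_i * E_l * c_il / 2 where D_i = mean_depth * depth_factor_i,
    E_l the locus amplification efficiency and c_il the chromosome copy
    number (2 autosome; 1 Z in females, 2 in males; 1 - loss_fraction W in
    females, 0 in males). Reproducible for a fixed ``params.seed``.
    """
    from .counting import CountMatrix  # local import: avoid cycle

    rng = np.random.default_rng([params.seed, 0x5EED])
    depth = params.mean_depth * _depth_factors(rng, len(cohort), params.depth_cv)
    depth = depth * np.array([s.depth_factor for s in cohort.samples])

    counts = np.zeros((len(cohort), len(panel.loci)), dtype=np.int64)
    for j, locus in enumerate(panel.loci):
        eff = params.locus_efficiency(locus.name)
        copies = np.array([_copy_number(locus, s) for s in cohort.samples])
        mu = depth * eff * copies / 2.0
        counts[:, j] = _nb_draw(rng, mu, params.dispersion)

    return CountMatrix(
        pd.DataFrame(counts, index=cohort.sample_ids, columns=panel.locus_names),
        provenance="simulated",
    )


# ---------------------------------------------------------------------------
# reads


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < error_rate
    for i in np.flatnonzero(hits):
        alternatives = [b for b in BASES if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def _read_record(rid: str, locus: str, seq: str, qual: int = 35) -> SeqRecord:
    # truth tag rides in the description (comment), not the id, so that
    # standard FASTQ parsers round-trip it
    rec = SeqRecord(Seq(seq), id=rid, description=f"{rid} locus={locus}")
    rec.letter_annotations["phred_quality"] = [qual] * len(seq)
    return rec


def simulate_reads(
    panel: ReferencePanel, sample: Sample, params: SimulationParams
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Simulate paired amplicon reads for one sample.

    The number of read pairs per locus is Poisson with the same mean as
    the count model; mates are drawn independently and uniformly along
    the amplicon (mate 2 on the reverse strand), with per-base
    substitution errors at ``error_rate``. W loci are omitted for males
    and thinned by the sample's mosaic-loss fraction for females. Each
    record's description carries the source locus for truth tracking.
    """
    L = params.read_length
    shortest = min(len(l) for l in panel.loci)
    if L > shortest:
        raise ParameterError(f"read_length {L} exceeds shortest locus ({shortest} bp)")

    rng = np.random.default_rng(
        [params.seed, zlib.crc32(sample.id.encode()) & 0x7FFFFFFF, 0x4EAD]
    )
    depth = params.mean_depth * sample.depth_factor
    mates1: list[SeqRecord] = []
    mates2: list[SeqRecord] = []
    for locus in panel.loci:
        mu = depth * params.locus_efficiency(locus.name) * _copy_number(locus, sample) / 2.0
        n_pairs = int(rng.poisson(mu)) if mu > 0 else 0
        span = len(locus) - L
        seq = locus.sequence
        from .dna import revcomp

        for i in range(n_pairs):
            rid = f"{sample.id}:{locus.name}:{i}"
            s1 = int(rng.integers(span + 1))
            s2 = int(rng.integers(span + 1))
            fwd = _apply_errors(rng, seq[s1 : s1 + L], params.error_rate)
            rev = _apply_errors(rng, revcomp(seq[s2 : s2 + L]), params.error_rate)
            mates1.append(_read_record(rid + "/1", locus.name, fwd))
            mates2.append(_read_record(rid + "/2", locus.name, rev))
    return mates1, mates2


def truth_locus(record: SeqRecord) -> str | None:
    """Recover the source-locus truth tag from a simulated read."""
    for token in record.description.split():
        if token.startswith("locus="):
            return token[len("locus=") :]
    return None


def with_loss(cohort: Cohort, group: str, loss_fraction: float) -> Cohort:
    """A copy of the cohort with one group's loss fraction replaced."""
    if not 0.0 <= loss_fraction <= 1.0:
        raise ParameterError("loss_fraction must lie in [0, 1]")
    samples = tuple(
        replace(s, loss_fraction=loss_fraction) if s.group == group else s
        for s in cohort.samples
    )
    return Cohort(samples=samples, design=cohort.design)
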