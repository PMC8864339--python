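# Methods

## The measurement model

The assay estimates chromosome copy number from targeted-sequencing
coverage of three ~550 bp amplicons per species: one autosomal, one
Z-linked, one W-linked. In a female blood sample in which a fraction *f*
of cells lacks the W chromosome, the expected per-cell locus copies are
2 (autosome), 1 (Z) and 1 − *f* (W). Coverage is proportional to copies
times sample sequencing depth times a locus amplification efficiency, so
copy number is identifiable only after two normalizations:

* **Autosomal depth correction.** `factor_i = A_i / median_j(A_j)`
  estimates sample *i*'s relative depth because all samples share the
  autosomal copy number; dividing W and Z counts by it cancels depth
  exactly (a multiplicative correction — coverage scales multiplicatively
  with depth, so an additive correction would not cancel it; an additive
  mode is nevertheless available behind `mode="additive"` for
  sensitivity analysis).
* **Nestling calibration.** Corrected coverage is divided by the median
  corrected coverage of the nestling group, which carries exactly one W
  (and one Z) per cell and has had no time to accumulate mosaic loss.
  This absorbs the unknown per-locus amplification efficiency and puts
  copy number in chromosome units: the nestling median is exactly 1 by
  construction, and a group mean of 1 − *f* indicates loss fraction *f*.
  Z copy number is calibrated the same way on the same group.

Samples with zero autosomal counts have an undefined depth factor; they
are excluded with a logged warning, never silently dropped.

## Inference layer

All unordered age-group pairs are compared with two-sided Mann–Whitney U
tests on the calibrated copy numbers. The p-value is exact (full
enumeration, via the published reference implementation) when the smaller
sample has at most 8 observations and the pooled values are tie-free —
enumeration is cheap there — and otherwise uses the normal approximation
with midranks, tie correction and continuity correction. The pairwise
family for one marker is Benjamini–Hochberg-corrected (step-up, FDR
0.05); W and Z families are corrected separately, matching the
per-marker presentation of the analysis.

The age trend is ordinary least squares of copy number on age. "Outlier"
is operationalized as the 1.5×IQR rule on the response (configurable off
with `outlier_rule="none"`); which specific observations the original
field analysis excluded is not recoverable, so only the rule is fixed
here. A zero-variance response returns slope 0 with p = 1 rather than an
undefined fit.

`estimate_loss` inverts the copy-number model, `f̂ = max(0, 1 − mean cn)`
for a group, with a percentile bootstrap (default 1000 resamples,
seeded). The bootstrap resamples the target group *and* the nestling
calibration group jointly, re-deriving the calibration median in every
resample: the anchor median is a shared, noisy quantity, and resampling
the target group alone would understate the interval and undercover.

## Marker discovery

Candidate W-linked reads are found by subtraction: build the set of
canonical 25-mers (lexicographic minimum of a k-mer and its reverse
complement; k must be odd so no k-mer is its own reverse complement) of
a male read set, then classify each female read by the fraction of its
canonical k-mers present in that set. "Shared" is defined as fraction
≥ 0.5 — tolerant of read-end sequencing errors while still removing
autosomal and Z reads; the threshold is exposed as a flag, and reads
shorter than k are routed to shared (removed), the conservative choice
for a specificity-driven filter. Canonical (strand-collapsed) k-mers are
used because library strandedness cannot be assumed for arbitrary
inputs.

Surviving reads are assembled into unitigs — maximal non-branching paths
of the bidirected canonical de Bruijn graph — emitted in canonical
orientation and lexicographic order so output is byte-deterministic.
This is deliberately minimal: no bubble popping, no isoform resolution,
no scaffolding. An optional abundance filter (`min_count`) drops k-mers
observed fewer than N times; at amplicon coverage depths, singleton
k-mers are almost always sequencing errors and would otherwise fragment
the graph. Terminal k-mers are covered by few reads, so with the filter
on, a deeply covered 550 bp amplicon typically assembles into a single
unitig a few bases short of full length.

Primer screening slides 20-mer windows over the W amplicon and keeps
those with ≥ 2 mismatches against the pre-aligned Z gametologue
(ambiguous bases always count as mismatches; the comparison is ungapped
— alignment construction is out of scope and aligned gametologue regions
are the input). Whether the two-mismatch rule should weight the 3′ end
specifically is unstated in the assay description; whole-primer counting
is implemented. Forward/reverse survivors are paired when the implied
product is within 550 ± 50 bp (primer length and tolerance are typical
assay values, both configurable). Melting temperature, GC content and
dimer formation are not modelled.

"Uniquely mapped" counting is operationalized two ways: from SAM/BAM,
primary mapped records with MAPQ ≥ 20 (a standard uniqueness proxy, a
flag); or alignment-free, assigning each read to the locus with the
strictly greatest canonical k-mer overlap, discarding ties and
zero-overlap reads. Mates are counted individually, not as fragments.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:

* **Cohorts.** Presets `booby` (13/19/10/19 females in age bands 0–1,
  2–7, 8–11, 12–18 y) and `frigatebird` (12 nestlings of 1 month, 29
  adults 6–30 y). Individual ages are not published, so ages are drawn
  uniformly within each band.
* **Counts.** Per sample and locus, negative binomial with mean
  `D_i · E_l · c_il / 2` and variance `μ + μ²/dispersion`, where `D_i`
  is `mean_depth` times a log-normal per-sample factor (CV `depth_cv`)
  and `c_il` the copy number above. The ÷2 puts the autosome at copy 2,
  so simulated "copy number" reads directly in chromosome units.
* **Scale.** `mean_depth` and `depth_cv` default to the assay's reported
  unique-read yields: 185,578 ± 22,995 reads/sample (booby) and
  821,199 ± 156,573 (frigatebird), i.e. `mean_depth` = total/2 (the
  autosome contributes two of the four expected locus-copies in a
  female) → 92,789 and 410,600, with `depth_cv` = sd/mean → 0.124 and
  0.191.
* **Dispersion.** No overdispersion measurement is published; the
  default NB size of 30 gives a per-locus count CV of ≈ 18% at these
  depths, a realistic magnitude for multiplex-PCR amplification
  stochasticity. This single number controls how noisy copy-number
  estimates are and therefore the power results' absolute scale.
* **Reads.** Paired 75 nt reads drawn uniformly along each amplicon,
  mates independent, substitution errors at `error_rate` (default
  0.001), Phred+33 qualities, and the source locus carried in the FASTQ
  description (not the id) so standard parsers round-trip the truth tag.

Not emulated: insert-size structure (mates are independent), indels,
quality-dependent error profiles, GC/length amplification bias,
contamination, and any real W/Z/autosome sequence homology structure
beyond a tunable Z–W gametologue divergence (default 0.1 substitutions
per site). Passing tests therefore show the *pipeline logic* is correct
under the stated noise model, not that real libraries meet that model.

## Power analysis

`run_power` plants loss fraction *f* in one group, simulates the full
pipeline per replicate, and scores a detection when the BH-adjusted
calibration-vs-affected W comparison is significant — a single,
interpretable criterion (alternatives such as "any pair" can be built
from `compare_groups` directly). Power is the detection fraction with a
Clopper–Pearson 95% interval. Grid evaluations reuse per-replicate seeds
across grid points (common random numbers), so monotonicity in *f* is
visible at modest replicate counts. Note that with four groups the BH
correction makes the *f* = 0 detection rate conservative (below the
nominal α); with the two-group design there is a single comparison and
the *f* = 0 rate estimates α directly.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integer seeds; sub-streams are derived from (seed, tag)
  pairs, with string tags hashed by CRC32. Identical seeds give
  byte-identical FASTQ/TSV outputs.
* Pipeline outputs carry `#`-prefixed metadata headers (tool version,
  seed, SHA-256 config hash); unknown config keys are rejected.
* Problem sizes used by the test suite and the acceptance script: 200
  replicate cohorts for parameter recovery and bootstrap coverage, 1000
  null cohorts for type-I calibration, 200 replicates per power-grid
  point (500 at f = 0) — enough for the Monte-Carlo error of each check
  to sit well inside its tolerance while the whole suite runs in about a
  minute.

## Known limitations

* The copy-number mean has a small positive bias (≈ +0.02 at these
  depths) because it divides by a noisy nestling median; the bootstrap
  covers it, but very small loss fractions (f ≲ 0.05) are not separable
  from this bias at the assay's noise level.
* The exact Mann–Whitney branch requires tie-free data; calibrated copy
  numbers are continuous so ties are not expected there, but heavily
  rounded inputs will silently use the asymptotic branch.
* The subtraction stage assumes male and female libraries sample the
  same loci at comparable depth; strong male-specific dropout would
  misclassify autosomal reads as female-specific.
* The unitig builder is a minimal assembler and will fragment on
  repeats or high error rates; it is intended for amplicon-scale
  reconstruction, not transcriptome assembly.
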