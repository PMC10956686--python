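# Methods

This note documents the models, parameter choices and numerical conventions
behind `evtrf`, and what the synthetic-data generator does and does not
emulate.

## Preprocessing

Reads are processed independently per sample and then collapsed cohort-wide.

**Adapter trimming.** A minimal 3′-adapter trimmer is implemented in-package
so its semantics are exact and testable: every alignment of the adapter
against the read is considered — internal full-adapter matches and
suffix-of-read/prefix-of-adapter overlaps — and a candidate is acceptable
when `errors / overlap ≤ max_error_rate` (default 0.1) with overlap ≥
`min_overlap` (default 3). The best candidate minimises the error rate, with
ties broken by longest overlap then leftmost position; the read is cut at
the match start. Reads without an acceptable match are kept untrimmed. Exact
matches are found by fast string search; the full scan only runs for reads
with errors in the adapter region.

**Quality and size selection.** Reads are dropped when mean Phred < 20
(default) or when they contain more than the allowed number of `N` bases
(default 0). Inserts outside 15–50 nt (inclusive) are removed, mirroring the
gel size-selection window of small-RNA library preparation.

**Collapsing.** Identical retained reads across the cohort become one
*fragment ID* with a count per sample. Column sums equal retained read
counts by construction, and collapsing is order-insensitive — both are
asserted as invariants in the tests.

## Mapping and class assignment

Fragments are mapped forward-strand against five reference databases
(miRNA, piRNA, snoRNA, rRNA, tRNA) with a Hamming scan over all reference
windows allowing at most 2 substitutions (no indels at this stage — indel
handling is deliberately deferred to the post-hoc variant step). Classes are
probed in the listed priority order; the first class with at least one hit
claims the fragment, and only minimal-mismatch hits within that class are
kept (ties all retained). Multi-mapping within a class counts the fragment
once for class totals — the unit of analysis is the fragment, not the
alignment. The mismatch allowance is applied globally, the same for every
class.

**tRF typing.** A tRNA hit starting within `end_tol` (default 3) nt of the
5′ end is a 5′-tRF; one ending within `end_tol` of the 3′ end is a 3′-tRF;
anything else is internal. Where a fragment's tied best hits disagree, 5′
wins over 3′ over internal. The tolerance is configurable because the
boundary between a "5′ fragment" and an internal fragment is a convention,
not a measurement.

**Coverage profiles.** Each tRNA-mapped fragment adds its read count (split
1/n across tied hits) to the 100 relative-position bins its reference
interval `[start, start+len)` intersects after rescaling to `[0, 100)`.
Two normalisations are available: `max` (default) scales so the deepest bin
reads 100%, matching a per-base-coverage-relative-to-peak reading of typical
coverage plots; `reads` reports the percentage of tRNA-mapped read weight
covering each bin. Both are exposed because published coverage percentages
are usually not defined precisely enough to distinguish them; the ratio of
5′-half to total mass is identical under both.

**CCA handling.** Reference tRNAs are stored as given; `ReferenceSet.with_cca()`
appends the post-transcriptional 3′-CCA where absent, as an explicit opt-in,
since databases vary in whether they include it. The synthetic tRNAs are
generated CCA-terminated.

## Normalisation and differential expression

RPM is computed within RNA class: the scaling factor for a fragment is the
total reads of its class in that sample, so for every sample and class with
reads the class column sums to exactly 10⁶. A class with zero reads in a
sample yields missing (not zero) RPM for that class/sample; for hypothesis
testing missing values are treated as zero abundance, since the class truly
contributed no reads to that library. Unmapped fragments carry no RPM.

The DE procedure filters to fragments with RPM strictly above 100 in at
least one filter sample (default: all samples of the contrast; a case-only
scope is available since the filtering sentence of the original protocol is
ambiguous on this point), tests each fragment case vs control with a
two-sided Mann–Whitney U, and corrects across the filtered set with
Benjamini–Hochberg. The exact permutation null is used when the pooled
sample size is ≤ 20 and the pooled values are tie-free; ties force the
tie-corrected normal approximation with continuity correction. Fold change
is `(median_case + 1) / (median_control + 1)` in RPM — medians, not means,
with a 1-RPM pseudocount to keep ratios finite. "Significant" means
BH-adjusted q < α (default 0.05). A paired Wilcoxon signed-rank test
(exact sign-pattern null up to 15 tie-free pairs) is provided for paired
designs such as uterine-vs-peripheral vein comparisons.

The top-k cumulative share ranks significant fragments by summed case-group
RPM and reports the fraction of the significant total captured by the top k
(k = 12 by default, matching the convention of summarising a complex DE
profile by its dozen most abundant fragments).

## Variant re-annotation

Fragments that fail substitution-only mapping are scored against an index of
exact tRNA 5′ prefixes (default lengths 28–36 nt, bracketing the 30–34 nt
tRF mode with margin for indels; identical prefixes from several tRNAs merge
into one entry listing all sources). The distance is a banded Levenshtein
distance with unit costs and band half-width 2; candidates whose length
differs from the fragment by more than 2 are skipped (an exhaustive mode
exists for verification and is tested equivalent). Substitutions are counted
by default — the primary mapper has already absorbed ≤2 substitutions, so
the post-hoc step is usually reached by indel variants, but a strict
indel-only cost model (substitution = delete + insert) is available by flag.
Ties at the minimal distance prefer the prefix shared by more tRNAs, then
the lexicographically smallest prefix; note a 1-indel variant of a length-L
prefix can tie at distance 1 with the length-(L±1) prefix of the *same*
tRNA, in which case either winner names the correct source. The operation
breakdown (substitutions/insertions/deletions) comes from a full-matrix
traceback against the winning prefix only.

## qPCR

Cq values strictly above 35 cycles are undetectable; 35.0 exactly is
retained. Pfaffl relative expression uses per-assay amplification
efficiencies E ∈ (1, 2] (default 2.0 — perfect doubling — since verified
assay linearity is typically reported without numeric efficiencies, and a
per-assay override is accepted), control-group median Cq as the calibrator,
and a final rescale so the control median is exactly 1. Samples with an
undetectable well in either assay are dropped with a log message rather than
imputed. Spike-in and endogenous reference assays are handled identically as
"reference assay".

Target selection requires a fragment to be significant, upregulated
(FC > 1), at or above the 90th percentile (linear interpolation between
order statistics — the convention used for every percentile in this package)
of case-median RPM among significant fragments, and at most 100 RPM
(configurable; a deliberate repo default, since "low abundance" has no
published cutoff) in every background dataset standing in for contaminating
blood-cell EV sources. The 85th-centile suspected-outlier rule removes
values strictly above the interpolated 85th percentile of their group; it is
off by default and applied, when enabled, to relative expression per group
per assay — the scope of the original rule is ambiguous, so it is an
explicit analysis choice rather than silent behaviour. The scramble-control
rule maps an RNA sequence U→A, preserving length.

## Synthetic-data generator

The generator emulates the study conditions rather than downloading data:

- **Cohort design**: 8 case vs 6 control samples by default, one compartment
  profile per cohort (EV-like or tissue-like).
- **Class mixtures**: EV-like libraries are tRNA-dominated (72% tRNA reads);
  tissue-like libraries are miRNA/rRNA-dominated (45%/33%) with a sharp
  22-nt miRNA mode. These produce the qualitative library signatures —
  EV modal insert length in 30–34 nt, tissue modal length 22 nt — that the
  pipeline's profiling stage must recover.
- **Fragments**: tRF fragments are exact 5′ prefixes (30–34 nt, mode 32) of
  random CCA-terminated 72–90 nt tRNAs; miRNA/piRNA fragments are whole
  references; snoRNA/rRNA fragments are internal windows. Within-class
  abundances are log-normal (σ = 1.3) so a few fragments dominate, as in
  real small-RNA libraries. Note the modal-length structure is only
  expressed at realistic fragment diversity (the defaults: ~340 fragments);
  heavily scaled-down universes let single abundant fragments distort the
  length histogram.
- **Counts**: negative-binomial via gamma–Poisson mixing with dispersion
  α = 0.3 (var = m + αm², i.e. biological CV ≈ 0.55), per fragment per
  sample; case-group means are multiplied by the configured fold change for
  designated fragments. Differentially expressed fragments are drawn from
  tRF fragments whose expected abundance is ≥ 500 RPM.
- **Reads**: fragment sequence + optional substitution errors + 3′ adapter +
  random padding to the 50-nt read length; constant Q40 qualities.
  Quality-degradation is configurable but off by default so quality
  filtering can be exercised without confounding other tests.
- **Indel variants**: a configured fraction of tRF *fragments* carry a fixed
  1–2-nt indel variant of their canonical prefix (indels never in the first
  3 nt, so the 5′ anchor stays intact). Draws whose applied operations
  reduce to fewer net edits (e.g. an insert/delete pair cancelling inside a
  homopolymer run) or collapse onto an exact prefix are rejected, so the
  recorded edit count equals the realized distance to the canonical 5′-tRF.
  Variants are fixed per fragment rather than drawn per read so that every
  read traces to exactly one truth row and differential expression stays
  well defined at the fragment level.
- **qPCR plates**: Cq = intercept − log_E(abundance) + N(0, σ), with
  per-sample loading variation shared between target and endogenous
  reference (so the Pfaffl ratio cancels it) and a constant-abundance
  spike-in assay. Non-positive abundance emits a Cq above the censoring
  cutoff.

Everything is deterministic for a fixed seed (byte-identical FASTQ and stage
outputs), which the tests assert.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: platform-specific error and quality profiles,
ligation and PCR biases of small-RNA library chemistry (including the
5′-phosphate/2′-3′-cyclic-phosphate end-chemistry differences that affect
which tRF species are captured), genomic multi-mapping across tRNA gene
families with realistic sequence similarity, isomiR complexity, and
batch or covariate structure between samples.

## Design notes and known limitations

- Class priority follows the database listing order (miRNA, piRNA, snoRNA,
  rRNA, tRNA) and is configurable; the arbitration rule of the original
  pipeline is not published, so the least surprising default is exposed
  rather than hidden.
- With n = 8 vs 6, the exact Mann–Whitney two-sided p-value floor is
  2/3003 ≈ 6.7 × 10⁻⁴. After BH across a few hundred filtered fragments,
  only fragments with at most about one rank inversion between groups can
  reach q < 0.05. Under the generator's dispersion default (α = 0.3) a
  4-fold change produces complete separation in only ~40% of replicates, so
  the measured sensitivity of the full procedure sits near 20–30% with
  per-seed FDR around 10–15%, driven by chance complete separations among
  null fragments and by the compositional shift class-wise RPM induces when
  abundant fragments change in one group. These measured operating
  characteristics are reported by `scripts/acceptance.py`; they are a
  property of small-cohort rank tests with discrete nulls, not a code
  limitation, and they would improve substantially at lower biological
  dispersion or larger cohorts.
- Under a global null the fraction of q < 0.05 calls is far below 0.05
  (BH is conservative for discrete, conservative per-test p-values); this
  calibration is asserted over hundreds of simulated cohorts.
- Problem sizes in the test-suite and acceptance script (cohorts of
  150–500 fragments, libraries of 10⁴–3 × 10⁴ reads, 20-seed averages for
  stochastic quantities, 100–200 cohorts for null calibration) are chosen as
  the smallest sizes at which the asserted properties are stable.
- The trimmer handles 3′ adapters only (no 5′ adapters, paired ends or
  UMIs); mapping is forward-strand, ungapped-within-class and
  transcriptome-only (no genome coordinates, no intron-containing
  pre-tRNAs).
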