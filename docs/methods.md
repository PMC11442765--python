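# Methods

## Assay model

The package models a targeted methylation assay in which genomic DNA is
digested by four methylation-sensitive restriction enzymes (HpaII CCGG,
HpyCH4IV ACGT, AciI CCGC, HinP1I GCGC; every motif carries a central CpG),
surviving fragments are captured by single-molecule molecular inversion
probes (smMIPs), and deduplicated read counts per probe measure the
abundance of fully methylated fragments.  Three probe classes exist:

* **CpG smMIPs** target regions with at least one recognition site; their
  fragments survive digestion only when every site is methylated (or when
  digestion fails).
* **Reference smMIPs** target regions with no recognition site, or no CpG
  at all; they are never cleaved and measure effective DNA input.
* **Lambda smMIPs** target unmethylated phage spike-in DNA in both
  flavors; surviving lambda CpG-target signal measures incomplete
  digestion.

### Motif scanning

Recognition sites are matched on both strands: forward occurrences of each
motif, plus forward occurrences of the reverse complement of the one
non-palindromic motif (CCGC → GCGG).  Palindromic motifs are counted once.
Coordinates are 0-based half-open throughout.  CpG coverage counts a CpG
as covered when its dinucleotide overlaps a recognition-site footprint;
overlap (rather than "C inside the footprint") is used because it makes
the fraction exactly invariant under reverse complementation, which a
double-stranded cutting model requires.

### Target selection

Candidate hypermethylated CpG sites from array beta values must have mean
methylation ≥ 0.5 in tumors, ≤ 0.3 in normal tissue and blood, and at
least one recognition site.  The tumor/normal thresholds are applied
per tissue type by default (`mode="per_type"`); whether the underlying
selection pooled the types is genuinely ambiguous, so a `pooled` switch is
provided.  Per-type is the stricter, more defensible reading: a site that
discriminates in every cancer type is what a multi-cancer panel needs.

## Synthetic-data generator

The simulator is the package's study surrogate: the real assay's cohort
data is controlled-access, so all statistical guarantees are demonstrated
on synthetic data whose generating process mirrors the assay.

* Per sample and CpG target, the true methylated fraction *m* is drawn
  from a condition-specific Beta distribution.  Defaults: tumor
  Beta(5.5, 4.5) (mean 0.55), adjacent normal Beta(2.5, 7.5) (mean 0.25),
  blood Beta(1.5, 8.5) (mean 0.15) — hypermethylated panel targets with a
  tumor–normal mean separation of 0.3 and blood lowest, matching the
  qualitative ordering the assay is designed around.
* A molecule survives digestion with probability `m + (1 − m)·ε_nd`, where
  `ε_nd` (default 0.013) is the incomplete-digestion rate; reference
  targets survive with probability 1, lambda CpG targets with `ε_nd`
  (lambda DNA is never methylated), and undigested control samples skip
  digestion entirely.  Capture is an independent Bernoulli event (default
  efficiency 0.5), so the deduplicated count is binomial with success
  probability `efficiency × survival` over `n_molecules_per_target`
  pre-capture molecules (default 1000).
* At read level each captured molecule is expanded into
  Geometric(1/mean) ≥ 1 PCR-duplicate read pairs (default mean 1, i.e. no
  duplication; the geometric is the simplest one-parameter overdispersed
  duplication model) sharing one 10-nt UMI.  Read 1 is a 5-nt UMI followed
  by the molecule 5' end (probe arm + insert prefix); read 2 is a 5-nt UMI
  followed by the reverse complement of the 3' end.  The exact molecular
  layout of the real assay is not modeled; arms, UMIs and barcodes sit at
  declared, configurable offsets, which is all the read processor relies
  on.  Uniform substitution errors are applied at `read_error_rate`.
* UMIs are drawn uniformly but re-sampled on collision within a
  (sample, probe) cell.  This is a deliberate idealization: it makes
  exact-key deduplication lossless, so a zero-error read-level run
  reproduces the count-level simulation exactly — an identity the test
  suite exploits as a pipeline oracle.  Real data would show rare UMI
  collisions and sequencing errors in tags, which this generator
  deliberately excludes from the identity check (they are exercised
  separately via nonzero error rates).
* Dual 8-nt sample barcodes are generated with pairwise combined Hamming
  distance ≥ 3, the minimum for unambiguous demultiplexing at one
  tolerated mismatch per barcode; configurations violating this are
  rejected at validation.
* Spike-in series: one tumor and one background (blood-like) methylation
  profile are drawn per target; a sample at spike fraction *f* has
  per-target `m = f·m_tumor + (1 − f)·m_background`, the linear mixture a
  DNA dilution produces.

What passing tests on this generator do **not** show: robustness to
fragment-length effects (cfDNA fragmentation is not modeled), enzyme- or
locus-specific digestion biases, non-uniform error profiles, mapping
ambiguity on a real genome, or batch effects between sequencing runs.

## Read processing

Demultiplexing requires each index read to match exactly one sample's
barcode within one mismatch; ambiguous hits are unassigned (specificity
over yield — unreachable in practice given the barcode-distance
validation).  Pairs are assigned to probes by looking up the read-proximal
arm sequence of each mate (exact dictionary lookup, then a one-mismatch
fallback) in a positional window; both mates must agree on the probe and
each mate's offset from the expected start must be ≤ 5 bp (inclusive).
Whole-genome alignment is unnecessary because targets are known; the
arm-lookup is the panel-reference equivalent.  A pairing-quality proxy
(60 minus 20 per arm mismatch) is filtered at strictly > 15.  Duplicates
collapse on the exact (sample, probe, 10-nt UMI) key — mirroring duplicate
marking on identical tags; UMI-network error correction is a possible
extension, not implemented.  UMIs containing N are discarded and tallied.
Every read pair ends in exactly one bucket (counted, a named discard
reason, or duplicate), and the tallies reconcile by construction.

## QC

The non-digestion percentage of a sample is

```
100 × (Σ lambda-CpG counts / Σ lambda-ref counts)_sample
    / mean over undigested controls of the same ratio
```

Depth is filtered first (total counts ≥ 5000, inclusive), and the control
mean is taken over undigested samples passing depth.  A digested sample is
removed when the percentage strictly exceeds 5% — "exceeds" read as
strict, so a sample at exactly 5.0% is retained.  CpG smMIPs with zero
counts in every sample are dropped as dead probes; all-zero reference or
lambda smMIPs are flagged but kept, because silently shrinking the
normalization denominator or the digestion control would bias downstream
statistics.

## Classifier construction

* **Normalization** divides each count by the sample's summed reference
  counts.  The default denominator is all reference smMIPs surviving the
  dead-probe rule; restricting to the ≥ 1000-cumulative-count "efficient"
  subset is available as an option, since normalization precedes
  efficiency selection in the analysis order and is not redone by default.
* **LDA** is one-dimensional per smMIP: class means, pooled within-class
  variance with an (n − 2) denominator, priors from class proportions.
  The score is the signed discriminant difference, oriented so larger
  values favor tumor.  Zero pooled variance yields a degenerate model that
  scores ±∞ by side of the class-mean midpoint.  LDA operates on
  normalized counts by default (`scale="raw"` available): the raw scale
  depends on DNA input, which normalization exists to remove.
* **Cross-validation** uses 5 folds stratified jointly on tissue ×
  condition: stratum members are shuffled and dealt cyclically, so
  per-stratum fold sizes differ by at most one; strata smaller than the
  fold count trigger a warning and leave some folds without that stratum.
  Folds whose held-out part is single-class are skipped and recorded.
  cvAUC is the arithmetic mean of fold AUCs.  AUC itself is the midrank
  (Mann-Whitney) statistic, ties counted half.
* **Filters**: cvAUC ≥ 0.8 ("below 0.8 removed", so 0.8 survives) and
  cumulative undigested counts ≥ 1000, both inclusive.  Of double-tiled
  sites the tile with higher cvAUC wins; ties break by higher undigested
  count, then lexicographic id.
* **Cutoffs**: per-model cutoffs are refit on the full training set after
  CV-based selection (the data split for cutoff fitting is not otherwise
  constrained; using all training data is the highest-power choice).
  Candidates are midpoints between adjacent distinct scores plus sentinels
  beyond both extremes; minimal FP + FN wins, ties resolved to the largest
  cutoff (favoring specificity).  The ensemble threshold *k* maximizes
  training accuracy of "≥ k votes ⇒ tumor", ties resolved to the smallest
  *k* (favoring sensitivity).  Blood samples train in the non-tumor class.
  All tie-breaks are deterministic; the seed only governs fold assignment.

## Characterization statistics

* **Bland-Altman**: bias = mean of run1 − run2, SD with n − 1, limits
  bias ± 1.96·SD.
* **Mann-Whitney**: exact two-sided p by enumeration of all label
  assignments for combined n ≤ 10 (naturally tie-correct); the normal
  approximation with continuity and tie correction otherwise.
* **Spike-in calibration**: classical calibration — regress response on
  expected percentage, invert the line for calculated percentages.
* **LOB/LOD**: LOB = mean(blank) + 1.645·SD(blank); LOD = LOB +
  1.645·SD(low-level), with the one-sided 95th-percentile constant 1.645
  and sample SDs; the methylation percentage at the LOD comes from the
  dilution-series calibration line.
* **Power**: two-sided unequal-variance normal approximation at Bonferroni
  per-test alpha.  The normal approximation (rather than noncentral t) is
  appropriate because the design claims are bounds ("holds 80% power") and
  the comparison direction is ≥.
* **ΔCt**: undigested fraction 2^(−ΔCt) with ΔCt = Ct(digested) −
  Ct(undigested); a negative ΔCt warns rather than errors.

## Problem sizes and determinism

Simulated demonstrations use a 58-target panel (40 CpG + 20 reference +
8 lambda smMIPs), training cohorts of 60 tumor / 48 normal / 12 blood
digested samples plus 4 undigested controls at 2000 molecules per target,
and held-out cohorts of 30 + 30; digestion-rate recovery uses 24 digested
samples at 100 000 molecules per target; the read-level fixture uses 12
samples at 150–200 molecules per target.  These sizes give stable
statistics while keeping any single run in seconds.  All randomness flows
from a single integer seed through `numpy.random.default_rng`; equal seeds
give byte-identical counts, reads and models.

## Known limitations

* Copy-number variation, partial methylation within a region, and
  hemimethylation are not modeled; a region counts only when fully
  methylated, matching the assay's all-sites-methylated readout.
* The classifier is binary (tumor vs non-tumor); tissue-of-origin
  prediction is out of scope.
* Probe design thermodynamics, SNP/repeat masking and real-genome scans
  are out of scope; synthetic arms are unique by construction.
* The exact-key UMI collapse does not correct sequencing errors inside
  tags; at nonzero read error rates a small count inflation is expected
  and visible in the discard tallies.
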