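# Methods

This note documents the models, defaults and numerical choices behind
amplipanel, and what the synthetic-data generators do and do not emulate.

## Panel-design cascade

The cascade turns a dense wild-population variant call set into a small,
well-spaced amplicon target panel. Stages run in a fixed order — dedup,
repeat-flank, indel, MAF/depth, placed, subsample, context, thinning — and
the exclusion ledger records (in, removed, out) for each, so `out` of stage
k always equals `in` of stage k+1 and any reordering is visible.

Parameters (all configurable in `DesignConfig`; defaults are the values a
MiSeq-scale fish-breeding study would use):

| parameter | default | meaning |
|---|---|---|
| `repeat_flank` | 200 bp | exclusion zone either side of an annotated repeat |
| `min_maf` | 0.2 | MAF floor, inclusive (MAF = 0.2 is kept) |
| `max_mean_depth` | 60× | exclusive ceiling (depth = 60 is removed); mean depth well above the genome-wide mode indicates collapsed paralogs/CNV |
| `subsample_fraction` | 0.0125 | exact-count random down-sampling |
| `context_flank` | 200 bp | window either side of the SNP scanned for bad context |
| `homopolymer_min` | 10 bp | poly-A/T/G/C run length that disqualifies a window |
| `microsat_min_units` | 5 | tandem CA/AC/GT/TG units (10 bp) that disqualify |
| `min_spacing` | 20,000 bp | minimum same-chromosome gap after thinning |
| `amplicon_size_range` | 125–175 bp | used to annotate target windows for primer design |

Decisions made where the design was genuinely open:

* **Depth ceiling reading.** The ceiling is exclusive (keep iff depth < 60);
  the boundary is configurable for users who prefer an inclusive rule.
* **Subsampling** selects exactly `round(fraction × n)` variants without
  replacement rather than per-variant Bernoulli draws, so output size is
  deterministic given the seed and downstream budgets are predictable.
* **Microsatellite motif family.** A CA tandem read one base later is an AC
  tandem, and GT/TG are the reverse-complement phases, so all four units
  are treated as one motif. The minimum tandem length is set at 5 units
  (10 bp) for parity with the homopolymer threshold.
* **Thinning** is a strict greedy left-to-right scan (accept a variant iff
  it lies ≥ `min_spacing` beyond the last accepted one). For 1-D selection
  under a minimum-gap constraint the greedy scan is optimal in count
  (verified against brute-force enumeration in the tests). Real designs
  often relax to "roughly" the target spacing; the strict rule is the
  reproducible choice and the spacing is a parameter.
* **Repeat proximity** is tested at the variant's point position, not over
  the whole future amplicon window, because the exclusion zone already
  includes a flank.
* **Ties** at identical (chrom, pos) are de-duplicated keeping the first
  record in file order, counted in the ledger's dedup stage.

Throughput budgeting is exact integer arithmetic:
`required_bases = amplicons × bases_per_amplicon × depth`,
`max_panel_size = floor(run_bases / (bases_per_amplicon × depth × samples))`.

## Genotype QC

Triage assigns each designed locus exactly one category, first match wins:
`no_amplicon` (locus absent from the genotyped output), `monoallelic` (only
one allele observed among called genotypes), `multiallelic` (≥ 3 alleles in
the call), `indel` (any allele longer than 1 bp), then `fail_qc`/`pass`
from the matrix filter. Report percentages use the designed panel size as
the denominator.

The matrix filter keeps a locus iff call rate ≥ 0.70, the locus is
biallelic, and mean depth ≥ 6× (both boundaries inclusive). When a locus
fails several criteria, its removal is attributed to the first failing
criterion in the order (call rate, biallelic, depth) so the per-criterion
counts are reproducible.

**Imputation.** LD-kNN imputation (the approach production pipelines often
use) is an external published algorithm and out of scope here. The default
imputer is the per-locus mode (ties → lower code): transparent,
deterministic, and adequate for the low missingness that survives a 70%
call-rate filter. A seeded Hardy-Weinberg draw (`allele_freq_draw`) is
provided for sensitivity analysis. Every QC report names the imputer used.
After imputation a final MAF ≥ 0.05 floor runs (inclusive).

Genotype codes count copies of the **minor** allele, recomputed per locus
from the analyzed samples (ALT dosage is flipped when the ALT frequency
exceeds 0.5; a tie keeps ALT as minor). This matches standard GWAS tooling
rather than raw VCF dosage.

## Repeatability

Per-locus mean depth is the arithmetic mean over **all** samples in a run;
absent (sample, locus) pairs count as depth 0 rather than being dropped, so
a panel locus that never amplifies contributes 0 instead of disappearing.
Zero-depth loci likewise stay in the between-run Pearson correlation by
default — a locus with no amplicon in either run is informative about the
panel — with a `detected_only` mode for the alternative convention.
Detection tables count loci at mean depth ≥ 1× and ≥ 6× as fractions of the
designed panel.

## Population structure and association

**Clustering** uses Euclidean distances between genotype-code vectors and
Ward linkage in the "D2" dialect (Lance–Williams update on squared
distances, merge heights on the distance scale), delegated to scipy's
`linkage(method="ward")`. Heights are non-decreasing by construction.

**Association** uses the dominant coding: carrier iff code ≥ 1. Each locus
yields a 2×2 carrier × case/control table (unknown phenotypes excluded) and
a two-sided Fisher's exact p: the sum of hypergeometric probabilities of
all tables with the observed margins whose probability is ≤ the observed
table's. The sum is computed from `hypergeom.logpmf` via `logsumexp`, with
the standard 1e-7 relative tie tolerance, so p-values remain accurate down
to the 10⁻⁵⁰ scale (verified against exact-rational enumeration to 1e-12).
A monomorphic carrier split returns p = 1 by convention, flagged. The
genome-wide significance line defaults to 5.2 × 10⁻⁸, treated as an opaque
configurable constant; no further multiple-testing correction is applied.
Odds ratios use the Haldane–Anscombe +0.5 correction when a cell is zero;
the correction never enters the p-value.

## Synthetic-data generators

All generators are pure functions of (plan, seed); a `numpy` Generator
seeded per output stream and fixed-width text serialization make outputs
byte-identical across runs. Each generator emits a truth manifest, and
tests read expectations only from the manifest.

* **Reference** (`gen_reference`): uniform-ACGT contigs with planted repeat
  intervals, homopolymer runs and microsatellites at manifest positions.
  The background is scrubbed of chance homopolymer runs ≥ 8 bp and chance
  ≥ 4-unit CA/AC/GT/TG tandems before planting (the scan thresholds are
  10 bp / 5 units), so context-scan outcomes are exactly the planted ones.
* **Wild panel** (`gen_wild_vcf`): 20 samples, 90 clean variants plus 30
  planted violators per filter class on a 40 kb slot grid (too-close pairs
  ride 10 kb behind a clean variant; unplaced variants get a scaffold).
  Genotypes are laid down with an exact minor-allele count at
  Hardy-Weinberg het/hom composition and permuted across samples, so each
  variant's realized MAF equals its planted MAF and its filter fate is
  deterministic, not merely probable. Per-sample depths are log-normal
  (mean 25×, σ = 0.35 — amplicon panels show locus-level amplification
  efficiency variance, which Poisson counts would understate); excess-depth
  violators use mean 120×, far from the 60× boundary.
* **Families** (`gen_families`): 10 full-sib families × 20 offspring, 500
  loci on 5 chromosomes. Founders are drawn from global allele frequencies
  (uniform 0.1–0.5); offspring segregate Mendelian with independent loci,
  except the sex block: the sire is heterozygous at the sex locus (dam
  homozygous), and transmits the carrier haplotype as a block over 5
  flanking markers each side with a per-marker flip probability of
  0.05 × distance — a recombination-style LD decay, so the nearest flanking
  marker associates almost as strongly as the causal locus. Carrier
  offspring are cases (males) with penetrance 1.0 by default; 2% of codes
  are masked missing to exercise the QC path.
* **Dual-run depths** (`gen_dual_run_depths`): 3,000 loci; per-locus
  log-depth is a shared latent efficiency plus independent per-run noise.
  For bivariate log-normals with common log-variance σ² and log-scale
  correlation ρ, the depth-scale Pearson correlation is
  (e^{ρσ²} − 1)/(e^{σ²} − 1); ρ is obtained by inverting this at the
  target r (0.99 default, σ = 0.6). Run means (28.2× / 23.2×) differ only
  through the location parameter, which leaves r untouched. Nine
  zero-amplicon loci are set to exactly 0 in both runs.

What the generators do **not** emulate: read-level sequencing error,
primer-competition and GC-amplification bias, genotyping-caller artifacts,
linkage between autosomal loci, population admixture beyond family
structure, and batch effects between runs. Passing tests therefore
demonstrate that the algorithms are correct against planted truth under
the stated models, not that a real study's error modes are handled.

## Problem sizes and runtime

Defaults are desk-scale: 300 wild variants / 20 samples for the design
fixture, 200 offspring × 500 loci for the family study, 3,000 loci for the
dual-run comparison, 100 simulation seeds for the recovery-rate estimate.
These sizes keep the full test suite and the acceptance script in the
tens-of-seconds range while leaving every estimator's sampling error small
relative to the tolerances tested.

## Known limitations

* The VCF writer emits dosage-coded diploid GT against the first ALT;
  het-alt multiallelic genotypes (e.g. 1/2) round-trip as dosage 2, not as
  the original allele pair (triage still counts them multiallelic via the
  record's allele set).
* The mode imputer ignores LD entirely; with high missingness it biases
  toward the major genotype and will shrink MAF estimates.
* `filter_near_repeats` tests the SNP point position; a repeat inside the
  amplicon window but > `repeat_flank` from the SNP is not flagged.
* Ward clustering inherits scipy's tie-breaking; trees for degenerate
  distance ties may differ from other implementations in leaf order,
  though merge heights agree.
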