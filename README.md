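# amplipanel

Toolkit for designing and analyzing **ultrahigh-multiplex amplicon SNP
genotyping panels** — the "design a few thousand genome-wide SNP targets,
amplify them all in one PCR tube, sequence hundreds of multiplexed samples
per run" approach used for aquaculture breeding programs and other
genotyping studies that need moderate marker density over many individuals.

It covers the desk side of such a study end to end:

* **Panel design** — select target SNPs from a wild-population variant call
  set through an auditable filter cascade: remove SNPs within 200 bp of
  annotated repeats, drop indels, require minor allele frequency (MAF)
  ≥ 0.2 and mean depth < 60× (a paralog/CNV guard), keep only placed
  chromosomes, randomly down-sample, screen ±200 bp of flanking sequence
  for homopolymer runs (≥ 10 bp) and CA/GT microsatellites, and thin so
  neighboring targets sit ≥ 20 kb apart. Every stage records
  (in, removed, out) in an exclusion ledger.
* **Throughput budgeting** — exact arithmetic for how many loci fit a run:
  `max_panel_size = floor(run_bases / (amplicon_bases × depth × samples))`.
* **Genotype QC** — triage every designed locus (no amplicon, monoallelic,
  multiallelic ≥ 3 alleles, indel, QC fail, pass), filter the genotype
  matrix (call rate ≥ 70%, biallelic, mean depth ≥ 6×), impute missing
  genotypes (per-locus mode by default), and apply a final MAF ≥ 5% floor.
* **Repeatability** — per-locus mean depth per run, Pearson *r* between
  independent runs, and detection tables at ≥ 1× / ≥ 6× thresholds.
* **Population structure & association** — Ward hierarchical clustering
  (ward.D2) on Euclidean distances between genotype vectors, and a
  dominant-model genome scan using Fisher's exact two-sided test per locus
  (carrier = at least one minor-allele copy), computed in log space so
  p-values at the 10⁻³⁰ scale remain exact.
* **Synthetic data** — seeded generators for every input format (reference
  FASTA with planted repeats/homopolymers/microsatellites, wild-panel VCF
  with planted filter violations, full-sib family genotypes segregating a
  heterogametic sex locus with an LD block, correlated dual-run depth
  tables), each with a truth manifest.

## Worked example

Simulate a study and run the whole workflow from the shell:

```sh
amplipanel simulate reference --seed 7 --out sim/ref
amplipanel simulate wild      --seed 7 --out sim/wild
amplipanel design --vcf sim/wild/wild.vcf --ref sim/ref/reference.fasta \
    --repeats sim/ref/repeats.bed --placed-chroms chr1 \
    --subsample-fraction 1.0 --out sim/design
```

prints the exclusion ledger of the cascade (the synthetic wild panel plants
30 violators of each filter among 90 clean variants):

```
dedup             300 ->      300 (-0)
repeat_flank      300 ->      270 (-30)
indel             270 ->      240 (-30)
maf_depth         240 ->      180 (-60)
placed            180 ->      150 (-30)
subsample         150 ->      150 (-0)
context           150 ->      120 (-30)
thinning          120 ->       90 (-30)
panel size: 90
```

Each line is one filter stage: 30 variants fall at the repeat-flank screen,
30 indels, 60 at the MAF/depth screen (30 low-MAF + 30 excess-depth), 30 on
unplaced scaffolds, 30 at the flanking-context screen and 30 at the 20 kb
thinning — exactly the planted violations — leaving the 90 clean variants
as the panel. Budgeting the published run parameters:

```sh
$ amplipanel budget --run-bases 4.5e9 --amplicon-bases 300 --depth 15 \
      --samples 326 --panel-size 3000
max panel size: 3067
genotypes per run: 978000
required bases for this panel: 4.4e+09
```

i.e. a MiSeq-class run of 4.5 Gb supports ~3,000 amplicons × 326 samples at
15× (978,000 genotype calls per run). The same library surface is available
in Python (`amplipanel.design_panel`, `amplipanel.gwas_dominant`, …); see
`docs/methods.md` for the underlying models and defaults.

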