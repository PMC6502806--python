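"""Seeded generators for every input the toolkit consumes.

The generators emulate the study design the analysis modules assume:

* a reference genome with planted repeat intervals, homopolymer runs and
  CA/GT microsatellites at manifest-recorded positions,
* a wild-population variant panel (default 20 samples) in which a known
  number of variants violate each panel-design filter — so the design
  cascade's exclusion ledger can be checked against planted truth,
* cultured full-sib families (default 10) segregating a heterogametic
  sex locus with an LD block of flanking markers, for clustering and
  association tests,
* correlated dual-run per-locus depths (default 3,000 loci, target
  Pearson r 0.99, nine zero-amplicon loci present in neither run).

Everything is a pure function of (plan, seed): fixed-width text
serialization and a single numpy Generator per output stream make outputs
byte-identical across runs.  Each generator returns a truth manifest;
downstream tests read expectations from the manifest, never by
re-deriving them.

Determinism of the planted-violator fixture is strict by design: the
random background sequence is scrubbed of chance homopolymer runs (>= 8 bp)
and chance >= 4-unit CA/AC/GT/TG tandems before features are planted, and
wild-panel genotypes are laid down with exact minor-allele counts (then
permuted across samples), so every variant's fate in the design cascade is
exactly the planted one rather than merely the most likely one.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .formats_io import (
    MISSING,
    GenomicInterval,
    PhenotypeTable,
    VariantRecord,
)
from .genotype_qc import GenotypeMatrix, LocusInfo
from .repeatability import DepthTable

__all__ = [
    "WildPanelPlan",
    "FamilyPlan",
    "DualRunPlan",
    "SimulationPlan",
    "ReferenceBundle",
    "gen_reference",
    "gen_wild_vcf",
    "gen_families",
    "gen_dual_run_depths",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Violation classes and the design-cascade stage at which each must fall.
VIOLATION_STAGE = {
    "near_repeat": "repeat_flank",
    "indel": "indel",
    "low_maf": "maf_depth",
    "high_depth": "maf_depth",
    "unplaced": "placed",
    "bad_context": "context",
    "too_close": "thinning",
}


@dataclass
class WildPanelPlan:
    """Wild-population variant panel with planted filter violations."""

    n_samples: int = 20           # wild-caught individuals resequenced
    n_clean: int = 90             # variants meant to survive the cascade
    n_per_violation: int = 30     # planted violators per filter class
    clean_allele_counts: tuple[int, int] = (8, 20)  # of 2n=40 -> MAF 0.2..0.5
    low_maf_allele_count: int = 2                   # 2/40 -> MAF 0.05
    depth_mean: float = 25.0      # lognormal mean per-sample depth
    depth_sigma: float = 0.35
    high_depth_mean: float = 120.0  # planted paralog-like excess depth
    slot_spacing: int = 40_000    # bp between variant slots on a contig
    too_close_offset: int = 10_000  # offset of a too-close planted pair

    @property
    def n_variants(self) -> int:
        return self.n_clean + len(VIOLATION_STAGE) * self.n_per_violation


@dataclass
class FamilyPlan:
    """Cultured full-sib families with a planted heterogametic sex locus."""

    n_families: int = 10
    sibs_per_family: int = 20
    n_loci: int = 500
    n_chrom: int = 5
    chrom_len: int = 2_000_000
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_halfwidth: int = 5     # markers either side of the sex locus
    ld_flip_base: float = 0.05      # per-step recombination-style flip prob
    penetrance: float = 1.0         # P(carrier -> case phenotype)
    missing_rate: float = 0.02
    depth_mean: float = 25.0
    depth_sigma: float = 0.3

    @property
    def n_samples(self) -> int:
        return self.n_families * self.sibs_per_family


@dataclass
class DualRunPlan:
    """Two sequencing runs sharing per-locus amplification efficiency."""

    n_loci: int = 3000
    target_r: float = 0.99          # Pearson r on the depth scale
    mean_depth: tuple[float, float] = (28.2, 23.2)
    sigma: float = 0.6              # total log-depth sd per run
    n_zero: int = 9                 # loci with no amplicon in either run


@dataclass
class SimulationPlan:
    """The full study-design plan; serializable to YAML byte-identically."""

    wild: WildPanelPlan = field(default_factory=WildPanelPlan)
    families: FamilyPlan = field(default_factory=FamilyPlan)
    dual_run: DualRunPlan = field(default_factory=DualRunPlan)
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def build(klass, data):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for key, value in data.items():
                if key not in fields:
                    raise ValueError(f"unknown plan field {key!r} for {klass.__name__}")
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[key] = value
            return klass(**kwargs)

        return cls(
            wild=build(WildPanelPlan, raw.get("wild", {})),
            families=build(FamilyPlan, raw.get("families", {})),
            dual_run=build(DualRunPlan, raw.get("dual_run", {})),
            seed=int(raw.get("seed", 0)),
        )


def _rng(plan_seed: int, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator."""
    return np.random.default_rng([plan_seed, stream])


# ---------------------------------------------------------------------------
# Shared genome layout for the wild panel + reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Slot:
    chrom: str
    pos: int        # 1-based variant position
    vclass: str     # "clean" or a VIOLATION_STAGE key


def _layout(plan: WildPanelPlan, seed: int) -> list[_Slot]:
    """Deterministic slot layout: which class sits at which position.

    Placed classes occupy 40 kb slots on chr1 in a seeded shuffled order;
    'too_close' violators ride 10 kb after the first clean slots;
    'unplaced' variants get their own scaffold.  The spacing guarantees a
    variant can only fail the filter its class plants.
    """
    rng = _rng(seed, 11)
    placed_classes = (
        ["clean"] * plan.n_clean
        + ["near_repeat"] * plan.n_per_violation
        + ["indel"] * plan.n_per_violation
        + ["low_maf"] * plan.n_per_violation
        + ["high_depth"] * plan.n_per_violation
        + ["bad_context"] * plan.n_per_violation
    )
    order = rng.permutation(len(placed_classes))
    shuffled = [placed_classes[i] for i in order]
    slots: list[_Slot] = []
    base = 100_000
    clean_seen = 0
    for vclass in shuffled:
        pos = base + 1  # 1-based
        slots.append(_Slot("chr1", pos, vclass))
        if vclass == "clean":
            clean_seen += 1
            if clean_seen <= plan.n_per_violation:
                slots.append(_Slot("chr1", pos + plan.too_close_offset, "too_close"))
        base += plan.slot_spacing
    sbase = 50_000
    for _ in range(plan.n_per_violation):
        slots.append(_Slot("scaffold_1", sbase + 1, "unplaced"))
        sbase += plan.slot_spacing
    return sorted(slots, key=lambda s: (s.chrom, s.pos))


def _contig_lengths(plan: WildPanelPlan) -> dict[str, int]:
    # chr1 hosts clean + near_repeat/indel/low_maf/high_depth/bad_context slots
    n_chr1_slots = plan.n_clean + 5 * plan.n_per_violation
    return {
        "chr1": 100_000 + plan.slot_spacing * (n_chr1_slots + 1),
        "scaffold_1": 50_000 + plan.slot_spacing * (plan.n_per_violation + 1),
    }


_SCRUB_HOMOPOLYMER = re.compile(rb"([ACGT])\1{7,}")
_SCRUB_MICROSAT = re.compile(rb"(?:CA){4,}|(?:AC){4,}|(?:GT){4,}|(?:TG){4,}")


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    """Uniform ACGT background with chance scanner-triggering motifs broken.

    Runs of >= 8 identical bases and >= 4 tandem CA/AC/GT/TG units are
    interrupted so that only *planted* features can fire the context
    scanners (the design thresholds are 10 bp and 5 units).
    """
    seq = bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())
    swap = {65: 67, 67: 65, 71: 84, 84: 71}  # A<->C, G<->T
    for pattern in (_SCRUB_HOMOPOLYMER, _SCRUB_MICROSAT):
        # breaking a run can in principle seed a new motif upstream, so
        # rescan until clean (converges immediately in practice)
        while True:
            hits = list(pattern.finditer(bytes(seq)))
            if not hits:
                break
            for m in hits:
                mid = (m.start() + m.end()) // 2
                seq[mid] = swap[seq[mid]]
    return seq


@dataclass
class ReferenceBundle:
    sequences: dict[str, str]
    repeats: list[GenomicInterval]
    manifest: dict


def gen_reference(plan: SimulationPlan) -> ReferenceBundle:
    """Reference FASTA sequences + repeat BED + planted-feature manifest.

    Feature placement relative to each violator slot (0-based, pos0 = the
    variant's 0-based position):

    * near_repeat, even slots: repeat interval [pos0-20, pos0+30) — the
      variant sits inside the repeat;
    * near_repeat, odd slots: repeat [pos0+100, pos0+160) — the variant is
      100 bp away, inside the 200 bp flank but outside the repeat;
    * bad_context, even slots: poly-T x 12 at [pos0+50, pos0+62);
    * bad_context, odd slots: (CA) x 6 at [pos0+50, pos0+62).
    """
    wild = plan.wild
    rng = _rng(plan.seed, 12)
    lengths = _contig_lengths(wild)
    seqs = {name: _random_sequence(rng, length) for name, length in lengths.items()}
    repeats: list[GenomicInterval] = []
    features: list[dict] = []
    for i, slot in enumerate(s for s in _layout(wild, plan.seed) if s.vclass != "clean"):
        pos0 = slot.pos - 1
        if slot.vclass == "near_repeat":
            if i % 2 == 0:
                iv = GenomicInterval(slot.chrom, pos0 - 20, pos0 + 30)
            else:
                iv = GenomicInterval(slot.chrom, pos0 + 100, pos0 + 160)
            repeats.append(iv)
            features.append(
                dict(kind="repeat", chrom=iv.chrom, start=iv.start, end=iv.end)
            )
        elif slot.vclass == "bad_context":
            motif = b"T" * 12 if i % 2 == 0 else b"CA" * 6
            start = pos0 + 50
            seqs[slot.chrom][start : start + len(motif)] = motif
            features.append(
                dict(
                    kind="homopolymer" if i % 2 == 0 else "microsatellite",
                    chrom=slot.chrom,
                    start=start,
                    end=start + len(motif),
                )
            )
    manifest = dict(
        contigs=lengths,
        features=features,
        placed_chroms=["chr1"],
        seed=plan.seed,
    )
    return ReferenceBundle(
        sequences={k: v.decode() for k, v in seqs.items()},
        repeats=repeats,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Wild-population VCF with planted violations
# ---------------------------------------------------------------------------


def _genotypes_for_count(
    rng: np.random.Generator, n_samples: int, allele_count: int
) -> np.ndarray:
    """Genotype codes with an exact total allele count, at Hardy-Weinberg
    het/hom composition for that frequency, shuffled across samples."""
    p = allele_count / (2 * n_samples)
    n_hom = int(round(n_samples * p * p))
    n_hom = min(n_hom, allele_count // 2)
    n_het = allele_count - 2 * n_hom
    if n_hom + n_het > n_samples:  # p near 0.5 rounding overflow
        n_hom = allele_count - n_samples
        n_het = allele_count - 2 * n_hom
    codes = np.array(
        [2] * n_hom + [1] * n_het + [0] * (n_samples - n_hom - n_het), dtype=np.int8
    )
    return rng.permutation(codes)


def gen_wild_vcf(
    plan: SimulationPlan,
) -> tuple[list[VariantRecord], dict]:
    """Wild-panel variant records plus a per-variant truth manifest.

    The manifest maps locus id -> {class, stage}; ``stage`` names the
    design-cascade stage that must remove the variant (None for clean
    variants, which must reach the final panel when the cascade runs with
    subsampling disabled).
    """
    wild = plan.wild
    rng = _rng(plan.seed, 13)
    slots = _layout(wild, plan.seed)
    records: list[VariantRecord] = []
    manifest_variants: dict[str, dict] = {}
    n = wild.n_samples
    lo, hi = wild.clean_allele_counts
    for slot in slots:
        if slot.vclass == "low_maf":
            k = wild.low_maf_allele_count
        else:
            k = int(rng.integers(lo, hi + 1))
        genotypes = _genotypes_for_count(rng, n, k)
        depth_mean = (
            wild.high_depth_mean if slot.vclass == "high_depth" else wild.depth_mean
        )
        mu = np.log(depth_mean) - wild.depth_sigma**2 / 2
        depths = np.maximum(
            1, np.round(rng.lognormal(mu, wild.depth_sigma, size=n))
        ).astype(int)
        if slot.vclass == "indel":
            ref, alts = "A", ("AT",)
        else:
            ref, alts = "A", ("G",)
        rec = VariantRecord(
            chrom=slot.chrom,
            pos=slot.pos,
            ref=ref,
            alts=alts,
            genotypes=tuple(int(g) for g in genotypes),
            depths=tuple(int(d) for d in depths),
            placed=slot.chrom == "chr1",
        )
        records.append(rec)
        manifest_variants[rec.locus_id()] = dict(
            vclass=slot.vclass, stage=VIOLATION_STAGE.get(slot.vclass)
        )
    manifest = dict(
        variants=manifest_variants,
        n_clean=wild.n_clean,
        n_per_violation=wild.n_per_violation,
        samples=[f"wild_{i:02d}" for i in range(n)],
        placed_chroms=["chr1"],
        seed=plan.seed,
    )
    return records, manifest


# ---------------------------------------------------------------------------
# Full-sib families with a heterogametic sex locus
# ---------------------------------------------------------------------------


def _family_loci(plan: FamilyPlan) -> tuple[list[LocusInfo], int]:
    """Evenly spaced loci over the chromosomes; returns loci and the index
    of the sex locus (middle locus of the last chromosome)."""
    per_chrom = plan.n_loci // plan.n_chrom
    extra = plan.n_loci - per_chrom * plan.n_chrom
    loci: list[LocusInfo] = []
    for c in range(plan.n_chrom):
        m = per_chrom + (1 if c < extra else 0)
        step = plan.chrom_len // (m + 1)
        chrom = f"chr{c + 1}"
        for i in range(m):
            pos = step * (i + 1)
            loci.append(LocusInfo(f"{chrom}:{pos}", chrom, pos))
    last_chrom = f"chr{plan.n_chrom}"
    last_idx = [i for i, l in enumerate(loci) if l.chrom == last_chrom]
    sex_idx = last_idx[len(last_idx) // 2]
    return loci, sex_idx


def gen_families(
    plan: SimulationPlan,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Full-sib family genotypes, sex phenotypes, and the truth manifest.

    Founders are drawn per family from global allele frequencies; offspring
    genotypes follow Mendelian segregation with independent loci, except the
    sex-chromosome block: the sire is heterozygous at the sex locus, the dam
    homozygous reference, and the sire transmits the carrier haplotype as a
    block over the flanking LD markers with a per-marker, distance-scaled
    flip probability (a recombination-style LD decay).  A child carrying the
    sex allele is a case (male) with the plan's penetrance.
    """
    fam = plan.families
    rng = _rng(plan.seed, 14)
    loci, sex_idx = _family_loci(fam)
    n_loci = len(loci)
    q = rng.uniform(*fam.founder_maf_range, size=n_loci)

    ld_idx = [
        sex_idx + d
        for d in range(-fam.ld_block_halfwidth, fam.ld_block_halfwidth + 1)
        if d != 0
        and 0 <= sex_idx + d < n_loci
        and loci[sex_idx + d].chrom == loci[sex_idx].chrom
    ]
    flip_prob = {j: min(0.5, fam.ld_flip_base * abs(j - sex_idx)) for j in ld_idx}
    block = [sex_idx] + ld_idx

    samples: list[str] = []
    codes = np.zeros((fam.n_samples, n_loci), dtype=np.int8)
    phenos: dict[str, str] = {}
    families: dict[str, str] = {}
    row = 0
    for f in range(fam.n_families):
        # founder haplotypes: [parent 0=sire, 1=dam] x [hap] x [locus]
        haps = rng.random((2, 2, n_loci)) < q  # allele 1 = minor
        haps[0, 0, sex_idx] = True   # sire carrier haplotype
        haps[0, 1, sex_idx] = False
        haps[1, :, sex_idx] = False  # dam homozygous non-carrier
        for j in ld_idx:  # carrier haplotype carries the block alleles
            haps[0, 0, j] = True
            haps[0, 1, j] = False
        for s in range(fam.sibs_per_family):
            sample = f"fam{f:02d}_sib{s:02d}"
            child = np.zeros(n_loci, dtype=np.int8)
            for parent in (0, 1):
                # independent Mendelian pick per locus...
                pick = rng.integers(0, 2, size=n_loci)
                allele = haps[parent, pick, np.arange(n_loci)]
                if parent == 0:
                    # ...except the sex block, transmitted as one haplotype
                    hap_choice = int(rng.integers(0, 2))
                    for j in block:
                        a = haps[0, hap_choice, j]
                        if j != sex_idx and rng.random() < flip_prob[j]:
                            a = haps[0, 1 - hap_choice, j]
                        allele[j] = a
                child += allele.astype(np.int8)
            codes[row] = child
            carrier = child[sex_idx] >= 1
            case = carrier if rng.random() < fam.penetrance else not carrier
            phenos[sample] = "case" if case else "control"
            families[sample] = f"fam{f:02d}"
            samples.append(sample)
            row += 1

    if fam.missing_rate > 0:
        mask = rng.random(codes.shape) < fam.missing_rate
        codes[mask] = MISSING

    mu = np.log(fam.depth_mean) - fam.depth_sigma**2 / 2
    depth = rng.lognormal(mu, fam.depth_sigma, size=n_loci)
    matrix = GenotypeMatrix(
        samples=samples, loci=loci, codes=codes, locus_mean_depth=depth
    )
    manifest = dict(
        families=families,
        sex_locus=loci[sex_idx].id,
        ld_block=[loci[j].id for j in ld_idx],
        ld_flip_prob={loci[j].id: flip_prob[j] for j in ld_idx},
        penetrance=fam.penetrance,
        seed=plan.seed,
    )
    return matrix, PhenotypeTable(phenos), manifest


# ---------------------------------------------------------------------------
# Dual-run depths
# ---------------------------------------------------------------------------


def gen_dual_run_depths(
    plan: SimulationPlan,
) -> tuple[DepthTable, DepthTable, dict]:
    """Two per-locus depth tables with a target depth-scale correlation.

    Per-locus log-depth is a shared latent efficiency plus independent
    per-run noise.  For bivariate lognormal variables with common log-scale
    variance sigma^2 and log-scale correlation rho, the depth-scale Pearson
    correlation is (exp(rho sigma^2) - 1) / (exp(sigma^2) - 1); rho is
    chosen by inverting that relation at the plan's target r.  Run means
    differ (28.2x vs 23.2x by default) through the location parameter only,
    which leaves r untouched (correlation is scale-invariant).  The plan's
    zero-amplicon loci are set to exactly zero in both runs.
    """
    dr = plan.dual_run
    rng = _rng(plan.seed, 15)
    s2 = dr.sigma**2
    if dr.target_r >= 1.0:
        rho = 1.0
    else:
        rho = float(np.log1p(dr.target_r * np.expm1(s2)) / s2)
    shared = rng.normal(0.0, np.sqrt(rho * s2), size=dr.n_loci)
    noise_sd = np.sqrt(max(0.0, (1 - rho)) * s2)
    loci = [f"locus_{i:04d}" for i in range(dr.n_loci)]
    tables = []
    for run_i, mean in enumerate(dr.mean_depth):
        eps = rng.normal(0.0, noise_sd, size=dr.n_loci)
        mu = np.log(mean) - s2 / 2
        depths = np.exp(mu + shared + eps)
        tables.append(depths)
    zero_idx = np.sort(rng.choice(dr.n_loci, size=dr.n_zero, replace=False))
    for depths in tables:
        depths[zero_idx] = 0.0
    import pandas as pd

    run1 = DepthTable("run1", pd.Series(tables[0], index=loci), n_samples=326)
    run2 = DepthTable("run2", pd.Series(tables[1], index=loci), n_samples=326)
    manifest = dict(
        zero_loci=[loci[i] for i in zero_idx],
        target_r=dr.target_r,
        log_scale_rho=rho,
        seed=plan.seed,
    )
    return run1, run2, manifest
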