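"""Readers and writers for the standard formats the toolkit touches.

One coordinate convention is used throughout: intervals (BED, amplicon
windows, repeat annotations) are 0-based half-open; variant positions mirror
VCF and stay 1-based.  Every function that mixes the two states the
conversion explicitly.

VCF access goes through :mod:`pysam`; FASTA through :mod:`pyfaidx`.
Multi-allelic VCF records are kept intact (not split into biallelic rows)
because downstream locus triage must count loci with three or more alleles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import pysam
from pyfaidx import Fasta

__all__ = [
    "MISSING",
    "GenomicInterval",
    "VariantRecord",
    "PhenotypeTable",
    "FormatError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "read_phenotypes",
    "write_phenotypes",
]

#: Sentinel genotype / depth code for a missing value.
MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def expanded(self, flank: int) -> "GenomicInterval":
        """Interval widened by ``flank`` on both sides, clipped at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank)

    def contains_pos1(self, pos: int) -> bool:
        """Whether a 1-based position falls inside this interval."""
        return self.start <= pos - 1 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class VariantRecord:
    """One candidate variant with per-sample genotypes and depths.

    ``pos`` is 1-based as in VCF.  ``genotypes`` holds per-sample
    non-reference allele counts in {0, 1, 2} with :data:`MISSING` for
    uncalled samples; the *minor*-allele orientation is recomputed per
    locus at use time (it depends on the analyzed sample set, and PLINK
    and VCF disagree on the stored dosage convention).  ``depths`` holds
    per-sample read depths with :data:`MISSING` where no DP was reported.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[int, ...]
    depths: tuple[int, ...] = ()
    placed: bool = True
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alts or any(not a for a in self.alts):
            raise ValueError("ref and alts must be nonempty")
        bad = [g for g in self.genotypes if g not in (0, 1, 2, MISSING)]
        if bad:
            raise ValueError(f"invalid genotype codes: {bad}")

    # -- derived statistics ------------------------------------------------

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def is_snv(self) -> bool:
        """True iff ref and every alt are single bases."""
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def called_genotypes(self) -> list[int]:
        return [g for g in self.genotypes if g != MISSING]

    def maf(self) -> float:
        """Minor allele frequency over called genotypes; NaN if none called.

        For multi-allelic records this folds all alternate alleles
        together (non-reference dosage), which is the convention the
        design-stage MAF filter uses.
        """
        called = self.called_genotypes()
        if not called:
            return float("nan")
        p_alt = sum(called) / (2 * len(called))
        return min(p_alt, 1.0 - p_alt)

    def mean_depth(self) -> float:
        """Mean per-sample depth over samples with depth data; NaN if none."""
        obs = [d for d in self.depths if d != MISSING]
        if not obs:
            return float("nan")
        return sum(obs) / len(obs)

    def interval(self) -> GenomicInterval:
        """The reference span as a 0-based half-open interval.

        1-based ``pos`` converts to 0-based start ``pos - 1``; the identity
        round-trip back to VCF coordinates is ``start + 1``.
        """
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref))

    def locus_id(self) -> str:
        return self.id if self.id else f"{self.chrom}:{self.pos}"


@dataclass
class PhenotypeTable:
    """Sample id -> phenotype in {'case', 'control', 'unknown'}."""

    phenotypes: dict[str, str] = field(default_factory=dict)

    VALID = ("case", "control", "unknown")

    def __post_init__(self) -> None:
        for sample, pheno in self.phenotypes.items():
            if pheno not in self.VALID:
                raise ValueError(f"invalid phenotype {pheno!r} for {sample!r}")

    def __getitem__(self, sample: str) -> str:
        return self.phenotypes.get(sample, "unknown")

    def __len__(self) -> int:
        return len(self.phenotypes)

    def n_cases(self) -> int:
        return sum(1 for p in self.phenotypes.values() if p == "case")

    def n_controls(self) -> int:
        return sum(1 for p in self.phenotypes.values() if p == "control")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _decode_gt(allele_indices) -> int:
    """Collapse a GT allele-index tuple to a non-reference dosage code."""
    if allele_indices is None:
        return MISSING
    idx = [a for a in allele_indices if a is not None]
    if not idx:
        return MISSING
    return sum(1 for a in idx if a > 0)


def read_vcf(path: str, placed_chroms: set[str] | None = None) -> list[VariantRecord]:
    """Read a VCF 4.x file into :class:`VariantRecord` objects in file order.

    Missing GT maps to :data:`MISSING`; multi-allelic records are preserved
    as single records.  If ``placed_chroms`` is given, each record's
    ``placed`` flag is set by membership, otherwise all records are flagged
    placed.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    records: list[VariantRecord] = []
    with vf:
        for rec in vf:
            genotypes = []
            depths = []
            for sample in rec.samples.values():
                genotypes.append(_decode_gt(sample.get("GT")))
                dp = sample.get("DP")
                depths.append(MISSING if dp is None else int(dp))
            placed = True if placed_chroms is None else rec.chrom in placed_chroms
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotypes=tuple(genotypes),
                    depths=tuple(depths),
                    placed=placed,
                    id=rec.id,
                )
            )
    return records


def read_vcf_samples(path: str) -> list[str]:
    """Sample names from a VCF header, in column order."""
    with pysam.VariantFile(path) as vf:
        return list(vf.header.samples)


def write_vcf(
    path: str,
    records: list[VariantRecord],
    samples: list[str],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records to an uncompressed VCF 4.2 file with GT and DP.

    Dosage codes are emitted as unphased diploid GT against the first ALT
    (0 -> 0/0, 1 -> 0/1, 2 -> 1/1, missing -> ./.), which round-trips with
    :func:`read_vcf` for biallelic records; multi-allelic het-alt calls are
    not representable by a dosage code and are emitted against ALT 1.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    seen: dict[str, int | None] = dict(contigs or {})
    for rec in records:
        seen.setdefault(rec.chrom, None)
    for chrom, length in seen.items():
        if length is None:
            header.add_line(f"##contig=<ID={chrom}>")
        else:
            header.add_line(f"##contig=<ID={chrom},length={length}>")
    for sample in samples:
        header.add_sample(sample)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            if len(rec.genotypes) != len(samples):
                raise ValueError(
                    f"{rec.locus_id()}: {len(rec.genotypes)} genotypes for "
                    f"{len(samples)} samples"
                )
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,  # pysam takes 0-based start; VCF pos is 1-based
                alleles=(rec.ref, *rec.alts),
                id=rec.id,
            )
            for i, sample in enumerate(samples):
                vrec.samples[sample]["GT"] = gt_map[rec.genotypes[i]]
                if rec.depths and rec.depths[i] != MISSING:
                    vrec.samples[sample]["DP"] = rec.depths[i]
            out.write(vrec)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file; intervals come back sorted per chromosome.

    BED is already 0-based half-open, so no coordinate shift is applied.
    Overlapping intervals are preserved; merging only happens through an
    explicit :func:`merge_intervals` call.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append(GenomicInterval(fields[0], start, end))
    return sorted(intervals)


def write_bed(path: str, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into a chrom -> sequence mapping (uppercased)."""
    try:
        fa = Fasta(path, duplicate_action="stop", rebuild=True)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables (per-sample depths; phenotypes)
# ---------------------------------------------------------------------------


def read_depth_table(path: str) -> dict[tuple[str, str], float]:
    """Read a per-sample per-locus depth TSV (columns sample, locus, depth).

    Depth "NA" (or empty) maps to a missing value, returned as NaN.
    """
    depths: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample", "locus", "depth"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: header must contain columns {sorted(required)}")
        for lineno, row in enumerate(reader, 2):
            key = (row["sample"], row["locus"])
            if key in depths:
                raise FormatError(f"{path}:{lineno}: duplicate (sample, locus) {key}")
            raw = row["depth"]
            if raw in ("NA", "", None):
                depths[key] = float("nan")
            else:
                depths[key] = float(raw)
                if depths[key] < 0:
                    raise FormatError(f"{path}:{lineno}: negative depth {raw}")
    return depths


def write_depth_table(path: str, depths: dict[tuple[str, str], float]) -> None:
    import math

    with open(path, "w") as fh:
        fh.write("sample\tlocus\tdepth\n")
        for (sample, locus), depth in depths.items():
            val = "NA" if math.isnan(depth) else f"{depth:g}"
            fh.write(f"{sample}\t{locus}\t{val}\n")


def read_phenotypes(path: str, known_samples: set[str] | None = None) -> PhenotypeTable:
    """Read a phenotype TSV (columns sample, phenotype).

    Phenotypes must be case/control/unknown.  If ``known_samples`` is given,
    samples outside it are rejected.
    """
    phenos: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample", "phenotype"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: header must contain columns {sorted(required)}")
        for lineno, row in enumerate(reader, 2):
            sample = row["sample"]
            if sample in phenos:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            if known_samples is not None and sample not in known_samples:
                raise FormatError(f"{path}:{lineno}: unknown sample {sample!r}")
            phenos[sample] = row["phenotype"]
    return PhenotypeTable(phenos)


def write_phenotypes(path: str, table: PhenotypeTable) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tphenotype\n")
        for sample, pheno in table.phenotypes.items():
            fh.write(f"{sample}\t{pheno}\n")
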