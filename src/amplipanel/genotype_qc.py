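"""Post-genotyping locus triage and the QC cascade.

Raw amplicon genotyping output loses loci for structural reasons (no
amplicon at all, monoallelic in the genotyped population, extra alleles,
indel calls) and for data-quality reasons (call rate, depth).  This module
classifies every designed locus into exactly one of those categories, then
filters the surviving genotype matrix (call rate >= 70%, biallelic, mean
depth >= 6x), imputes the remaining missing genotypes, and applies a final
minor-allele-frequency floor (5%) — yielding the analysis-ready matrix.

The published workflow used LinkImpute's LD-kNNi for imputation; that is an
external algorithm, so the imputers here are deliberately simple and
transparent: per-locus mode (default, deterministic) and a seeded
Hardy-Weinberg draw for sensitivity checks.  Every report states which
imputer ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formats_io import MISSING, VariantRecord

__all__ = [
    "LocusInfo",
    "GenotypeMatrix",
    "LocusTriage",
    "TRIAGE_CATEGORIES",
    "matrix_from_variants",
    "triage_loci",
    "filter_matrix",
    "impute_missing",
    "filter_maf_post",
    "qc_report",
    "retained_percent",
]

TRIAGE_CATEGORIES = (
    "no_amplicon",
    "monoallelic",
    "multiallelic",
    "indel",
    "fail_qc",
    "pass",
)


@dataclass(frozen=True)
class LocusInfo:
    id: str
    chrom: str
    pos: int
    n_alleles: int = 2


@dataclass
class GenotypeMatrix:
    """Samples x loci minor-allele-count codes with locus annotations.

    ``codes`` is an int8 array (n_samples, n_loci) over {0, 1, 2} with
    :data:`~amplipanel.formats_io.MISSING` (-1) for uncalled entries.  Codes
    count copies of the locus's *minor* allele in the analyzed sample set
    (recomputed at construction; ties go to the ALT allele).
    """

    samples: list[str]
    loci: list[LocusInfo]
    codes: np.ndarray
    locus_mean_depth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        if self.locus_mean_depth is None:
            self.locus_mean_depth = np.full(len(self.loci), np.nan)
        self.locus_mean_depth = np.asarray(self.locus_mean_depth, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of samples with a non-missing code."""
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return (self.codes != MISSING).sum(axis=0) / self.n_samples

    def maf(self) -> np.ndarray:
        """Per-locus minor allele frequency over called codes (NaN if none).

        Codes are minor-allele counts, so the raw frequency sum(codes)/2n can
        exceed 0.5 after subsetting samples; fold it back to [0, 0.5].
        """
        called = self.codes != MISSING
        n_called = called.sum(axis=0)
        counts = np.where(called, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts / (2.0 * n_called)
        freq = np.where(n_called > 0, freq, np.nan)
        return np.minimum(freq, 1.0 - freq)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in keep],
            codes=self.codes[:, keep].copy(),
            locus_mean_depth=self.locus_mean_depth[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.samples, columns=self.locus_ids())

    def write_tsv(self, path: str) -> None:
        df = self.to_frame().astype(object)
        df[df == MISSING] = "NA"
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path: str) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample", na_values="NA")
        codes = df.to_numpy(dtype=float)
        codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
        loci = []
        for locus_id in df.columns:
            chrom, _, pos = locus_id.partition(":")
            loci.append(LocusInfo(locus_id, chrom, int(pos) if pos else 0))
        return cls(samples=list(df.index), loci=loci, codes=codes)


def matrix_from_variants(
    variants: list[VariantRecord], samples: list[str]
) -> GenotypeMatrix:
    """Build a minor-allele-coded matrix from genotyped variant records.

    The minor allele is determined per locus from the analyzed samples: if
    the non-reference allele frequency exceeds 0.5 the dosage is flipped
    (code -> 2 - code); at exactly 0.5 the ALT allele is kept as minor.
    """
    n = len(samples)
    codes = np.full((n, len(variants)), MISSING, dtype=np.int8)
    depths = np.full(len(variants), np.nan)
    loci = []
    for j, rec in enumerate(variants):
        if len(rec.genotypes) != n:
            raise ValueError(
                f"{rec.locus_id()}: {len(rec.genotypes)} genotypes, {n} samples"
            )
        g = np.array(rec.genotypes, dtype=np.int8)
        called = g != MISSING
        if called.any():
            p_alt = g[called].sum() / (2.0 * called.sum())
            if p_alt > 0.5:
                g = np.where(called, 2 - g, MISSING).astype(np.int8)
        codes[:, j] = g
        depths[j] = rec.mean_depth()
        loci.append(LocusInfo(rec.locus_id(), rec.chrom, rec.pos, rec.n_alleles))
    return GenotypeMatrix(samples=list(samples), loci=loci, codes=codes,
                          locus_mean_depth=depths)


# ---------------------------------------------------------------------------
# Locus triage
# ---------------------------------------------------------------------------


@dataclass
class LocusTriage:
    """Mutually exclusive category per designed panel locus."""

    categories: dict[str, str]
    panel_size: int

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in TRIAGE_CATEGORIES + ("candidate",)}
        for cat in self.categories.values():
            out[cat] += 1
        return {k: v for k, v in out.items() if v or k != "candidate"}

    def finalize(self, pass_ids: set[str]) -> "LocusTriage":
        """Resolve 'candidate' loci into pass / fail_qc given the QC survivors."""
        resolved = {
            locus: (
                ("pass" if locus in pass_ids else "fail_qc")
                if cat == "candidate"
                else cat
            )
            for locus, cat in self.categories.items()
        }
        return LocusTriage(resolved, self.panel_size)


def triage_loci(
    genotyped_variants: list[VariantRecord],
    panel_locus_ids: list[str],
) -> tuple[LocusTriage, list[VariantRecord]]:
    """Classify each panel locus from the genotyped output.

    Categories (first match wins): absent from the genotyped set ->
    ``no_amplicon``; only one allele observed among called genotypes ->
    ``monoallelic``; >= 3 alleles in the call -> ``multiallelic``; any
    allele longer than one base -> ``indel``; otherwise ``candidate``
    (forwarded to the QC matrix filter).  Genotyped loci not in the panel
    are off-target: warned about and ignored.

    Returns the triage plus the candidate records, in panel order.
    """
    import logging

    by_id = {rec.locus_id(): rec for rec in genotyped_variants}
    off_target = set(by_id) - set(panel_locus_ids)
    if off_target:
        logging.getLogger(__name__).warning(
            "%d genotyped loci are not in the panel; ignored", len(off_target)
        )
    categories: dict[str, str] = {}
    candidates: list[VariantRecord] = []
    for locus in panel_locus_ids:
        rec = by_id.get(locus)
        if rec is None:
            categories[locus] = "no_amplicon"
            continue
        called = rec.called_genotypes()
        ref_seen = any(g in (0, 1) for g in called)
        alt_seen = any(g in (1, 2) for g in called)
        if not (ref_seen and alt_seen):
            categories[locus] = "monoallelic"
        elif rec.n_alleles >= 3:
            categories[locus] = "multiallelic"
        elif not rec.is_snv():
            categories[locus] = "indel"
        else:
            categories[locus] = "candidate"
            candidates.append(rec)
    return LocusTriage(categories, len(panel_locus_ids)), candidates


# ---------------------------------------------------------------------------
# Matrix QC cascade
# ---------------------------------------------------------------------------


def filter_matrix(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.70,
    min_mean_depth: float = 6.0,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Keep loci with call rate >= 70%, two alleles, and mean depth >= 6x.

    Removal counts attribute each removed locus to its *first* failing
    criterion in the fixed order (call_rate, biallelic, depth) so counts are
    reproducible when a locus fails several criteria at once.
    """
    call_rate = matrix.call_rate()
    depth = matrix.locus_mean_depth
    removed = {"call_rate": 0, "biallelic": 0, "depth": 0}
    keep = np.ones(matrix.n_loci, dtype=bool)
    for j in range(matrix.n_loci):
        if call_rate[j] < min_call_rate:
            removed["call_rate"] += 1
            keep[j] = False
        elif biallelic_only and matrix.loci[j].n_alleles != 2:
            removed["biallelic"] += 1
            keep[j] = False
        elif not np.isnan(depth[j]) and depth[j] < min_mean_depth:
            removed["depth"] += 1
            keep[j] = False
    return matrix.subset_loci(keep), removed


def impute_missing(
    matrix: GenotypeMatrix, method: str = "locus_mode", seed: int = 0
) -> GenotypeMatrix:
    """Replace every missing code; called codes are never altered.

    ``locus_mode``: the most frequent code at the locus (ties -> lower
    code), deterministic.  ``allele_freq_draw``: seeded draw from
    Hardy-Weinberg proportions at the locus MAF.
    """
    if method not in ("locus_mode", "allele_freq_draw"):
        raise ValueError(f"unknown imputation method {method!r}")
    codes = matrix.codes.copy()
    rng = np.random.default_rng(seed)
    for j in range(matrix.n_loci):
        col = codes[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        called = col[~miss]
        if called.size == 0:
            raise ValueError(
                f"locus {matrix.loci[j].id}: no called genotypes to impute from "
                "(should have been removed by the call-rate filter)"
            )
        if method == "locus_mode":
            counts = np.bincount(called, minlength=3)
            fill = int(np.argmax(counts))  # argmax takes the lowest code on ties
            col[miss] = fill
        else:
            q = called.sum() / (2.0 * called.size)  # minor allele frequency
            probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
            col[miss] = rng.choice(3, size=int(miss.sum()), p=probs)
    return replace(matrix, codes=codes)


def filter_maf_post(
    matrix: GenotypeMatrix, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Final MAF floor, applied after imputation: keep iff MAF >= 0.05."""
    maf = matrix.maf()
    keep = ~np.isnan(maf) & (maf >= min_maf)
    return matrix.subset_loci(keep)


def qc_report(
    triage: LocusTriage,
    removal_counts: dict[str, int],
    final_matrix: GenotypeMatrix,
) -> pd.DataFrame:
    """Per-category counts and percentages of the designed panel size.

    Percentages use the designed panel size as denominator and are rounded
    to one decimal; the final row is the retained ('pass') fraction.
    """
    final = triage.finalize(set(final_matrix.locus_ids()))
    counts = final.counts()
    rows = []
    for cat in TRIAGE_CATEGORIES:
        n = counts.get(cat, 0)
        rows.append((cat, n, round(100.0 * n / final.panel_size, 1)))
    df = pd.DataFrame(rows, columns=["category", "count", "percent_of_panel"])
    df.attrs["panel_size"] = final.panel_size
    df.attrs["removal_counts"] = dict(removal_counts)
    df.attrs["retained_percent"] = round(
        100.0 * final_matrix.n_loci / final.panel_size, 1
    )
    return df


def retained_percent(n_retained: int, panel_size: int) -> float:
    """Retained fraction of the designed panel, one decimal (e.g. 83.3)."""
    return round(100.0 * n_retained / panel_size, 1)
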