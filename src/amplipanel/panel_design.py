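"""Genome-wide SNP panel design for ultrahigh-multiplex amplicon sequencing.

The cascade selects a few thousand well-behaved, well-spaced SNPs from a
dense wild-population variant call set:

1. drop SNPs inside or within a flank (default 200 bp) of annotated repeats,
2. drop insertions/deletions (keep pure SNVs),
3. drop SNPs with minor allele frequency below a floor (default 0.2) or
   mean depth at or above a ceiling (default 60x, a paralog/CNV guard),
4. drop SNPs on unplaced scaffolds,
5. randomly down-sample to a workable candidate count (default 1.25%),
6. drop SNPs whose flanking sequence (default +/-200 bp) contains a
   homopolymer run (>=10 bp) or a CA/GT-type microsatellite tandem,
7. thin greedily so neighboring SNPs sit >= 20 kb apart.

Every stage records (in, removed, out) in an exclusion ledger so the design
is auditable, and throughput-budget arithmetic sizes the panel against the
sequencer's per-run output.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenomicInterval, VariantRecord

__all__ = [
    "DesignConfig",
    "BudgetSpec",
    "StageResult",
    "PanelDesign",
    "filter_near_repeats",
    "filter_snv_biallelic_prefilter",
    "filter_maf_depth",
    "filter_placed",
    "subsample",
    "scan_homopolymer",
    "scan_microsatellite",
    "filter_context",
    "thin_by_distance",
    "design_panel",
    "required_bases",
    "max_panel_size",
    "genotypes_per_run",
]

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "dedup",
    "repeat_flank",
    "indel",
    "maf_depth",
    "placed",
    "subsample",
    "context",
    "thinning",
)


@dataclass
class DesignConfig:
    """Tunable thresholds of the selection cascade (defaults = study values)."""

    repeat_flank: int = 200          # bp either side of an annotated repeat
    min_maf: float = 0.2             # keep iff MAF >= min_maf
    max_mean_depth: float = 60.0     # exclusive ceiling: keep iff depth < 60
    subsample_fraction: float = 0.0125
    context_flank: int = 200         # bp either side of the SNP scanned for context
    homopolymer_min: int = 10        # >=10 bp poly-A/T/G/C fires
    microsat_min_units: int = 5      # >=5 tandem 2-mer units (10 bp) fires
    min_spacing: int = 20_000        # bp between neighboring selected SNPs
    amplicon_size_range: tuple[int, int] = (125, 175)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positives = dict(
            repeat_flank=self.repeat_flank + 1,  # 0 allowed for the flank
            max_mean_depth=self.max_mean_depth,
            context_flank=self.context_flank,
            homopolymer_min=self.homopolymer_min,
            microsat_min_units=self.microsat_min_units,
            min_spacing=self.min_spacing,
        )
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.min_maf < 0:
            raise ValueError("min_maf must be >= 0")


@dataclass(frozen=True)
class BudgetSpec:
    """Sequencer throughput budget for sizing a panel."""

    run_output: float = 4.5e9        # bases per run (MiSeq v2, 300 cycles PE)
    bases_per_amplicon: int = 300    # sequenced bases per amplicon (read pair)
    target_depth: int = 15           # desired mean fold-coverage
    n_samples: int = 326             # multiplexed samples per run

    def __post_init__(self) -> None:
        for name in ("run_output", "bases_per_amplicon", "target_depth", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StageResult:
    stage: str
    n_in: int
    n_removed: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in - self.n_removed != self.n_out:
            raise ValueError(f"ledger does not telescope at stage {self.stage!r}")


@dataclass
class PanelDesign:
    """An ordered selected-locus panel plus its per-stage exclusion ledger."""

    loci: list[VariantRecord]
    ledger: list[StageResult]
    config: DesignConfig
    budget: BudgetSpec | None = None
    amplicon_windows: list[GenomicInterval] = field(default_factory=list)

    def ledger_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(s.stage, s.n_in, s.n_removed, s.n_out) for s in self.ledger],
            columns=["stage", "n_in", "n_removed", "n_out"],
        )

    def removed_at(self, stage: str) -> int:
        for s in self.ledger:
            if s.stage == stage:
                return s.n_removed
        raise KeyError(stage)

    def export_rows(self):
        """Panel export rows suitable as primer-designer input.

        Columns: chrom, 1-based pos, ref, alt, MAF, mean depth, amplicon
        window start/end (0-based half-open).
        """
        rows = []
        for rec, window in zip(self.loci, self.amplicon_windows):
            rows.append(
                dict(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=",".join(rec.alts),
                    maf=round(rec.maf(), 6),
                    mean_depth=round(rec.mean_depth(), 3),
                    window_start=window.start,
                    window_end=window.end,
                )
            )
        return rows

    def write_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.export_rows()).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------


def filter_near_repeats(
    variants: list[VariantRecord],
    repeat_intervals: list[GenomicInterval],
    flank: int = 200,
) -> tuple[list[VariantRecord], int]:
    """Remove variants inside any repeat interval expanded by ``flank``.

    The test uses the variant's point position (VCF 1-based pos converted to
    0-based) against flank-expanded 0-based half-open intervals.  Chromosomes
    absent from the repeat annotation are treated as repeat-free.
    """
    expanded: dict[str, list[tuple[int, int]]] = {}
    for iv in repeat_intervals:
        e = iv.expanded(flank)
        expanded.setdefault(e.chrom, []).append((e.start, e.end))
    for spans in expanded.values():
        spans.sort()
    starts = {c: np.array([s for s, _ in v]) for c, v in expanded.items()}
    ends = {c: np.array([e for _, e in v]) for c, v in expanded.items()}

    survivors: list[VariantRecord] = []
    n_removed = 0
    missing_chroms: set[str] = set()
    for rec in variants:
        if rec.chrom not in starts:
            missing_chroms.add(rec.chrom)
            survivors.append(rec)
            continue
        pos0 = rec.pos - 1
        # rightmost interval starting at or before pos0; intervals may overlap
        # after expansion, so check all candidates whose start <= pos0.
        idx = int(np.searchsorted(starts[rec.chrom], pos0, side="right"))
        if np.any(ends[rec.chrom][:idx] > pos0):
            n_removed += 1
        else:
            survivors.append(rec)
    if missing_chroms:
        logger.info(
            "repeat annotation lacks %d chromosome(s) (%s ...); treated as repeat-free",
            len(missing_chroms),
            sorted(missing_chroms)[0],
        )
    return survivors, n_removed


def filter_snv_biallelic_prefilter(
    variants: list[VariantRecord],
) -> list[VariantRecord]:
    """Keep pure SNVs: ref and every alt exactly one base (drops indels)."""
    return [rec for rec in variants if rec.is_snv()]


def filter_maf_depth(
    variants: list[VariantRecord],
    min_maf: float = 0.2,
    max_mean_depth: float = 60.0,
) -> tuple[list[VariantRecord], int]:
    """Keep iff MAF >= ``min_maf`` and mean depth < ``max_mean_depth``.

    MAF is computed from called genotypes only; mean depth over samples with
    depth data.  Loci with zero called genotypes are removed and counted
    separately (returned as the second element).
    """
    survivors: list[VariantRecord] = []
    n_uncalled = 0
    for rec in variants:
        maf = rec.maf()
        if math.isnan(maf):
            n_uncalled += 1
            continue
        depth = rec.mean_depth()
        if maf >= min_maf and (math.isnan(depth) or depth < max_mean_depth):
            survivors.append(rec)
    return survivors, n_uncalled


def filter_placed(
    variants: list[VariantRecord], placed_chrom_set: set[str] | None = None
) -> list[VariantRecord]:
    """Keep variants on placed chromosomes.

    If ``placed_chrom_set`` is None, the per-record ``placed`` flag decides.
    """
    if placed_chrom_set is None:
        return [rec for rec in variants if rec.placed]
    return [rec for rec in variants if rec.chrom in placed_chrom_set]


def subsample(
    variants: list[VariantRecord], fraction: float, seed: int
) -> list[VariantRecord]:
    """Select exactly round(fraction * n) variants uniformly without
    replacement, deterministic given ``seed``, preserving genome order."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(variants)
    if n == 0:
        return []
    k = int(round(fraction * n))
    if k == 0:
        raise ValueError(
            f"subsample of {n} variants at fraction {fraction} selects 0; "
            "use a larger fraction"
        )
    if k == n:
        return list(variants)
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=k, replace=False))
    return [variants[i] for i in chosen]


_HOMOPOLYMER_RE = {}  # min_len -> compiled pattern


def scan_homopolymer(seq: str, min_len: int = 10):
    """First run of >= ``min_len`` identical bases, or None.

    Case-insensitive; only A/C/G/T form runs (N never does).  Returns a
    (start, end) 0-based half-open span of the first maximal hit, or None.
    """
    pat = _HOMOPOLYMER_RE.get(min_len)
    if pat is None:
        pat = re.compile(r"([ACGT])\1{%d,}" % (min_len - 1), re.IGNORECASE)
        _HOMOPOLYMER_RE[min_len] = pat
    m = pat.search(seq)
    return None if m is None else (m.start(), m.end())


#: The CA/GT microsatellite motif family: a CA run read one base later is an
#: AC run, and GT/TG are the reverse-complement phases of the same repeat.
MICROSAT_UNITS = ("CA", "AC", "GT", "TG")


def scan_microsatellite(
    seq: str,
    unit_set: tuple[str, ...] = MICROSAT_UNITS,
    min_units: int = 5,
):
    """First tandem run of >= ``min_units`` copies of a 2-mer unit, or None."""
    best = None
    for unit in unit_set:
        pat = re.compile("(?:%s){%d,}" % (unit, min_units), re.IGNORECASE)
        m = pat.search(seq)
        if m and (best is None or m.start() < best[0]):
            best = (m.start(), m.end())
    return best


def filter_context(
    variants: list[VariantRecord],
    reference: dict[str, str],
    context_flank: int = 200,
    homopolymer_min: int = 10,
    microsat_units: tuple[str, ...] = MICROSAT_UNITS,
    microsat_min_units: int = 5,
) -> list[VariantRecord]:
    """Drop variants whose flanking window contains a homopolymer run or a
    microsatellite tandem.

    The window is [pos0 - flank, pos0 + flank + 1) in 0-based coordinates
    (the variant base included), clipped at contig ends; a feature only
    fires on the bases that fall inside the window.
    """
    survivors: list[VariantRecord] = []
    for rec in variants:
        if rec.chrom not in reference:
            raise KeyError(f"reference lacks chromosome {rec.chrom!r}")
        seq = reference[rec.chrom]
        pos0 = rec.pos - 1
        if pos0 >= len(seq):
            raise ValueError(
                f"{rec.locus_id()}: position beyond contig length {len(seq)} "
                "(assembly mismatch?)"
            )
        window = seq[max(0, pos0 - context_flank) : pos0 + context_flank + 1]
        if scan_homopolymer(window, homopolymer_min):
            continue
        if scan_microsatellite(window, microsat_units, microsat_min_units):
            continue
        survivors.append(rec)
    return survivors


def thin_by_distance(
    variants: list[VariantRecord], min_spacing: int = 20_000
) -> list[VariantRecord]:
    """Greedy left-to-right thinning so same-chromosome neighbors sit
    >= ``min_spacing`` bp apart.

    Input must be sorted by (chrom, pos).  The greedy scan is optimal for
    this 1-D selection problem (it keeps the maximum number of loci among
    all spacing-feasible subsets).
    """
    kept: list[VariantRecord] = []
    last: dict[str, int] = {}
    prev_key: tuple[str, int] | None = None
    for rec in variants:
        key = (rec.chrom, rec.pos)
        if prev_key is not None and key < prev_key:
            raise ValueError("variants must be sorted by (chrom, pos)")
        prev_key = key
        if rec.chrom not in last or rec.pos - last[rec.chrom] >= min_spacing:
            kept.append(rec)
            last[rec.chrom] = rec.pos
    return kept


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------


def _dedup(variants: list[VariantRecord]) -> list[VariantRecord]:
    """De-duplicate identical (chrom, pos), keeping the first in file order."""
    seen: set[tuple[str, int]] = set()
    out = []
    for rec in variants:
        key = (rec.chrom, rec.pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def design_panel(
    variants: list[VariantRecord],
    reference: dict[str, str],
    repeats: list[GenomicInterval],
    config: DesignConfig | None = None,
    placed_chrom_set: set[str] | None = None,
    budget: BudgetSpec | None = None,
) -> PanelDesign:
    """Run the whole selection cascade and return the panel + ledger.

    Stage order is fixed: dedup, repeat-flank, indel, MAF/depth, placed,
    subsample, context, thinning.  Raises if the final panel is empty (the
    ledger is attached to the exception for diagnosis).
    """
    config = config or DesignConfig()
    ledger: list[StageResult] = []

    def record(stage: str, n_in: int, survivors: list[VariantRecord]):
        ledger.append(StageResult(stage, n_in, n_in - len(survivors), len(survivors)))
        logger.info("stage %-12s %7d -> %7d", stage, n_in, len(survivors))
        return survivors

    current = record("dedup", len(variants), _dedup(variants))
    survivors, _ = filter_near_repeats(current, repeats, config.repeat_flank)
    current = record("repeat_flank", len(current), survivors)
    current = record("indel", len(current), filter_snv_biallelic_prefilter(current))
    survivors, _ = filter_maf_depth(current, config.min_maf, config.max_mean_depth)
    current = record("maf_depth", len(current), survivors)
    current = record("placed", len(current), filter_placed(current, placed_chrom_set))
    current = record(
        "subsample",
        len(current),
        subsample(current, config.subsample_fraction, config.rng_seed),
    )
    current = record(
        "context",
        len(current),
        filter_context(
            current,
            reference,
            config.context_flank,
            config.homopolymer_min,
            MICROSAT_UNITS,
            config.microsat_min_units,
        ),
    )
    current = sorted(current, key=lambda r: (r.chrom, r.pos))
    current = record("thinning", len(current), thin_by_distance(current, config.min_spacing))

    if not current:
        err = ValueError("panel design produced no loci")
        err.ledger = ledger  # type: ignore[attr-defined]
        raise err

    half = config.amplicon_size_range[1] // 2
    windows = [
        GenomicInterval(
            rec.chrom,
            max(0, rec.pos - 1 - half),
            min(len(reference[rec.chrom]), rec.pos + half),
        )
        for rec in current
    ]
    return PanelDesign(
        loci=current, ledger=ledger, config=config, budget=budget,
        amplicon_windows=windows,
    )


# ---------------------------------------------------------------------------
# Throughput budgeting
# ---------------------------------------------------------------------------


def required_bases(n_amplicons: int, bases_per_amplicon: int, depth: int) -> int:
    """Bases of sequencer output needed: amplicons x bases x depth."""
    return n_amplicons * bases_per_amplicon * depth


def max_panel_size(
    run_output: float, bases_per_amplicon: int, depth: int, n_samples: int
) -> int:
    """Largest panel sequenceable per run at the target depth:
    floor(run_output / (bases_per_amplicon * depth * n_samples))."""
    return int(run_output // (bases_per_amplicon * depth * n_samples))


def genotypes_per_run(panel_size: int, n_samples: int) -> int:
    """Genotype calls produced by one run: panel_size x n_samples."""
    return panel_size * n_samples
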