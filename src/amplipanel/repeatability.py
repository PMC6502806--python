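"""Cross-run depth repeatability statistics.

A fixed amplicon panel should recover the same loci at similar depth every
run.  This module condenses per-sample per-locus depths into per-locus run
means, correlates the means between two independent runs (Pearson r), and
tabulates how many panel loci clear detection thresholds (>=1x, >=6x by
default).  Loci with no reads in a run enter the statistics at depth 0
rather than being dropped: a locus that amplifies in neither run is real
information about the panel, not missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthTable",
    "RunComparison",
    "mean_depth_per_locus",
    "pearson_r",
    "detection_table",
    "compare_runs",
]


@dataclass
class DepthTable:
    """Per-locus mean depth for one sequencing run."""

    run_id: str
    depths: pd.Series  # index: locus id, values: mean depth (>= 0)
    n_samples: int

    def __post_init__(self) -> None:
        self.depths = pd.Series(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("mean depths must be non-negative")

    @property
    def n_loci(self) -> int:
        return len(self.depths)

    def mean_depth(self) -> float:
        """Run-level mean of per-locus mean depths."""
        return float(self.depths.mean())

    def write_tsv(self, path: str) -> None:
        df = self.depths.rename("mean_depth").rename_axis("locus").reset_index()
        with open(path, "w") as fh:
            fh.write(f"# run={self.run_id}\tn_samples={self.n_samples}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "DepthTable":
        run_id, n_samples = "run", 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = dict(
                    kv.split("=", 1) for kv in first[1:].strip().split("\t") if "=" in kv
                )
                run_id = meta.get("run", run_id)
                n_samples = int(meta.get("n_samples", 0))
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(run_id, df.set_index("locus")["mean_depth"], n_samples)


def mean_depth_per_locus(
    per_sample_depths: dict[tuple[str, str], float],
    run_id: str = "run",
    loci: list[str] | None = None,
    samples: list[str] | None = None,
) -> DepthTable:
    """Per-locus arithmetic mean depth over all samples in the run.

    ``per_sample_depths`` maps (sample, locus) to depth.  Absent
    (sample, locus) pairs count as depth 0, so the denominator is the full
    sample count of the run for every locus; NaN depths are treated as
    absent (0).  ``loci`` may pin the locus universe (e.g. the panel) so
    loci with no reads anywhere appear with mean 0.
    """
    all_samples = sorted(samples or {s for s, _ in per_sample_depths})
    all_loci = list(loci) if loci is not None else sorted({l for _, l in per_sample_depths})
    n = len(all_samples)
    if n == 0:
        raise ValueError("no samples in depth table")
    totals = pd.Series(0.0, index=all_loci)
    for (sample, locus), depth in per_sample_depths.items():
        if locus in totals.index and not np.isnan(depth):
            totals[locus] += depth
    return DepthTable(run_id, totals / n, n)


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises on length < 2, length mismatch, or zero variance in either
    vector (the correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def detection_table(
    depth_table: DepthTable,
    thresholds: list[float] = (1, 6),
    panel_size: int | None = None,
) -> pd.DataFrame:
    """Loci with mean depth >= threshold, as count and fraction of panel.

    ``panel_size`` defaults to the table's locus count; fractions use the
    panel size as denominator so undetected panel loci count against it.
    """
    denom = panel_size if panel_size is not None else depth_table.n_loci
    rows = []
    for t in thresholds:
        count = int((depth_table.depths >= t).sum())
        rows.append((t, count, count / denom if denom else float("nan")))
    return pd.DataFrame(rows, columns=["threshold", "n_detected", "fraction"])


@dataclass
class RunComparison:
    r: float
    run_means: dict[str, float]
    detection: dict[str, pd.DataFrame]
    n_loci: int
    n_zero_fill: int = 0
    detected_only: bool = False

    def summary_frame(self) -> pd.DataFrame:
        rows = [("pearson_r", self.r), ("n_loci", self.n_loci)]
        rows += [(f"mean_depth[{k}]", v) for k, v in self.run_means.items()]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def compare_runs(
    run1: DepthTable,
    run2: DepthTable,
    thresholds: list[float] = (1, 6),
    panel_size: int | None = None,
    detected_only: bool = False,
) -> RunComparison:
    """Full repeatability report between two runs.

    Loci are outer-joined; a locus absent from one table is zero-filled (and
    the fill count reported).  ``detected_only`` restricts the correlation
    to loci with depth > 0 in at least one run.  The correlation is
    symmetric in run order.
    """
    joined = pd.concat(
        [run1.depths.rename("a"), run2.depths.rename("b")], axis=1
    )
    n_zero_fill = int(joined.isna().to_numpy().sum())
    joined = joined.fillna(0.0)
    if detected_only:
        joined = joined[(joined["a"] > 0) | (joined["b"] > 0)]
    r = pearson_r(joined["a"], joined["b"])
    denom = panel_size if panel_size is not None else len(joined)
    detection = {
        run1.run_id: detection_table(
            DepthTable(run1.run_id, joined["a"], run1.n_samples), thresholds, denom
        ),
        run2.run_id: detection_table(
            DepthTable(run2.run_id, joined["b"], run2.n_samples), thresholds, denom
        ),
    }
    return RunComparison(
        r=r,
        run_means={run1.run_id: float(joined["a"].mean()),
                   run2.run_id: float(joined["b"].mean())},
        detection=detection,
        n_loci=len(joined),
        n_zero_fill=n_zero_fill,
        detected_only=detected_only,
    )


def scatter_plot(run1: DepthTable, run2: DepthTable, path: str) -> None:
    """Depth scatter with marginal histograms (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joined = pd.concat(
        [run1.depths.rename("a"), run2.depths.rename("b")], axis=1
    ).fillna(0.0)
    fig = plt.figure(figsize=(6, 6))
    grid = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                            hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(grid[1, 0])
    ax_top = fig.add_subplot(grid[0, 0], sharex=ax)
    ax_right = fig.add_subplot(grid[1, 1], sharey=ax)
    ax.scatter(joined["a"], joined["b"], s=4, alpha=0.4)
    ax.set_xlabel(f"mean depth, {run1.run_id}")
    ax.set_ylabel(f"mean depth, {run2.run_id}")
    ax_top.hist(joined["a"], bins=50)
    ax_right.hist(joined["b"], bins=50, orientation="horizontal")
    for a in (ax_top, ax_right):
        a.tick_params(labelbottom=False, labelleft=False)
    fig.savefig(path, dpi=120)
    plt.close(fig)
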