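"""Fixed-size windows along the assembly with per-parent coverage metrics.

The interval table is a pandas DataFrame with one row per window, carrying
mask/coverage counts for both parents, the information-sufficiency flag, and
(after the intermixing step) the Jaccard index and assignment columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, Thresholds
from .regions import RegionSet

INTERVAL_COLUMNS = [
    "chrom", "start", "end", "n_mask",
    "n_cov1", "mean_cov1", "frac_cov1",
    "n_cov2", "mean_cov2", "frac_cov2",
    "n_union", "n_excl1", "n_excl2", "sufficient",
]


def partition_genome(lengths: dict[str, int], window: int) -> pd.DataFrame:
    """Consecutive [kW, (k+1)W) windows per sequence; the last may be partial."""
    if window <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom in sorted(lengths):
        n = lengths[chrom]
        starts = np.arange(0, n, window, dtype=np.int64)
        ends = np.minimum(starts + window, n)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _window_stats(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum of `values` within windows delimited by `starts` (np.add.reduceat)."""
    if values.size == 0:
        return np.zeros(len(starts), dtype=np.int64)
    return np.add.reduceat(values.astype(np.int64), starts)


def interval_sufficiency(
    n_mask: np.ndarray, n_union: np.ndarray, thresholds: Thresholds
) -> np.ndarray:
    """Information-sufficiency rule for a window.

    Sufficient iff the window has at least ``interval_min_positions`` mask
    positions, at least ``interval_min_covered`` of them covered by one or
    both parents, and that covered count is at least
    ``interval_min_covered_frac`` of the mask positions.
    """
    n_mask = np.asarray(n_mask)
    n_union = np.asarray(n_union)
    return (
        (n_mask >= thresholds.interval_min_positions)
        & (n_union >= thresholds.interval_min_covered)
        & (n_union >= thresholds.interval_min_covered_frac * n_mask)
    )


def interval_table(
    mask: RegionSet,
    track1: CoverageTrack,
    track2: CoverageTrack,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Per-window coverage metrics for both parents.

    Mean coverage is over covered positions only; covered fraction is
    n_covered / n_mask; exclusive counts are positions covered (depth >=
    min_coverage) by one parent and not the other.
    """
    windows = partition_genome(mask.lengths, thresholds.interval_size)
    parts = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        m = mask.to_bool_array(chrom)
        d1 = track1.depth[chrom]
        d2 = track2.depth[chrom]
        c1 = d1 > 0
        c2 = d2 > 0
        starts = sub["start"].to_numpy()
        n_mask = _window_stats(m, starts)
        n_cov1 = _window_stats(c1, starts)
        n_cov2 = _window_stats(c2, starts)
        sum1 = _window_stats(d1, starts)
        sum2 = _window_stats(d2, starts)
        n_union = _window_stats(c1 | c2, starts)
        n_excl1 = _window_stats(c1 & ~c2, starts)
        n_excl2 = _window_stats(c2 & ~c1, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean1 = np.where(n_cov1 > 0, sum1 / np.maximum(n_cov1, 1), np.nan)
            mean2 = np.where(n_cov2 > 0, sum2 / np.maximum(n_cov2, 1), np.nan)
            frac1 = np.where(n_mask > 0, n_cov1 / np.maximum(n_mask, 1), 0.0)
            frac2 = np.where(n_mask > 0, n_cov2 / np.maximum(n_mask, 1), 0.0)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": sub["start"].to_numpy(),
                    "end": sub["end"].to_numpy(),
                    "n_mask": n_mask,
                    "n_cov1": n_cov1,
                    "mean_cov1": mean1,
                    "frac_cov1": frac1,
                    "n_cov2": n_cov2,
                    "mean_cov2": mean2,
                    "frac_cov2": frac2,
                    "n_union": n_union,
                    "n_excl1": n_excl1,
                    "n_excl2": n_excl2,
                }
            )
        )
    table = pd.concat(parts, ignore_index=True)
    table["sufficient"] = interval_sufficiency(
        table["n_mask"].to_numpy(), table["n_union"].to_numpy(), thresholds
    )
    return table[INTERVAL_COLUMNS]


def featured_fraction(table: pd.DataFrame, assembly_size: int) -> dict[str, float]:
    """Genome-representation bookkeeping.

    ``informative``: fraction of assembly positions inside the include mask;
    ``featured``: fraction of assembly bp lying in information-sufficient
    windows.
    """
    informative = int(table["n_mask"].sum())
    suff = table[table["sufficient"]]
    featured_bp = int((suff["end"] - suff["start"]).sum())
    return {
        "informative_fraction": informative / assembly_size if assembly_size else 0.0,
        "featured_fraction": featured_bp / assembly_size if assembly_size else 0.0,
    }
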