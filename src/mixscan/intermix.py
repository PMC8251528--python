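"""Binned presence/absence vectors and the per-interval Jaccard intermixing index.

Each information-sufficient window is split into ``bin_count`` bins. A parent
is present in a bin when it covers at least ``bin_min_frac`` of the bin's
mask positions; after normalizing the second parent's bin coverage by the
genome-wide mean-depth ratio, a bin where the lower normalized mean falls
below (1 - coverage_band) of the higher loses the lower parent. The Jaccard
index of a window is the number of bins present for both parents divided by
the number present for at least one.

The band comparison is computed by cross-multiplication (c1 * mean2 versus
c2 * mean1) so that swapping the declaration order of the parents yields
bit-identical presence vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, PairNormalization, Thresholds
from .regions import RegionSet


@dataclass
class BinPresence:
    """Per-bin presence vectors and audit metrics for one window."""

    chrom: str
    start: int
    end: int
    edges: np.ndarray          # bin boundaries, length B+1
    n_mask: np.ndarray         # mask positions per bin
    present1: np.ndarray       # bool, length B
    present2: np.ndarray
    frac1: np.ndarray          # per-bin covered fraction, audit
    frac2: np.ndarray
    mean1: np.ndarray          # per-bin mean depth over covered positions, audit
    mean2: np.ndarray


@dataclass
class JaccardResult:
    jaccard: float             # NaN when union empty
    n_intersection: int
    n_union: int


def bin_edges(start: int, end: int, bin_count: int) -> np.ndarray:
    """Bin boundaries: width ceil((end-start)/B); the last bin may be short."""
    width = math.ceil((end - start) / bin_count)
    edges = start + width * np.arange(bin_count + 1, dtype=np.int64)
    return np.minimum(edges, end)


def _bin_sums(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Sums of `values` (a slice-aligned array starting at edges[0]) per bin."""
    rel = edges - edges[0]
    out = np.zeros(len(edges) - 1, dtype=np.int64)
    for i in range(len(out)):
        if rel[i + 1] > rel[i]:
            out[i] = values[rel[i]:rel[i + 1]].sum(dtype=np.int64)
    return out


def bin_presence(
    chrom: str,
    start: int,
    end: int,
    mask_arr: np.ndarray,
    depth1: np.ndarray,
    depth2: np.ndarray,
    norm: PairNormalization,
    thresholds: Thresholds,
) -> BinPresence:
    """Presence vectors for one window.

    ``mask_arr``/``depth1``/``depth2`` are the dense per-position arrays of
    the whole sequence; depths are already mask-restricted and thresholded.
    """
    edges = bin_edges(start, end, thresholds.bin_count)
    m = mask_arr[start:end]
    d1 = depth1[start:end]
    d2 = depth2[start:end]
    c1 = d1 > 0
    c2 = d2 > 0
    n_mask = _bin_sums(m, edges)
    n_cov1 = _bin_sums(c1, edges)
    n_cov2 = _bin_sums(c2, edges)
    sum1 = _bin_sums(d1, edges)
    sum2 = _bin_sums(d2, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = np.where(n_mask > 0, n_cov1 / np.maximum(n_mask, 1), 0.0)
        frac2 = np.where(n_mask > 0, n_cov2 / np.maximum(n_mask, 1), 0.0)
        mean1 = np.where(n_cov1 > 0, sum1 / np.maximum(n_cov1, 1), np.nan)
        mean2 = np.where(n_cov2 > 0, sum2 / np.maximum(n_cov2, 1), np.nan)

    # step 1: the 10% bin-coverage filter (empty-mask bins fail for both)
    present1 = (n_mask > 0) & (frac1 >= thresholds.bin_min_frac)
    present2 = (n_mask > 0) & (frac2 >= thresholds.bin_min_frac)

    # steps 2+3: normalize parent2 by the genome-wide ratio and drop the
    # parent with the lower normalized mean when outside the +-band.
    # c2 * ratio < (1-band) * c1  <=>  c2 * mean1 < (1-band) * c1 * mean2
    both = present1 & present2
    keep = 1.0 - thresholds.coverage_band
    u = mean1 * norm.mean2   # parent1 bin mean, common scale
    v = mean2 * norm.mean1   # parent2 bin mean, normalized, common scale
    with np.errstate(invalid="ignore"):
        drop2 = both & (v < keep * u)
        drop1 = both & (u < keep * v)
    present1 = present1 & ~drop1
    present2 = present2 & ~drop2
    return BinPresence(
        chrom, start, end, edges, n_mask, present1, present2,
        frac1, frac2, mean1, mean2,
    )


def jaccard_index(presence: BinPresence) -> JaccardResult:
    """J = |both present| / |either present|; NaN when the union is empty."""
    inter = int((presence.present1 & presence.present2).sum())
    union = int((presence.present1 | presence.present2).sum())
    j = inter / union if union > 0 else float("nan")
    return JaccardResult(j, inter, union)


def add_intermixing(
    table: pd.DataFrame,
    mask: RegionSet,
    track1: CoverageTrack,
    track2: CoverageTrack,
    norm: PairNormalization,
    thresholds: Thresholds,
    collect_bins: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[BinPresence]]:
    """Append jaccard / n_intersection / n_union columns to the interval table.

    Insufficient windows get jaccard = NaN and zero counts.
    """
    table = table.copy()
    jac = np.full(len(table), np.nan)
    n_int = np.zeros(len(table), dtype=np.int64)
    n_uni = np.zeros(len(table), dtype=np.int64)
    audits: list[BinPresence] = []
    mask_cache: dict[str, np.ndarray] = {}
    for i, row in enumerate(table.itertuples(index=False)):
        if not row.sufficient:
            continue
        chrom = row.chrom
        if chrom not in mask_cache:
            mask_cache[chrom] = mask.to_bool_array(chrom)
        pres = bin_presence(
            chrom, row.start, row.end, mask_cache[chrom],
            track1.depth[chrom], track2.depth[chrom], norm, thresholds,
        )
        res = jaccard_index(pres)
        jac[i] = res.jaccard
        n_int[i] = res.n_intersection
        n_uni[i] = res.n_union
        if collect_bins:
            audits.append(pres)
    table["jaccard"] = jac
    table["n_intersection"] = n_int
    table["n_union_bins"] = n_uni
    return (table, audits) if collect_bins else table


def genome_intermixing_summary(table: pd.DataFrame) -> dict:
    """Mean Jaccard over windows with a defined index, NA count, histogram."""
    j = table["jaccard"].to_numpy(dtype=float)
    defined = j[~np.isnan(j)]
    counts, edges = np.histogram(defined, bins=20, range=(0.0, 1.0))
    mean_j = float(defined.mean()) if defined.size else float("nan")
    if not defined.size:
        import logging
        logging.getLogger("mixscan").warning(
            "no window has a defined Jaccard index; genome summary is NA"
        )
    return {
        "mean_jaccard": mean_j,
        "n_intervals": int(len(table)),
        "n_defined": int(defined.size),
        "n_na": int(len(table) - defined.size),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }
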