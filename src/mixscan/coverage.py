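"""Per-parent, per-position depth over the included positions of a hybrid assembly.

Depth is computed from alignments (SAM/BAM) or from a bedGraph track, then
restricted to the include mask and thresholded at a minimum depth. Depth
counts reference-consuming aligned bases (CIGAR M/=/X); deletions and splices
do not contribute. Secondary (0x100) and unmapped (0x4) records are excluded;
duplicate-marked and supplementary records are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .regions import RegionSet

log = logging.getLogger("mixscan")

# CIGAR operations that consume the reference
_REF_COVERING = {0, 7, 8}   # M, =, X
_REF_SKIPPING = {2, 3}      # D, N


@dataclass
class Thresholds:
    """Tunable pipeline parameters.

    min_coverage
        Minimum per-position depth for a position to count as covered (x).
    interval_size
        Window width W along the assembly (bp).
    bin_count
        Number of bins per window for the intermixing index.
    bin_min_frac
        Minimum fraction of a bin's mask positions a parent must cover for
        the bin to count as present for that parent.
    coverage_band
        Relative band for the normalized bin-coverage comparison: both
        parents survive only if the lower normalized mean is within
        (1 - coverage_band) of the higher.
    interval_min_positions / interval_min_covered / interval_min_covered_frac
        Information-sufficiency rules for a window: at least this many mask
        positions, at least this many covered by >= 1 parent, and the covered
        count at least this fraction of the mask positions.
    assign_max_jaccard / assign_min_frac
        Interval-assignment rule: J <= assign_max_jaccard and one parent
        exclusively covering > assign_min_frac of the mask positions.
    gene_assign_max_jaccard
        Relaxed Jaccard ceiling for the gene-oriented assignment rule.
    """

    min_coverage: int = 5
    interval_size: int = 250_000
    bin_count: int = 10
    bin_min_frac: float = 0.10
    coverage_band: float = 0.25
    interval_min_positions: int = 1000
    interval_min_covered: int = 1000
    interval_min_covered_frac: float = 0.10
    assign_max_jaccard: float = 0.2
    gene_assign_max_jaccard: float = 0.5
    assign_min_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.min_coverage < 1 or self.interval_size < 1 or self.bin_count < 1:
            raise ValueError("counts and sizes must be positive")
        for name in ("bin_min_frac", "coverage_band",
                     "interval_min_covered_frac", "assign_min_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1)")
        for name in ("assign_max_jaccard", "gene_assign_max_jaccard"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1]")


@dataclass
class CoverageTrack:
    """Filtered depth of one parental read set over the hybrid assembly.

    ``depth[chrom]`` is a dense int32 array over the full sequence in which
    positions outside the include mask or below ``min_coverage`` are zero, so
    ``depth > 0`` is exactly "covered by this parent".
    """

    label: str
    depth: dict[str, np.ndarray]
    mask: RegionSet
    min_coverage: int
    n_mask_positions: int = field(init=False)
    n_covered: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_mask_positions = self.mask.total_length()
        self.n_covered = int(sum((d > 0).sum() for d in self.depth.values()))
        if self.n_covered > self.n_mask_positions:
            raise ValueError("covered positions exceed mask positions")

    def mean_depth(self) -> float:
        """Genome-wide mean depth over this track's covered positions."""
        if self.n_covered == 0:
            raise ValueError(
                f"track {self.label!r} covers no positions; mean depth undefined"
            )
        total = sum(int(d.sum(dtype=np.int64)) for d in self.depth.values())
        return total / self.n_covered

    def covered(self, chrom: str) -> np.ndarray:
        return self.depth[chrom] > 0

    def to_tsv(self, path) -> None:
        """Per-position export (chrom, pos0, depth) of covered positions."""
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tdepth\n")
            for chrom in sorted(self.depth):
                d = self.depth[chrom]
                for pos in np.flatnonzero(d):
                    fh.write(f"{chrom}\t{pos}\t{d[pos]}\n")


@dataclass
class PairNormalization:
    """Genome-wide mean depths of the two parental tracks and their ratio."""

    mean1: float
    mean2: float

    @property
    def ratio(self) -> float:
        return self.mean1 / self.mean2


def _finalize(
    label: str,
    raw: dict[str, np.ndarray],
    mask: RegionSet,
    thresholds: Thresholds,
) -> CoverageTrack:
    for chrom, d in raw.items():
        keep = mask.to_bool_array(chrom) & (d >= thresholds.min_coverage)
        d[~keep] = 0
    return CoverageTrack(label, raw, mask, thresholds.min_coverage)


def load_alignments_coverage(
    path,
    mask: RegionSet,
    thresholds: Thresholds,
    label: str = "parent",
) -> CoverageTrack:
    """Depth from a SAM/BAM file of one parental read set mapped to the hybrid.

    Counts primary, mapped alignments only; each alignment contributes one
    unit of depth at every reference position its M/=/X CIGAR blocks span.
    Input need not be sorted or indexed. Reference names absent from the mask
    lengths raise with the offenders listed.
    """
    diffs: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        unknown = [r for r in af.references if r not in mask.lengths]
        if unknown:
            raise ValueError(
                "alignment references not present in mask: " + ", ".join(unknown)
            )
        for chrom in af.references:
            diffs[chrom] = np.zeros(mask.lengths[chrom] + 1, dtype=np.int64)
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary:
                continue
            diff = diffs[rec.reference_name]
            pos = rec.reference_start
            for op, ln in rec.cigartuples or ():
                if op in _REF_COVERING:
                    diff[pos] += 1
                    diff[pos + ln] -= 1
                    pos += ln
                elif op in _REF_SKIPPING:
                    pos += ln
    raw = {
        chrom: np.cumsum(diff[:-1]).astype(np.int32)
        for chrom, diff in diffs.items()
    }
    for chrom in mask.lengths:
        raw.setdefault(chrom, np.zeros(mask.lengths[chrom], dtype=np.int32))
    return _finalize(label, raw, mask, thresholds)


def load_bedgraph_coverage(
    path,
    mask: RegionSet,
    thresholds: Thresholds,
    label: str = "parent",
) -> CoverageTrack:
    """Depth from a 4-column bedGraph track (chrom, start, end, depth).

    Records must be non-overlapping per sequence; negative depths are
    rejected. The resulting track is contract-identical to the alignment
    loader given equivalent depths.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str},
    )
    if (df["depth"] < 0).any():
        raise ValueError("negative depth in bedGraph")
    unknown = sorted(set(df["chrom"]) - set(mask.lengths))
    if unknown:
        raise ValueError("bedGraph references not in mask: " + ", ".join(unknown))
    raw = {c: np.zeros(n, dtype=np.int32) for c, n in mask.lengths.items()}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        if (ends[:-1] > starts[1:]).any():
            raise ValueError(f"overlapping bedGraph records on {chrom}")
        arr = raw[chrom]
        for s, e, d in zip(starts, ends, sub["depth"].to_numpy()):
            arr[s:e] = int(d)
    return _finalize(label, raw, mask, thresholds)


def write_bedgraph(depth: Mapping[str, np.ndarray], path) -> None:
    """Run-length-encode dense depth arrays to a bedGraph file (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(depth):
            d = np.asarray(depth[chrom])
            if d.size == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [d.size]))
            vals = d[starts]
            nz = vals != 0
            block = pd.DataFrame(
                {"chrom": chrom, "start": starts[nz], "end": ends[nz], "depth": vals[nz]}
            )
            block.to_csv(fh, sep="\t", header=False, index=False)


def normalization_factor(
    track1: CoverageTrack, track2: CoverageTrack
) -> PairNormalization:
    """Genome-wide mean-depth ratio between the two parental tracks.

    Means are taken over each track's own covered positions (uncovered
    positions omitted). The ratio multiplies the second-declared parent's bin
    coverages during intermixing analysis.
    """
    if track1.mask.lengths != track2.mask.lengths:
        raise ValueError("tracks built over different assemblies")
    return PairNormalization(track1.mean_depth(), track2.mean_depth())
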