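"""Shared fixtures: tiny in-memory assemblies, tracks and a SAM writer."""

from __future__ import annotations

import numpy as np
import pytest

from mixscan import CoverageTrack, RegionSet, Thresholds


@pytest.fixture
def thresholds_small() -> Thresholds:
    """Desk-scale thresholds: 10 kb windows, 10 bins, min coverage 5."""
    return Thresholds(
        interval_size=10_000,
        interval_min_positions=100,
        interval_min_covered=100,
    )


def make_track(
    label: str,
    depths: dict[str, np.ndarray],
    mask: RegionSet,
    min_coverage: int = 5,
) -> CoverageTrack:
    """Build a CoverageTrack from raw dense depth arrays (applies filters)."""
    filtered = {}
    for chrom, d in depths.items():
        d = np.asarray(d, dtype=np.int32).copy()
        keep = mask.to_bool_array(chrom) & (d >= min_coverage)
        d[~keep] = 0
        filtered[chrom] = d
    return CoverageTrack(label, filtered, mask, min_coverage)


@pytest.fixture
def full_mask():
    """A 30 kb single-sequence assembly, fully informative."""
    lengths = {"chr1": 30_000}
    return RegionSet({"chr1": np.array([[0, 30_000]])}, lengths)


def write_sam(path, lengths: dict[str, int], records: list[dict]) -> None:
    """Write a minimal SAM file.

    Each record dict: qname, flag, rname, pos (0-based), cigar; a dummy
    sequence matching the CIGAR read length is generated.
    """
    import re

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, ln in lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for r in records:
            read_len = sum(
                int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", r["cigar"])
                if op in "MIS=X"
            )
            seq = "A" * read_len if read_len else "*"
            qual = "I" * read_len if read_len else "*"
            fh.write(
                f"{r['qname']}\t{r['flag']}\t{r['rname']}\t{r['pos'] + 1}\t"
                f"{r.get('mapq', 60)}\t{r['cigar']}\t*\t0\t0\t{seq}\t{qual}\n"
            )
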