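"""Genomic region sets: masks of informative (non-repetitive, non-gap) positions.

All coordinates are 0-based half-open (BED convention). 1-based GFF input is
converted at parse time. Region sets are kept sorted, non-overlapping and
non-adjacent (bedtools-merge semantics), per sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("mixscan")

_N_RUN = re.compile(rb"[Nn]+")


def _merge_array(arr: np.ndarray) -> np.ndarray:
    """Merge a (n,2) array of half-open regions; adjacent regions coalesce."""
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        s, e = int(s), int(e)
        if s <= cur_e:  # overlap or adjacency
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


@dataclass
class RegionSet:
    """Sorted, non-overlapping half-open regions per sequence.

    Parameters
    ----------
    regions : mapping of sequence name -> (n, 2) int array of [start, end)
    lengths : mapping of sequence name -> sequence length (bp)
    """

    regions: dict[str, np.ndarray] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = {
            c: np.asarray(r, dtype=np.int64).reshape(-1, 2)
            for c, r in self.regions.items()
        }
        for chrom in self.regions:
            if chrom not in self.lengths:
                raise ValueError(f"missing sequence length for {chrom!r}")
            n = self.lengths[chrom]
            r = self.regions[chrom]
            if r.size and (r[:, 0].min() < 0 or r[:, 1].max() > n):
                raise ValueError(f"region out of bounds on {chrom!r}")

    # -- construction -------------------------------------------------

    @classmethod
    def merged(
        cls,
        raw: Mapping[str, Iterable[tuple[int, int]]],
        lengths: Mapping[str, int],
    ) -> "RegionSet":
        """Minimal sorted non-overlapping cover of possibly overlapping input.

        Records with start >= end are rejected with a logged warning;
        unknown sequence names raise.
        """
        out: dict[str, np.ndarray] = {}
        for chrom, regs in raw.items():
            if chrom not in lengths:
                raise ValueError(f"unknown sequence name {chrom!r}")
            kept = []
            for s, e in regs:
                if s >= e:
                    log.warning("rejecting empty/inverted region %s:%d-%d", chrom, s, e)
                    continue
                kept.append((s, e))
            out[chrom] = _merge_array(np.asarray(kept, dtype=np.int64).reshape(-1, 2))
        return cls(out, dict(lengths))

    def merge(self) -> "RegionSet":
        return RegionSet(
            {c: _merge_array(r) for c, r in self.regions.items()}, dict(self.lengths)
        )

    # -- set algebra ---------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        lengths = dict(self.lengths)
        lengths.update(other.lengths)
        chroms = set(self.regions) | set(other.regions)
        out = {}
        for c in chroms:
            parts = [
                self.regions.get(c, np.empty((0, 2), np.int64)),
                other.regions.get(c, np.empty((0, 2), np.int64)),
            ]
            out[c] = _merge_array(np.vstack(parts))
        return RegionSet(out, lengths)

    def complement(self, lengths: Mapping[str, int] | None = None) -> "RegionSet":
        """Complement within [0, length) per sequence.

        Sequences present in `lengths` but absent from the set come back
        fully covered.
        """
        lengths = dict(lengths if lengths is not None else self.lengths)
        out = {}
        for chrom, n in lengths.items():
            regs = _merge_array(self.regions.get(chrom, np.empty((0, 2), np.int64)))
            comp = []
            prev = 0
            for s, e in regs:
                if s > prev:
                    comp.append((prev, s))
                prev = e
            if prev < n:
                comp.append((prev, n))
            out[chrom] = np.asarray(comp, dtype=np.int64).reshape(-1, 2)
        return RegionSet(out, lengths)

    # -- queries -------------------------------------------------------

    def to_bool_array(self, chrom: str) -> np.ndarray:
        """Dense per-position membership array for one sequence."""
        mask = np.zeros(self.lengths[chrom], dtype=bool)
        for s, e in self.regions.get(chrom, ()):
            mask[s:e] = True
        return mask

    def total_length(self) -> int:
        return int(
            sum((r[:, 1] - r[:, 0]).sum() for r in self.regions.values() if r.size)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if self.lengths != other.lengths:
            return False
        if set(self.regions) != set(other.regions):
            return False
        return all(
            np.array_equal(self.regions[c], other.regions[c]) for c in self.regions
        )

    # -- IO ------------------------------------------------------------

    @classmethod
    def from_bed(cls, path, lengths: Mapping[str, int]) -> "RegionSet":
        """Read a BED3 file (tab-separated chrom/start/end, no header)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
            dtype={"chrom": str},
        )
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in df.itertuples(index=False):
            raw.setdefault(chrom, []).append((int(s), int(e)))
        return cls.merged(raw, lengths)

    @classmethod
    def from_gff(
        cls,
        path,
        lengths: Mapping[str, int],
        feature_types: set[str] | None = None,
    ) -> "RegionSet":
        """Read GFF/GFF3 features as regions (1-based closed -> half-open)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=[
                "chrom", "source", "type", "start", "end",
                "score", "strand", "frame", "attr",
            ],
            dtype={"chrom": str},
        )
        if feature_types is not None:
            df = df[df["type"].isin(feature_types)]
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in df[["chrom", "start", "end"]].itertuples(index=False):
            raw.setdefault(chrom, []).append((int(s) - 1, int(e)))
        return cls.merged(raw, lengths)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.regions):
                for s, e in self.regions[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def assembly_gaps(sequences: Mapping[str, str]) -> RegionSet:
    """Maximal runs of the ambiguity character 'N' per sequence."""
    lengths = {c: len(s) for c, s in sequences.items()}
    regs = {}
    for chrom, seq in sequences.items():
        data = seq.encode() if isinstance(seq, str) else bytes(seq)
        regs[chrom] = np.asarray(
            [(m.start(), m.end()) for m in _N_RUN.finditer(data)], dtype=np.int64
        ).reshape(-1, 2)
    return RegionSet(regs, lengths)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def assembly_gaps_from_fasta(path) -> RegionSet:
    return assembly_gaps(read_fasta(path))


def build_informative_mask(
    repeats: RegionSet, gaps: RegionSet, lengths: Mapping[str, int]
) -> RegionSet:
    """Informative positions: complement of (repeats union gaps) in [0, length).

    This is the include mask over which all coverage statistics run:
    non-repetitive, non-gap assembly positions.
    """
    for rs in (repeats, gaps):
        for chrom in rs.regions:
            if chrom not in lengths:
                raise ValueError(f"missing sequence length for {chrom!r}")
    excluded = repeats.union(gaps)
    return excluded.complement(lengths)
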