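"""Synthetic allotetraploid fixtures with known truth.

Generates two parental genomes diverged from a common ancestor, a hybrid
carrying one chromosome from each parent with optional homoeologous-exchange
blocks and biased deletions, a repeat mask, and per-parent coverage tracks
shaped like real parental read mappings: the parent of origin covers a
position deeply (Poisson around ``lambda_own``) while the other parent
covers only homologous tracts, shallowly (Poisson around ``lambda_cross``)
and with block-wise dropout.

All randomness flows through one seeded numpy Generator; the same seed
reproduces every artifact bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .coverage import CoverageTrack, Thresholds
from .regions import RegionSet

log = logging.getLogger("mixscan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for a simulated allotetraploid.

    divergence
        Target *pairwise* substitution divergence between the two parents
        (fraction of sites differing). The per-parent substitution
        probability is solved so the realized pairwise distance is unbiased.
    exchange_rate_per_mb / exchange_mean_len
        Homoeologous-exchange events per Mb of subgenome and their mean
        length (bp); blocks swap material reciprocally between homoeologs.
    deletion_fractions
        Fraction of each subgenome's chromosome removed by block deletions.
    repeat_fraction
        Fraction of the hybrid masked as repetitive (emits no coverage).
    lambda_own / lambda_cross
        Mean depth (x) of a parent's reads over its own subgenome and over
        the homoeologous subgenome. Defaults put the own-subgenome peak in
        the 15-45x band expected after downsampling to 10-15x of the hybrid.
    cross_dropout
        Fraction of ~dropout_block_bp tracts of the *other* subgenome that a
        parent's reads fail to cover at all (diverged, unalignable tracts);
        the 0.6 default leaves the wrong parent covering ~35-40% of
        positions, as observed when mapping a non-parent read set.
    coverage_tile_bp
        Depth is drawn per tile of this size (reads make neighbouring
        positions strongly correlated; tiling also keeps bedGraph output
        run-length compressible).
    """

    seed: int = 0
    ancestor_length: int = 10_000_000
    n_chromosome_pairs: int = 1
    divergence: float = 0.05
    exchange_rate_per_mb: float = 0.0
    exchange_mean_len: int = 100_000
    deletion_fractions: tuple[float, float] = (0.0, 0.0)
    deletion_mean_len: int = 20_000
    repeat_fraction: float = 0.2
    repeat_mean_len: int = 5_000
    lambda_own: float = 30.0
    lambda_cross: float = 8.0
    cross_dropout: float = 0.6
    dropout_block_bp: int = 2_000
    coverage_tile_bp: int = 50

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0 or self.n_chromosome_pairs <= 0:
            raise ValueError("lengths and counts must be positive")
        if not 0 <= self.divergence <= 0.75:
            raise ValueError("divergence outside [0, 0.75] (saturation)")
        for f in (*self.deletion_fractions, self.repeat_fraction,
                  self.cross_dropout):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.lambda_own <= self.lambda_cross:
            raise ValueError("lambda_own must exceed lambda_cross")

    @classmethod
    def from_exchange_fraction(cls, fraction: float, **kwargs) -> "SimConfig":
        """Parameterize by target swapped-bp fraction instead of event rate."""
        mean_len = kwargs.get("exchange_mean_len", cls.exchange_mean_len)
        rate = fraction * 1e6 / mean_len
        return cls(exchange_rate_per_mb=rate, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulated hybrid.

    ``origin[chrom]`` labels every hybrid position 1 or 2 by parent of
    origin; exchange blocks and deletions are in pre-deletion chromosome
    coordinates; the repeat mask is a RegionSet over the final hybrid.
    """

    origin: dict[str, np.ndarray]
    exchange_blocks: dict[str, list[tuple[int, int]]]
    deletions: dict[str, list[tuple[int, int]]]
    repeats: RegionSet = None
    config: SimConfig = None

    def lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.origin.items()}


def _per_parent_substitution_rate(divergence: float) -> float:
    """Solve 2p - (4/3)p^2 = d for the per-parent substitution probability.

    Two lineages substituting independently at probability p (to a uniformly
    chosen different base) differ at a site with probability 2p(1-p) +
    (2/3)p^2; inverting removes the downward bias of double hits.
    """
    if divergence == 0:
        return 0.0
    return 0.75 * (1.0 - math.sqrt(1.0 - 4.0 * divergence / 3.0))


def _substitute(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability p, to a uniform different base."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size:
        # shift by 1..3 positions in base alphabet => always a different base
        idx = np.searchsorted(_BASES, seq[hit])
        out[hit] = _BASES[(idx + rng.integers(1, 4, hit.size)) % 4]
    return out


def simulate_parents(
    config: SimConfig,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Ancestor and two parental genomes as uint8 base arrays per chromosome.

    Chromosomes are named chr1..chrN; each parent derives from the ancestor
    by independent substitutions calibrated to the configured pairwise
    divergence. Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    p = _per_parent_substitution_rate(config.divergence)
    ancestor, parent1, parent2 = {}, {}, {}
    for i in range(config.n_chromosome_pairs):
        name = f"chr{i + 1}"
        anc = rng.choice(_BASES, size=config.ancestor_length)
        ancestor[name] = anc
        parent1[name] = _substitute(anc, p, rng)
        parent2[name] = _substitute(anc, p, rng)
    return ancestor, parent1, parent2


def _random_blocks(
    length: int, total_bp: int, mean_len: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Disjoint random blocks totalling ~total_bp (geometric-ish lengths)."""
    blocks: list[tuple[int, int]] = []
    covered = np.zeros(length, dtype=bool)
    got = 0
    attempts = 0
    while got < total_bp and attempts < 10_000:
        attempts += 1
        ln = max(1, int(rng.exponential(mean_len)))
        ln = min(ln, total_bp - got)
        if ln >= length:
            log.warning("block length %d exceeds chromosome; clipping", ln)
            ln = length
            start = 0
        else:
            start = int(rng.integers(0, length - ln + 1))
        if covered[start:start + ln].any():
            continue
        covered[start:start + ln] = True
        blocks.append((start, start + ln))
        got += ln
    return sorted(blocks)


def simulate_hybrid(
    parent1: dict[str, np.ndarray],
    parent2: dict[str, np.ndarray],
    config: SimConfig,
) -> tuple[dict[str, np.ndarray], SimTruth]:
    """Hybrid assembly (one chromosome per parent per pair) with truth labels.

    For each ancestral chromosome pair the hybrid carries ``<chr>_sub1``
    (parent 1 copy) and ``<chr>_sub2`` (parent 2 copy). Exchange events swap
    the same coordinates reciprocally between the two homoeologs (sequence
    and origin labels); block deletions then remove the configured fraction
    of each subgenome's chromosome. A repeat mask is drawn over the final
    hybrid coordinates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    hybrid: dict[str, np.ndarray] = {}
    origin: dict[str, np.ndarray] = {}
    exchanges: dict[str, list[tuple[int, int]]] = {}
    deletions: dict[str, list[tuple[int, int]]] = {}
    for chrom in parent1:
        n = len(parent1[chrom])
        seq1 = parent1[chrom].copy()
        seq2 = parent2[chrom].copy()
        lab1 = np.ones(n, dtype=np.int8)
        lab2 = np.full(n, 2, dtype=np.int8)
        n_events = rng.poisson(config.exchange_rate_per_mb * n / 1e6)
        blocks: list[tuple[int, int]] = []
        for _ in range(n_events):
            ln = max(1, int(rng.exponential(config.exchange_mean_len)))
            if ln >= n:
                log.warning("exchange block longer than chromosome; clipped")
                ln = n
            start = int(rng.integers(0, n - ln + 1))
            end = start + ln
            seq1[start:end], seq2[start:end] = (
                seq2[start:end].copy(), seq1[start:end].copy()
            )
            lab1[start:end], lab2[start:end] = (
                lab2[start:end].copy(), lab1[start:end].copy()
            )
            blocks.append((start, end))
        for sub, seq, lab, frac in (
            (1, seq1, lab1, config.deletion_fractions[0]),
            (2, seq2, lab2, config.deletion_fractions[1]),
        ):
            name = f"{chrom}_sub{sub}"
            dels = (
                _random_blocks(n, int(frac * n), config.deletion_mean_len, rng)
                if frac > 0
                else []
            )
            if dels:
                keep = np.ones(n, dtype=bool)
                for s, e in dels:
                    keep[s:e] = False
                seq, lab = seq[keep], lab[keep]
            hybrid[name] = seq
            origin[name] = lab
            deletions[name] = dels
            exchanges[name] = sorted(blocks)
    lengths = {c: len(s) for c, s in hybrid.items()}
    repeat_regions = {
        c: np.asarray(
            _random_blocks(
                lengths[c], int(config.repeat_fraction * lengths[c]),
                config.repeat_mean_len, rng,
            ),
            dtype=np.int64,
        ).reshape(-1, 2)
        for c in hybrid
    }
    repeats = RegionSet(repeat_regions, lengths).merge()
    truth = SimTruth(origin, exchanges, deletions, repeats, config)
    return hybrid, truth


def _tiled_poisson(
    lam: float, n: int, tile: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-position depth, Poisson(lam) drawn once per tile of `tile` bp."""
    n_tiles = (n + tile - 1) // tile
    draws = rng.poisson(lam, n_tiles).astype(np.int32)
    return np.repeat(draws, tile)[:n]


def simulate_coverage_tracks(
    truth: SimTruth,
    config: SimConfig,
    thresholds: Thresholds | None = None,
) -> tuple[CoverageTrack, CoverageTrack, RegionSet]:
    """Per-parent coverage tracks over the hybrid, plus the include mask.

    At every non-repeat position the origin parent's depth is Poisson
    around ``lambda_own`` and the other parent's Poisson around
    ``lambda_cross`` thinned by block dropout; repeats emit no coverage.
    Returns mask-restricted, min-coverage-filtered tracks ready for the
    interval engine.
    """
    thresholds = thresholds or Thresholds()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lengths = truth.lengths()
    mask = truth.repeats.complement(lengths)
    depth1: dict[str, np.ndarray] = {}
    depth2: dict[str, np.ndarray] = {}
    tile = config.coverage_tile_bp
    for chrom, lab in truth.origin.items():
        n = len(lab)
        own1 = _tiled_poisson(config.lambda_own, n, tile, rng)
        own2 = _tiled_poisson(config.lambda_own, n, tile, rng)
        cross1 = _tiled_poisson(config.lambda_cross, n, tile, rng)
        cross2 = _tiled_poisson(config.lambda_cross, n, tile, rng)
        nb = (n + config.dropout_block_bp - 1) // config.dropout_block_bp
        drop1 = np.repeat(
            rng.random(nb) < config.cross_dropout, config.dropout_block_bp
        )[:n]
        drop2 = np.repeat(
            rng.random(nb) < config.cross_dropout, config.dropout_block_bp
        )[:n]
        is1 = lab == 1
        d1 = np.where(is1, own1, np.where(drop1, 0, cross1)).astype(np.int32)
        d2 = np.where(~is1, own2, np.where(drop2, 0, cross2)).astype(np.int32)
        rep = truth.repeats.to_bool_array(chrom)
        d1[rep] = 0
        d2[rep] = 0
        keep1 = d1 >= thresholds.min_coverage
        keep2 = d2 >= thresholds.min_coverage
        d1[~keep1] = 0
        d2[~keep2] = 0
        depth1[chrom] = d1
        depth2[chrom] = d2
    track1 = CoverageTrack("parent1", depth1, mask, thresholds.min_coverage)
    track2 = CoverageTrack("parent2", depth2, mask, thresholds.min_coverage)
    return track1, track2, mask


def write_fasta(sequences: dict[str, np.ndarray], path, width: int = 80) -> None:
    """Write uint8 base arrays as FASTA."""
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name].tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def truth_to_config_json(truth: SimTruth) -> dict:
    """SimConfig echo for run provenance."""
    return asdict(truth.config) if truth.config else {}


def downsample_read_pairs(
    fastq1_in,
    fastq2_in,
    fastq1_out,
    fastq2_out,
    genome_size: int,
    target_depth: float,
    seed: int = 0,
) -> int:
    """Uniformly downsample a FASTQ pair to ~target_depth x genome_size bases.

    Pairs are kept or dropped together; the number of retained pairs is the
    closest achievable to the base target given the mean pair length. When
    the target exceeds the available bases all pairs are kept with a
    warning. Returns the number of pairs written. Deterministic per seed.
    """
    from Bio import SeqIO

    recs1 = list(SeqIO.parse(str(fastq1_in), "fastq"))
    recs2 = list(SeqIO.parse(str(fastq2_in), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("paired FASTQ files differ in record count")
    pair_bases = np.array(
        [len(a.seq) + len(b.seq) for a, b in zip(recs1, recs2)], dtype=np.int64
    )
    total = int(pair_bases.sum())
    target = target_depth * genome_size
    if target >= total:
        log.warning("target depth exceeds available bases; keeping all pairs")
        keep = np.arange(len(recs1))
    else:
        mean_pair = total / len(recs1)
        n_keep = max(1, int(round(target / mean_pair)))
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(recs1), size=n_keep, replace=False))
    with open(fastq1_out, "w") as f1, open(fastq2_out, "w") as f2:
        SeqIO.write((recs1[i] for i in keep), f1, "fastq")
        SeqIO.write((recs2[i] for i in keep), f2, "fastq")
    return int(len(keep))
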