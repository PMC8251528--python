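"""Depth computation from alignments and bedGraph, filters and normalization."""

import numpy as np
import pytest

from mixscan import (
    RegionSet,
    Thresholds,
    load_alignments_coverage,
    load_bedgraph_coverage,
    normalization_factor,
    write_bedgraph,
)
from conftest import make_track, write_sam


LENGTHS = {"chr1": 1000}
MASK = RegionSet({"chr1": np.array([[0, 1000]])}, LENGTHS)


def brute_depth(reads, length):
    """Per-position depth oracle over (start, end) reference spans."""
    d = np.zeros(length, dtype=int)
    for s, e in reads:
        d[s:e] += 1
    return d


def test_primary_alignment_depth_matches_span(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(sam, LENGTHS, [
        {"qname": "r1", "flag": 0, "rname": "chr1", "pos": 100, "cigar": "50M"},
    ])
    track = load_alignments_coverage(sam, MASK, Thresholds(min_coverage=1))
    d = track.depth["chr1"]
    assert d[100:150].tolist() == [1] * 50
    assert d.sum() == 50


def test_secondary_and_unmapped_filtered(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(sam, LENGTHS, [
        {"qname": "r1", "flag": 0x100, "rname": "chr1", "pos": 100, "cigar": "50M"},
        {"qname": "r2", "flag": 0x4, "rname": "chr1", "pos": 200, "cigar": "50M"},
    ])
    track = load_alignments_coverage(sam, MASK, Thresholds(min_coverage=1))
    assert track.n_covered == 0


def test_cigar_reference_consumption(tmp_path):
    """M/=/X cover; D and N advance without covering; I and S are ignored."""
    sam = tmp_path / "a.sam"
    write_sam(sam, LENGTHS, [
        {"qname": "r1", "flag": 0, "rname": "chr1", "pos": 10,
         "cigar": "5M3D5M2I5M4S"},
    ])
    track = load_alignments_coverage(sam, MASK, Thresholds(min_coverage=1))
    d = track.depth["chr1"]
    covered = np.flatnonzero(d)
    assert covered.tolist() == list(range(10, 15)) + list(range(18, 28))


def test_depth_equal_to_min_coverage_retained(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(sam, LENGTHS, [
        {"qname": f"r{i}", "flag": 0, "rname": "chr1", "pos": 100, "cigar": "10M"}
        for i in range(5)
    ])
    track = load_alignments_coverage(sam, MASK, Thresholds(min_coverage=5))
    assert np.all(track.depth["chr1"][100:110] == 5)
    track6 = load_alignments_coverage(sam, MASK, Thresholds(min_coverage=6))
    assert track6.n_covered == 0


def test_pileup_matches_bruteforce_on_random_reads(tmp_path):
    rng = np.random.default_rng(11)
    spans = []
    recs = []
    for i in range(80):
        s = int(rng.integers(0, 900))
        ln = int(rng.integers(20, 100))
        e = min(s + ln, 1000)
        spans.append((s, e))
        recs.append({"qname": f"r{i}", "flag": 0, "rname": "chr1", "pos": s,
                     "cigar": f"{e - s}M"})
    sam = tmp_path / "a.sam"
    write_sam(sam, LENGTHS, recs)
    track = load_alignments_coverage(sam, MASK, Thresholds(min_coverage=1))
    assert np.array_equal(track.depth["chr1"], brute_depth(spans, 1000))


def test_mask_restriction(tmp_path):
    mask = RegionSet({"chr1": np.array([[0, 120]])}, LENGTHS)
    sam = tmp_path / "a.sam"
    write_sam(sam, LENGTHS, [
        {"qname": "r1", "flag": 0, "rname": "chr1", "pos": 100, "cigar": "50M"},
    ])
    track = load_alignments_coverage(sam, mask, Thresholds(min_coverage=1))
    assert np.flatnonzero(track.depth["chr1"]).tolist() == list(range(100, 120))


def test_unknown_reference_rejected(tmp_path):
    sam = tmp_path / "a.sam"
    write_sam(sam, {"other": 500}, [])
    with pytest.raises(ValueError, match="other"):
        load_alignments_coverage(sam, MASK, Thresholds())


def test_bedgraph_basic_and_threshold(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chr1\t0\t10\t7\nchr1\t10\t20\t4\n")
    track = load_bedgraph_coverage(p, MASK, Thresholds(min_coverage=5))
    assert track.depth["chr1"][0:10].tolist() == [7] * 10
    assert track.depth["chr1"][10:20].sum() == 0  # below threshold


@pytest.mark.parametrize(
    "content, err",
    [
        ("chr1\t0\t10\t5\nchr1\t5\t15\t5\n", "overlap"),
        ("chr1\t0\t10\t-3\n", "negative"),
    ],
)
def test_bedgraph_rejects_bad_records(tmp_path, content, err):
    p = tmp_path / "t.bedgraph"
    p.write_text(content)
    with pytest.raises(ValueError, match=err):
        load_bedgraph_coverage(p, MASK, Thresholds())


def test_bedgraph_round_trip_equals_alignment_track(tmp_path):
    rng = np.random.default_rng(3)
    recs = [
        {"qname": f"r{i}", "flag": 0, "rname": "chr1",
         "pos": int(rng.integers(0, 900)), "cigar": "60M"}
        for i in range(60)
    ]
    sam = tmp_path / "a.sam"
    write_sam(sam, LENGTHS, recs)
    th = Thresholds(min_coverage=1)
    track = load_alignments_coverage(sam, MASK, th)
    bg = tmp_path / "t.bedgraph"
    write_bedgraph(track.depth, bg)
    track2 = load_bedgraph_coverage(bg, MASK, th)
    assert np.array_equal(track.depth["chr1"], track2.depth["chr1"])


def test_normalization_ratio_and_antisymmetry(full_mask):
    rng = np.random.default_rng(5)
    d1 = rng.poisson(30, 30_000)
    d2 = rng.poisson(20, 30_000)
    t1 = make_track("p1", {"chr1": d1}, full_mask)
    t2 = make_track("p2", {"chr1": d2}, full_mask)
    norm = normalization_factor(t1, t2)
    cov1 = d1[d1 >= 5]
    cov2 = d2[d2 >= 5]
    assert norm.mean1 == pytest.approx(cov1.mean())
    assert norm.mean2 == pytest.approx(cov2.mean())
    back = normalization_factor(t2, t1)
    assert norm.ratio * back.ratio == pytest.approx(1.0, abs=1e-12)
    # identical tracks -> ratio exactly 1
    assert normalization_factor(t1, t1).ratio == 1.0


def test_normalization_undefined_on_empty_track(full_mask):
    t1 = make_track("p1", {"chr1": np.zeros(30_000)}, full_mask)
    t2 = make_track("p2", {"chr1": np.full(30_000, 10)}, full_mask)
    with pytest.raises(ValueError, match="covers no positions"):
        normalization_factor(t1, t2)
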