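"""Bin presence rules, Jaccard index and parent-order invariance."""

import numpy as np
import pytest

from mixscan import (
    PairNormalization,
    RegionSet,
    Thresholds,
    add_intermixing,
    bin_presence,
    genome_intermixing_summary,
    interval_table,
    jaccard_index,
    normalization_factor,
)
from mixscan.intermix import BinPresence, bin_edges
from conftest import make_track

TH = Thresholds(interval_size=10_000, interval_min_positions=100,
                interval_min_covered=100)


def presence_for(c1_depth, c2_depth, mean1=30.0, mean2=20.0):
    """Single-window presence from two constant-depth arrays."""
    n = 10_000
    mask = RegionSet({"c": np.array([[0, n]])}, {"c": n})
    d1 = np.asarray(c1_depth, dtype=np.int32)
    d2 = np.asarray(c2_depth, dtype=np.int32)
    return bin_presence("c", 0, n, mask.to_bool_array("c"), d1, d2,
                        PairNormalization(mean1, mean2), TH)


def constant(depth, n=10_000):
    return np.full(n, depth, dtype=np.int32)


def test_equal_normalized_coverage_keeps_both():
    """c1=30, c2=20 under r=1.5: normalized equal, both parents present."""
    pres = presence_for(constant(30), constant(20))
    assert pres.present1.all() and pres.present2.all()


def test_band_drops_lower_parent():
    """c1=30, c2=10, r=1.5: normalized 15 < 0.75*30 -> parent2 absent."""
    pres = presence_for(constant(30), constant(10))
    assert pres.present1.all()
    assert not pres.present2.any()


def test_band_boundary_is_inclusive():
    """Exactly 0.75x after normalization keeps both parents."""
    pres = presence_for(constant(40), constant(30), mean1=1.0, mean2=1.0)
    assert pres.present1.all() and pres.present2.all()
    # just below the band -> dropped
    pres2 = presence_for(constant(41), constant(30), mean1=1.0, mean2=1.0)
    assert not pres2.present2.any()


def test_bin_coverage_filter_beats_depth():
    """A parent covering 5% of a bin's mask positions is absent regardless."""
    d1 = np.zeros(10_000, dtype=np.int32)
    for b in range(10):
        d1[b * 1000: b * 1000 + 50] = 100  # 5% of each bin, deep
    pres = presence_for(d1, constant(20), mean1=100.0, mean2=20.0)
    assert not pres.present1.any()
    assert pres.present2.all()


def test_single_parent_bins_skip_band_comparison():
    """With the other parent absent, low coverage alone keeps a parent."""
    pres = presence_for(constant(6), np.zeros(10_000, dtype=np.int32),
                        mean1=6.0, mean2=1.0)
    assert pres.present1.all()
    assert not pres.present2.any()


def test_bin_edges_partial_window():
    edges = bin_edges(0, 9_999, 10)
    assert edges[0] == 0 and edges[-1] == 9_999
    assert len(edges) == 11
    assert (np.diff(edges) <= 1000).all()


def jaccard_bruteforce(p1, p2):
    s1 = {i for i, v in enumerate(p1) if v}
    s2 = {i for i, v in enumerate(p2) if v}
    union = s1 | s2
    return len(s1 & s2) / len(union) if union else float("nan")


def make_presence(p1, p2):
    b = len(p1)
    return BinPresence("c", 0, b, np.arange(b + 1), np.ones(b, int),
                       np.asarray(p1, bool), np.asarray(p2, bool),
                       np.ones(b), np.ones(b), np.ones(b), np.ones(b))


@pytest.mark.parametrize(
    "p1, p2, expected",
    [
        ([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 1, 1, 1, 0, 0, 0, 0], 0.0),
        ([1] * 10, [1] * 10, 1.0),
        # intersection {1,6}, union {0,1,2,4,5,6,7,8} -> 2/8
        ([1, 1, 0, 0, 1, 0, 1, 1, 0, 0], [0, 1, 1, 0, 0, 1, 1, 0, 1, 0], 0.25),
    ],
)
def test_jaccard_examples(p1, p2, expected):
    res = jaccard_index(make_presence(p1, p2))
    assert res.jaccard == pytest.approx(expected)
    assert res.jaccard == pytest.approx(jaccard_bruteforce(p1, p2))


def test_jaccard_na_on_empty_union_and_bounds():
    res = jaccard_index(make_presence([0] * 10, [0] * 10))
    assert np.isnan(res.jaccard) and res.n_union == 0
    rng = np.random.default_rng(9)
    for _ in range(200):
        p1 = rng.random(10) < 0.4
        p2 = rng.random(10) < 0.4
        j = jaccard_index(make_presence(p1, p2)).jaccard
        oracle = jaccard_bruteforce(p1, p2)
        assert (np.isnan(j) and np.isnan(oracle)) or j == pytest.approx(oracle)
        if not np.isnan(j):
            assert 0.0 <= j <= 1.0


def test_adding_both_true_bin_never_decreases_jaccard():
    rng = np.random.default_rng(4)
    for _ in range(100):
        p1 = list(rng.random(10) < 0.5)
        p2 = list(rng.random(10) < 0.5)
        j0 = jaccard_index(make_presence(p1, p2)).jaccard
        j1 = jaccard_index(make_presence(p1 + [True], p2 + [True])).jaccard
        if not np.isnan(j0):
            assert j1 >= j0


def _random_fixture(seed):
    n = 40_000
    rng = np.random.default_rng(seed)
    mask = RegionSet({"c": np.array([[0, n]])}, {"c": n})
    lam = rng.uniform(10, 40, size=2)
    d1 = rng.poisson(lam[0], n)
    segs = rng.random(n // 2000) < 0.5
    d2 = rng.poisson(lam[1], n) * np.repeat(segs, 2000)[:n]
    t1 = make_track("p1", {"c": d1}, mask)
    t2 = make_track("p2", {"c": d2}, mask)
    return mask, t1, t2


@pytest.mark.parametrize("seed", range(5))
def test_parent_order_invariance(seed):
    """Swapping parent declaration order leaves presence and J identical."""
    mask, t1, t2 = _random_fixture(seed)
    fwd = add_intermixing(interval_table(mask, t1, t2, TH), mask, t1, t2,
                          normalization_factor(t1, t2), TH)
    rev = add_intermixing(interval_table(mask, t2, t1, TH), mask, t2, t1,
                          normalization_factor(t2, t1), TH)
    assert np.array_equal(fwd["jaccard"], rev["jaccard"], equal_nan=True)
    assert fwd["n_intersection"].equals(rev["n_intersection"])
    assert fwd["n_union_bins"].equals(rev["n_union_bins"])
    assert fwd["frac_cov1"].equals(rev["frac_cov2"])


def test_genome_summary_arithmetic():
    import pandas as pd

    table = pd.DataFrame({"jaccard": [0.1, 0.2, np.nan]})
    s = genome_intermixing_summary(table)
    assert s["mean_jaccard"] == pytest.approx(0.15)
    assert s["n_na"] == 1
    all_na = genome_intermixing_summary(pd.DataFrame({"jaccard": [np.nan] * 3}))
    assert np.isnan(all_na["mean_jaccard"])
    zeros = genome_intermixing_summary(pd.DataFrame({"jaccard": [0.0, 0.0]}))
    assert zeros["mean_jaccard"] == 0.0
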