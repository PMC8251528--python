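"""Synthetic allotetraploid generator: determinism, calibration, truth."""

import numpy as np
import pytest

from mixscan import (
    SimConfig,
    Thresholds,
    downsample_read_pairs,
    simulate_coverage_tracks,
    simulate_hybrid,
    simulate_parents,
)


def small_config(**kw):
    defaults = dict(seed=5, ancestor_length=200_000)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_zero_divergence_parents_equal_ancestor():
    anc, p1, p2 = simulate_parents(small_config(divergence=0.0))
    assert np.array_equal(anc["chr1"], p1["chr1"])
    assert np.array_equal(anc["chr1"], p2["chr1"])


def test_divergence_calibration():
    """Pairwise parent divergence matches the configured value."""
    cfg = SimConfig(seed=2, ancestor_length=1_000_000, divergence=0.05)
    _, p1, p2 = simulate_parents(cfg)
    diff = (p1["chr1"] != p2["chr1"]).mean()
    assert diff == pytest.approx(0.05, abs=0.002)


def test_divergence_saturation_rejected():
    with pytest.raises(ValueError, match="saturation"):
        SimConfig(divergence=0.8)


def test_simulation_deterministic_per_seed():
    cfg = small_config(exchange_rate_per_mb=2.0, deletion_fractions=(0.1, 0.0))
    out1 = simulate_parents(cfg)
    out2 = simulate_parents(cfg)
    assert np.array_equal(out1[1]["chr1"], out2[1]["chr1"])
    h1, t1 = simulate_hybrid(out1[1], out1[2], cfg)
    h2, t2 = simulate_hybrid(out2[1], out2[2], cfg)
    assert all(np.array_equal(h1[c], h2[c]) for c in h1)
    assert all(np.array_equal(t1.origin[c], t2.origin[c]) for c in t1.origin)
    tr1 = simulate_coverage_tracks(t1, cfg)[0]
    tr2 = simulate_coverage_tracks(t2, cfg)[0]
    assert all(np.array_equal(tr1.depth[c], tr2.depth[c]) for c in tr1.depth)


def test_zero_exchange_labels_constant_per_chromosome():
    _, p1, p2 = simulate_parents(small_config())
    _, truth = simulate_hybrid(p1, p2, small_config())
    assert np.all(truth.origin["chr1_sub1"] == 1)
    assert np.all(truth.origin["chr1_sub2"] == 2)


def test_exchange_swaps_reciprocally():
    cfg = small_config(exchange_rate_per_mb=10.0, exchange_mean_len=10_000)
    _, p1, p2 = simulate_parents(cfg)
    hybrid, truth = simulate_hybrid(p1, p2, cfg)
    lab1 = truth.origin["chr1_sub1"]
    lab2 = truth.origin["chr1_sub2"]
    assert truth.exchange_blocks["chr1_sub1"]  # events happened
    # reciprocal: at every position exactly one homoeolog is parent-1 origin
    assert np.all((lab1 == 1) ^ (lab2 == 1))
    swapped = (lab1 == 2).mean()
    assert swapped > 0
    # swapped sequence really is the other parent's
    sw = lab1 == 2
    assert np.array_equal(hybrid["chr1_sub1"][sw], p2["chr1"][sw])


def test_exchange_fraction_parameterization():
    cfg = SimConfig.from_exchange_fraction(
        0.3, seed=8, ancestor_length=2_000_000, exchange_mean_len=50_000
    )
    _, p1, p2 = simulate_parents(cfg)
    _, truth = simulate_hybrid(p1, p2, cfg)
    swapped = (truth.origin["chr1_sub1"] == 2).mean()
    # realized swapped fraction near target (block overlap deflates slightly)
    assert 0.15 < swapped < 0.45


def test_deletions_hit_target_within_tolerance():
    cfg = small_config(deletion_fractions=(0.2, 0.05))
    _, p1, p2 = simulate_parents(cfg)
    hybrid, truth = simulate_hybrid(p1, p2, cfg)
    n = cfg.ancestor_length
    del1 = sum(e - s for s, e in truth.deletions["chr1_sub1"])
    del2 = sum(e - s for s, e in truth.deletions["chr1_sub2"])
    assert del1 == pytest.approx(0.2 * n, rel=0.10)
    assert del2 == pytest.approx(0.05 * n, rel=0.10)
    assert len(hybrid["chr1_sub1"]) == n - del1
    assert len(hybrid["chr1_sub2"]) == n - del2


def test_coverage_means_and_exclusivity():
    cfg = small_config(repeat_fraction=0.0, cross_dropout=1.0, lambda_cross=0.0)
    _, p1, p2 = simulate_parents(cfg)
    _, truth = simulate_hybrid(p1, p2, cfg)
    t1, t2, mask = simulate_coverage_tracks(truth, cfg, Thresholds(min_coverage=1))
    # dropout 1 and lambda_cross 0: only the origin parent covers anything
    assert t1.depth["chr1_sub2"].sum() == 0
    assert t2.depth["chr1_sub1"].sum() == 0
    own = t1.depth["chr1_sub1"]
    assert own[own > 0].mean() == pytest.approx(30.0, abs=1.0)


def test_repeats_emit_no_coverage():
    cfg = small_config(repeat_fraction=0.3)
    _, p1, p2 = simulate_parents(cfg)
    _, truth = simulate_hybrid(p1, p2, cfg)
    t1, t2, mask = simulate_coverage_tracks(truth, cfg)
    rep = truth.repeats.to_bool_array("chr1_sub1")
    assert t1.depth["chr1_sub1"][rep].sum() == 0
    # mask is the complement of the repeats
    assert not (mask.to_bool_array("chr1_sub1") & rep).any()


def write_fastq_pair(tmp_path, n_pairs, read_len=100):
    p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    for p, mate in ((p1, 1), (p2, 2)):
        with open(p, "w") as fh:
            for i in range(n_pairs):
                fh.write(f"@read{i}/{mate}\n{'A' * read_len}\n+\n{'I' * read_len}\n")
    return p1, p2


def test_downsample_hits_base_target(tmp_path):
    p1, p2 = write_fastq_pair(tmp_path, 1000)
    o1, o2 = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
    n = downsample_read_pairs(p1, p2, o1, o2, genome_size=10_000,
                              target_depth=5, seed=1)
    assert n == 250  # 250 pairs x 200 bp = 5 x 10 kb
    assert o1.read_text().count("@read") == 250
    # pairs kept together
    ids1 = [l.split("/")[0] for l in o1.read_text().splitlines() if l.startswith("@")]
    ids2 = [l.split("/")[0] for l in o2.read_text().splitlines() if l.startswith("@")]
    assert ids1 == ids2
    # deterministic per seed
    o3, o4 = tmp_path / "o3.fastq", tmp_path / "o4.fastq"
    downsample_read_pairs(p1, p2, o3, o4, 10_000, 5, seed=1)
    assert o1.read_text() == o3.read_text()


def test_downsample_target_above_available_keeps_all(tmp_path):
    p1, p2 = write_fastq_pair(tmp_path, 10)
    o1, o2 = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
    n = downsample_read_pairs(p1, p2, o1, o2, 10_000, 1e6, seed=0)
    assert n == 10
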