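"""Background rate estimators against brute-force window/pooling oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from mutburden.background import (
    aggregate_rate,
    candidate_windows,
    cluster_features,
    clustered_rate,
    global_rate,
    local_clustered_rate,
    local_rate,
    prepare_covariates,
)
from mutburden.io import PositionIndex

from conftest import region


def make_index(sample_positions: dict[str, list[int]], chrom="chr1", cls="unknown"):
    idx = PositionIndex()
    for sid, positions in sample_positions.items():
        for pos in positions:  # 1-based
            idx.add(sid, chrom, pos, cls)
    return idx


# ---------------------------------------------------------------------------
# global


def test_global_rate_examples():
    feats = [region("a", "chr1", 0, 600_000), region("b", "chr1", 700_000, 1_100_000)]
    assert global_rate("s", feats, {"a": 6, "b": 4}) == pytest.approx(1e-5)
    assert global_rate("s", feats, {}) == 0.0
    # linearity
    assert global_rate("s", feats, {"a": 12, "b": 8}) == pytest.approx(2e-5)


def test_global_rate_zero_length_fatal():
    with pytest.raises(ValueError):
        global_rate("s", [], {})


# ---------------------------------------------------------------------------
# local


def brute_force_local(feature, positions, window_length, step, chrom_length):
    """Recount every candidate placement by linear scan (oracle)."""
    best = 0.0
    for ws, we in candidate_windows(feature, window_length, step, chrom_length):
        count = sum(1 for p in positions if ws <= p - 1 < we)
        best = max(best, count / (we - ws))
    return best


def test_local_rate_is_maximum_over_windows():
    # mutations piled left of the feature: the feature-at-right-edge window wins
    feat = region("r", "chr1", 5000, 5100)
    positions = [3001, 3002, 3003, 3004, 3005, 5050]
    idx = make_index({"s": positions})
    got = local_rate("s", feat, idx, window_length=2500, step=500, chrom_length=10_000)
    want = brute_force_local(feat, positions, 2500, 500, 10_000)
    assert got == pytest.approx(want)
    assert got == pytest.approx(6 / 2500)  # window [2600, 5100) catches all six


def test_local_rate_brute_force_grid():
    rng = np.random.default_rng(99)
    feat = region("r", "chr1", 4000, 4800)
    for trial in range(10):
        positions = sorted(rng.integers(1, 10_000, size=25).tolist())
        idx = make_index({"s": positions})
        for window, step in [(1000, 250), (2000, 500), (801, 100)]:
            got = local_rate("s", feat, idx, window, step, chrom_length=10_000)
            want = brute_force_local(feat, positions, window, step, 10_000)
            assert got == pytest.approx(want), (trial, window, step)


def test_local_rate_no_mutations_and_fallback():
    feat = region("r", "chr1", 100, 400)
    assert local_rate("s", feat, make_index({}), window_length=1000) == 0.0
    # feature longer than window -> single feature-span window, warned
    wide = region("w", "chr1", 0, 5000)
    idx = make_index({"s": [10, 20, 30]})
    with pytest.warns(UserWarning, match="exceeds the window"):
        rate = local_rate("s", wide, idx, window_length=1000)
    assert rate == pytest.approx(3 / 5000)


def test_local_rate_at_least_feature_density():
    feat = region("r", "chr1", 1000, 2000)
    idx = make_index({"s": [1500, 1501, 1502]})
    own_density = 3 / 1000
    got = local_rate("s", feat, idx, window_length=1000, chrom_length=10_000)
    assert got >= own_density  # window == feature span is among the placements


# ---------------------------------------------------------------------------
# covariates


def test_prepare_covariates_gc_and_tracks(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">chr1\n" + "GGCC" + "ATAT" + "GCAT" + "\n")
    pysam.faidx(str(fasta))
    feats = [
        region("hi", "chr1", 0, 4),
        region("lo", "chr1", 4, 8),
        region("half", "chr1", 8, 12),
    ]
    track = tmp_path / "t.bed"
    track.write_text("chr1\t0\t2\t1\nchr1\t2\t4\t3\n")
    with pytest.warns(UserWarning, match="missing track"):
        df = prepare_covariates(feats, genome=fasta, tracks={"rt": track})
    assert df.loc["hi", "gc"] == 1.0
    assert df.loc["lo", "gc"] == 0.0
    assert df.loc["half", "gc"] == 0.5
    # two equal-length intervals with values 1 and 3 -> length-weighted mean 2
    assert df.loc["hi", "rt"] == pytest.approx(2.0)
    # features without track coverage get the cohort median
    assert df.loc["lo", "rt"] == pytest.approx(2.0)


def test_prepare_covariates_missing_chrom_fatal(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">chr1\nACGT\n")
    pysam.faidx(str(fasta))
    with pytest.raises(ValueError, match="chr2"):
        prepare_covariates([region("r", "chr2", 0, 2)], genome=fasta)


# ---------------------------------------------------------------------------
# affinity propagation clustering


def two_group_profiles(rng):
    rows = {}
    for i in range(8):
        rows[f"low_{i}"] = [0.0 + rng.normal(0, 0.01), 0.0 + rng.normal(0, 0.01)]
    for i in range(8):
        rows[f"high_{i}"] = [10.0 + rng.normal(0, 0.01), 10.0 + rng.normal(0, 0.01)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["gc", "rt"])


def test_cluster_features_purity_and_order_invariance():
    rng = np.random.default_rng(5)
    profiles = two_group_profiles(rng)
    clusters, fallback = cluster_features(profiles)
    assert not fallback
    for cluster in clusters:
        prefixes = {fid.split("_")[0] for fid in cluster.members}
        assert len(prefixes) == 1  # every cluster is pure
        assert cluster.exemplar in cluster.members
    # partition covers all features exactly once
    all_members = [fid for c in clusters for fid in c.members]
    assert sorted(all_members) == sorted(profiles.index)
    # input order must not matter
    shuffled = profiles.sample(frac=1.0, random_state=11)
    clusters2, _ = cluster_features(shuffled)
    assert {c.members for c in clusters} == {c.members for c in clusters2}


def test_cluster_identical_covariates_single_cluster():
    profiles = pd.DataFrame(
        {"gc": [0.5] * 5, "rt": [1.0] * 5}, index=[f"f{i}" for i in range(5)]
    )
    clusters, _ = cluster_features(profiles)
    assert len(clusters) == 1
    assert clusters[0].members == frozenset(profiles.index)


# ---------------------------------------------------------------------------
# clustered rates


def test_clustered_rate_examples():
    feats = {
        "a": region("a", "chr1", 0, 1000),
        "b": region("b", "chr1", 2000, 3000),
    }
    from mutburden.background import FeatureCluster

    pair = [FeatureCluster("c0", "a", frozenset({"a", "b"}), 2000)]
    single = [
        FeatureCluster("c0", "a", frozenset({"a"}), 1000),
        FeatureCluster("c1", "b", frozenset({"b"}), 1000),
    ]
    counts = {"a": 2, "b": 0}
    assert clustered_rate("s", feats["a"], pair, counts, feats) == pytest.approx(1e-3)
    assert clustered_rate("s", feats["a"], single, counts, feats) == pytest.approx(2e-3)
    # singleton cluster == the feature's own density
    assert clustered_rate("s", feats["b"], single, counts, feats) == 0.0


def test_all_in_one_cluster_equals_global():
    from mutburden.background import FeatureCluster

    feats = [region(f"f{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(6)]
    by_id = {f.feature_id: f for f in feats}
    counts = {f"f{i}": i for i in range(6)}
    whole = [FeatureCluster("c0", "f0", frozenset(by_id), 3000)]
    for feat in feats:
        assert clustered_rate("s", feat, whole, counts, by_id) == global_rate(
            "s", feats, counts
        )


def test_local_clustered_rate():
    from mutburden.background import FeatureCluster

    a = region("a", "chr1", 1000, 1500)
    b = region("b", "chr1", 6000, 7000)
    by_id = {"a": a, "b": b}
    positions = {"s": [1100, 1101, 1102, 6500]}
    idx = make_index(positions)
    clusters = [FeatureCluster("c0", "a", frozenset({"a", "b"}), 1500)]
    got = local_clustered_rate(
        "s", a, clusters, idx, by_id,
        window_length=1000, step=250, chrom_lengths={"chr1": 10_000},
    )
    la = brute_force_local(a, positions["s"], 1000, 250, 10_000)
    lb = brute_force_local(b, positions["s"], 1000, 250, 10_000)
    want = (la * 500 + lb * 1000) / 1500  # length-weighted mean
    assert got == pytest.approx(want)
    # singleton cluster reduces to plain local_rate
    singles = [
        FeatureCluster("c0", "a", frozenset({"a"}), 500),
        FeatureCluster("c1", "b", frozenset({"b"}), 1000),
    ]
    got_single = local_clustered_rate(
        "s", a, singles, idx, by_id,
        window_length=1000, step=250, chrom_lengths={"chr1": 10_000},
    )
    assert got_single == pytest.approx(
        local_rate("s", a, idx, 1000, 250, 10_000)
    )


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_rate_geometric_mean():
    rates = {"A": 1e-6, "B": 4e-6}
    assert aggregate_rate(rates, {"A", "B"}) == pytest.approx(2e-6)
    assert aggregate_rate({"A": 3e-5, "B": 3e-5}, {"A", "B"}) == pytest.approx(3e-5)
    # floor rule: zero-rate foreground sample contributes the floor
    got = aggregate_rate({"A": 0.0, "B": 1e-8}, {"A", "B"}, floor=1e-8)
    assert got == pytest.approx(1e-8)


def test_aggregate_rate_scale_equivariant():
    rng = np.random.default_rng(3)
    rates = {f"s{i}": float(r) for i, r in enumerate(rng.uniform(1e-7, 1e-5, size=12))}
    fg = set(rates)
    base = aggregate_rate(rates, fg)
    scaled = aggregate_rate({k: 5 * v for k, v in rates.items()}, fg)
    assert scaled == pytest.approx(5 * base, rel=1e-9)


def test_aggregate_rate_empty_foreground_is_error():
    with pytest.raises(ValueError, match="untestable"):
        aggregate_rate({"A": 1e-6}, set())
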