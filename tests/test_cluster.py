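"""Stratified sampling, k-means on RMSD rows, apRMSD and repeat averaging."""

import numpy as np
import pandas as pd
import pytest

from gpcrdyn import cluster as cl
from gpcrdyn.cluster import (ClusterConfig, centroid_frames, kmeans_cluster,
                             repeat_and_average, stratified_sample,
                             summarize_clusters)
from gpcrdyn.errors import ConfigurationError, DataError


def _frame_table(n_per, conditions=("etic", "risp"), states=("helical", "extended")):
    rows = []
    for c in conditions:
        for s in states:
            rows += [{"condition": c, "el2_state": s}] * n_per
    return pd.DataFrame(rows)


def _planted_matrix(sizes, within=0.3, between=1.5, seed=0):
    """Symmetric pseudo-RMSD matrix with planted block structure."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    block = np.repeat(np.arange(len(sizes)), sizes)
    base = np.where(block[:, None] == block[None, :], within, between)
    jitter = rng.uniform(0, 0.02, size=(n, n))
    jitter = (jitter + jitter.T) / 2
    mat = base + jitter
    np.fill_diagonal(mat, 0.0)
    return mat, block


# ------------------------------------------------------------ stratified sample

def test_stratified_sample_sizes_and_strata():
    table = _frame_table(1500)
    idx = stratified_sample(table, 1000, seed=3)
    assert len(idx) == 4000
    picked = table.loc[idx]
    assert (picked.groupby(["condition", "el2_state"]).size() == 1000).all()
    assert len(np.unique(idx)) == 4000  # without replacement


def test_stratified_sample_deterministic_under_seed():
    table = _frame_table(30)
    a = stratified_sample(table, 1, seed=7)
    b = stratified_sample(table, 1, seed=7)
    np.testing.assert_array_equal(a, b)
    assert len(a) == 4


def test_stratified_sample_undersized_stratum_named():
    table = _frame_table(5)
    with pytest.raises(DataError, match="etic"):
        stratified_sample(table, 10, seed=0)


# ----------------------------------------------------------------- k-means

def test_kmeans_recovers_planted_blocks():
    mat, truth = _planted_matrix([30, 30])
    assign = kmeans_cluster(mat, ClusterConfig(k=2, seed=1))
    # exact recovery up to label permutation
    table = pd.crosstab(truth, assign).to_numpy()
    assert sorted(table.flatten()) == [0, 0, 30, 30]


def test_kmeans_one_frame_per_cluster_zero_withinss(rng):
    mat = np.abs(rng.normal(size=(5, 5)))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0)
    assign = kmeans_cluster(mat, ClusterConfig(k=5, seed=0))
    assert len(set(assign)) == 5  # singletons: within-cluster SS is zero


def test_kmeans_duplicate_rows_co_clustered():
    mat, _ = _planted_matrix([20, 20])
    mat[3] = mat[2]
    mat[:, 3] = mat[:, 2]
    assign = kmeans_cluster(mat, ClusterConfig(k=2, seed=5))
    assert assign[2] == assign[3]


def test_kmeans_k_exceeding_frames_rejected():
    mat, _ = _planted_matrix([3, 3])
    with pytest.raises(ConfigurationError):
        kmeans_cluster(mat, ClusterConfig(k=10, seed=0))


def test_kmeans_mds_embedding_also_recovers_blocks():
    mat, truth = _planted_matrix([25, 25])
    assign = kmeans_cluster(mat, ClusterConfig(k=2, seed=2, embedding="mds"))
    table = pd.crosstab(truth, assign).to_numpy()
    assert sorted(table.flatten()) == [0, 0, 25, 25]


# ------------------------------------------------------------- summaries

def test_within_aprmsd_of_pair_is_their_rmsd():
    mat = np.array([[0.0, 0.7], [0.7, 0.0]])
    labels = pd.DataFrame({"condition": ["a", "a"], "el2_state": ["h", "h"]})
    res = summarize_clusters(mat, np.array([0, 0]), labels)
    assert res.apRMSD[0, 0] == pytest.approx(0.7)


def test_condition_pure_cluster_is_100_percent():
    mat, _ = _planted_matrix([4, 4])
    labels = pd.DataFrame({"condition": ["a"] * 4 + ["b"] * 4,
                           "el2_state": ["h"] * 8})
    res = summarize_clusters(mat, np.array([0] * 4 + [1] * 4), labels)
    comp = res.composition
    a_in_0 = comp[(comp.cluster == 0) & (comp.axis == "condition") &
                  (comp.category == "a")]["mean"].item()
    b_in_0 = comp[(comp.cluster == 0) & (comp.axis == "condition") &
                  (comp.category == "b")]["mean"].item()
    assert a_in_0 == 100.0 and b_in_0 == 0.0


def test_aprmsd_matches_brute_force_pair_loop(rng):
    mat, block = _planted_matrix([6, 5, 7, 4], seed=3)
    res = summarize_clusters(mat, block)
    k = 4
    for a in range(k):
        ia = np.flatnonzero(block == a)
        pairs = [mat[i, j] for i in ia for j in ia if i < j]
        assert res.apRMSD[a, a] == pytest.approx(np.mean(pairs), abs=1e-10)
        for b in range(a + 1, k):
            ib = np.flatnonzero(block == b)
            cross = [mat[i, j] for i in ia for j in ib]
            assert res.apRMSD[a, b] == pytest.approx(np.mean(cross), abs=1e-10)


def test_composition_percentages_sum_to_100():
    mat, block = _planted_matrix([10, 10, 10, 10], seed=1)
    labels = _frame_table(10)
    res = summarize_clusters(mat, block, labels)
    sums = res.composition.groupby(["cluster", "axis"])["mean"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=0.1)


def test_planted_within_aprmsd_below_between():
    mat, block = _planted_matrix([12, 12, 12, 12], seed=2)
    res = summarize_clusters(mat, block)
    k = 4
    for a in range(k):
        for b in range(k):
            if a != b:
                assert res.apRMSD[a, a] < res.apRMSD[a, b]


# -------------------------------------------------------------- centroids

def test_centroid_of_singleton_cluster():
    mat = np.array([[0.0, 1.0], [1.0, 0.0]])
    cents = centroid_frames(mat, np.array([0, 1]))
    np.testing.assert_array_equal(cents, [0, 1])


def test_centroid_middle_of_collinear_frames():
    mat = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    cents = centroid_frames(mat, np.zeros(3, dtype=int))
    assert cents[0] == 1


def test_centroid_matches_brute_force_argmin(rng):
    mat, block = _planted_matrix([8, 9], seed=6)
    cents = centroid_frames(mat, block)
    for c, cent in enumerate(cents):
        members = np.flatnonzero(block == c)
        means = [np.mean([mat[i, j] for j in members if j != i]) for i in members]
        assert cent == members[int(np.argmin(means))]


# -------------------------------------------------------- repeated protocol

def _builder_for(mat):
    def build(frame_ids):
        return mat[np.ix_(frame_ids, frame_ids)]
    return build


def test_single_repeat_has_zero_sd():
    mat, _ = _planted_matrix([40, 40, 40, 40], seed=4)
    table = _frame_table(40)
    cfg = ClusterConfig(k=4, n_starts=5, n_repeats=1, n_per_stratum=20, seed=0)
    res = repeat_and_average(table, _builder_for(mat), cfg)
    assert (res.composition.sd == 0.0).all()


def test_repeat_average_on_planted_structure():
    """Two-condition planted structure: condition-pure clusters with low sd
    across repeats, EL2 states mixed within clusters."""
    # 4 blocks = (condition x substate); EL2 labels deliberately cut across blocks
    mat, block = _planted_matrix([50, 50, 50, 50], seed=8)
    table = _frame_table(50, conditions=("etic", "risp"))
    cfg = ClusterConfig(k=4, n_starts=10, n_repeats=8, n_per_stratum=25, seed=3)
    res = repeat_and_average(table, _builder_for(mat), cfg)
    comp = res.composition
    cond = comp[comp.axis == "condition"]
    assert (cond.sd < 2.0).all()
    # every cluster is pure in condition: one condition at 100, the other at 0
    for c in sorted(cond.cluster.unique()):
        vals = sorted(cond[cond.cluster == c]["mean"].tolist())
        np.testing.assert_allclose(vals, [0.0, 100.0], atol=1e-8)


def test_repeat_average_invariant_to_frame_permutation():
    mat, _ = _planted_matrix([20, 20, 20, 20], seed=9)
    table = _frame_table(20)
    cfg = ClusterConfig(k=4, n_starts=5, n_repeats=3, n_per_stratum=10, seed=1)
    base = repeat_and_average(table, _builder_for(mat), cfg)
    perm = np.random.default_rng(0).permutation(len(table))
    table_p = table.iloc[perm].reset_index(drop=True)
    mat_p = mat[np.ix_(perm, perm)]
    res = repeat_and_average(table_p, _builder_for(mat_p), cfg)

    # cluster ids are nominal: the aggregated result must be identical up to
    # a relabeling, i.e. the multisets of per-cluster profiles must agree
    def profiles(comp):
        out = []
        for c in sorted(comp.cluster.unique()):
            sub = comp[comp.cluster == c].sort_values(["axis", "category"])
            out.append(tuple(np.round(sub["mean"].to_numpy(), 6)))
        return sorted(out)

    assert profiles(base.composition) == profiles(res.composition)
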