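"""Mean adjusted agreement relations, clustering and feature merging."""

import numpy as np
import pandas as pd
import pytest

from rfrelate.forest import ForestConfig, fit_forest
from rfrelate.relations import (
    RelationMatrix,
    cluster_relations,
    mean_adjusted_agreement,
    merge_features,
    pearson_relation,
)


def maa_oracle(forest):
    """Hand computation of M[i, j] from the serialized node/surrogate records."""
    p = forest.p
    sums = np.zeros((p, p))
    n_primary = np.zeros(p)
    for nd in range(len(forest.node_feature)):
        j = forest.node_feature[nd]
        if j >= 0:
            n_primary[j] += 1
            for si in range(forest.sur_count[nd]):
                sums[forest.sur_feat[nd, si], j] += forest.sur_adj[nd, si]
    M = sums / np.where(n_primary > 0, n_primary, 1.0)[None, :]
    np.fill_diagonal(M, 1.0)
    return M


def _two_group_data(seed=0, n=100):
    """Two mutually-informative but uncorrelated metabolite groups + noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat(["A", "B"], n // 2)
    shift = np.where(y == "A", 3.0, 0.0)
    g1 = shift[:, None] + rng.standard_normal((n, 2)) * 0.3  # corr within group
    dup = g1[:, :1] + 0.05 * rng.standard_normal((n, 1))  # near-duplicate of feature 0
    noise = rng.standard_normal((n, 4))
    return np.column_stack([g1, dup, noise]), y


def test_duplicate_feature_has_relation_one():
    X, y = _two_group_data()
    X = np.column_stack([X, X[:, 0].copy()])  # exact duplicate of feature 0
    # full surrogate list: the duplicate can never be crowded out
    forest = fit_forest(X, y, ForestConfig(ntree=50, n_surrogates=X.shape[1] - 1, seed=1))
    rel = mean_adjusted_agreement(forest)
    j_dup = X.shape[1] - 1
    assert rel.directed.iloc[j_dup, 0] == pytest.approx(1.0)


def test_independent_noise_relation_near_zero():
    # enough competing features that chance agreements at small nodes are
    # crowded out of the stored top-s surrogate lists
    vals = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 100
        y = np.repeat(["A", "B"], n // 2)
        x0 = np.where(y == "A", 3.0, 0.0) + rng.standard_normal(n)
        noise = rng.standard_normal((n, 19))
        X = np.column_stack([x0, noise])
        forest = fit_forest(X, y, ForestConfig(ntree=50, n_surrogates=2, seed=seed))
        rel = mean_adjusted_agreement(forest)
        vals.append(rel.directed.iloc[1:, 0].mean())  # noise as surrogate for informative
    assert np.mean(vals) < 0.1


def test_matrix_matches_hand_computation_on_toy_forest(two_class_block_dataset):
    table, _ = two_class_block_dataset
    y = table.labels("origin").to_numpy()
    forest = fit_forest(table, y, ForestConfig(ntree=5, n_surrogates=3, seed=2))
    rel = mean_adjusted_agreement(forest)
    assert np.allclose(rel.directed.to_numpy(), maa_oracle(forest))


def test_never_primary_feature_column_is_zero():
    X, y = _two_group_data(seed=4)
    forest = fit_forest(X, y, ForestConfig(ntree=30, n_surrogates=2, seed=3))
    rel = mean_adjusted_agreement(forest)
    never_primary = np.flatnonzero(
        np.bincount(
            forest.node_feature[forest.node_feature >= 0], minlength=forest.p
        ) == 0
    )
    for j in never_primary:
        col = rel.directed.iloc[:, j].drop(rel.directed.columns[j])
        assert (col == 0).all()


def test_subset_restriction_and_unknown_feature_error():
    X, y = _two_group_data(seed=5)
    forest = fit_forest(X, y, ForestConfig(ntree=20, n_surrogates=2, seed=4))
    rel = mean_adjusted_agreement(forest, feature_subset=[0, 1, 2])
    assert rel.directed.shape == (3, 3)
    with pytest.raises(KeyError):
        mean_adjusted_agreement(forest, feature_subset=[0, 999])


def test_values_bounded_and_symmetrization_preserves_bounds():
    X, y = _two_group_data(seed=6)
    forest = fit_forest(X, y, ForestConfig(ntree=30, n_surrogates=3, seed=5))
    rel = mean_adjusted_agreement(forest)
    M = rel.directed.to_numpy()
    S = rel.symmetrized().to_numpy()
    assert M.min() >= 0 and M.max() <= 1
    assert S.min() >= 0 and S.max() <= 1


# ----------------------------------------------------------------------
# Pearson comparison
# ----------------------------------------------------------------------


def test_pearson_self_anticorrelation_and_collinear(small_table):
    table = small_table.copy()
    table.intensities["f2"] = 100.0 - 2.0 * table.intensities["f1"]  # exact anti-corr
    rel = pearson_relation(table)
    assert rel.directed.loc["f1", "f1"] == pytest.approx(1.0)
    assert rel.directed.loc["f1", "f2"] == pytest.approx(1.0)  # |r| stored
    x = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
    assert np.corrcoef(x["x"], x["y"])[0, 1] == pytest.approx(1.0)


def test_pearson_zero_variance_feature_warned_and_zeroed(small_table):
    table = small_table.copy()
    table.intensities["f3"] = 5.0
    with pytest.warns(UserWarning, match="zero-variance"):
        rel = pearson_relation(table)
    assert (rel.directed.loc["f3"].drop("f3") == 0).all()


def test_relation_beyond_correlation_for_mutually_informative_groups():
    # two metabolite groups shifted in the same classes but with independent
    # noise: the forest links them (surrogate agreement through the class
    # signal) while plain correlation stays moderate
    rng = np.random.default_rng(8)
    n = 200
    y = np.repeat(["A", "B"], n // 2)
    shift = np.where(y == "A", 4.0, 0.0)
    f0 = shift + 0.5 * rng.standard_normal(n)
    f1 = shift + 0.5 * rng.standard_normal(n)  # same signal, independent noise
    noise = rng.standard_normal((n, 4))
    X = np.column_stack([f0, f1, noise])
    forest = fit_forest(X, y, ForestConfig(ntree=100, n_surrogates=2, seed=7))
    rel = mean_adjusted_agreement(forest)
    s01 = rel.symmetrized().iloc[0, 1]
    noise_level = rel.symmetrized().iloc[2:, :2].to_numpy().mean()
    assert s01 > 0.5
    assert s01 > 3 * max(noise_level, 0.05)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------


def _block_matrix():
    ids = [f"f{i}" for i in range(6)]
    M = np.full((6, 6), 0.05)
    M[:3, :3] = 0.9
    M[3:, 3:] = 0.9
    np.fill_diagonal(M, 1.0)
    return RelationMatrix(pd.DataFrame(M, index=ids, columns=ids))


def test_two_perfect_blocks_recovered_exactly():
    cl = cluster_relations(_block_matrix(), 2)
    labels = cl.labels
    assert labels["f0"] == labels["f1"] == labels["f2"]
    assert labels["f3"] == labels["f4"] == labels["f5"]
    assert labels["f0"] != labels["f3"]


def test_cluster_partition_invariant_to_feature_order():
    rel = _block_matrix()
    perm = ["f4", "f0", "f5", "f2", "f1", "f3"]
    rel_perm = RelationMatrix(rel.directed.loc[perm, perm])
    c1 = cluster_relations(rel, 2).labels
    c2 = cluster_relations(rel_perm, 2).labels
    for a in rel.feature_ids:
        for b in rel.feature_ids:
            assert (c1[a] == c1[b]) == (c2[a] == c2[b])


def test_too_many_clusters_rejected():
    with pytest.raises(ValueError):
        cluster_relations(_block_matrix(), 7)


# ----------------------------------------------------------------------
# merging
# ----------------------------------------------------------------------


def test_pair_above_threshold_forms_group():
    ids = ["a", "b", "c"]
    M = np.eye(3)
    M[0, 1] = M[1, 0] = 0.95
    mg = merge_features(RelationMatrix(pd.DataFrame(M, index=ids, columns=ids)), 0.9)
    assert mg.as_sets() == [{"a", "b"}]


def test_threshold_one_with_no_offdiagonal_ones_yields_nothing():
    ids = ["a", "b"]
    M = np.eye(2)
    M[0, 1] = M[1, 0] = 0.99
    mg = merge_features(RelationMatrix(pd.DataFrame(M, index=ids, columns=ids)), 1.0)
    assert mg.groups == []


def test_merge_monotone_in_threshold_and_order_invariant():
    rng = np.random.default_rng(3)
    ids = [f"f{i}" for i in range(8)]
    A = rng.uniform(0, 1, size=(8, 8))
    M = (A + A.T) / 2
    np.fill_diagonal(M, 1.0)
    rel = RelationMatrix(pd.DataFrame(M, index=ids, columns=ids))
    lo = merge_features(rel, 0.5)
    hi = merge_features(rel, 0.8)
    for g_hi in hi.as_sets():
        assert any(g_hi <= g_lo for g_lo in lo.as_sets())
    perm = list(rng.permutation(ids))
    rel_perm = RelationMatrix(rel.directed.loc[perm, perm])
    assert sorted(map(sorted, merge_features(rel_perm, 0.5).as_sets())) == sorted(
        map(sorted, lo.as_sets())
    )


def test_synthetic_triplets_merge_without_cross_metabolite_contamination():
    from rfrelate.preprocess import autoscale_by_batch
    from rfrelate.synthetic import adduct_benchmark_spec, generate_dataset

    table, truth = generate_dataset(adduct_benchmark_spec(seed=1))
    table = autoscale_by_batch(table)
    y = table.labels("origin").to_numpy()
    forest = fit_forest(table, y, ForestConfig(ntree=150, n_surrogates=36, seed=9))
    informative = sorted(truth.informative_metabolites)
    feats = [f for m in informative for f in truth.features_of_metabolite(m)]
    rel = mean_adjusted_agreement(forest, feature_subset=feats)
    mg = merge_features(rel, threshold=0.8)
    triplets = {m: set(truth.features_of_metabolite(m)) for m in informative}
    recovered = sum(any(t <= g for g in mg.as_sets()) for t in triplets.values())
    assert recovered == len(triplets)
    for g in mg.as_sets():
        mets = {truth.metabolite_of_feature[f] for f in g}
        assert len(mets) == 1  # no cross-metabolite merges
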