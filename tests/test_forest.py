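"""Forest engine: split search, surrogates, OOB machinery, importance."""

import numpy as np
import pytest

from rfrelate.forest import (
    Forest,
    ForestConfig,
    air_importance,
    best_split,
    case_weights,
    default_mtry,
    default_n_surrogates,
    find_surrogates,
    fit_forest,
    gini_impurity,
    oob_confusion,
    predict,
    predict_proba,
)
from rfrelate.evaluation import confusion_metrics


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------


def _gini_oracle(y):
    _, counts = np.unique(y, return_counts=True)
    props = counts / counts.sum()
    return 1.0 - (props**2).sum()


def _split_decrease(x, y, thr):
    left = x <= thr
    n = len(y)
    return _gini_oracle(y) - (
        left.sum() * _gini_oracle(y[left]) + (~left).sum() * _gini_oracle(y[~left])
    ) / n


def brute_force_best_split(X, y, candidates):
    """Exhaustive enumeration over all (candidate, midpoint) pairs."""
    best = None
    for f in sorted(candidates):
        u = np.unique(X[:, f])
        for thr in 0.5 * (u[:-1] + u[1:]):
            dec = _split_decrease(X[:, f], y, thr)
            if best is None or dec > best[2] + 1e-12:
                best = (f, thr, dec)
    return best


def brute_force_surrogates(X, primary_feature, primary_threshold, s):
    """Exhaustive search over all thresholds and both directions per feature."""
    go_left = X[:, primary_feature] <= primary_threshold
    n = len(go_left)
    maj = max(go_left.sum(), n - go_left.sum()) / n
    out = []
    for f in range(X.shape[1]):
        if f == primary_feature:
            continue
        u = np.unique(X[:, f])
        best = None
        for thr in 0.5 * (u[:-1] + u[1:]):
            for flip in (0, 1):
                side = X[:, f] <= thr if flip == 0 else X[:, f] > thr
                agreement = (side == go_left).mean()
                if best is None or agreement > best[0] + 1e-12:
                    best = (agreement, thr, flip)
        if best is not None:
            adj = (best[0] - maj) / (1.0 - maj)
            if adj > 0:
                out.append((f, best[1], best[2], adj))
    out.sort(key=lambda t: (-t[3], t[0]))
    return out[:s]


# ----------------------------------------------------------------------
# split primitives
# ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [([2, 2], 0.5), ([4, 0], 0.0), ([1, 1, 1, 1], 0.75)],
)
def test_gini_closed_forms(counts, expected):
    assert gini_impurity(counts) == pytest.approx(expected)


def test_gini_rejects_empty_node():
    with pytest.raises(ValueError):
        gini_impurity([0, 0])


def test_best_split_separates_pure_children():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array(["A", "A", "B", "B"])
    f, thr, dec = best_split(X, y, [0])
    assert (f, thr, dec) == (0, pytest.approx(2.5), pytest.approx(0.5))


def test_best_split_constant_feature_is_no_split():
    X = np.ones((6, 1))
    y = np.array(["A", "B", "A", "B", "A", "B"])
    assert best_split(X, y, [0]) is None


@pytest.mark.parametrize("seed", range(10))
def test_best_split_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 16)
    p = rng.integers(2, 7)
    X = rng.uniform(size=(n, p))
    y = rng.integers(0, 3, size=n)
    while len(np.unique(y)) < 2:
        y = rng.integers(0, 3, size=n)
    candidates = list(rng.choice(p, size=min(3, p), replace=False))
    got = best_split(X, y, candidates)
    want = brute_force_best_split(X, y, candidates)
    assert got is not None and want is not None
    assert got[2] == pytest.approx(want[2], abs=1e-10)
    # the returned split achieves the exhaustive optimum
    assert _split_decrease(X[:, got[0]], y, got[1]) == pytest.approx(want[2], abs=1e-10)


def test_surrogate_adjusted_agreement_formula():
    # node n=10, primary 6 left / 4 right (maj 0.6), surrogate agreeing on 9
    x_primary = np.array([0.0] * 6 + [1.0] * 4)
    x_sur = np.array([0.0] * 5 + [1.0] * 5)  # routes sample 5 wrongly: agrees on 9 of 10
    X = np.column_stack([x_primary, x_sur])
    sur = find_surrogates(X, primary_feature=0, primary_threshold=0.5, s=5)
    assert len(sur) == 1
    f, thr, flip, adj = sur[0]
    assert f == 1 and flip == 0
    assert adj == pytest.approx((0.9 - 0.6) / (1 - 0.6))


def test_identical_feature_is_perfect_surrogate_ranked_first():
    rng = np.random.default_rng(3)
    x = rng.uniform(size=12)
    X = np.column_stack([x, rng.uniform(size=12), x.copy()])
    sur = find_surrogates(X, primary_feature=0, primary_threshold=np.median(x), s=2)
    assert sur[0][0] == 2
    assert sur[0][3] == pytest.approx(1.0)


def test_anticorrelated_duplicate_scores_one_via_direction_flip():
    x = np.linspace(0, 1, 10)
    X = np.column_stack([x, -x])
    sur = find_surrogates(X, primary_feature=0, primary_threshold=0.45, s=1)
    assert sur[0][0] == 1 and sur[0][2] == 1
    assert sur[0][3] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(8))
def test_surrogate_search_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    n, p = 12, 5
    X = rng.uniform(size=(n, p))
    thr = float(np.median(X[:, 0]) + 0.01)
    got = find_surrogates(X, 0, thr, s=4)
    want = brute_force_surrogates(X, 0, thr, s=4)
    assert len(got) == len(want)
    for g, w in zip(got, want):
        assert g[0] == w[0]
        assert g[3] == pytest.approx(w[3], abs=1e-12)


# ----------------------------------------------------------------------
# forest fitting
# ----------------------------------------------------------------------


def test_case_weights_ratio_matches_inverse_class_frequency():
    sizes = (213, 25, 31, 13, 35)
    ycls = np.repeat(np.arange(5), sizes)
    w = case_weights(ycls, 5, "inverse_class_frequency")
    germany, peru = w[0], w[sum(sizes[:3])]
    assert peru / germany == pytest.approx(213 / 13)
    assert w.sum() == pytest.approx(1.0)


def test_parameter_defaults_follow_power_rules():
    assert default_mtry(718) == 138  # floor(718^0.75)
    assert default_n_surrogates(718) == 35  # floor(0.05 * 718)


def test_fit_is_deterministic_given_seed():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((60, 8))
    y = np.where(X[:, 0] > 0, "A", "B")
    cfg = ForestConfig(ntree=20, n_surrogates=2, seed=9)
    f1 = fit_forest(X, y, cfg)
    f2 = fit_forest(X, y, cfg)
    assert np.array_equal(f1.node_threshold, f2.node_threshold)
    assert np.array_equal(f1.node_feature, f2.node_feature)
    assert np.array_equal(f1.inbag, f2.inbag)
    assert np.array_equal(f1.sur_adj, f2.sur_adj)


def test_single_class_labels_rejected():
    X = np.random.default_rng(0).uniform(size=(10, 3))
    with pytest.raises(ValueError):
        fit_forest(X, ["A"] * 10, ForestConfig(ntree=2, seed=0))


def test_per_tree_oob_fraction_near_classical_limit():
    rng = np.random.default_rng(5)
    n = 317
    X = rng.standard_normal((n, 5))
    y = np.where(X[:, 0] > 0, "A", "B")
    cfg = ForestConfig(ntree=100, n_surrogates=0, case_weight_mode="none", seed=2)
    forest = fit_forest(X, y, cfg)
    frac = forest.oob_mask().mean(axis=1).mean()
    assert frac == pytest.approx(np.exp(-1), rel=0.02)


def test_gini_decrease_nonnegative_and_surrogate_lists_sorted(two_class_block_dataset):
    table, _ = two_class_block_dataset
    y = table.labels("origin").to_numpy()
    forest = fit_forest(table, y, ForestConfig(ntree=5, n_surrogates=4, seed=1))
    internal = forest.node_feature >= 0
    assert internal.any()
    for nd in np.flatnonzero(internal)[:200]:
        adj = forest.sur_adj[nd, : forest.sur_count[nd]]
        assert (adj > 0).all()
        assert (np.diff(adj) <= 1e-12).all()  # non-increasing


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------


def _toy_forest_two_trees():
    """A few single-split trees on one separating feature, probability mode."""
    X = np.array([[0.0], [1.0]] * 10)
    y = np.array(["A", "B"] * 10)
    return fit_forest(X, y, ForestConfig(ntree=5, mtry=1, n_surrogates=0, mode="probability", seed=0))


def test_vote_and_probability_prediction_agree(two_class_block_dataset):
    table, _ = two_class_block_dataset
    y = table.labels("origin").to_numpy()
    forest = fit_forest(
        table, y, ForestConfig(ntree=60, n_surrogates=0, mode="probability", seed=7)
    )
    proba = predict_proba(forest, table)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    hard = predict(forest, table)
    soft = forest.classes_[np.argmax(proba, axis=1)]
    # identical up to tie handling; with 60 trees on separable data ties are rare
    assert (hard == soft).mean() > 0.97


def test_probability_rows_average_leaf_proportions():
    forest = _toy_forest_two_trees()
    proba = predict_proba(forest, np.array([[0.0], [1.0]]))
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert proba[0, 0] > 0.9 and proba[1, 1] > 0.9


def test_probability_mode_required_for_proba():
    X = np.array([[0.0], [1.0], [0.0], [1.0]])
    y = np.array(["A", "B", "A", "B"])
    forest = fit_forest(X, y, ForestConfig(ntree=2, mtry=1, n_surrogates=0, seed=0))
    with pytest.raises(ValueError):
        predict_proba(forest, X)


def test_oob_confusion_null_labels_error_near_random_guess():
    rng = np.random.default_rng(11)
    n = 100
    X = rng.standard_normal((n, 10))
    y = rng.permutation(np.repeat(np.arange(5), n // 5)).astype(str)
    forest = fit_forest(X, y, ForestConfig(ntree=300, n_surrogates=0, seed=4))
    m = confusion_metrics(oob_confusion(forest, X, y))
    assert m["error"] / 100 == pytest.approx(0.8, abs=0.05)


def test_oob_error_beats_chance_on_informative_data(two_class_block_dataset):
    table, _ = two_class_block_dataset
    y = table.labels("origin").to_numpy()
    forest = fit_forest(table, y, ForestConfig(ntree=100, n_surrogates=0, seed=3))
    m = confusion_metrics(oob_confusion(forest, table, y))
    assert m["error"] < 50.0  # random guessing for 2 balanced classes


def test_oob_error_equals_one_minus_accuracy(two_class_block_dataset):
    table, _ = two_class_block_dataset
    y = table.labels("origin").to_numpy()
    forest = fit_forest(table, y, ForestConfig(ntree=30, n_surrogates=0, seed=8))
    cm = oob_confusion(forest, table, y)
    m = confusion_metrics(cm)
    trace = np.trace(cm.counts.to_numpy())
    assert m["accuracy"] == pytest.approx(100.0 * trace / cm.total)
    assert m["error"] == pytest.approx(100.0 - m["accuracy"])


# ----------------------------------------------------------------------
# importance
# ----------------------------------------------------------------------


def test_air_importance_unbiased_on_pure_noise():
    rng = np.random.default_rng(21)
    n, p = 80, 15
    X = rng.standard_normal((n, p))
    y = rng.permutation(np.repeat(["A", "B"], n // 2))
    imp = air_importance(X, y, ForestConfig(ntree=500, seed=13))
    se = imp.std() / np.sqrt(p)
    assert abs(imp.mean()) < 2 * se + 1e-12


def test_air_importance_dominant_feature_positive_and_largest():
    rng = np.random.default_rng(2)
    n = 60
    X = rng.standard_normal((n, 6))
    y = np.where(X[:, 3] > 0, "A", "B")
    imp = air_importance(X, y, ForestConfig(ntree=100, seed=5))
    assert imp.idxmax() == 3
    assert imp.max() > 0


def test_air_importance_resists_many_categories_bias():
    # a continuous (many split points) noise feature must not outrank a
    # genuinely informative binary feature
    rng = np.random.default_rng(31)
    n = 200
    informative = (rng.uniform(size=n) < 0.5).astype(float)
    y = np.where(rng.uniform(size=n) < 0.85, informative, 1 - informative).astype(int).astype(str)
    noise = rng.uniform(size=(n, 4))  # high-cardinality noise
    X = np.column_stack([informative, noise])
    imp = air_importance(X, y, ForestConfig(ntree=300, seed=17))
    assert imp.idxmax() == 0


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------


def test_forest_json_roundtrip(tmp_path):
    forest = _toy_forest_two_trees()
    path = tmp_path / "model.json"
    forest.to_json(str(path))
    loaded = Forest.from_json(str(path))
    X = np.array([[0.0], [1.0]])
    assert np.array_equal(predict(forest, X), predict(loaded, X))
    assert np.allclose(predict_proba(forest, X), predict_proba(loaded, X))
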