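"""Random-forest engine with surrogate splits and corrected impurity importance.

Classification trees are grown with Gini splitting on bootstrap samples
drawn with per-sample case weights (used to over-sample rare classes).
Each internal node can additionally record up to ``s`` surrogate splits --
secondary splits on other features that best mimic the primary split's
left/right assignment -- together with their adjusted agreement

    adj = (A - maj) / (1 - maj),

where ``A`` is the fraction of node samples routed like the primary split
and ``maj`` the weight share of the primary split's larger child.
Surrogates drive Surrogate Minimal Depth feature selection and the mean
adjusted agreement relation analysis.

Importance is the actual impurity reduction (AIR): during growth every
candidate feature competes both with its actual values and with a
within-node permuted copy; a feature's score collects the Gini decrease of
nodes split on its actual values and loses the decrease of nodes split on
its permuted copy, which cancels the split-selection optimism of the plain
Gini importance.  Probability forests ("probability machines") average
leaf class proportions over trees instead of voting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import (
    _accumulate_leaf,
    _bootstrap,
    _eval_split,
    _eval_surrogate,
    _grow_tree,
    _maa_accumulate,
    _smd_accumulate,
)
from .table import FeatureTable

__all__ = [
    "ForestConfig",
    "Forest",
    "gini_impurity",
    "best_split",
    "find_surrogates",
    "fit_forest",
    "predict",
    "predict_proba",
    "oob_votes",
    "oob_confusion",
    "air_importance",
    "permutation_importance",
    "default_mtry",
    "default_n_surrogates",
]


def default_mtry(p: int) -> int:
    """Candidate features per node: floor(p^(3/4)), at least 1."""
    return max(1, math.floor(p ** 0.75))


def default_n_surrogates(p: int) -> int:
    """Surrogates stored per node: floor(0.05 * p), at least 1."""
    return max(1, math.floor(0.05 * p))


@dataclass
class ForestConfig:
    """Growth parameters.

    ``mtry`` defaults to floor(p^(3/4)) and ``n_surrogates`` to
    floor(0.05 * p) when left ``None``; both are resolved against the
    training table at fit time.  ``case_weight_mode='inverse_class_frequency'``
    samples each bootstrap draw with probability proportional to
    1 / (k * n_class), so rare classes enter the bags more often.
    """

    ntree: int = 10_000
    mtry: Optional[int] = None
    min_node_size: int = 1
    n_surrogates: Optional[int] = None
    case_weight_mode: str = "inverse_class_frequency"
    mode: str = "classification"
    seed: int = 0

    def resolve(self, p: int) -> "ForestConfig":
        mtry = self.mtry if self.mtry is not None else default_mtry(p)
        s = self.n_surrogates if self.n_surrogates is not None else default_n_surrogates(p)
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry={mtry} outside [1, {p}]")
        if not 0 <= s <= p - 1:
            raise ValueError(f"n_surrogates={s} outside [0, {p - 1}]")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.case_weight_mode not in ("none", "inverse_class_frequency"):
            raise ValueError(f"unknown case_weight_mode {self.case_weight_mode!r}")
        if self.mode not in ("classification", "probability"):
            raise ValueError(f"unknown mode {self.mode!r}")
        return ForestConfig(
            ntree=self.ntree,
            mtry=mtry,
            min_node_size=self.min_node_size,
            n_surrogates=s,
            case_weight_mode=self.case_weight_mode,
            mode=self.mode,
            seed=self.seed,
        )


# ----------------------------------------------------------------------
# seeding
# ----------------------------------------------------------------------

_MASK64 = (1 << 64) - 1


def _splitmix64_py(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def _tree_state(seed: int, tree: int) -> np.ndarray:
    """Independent per-tree RNG state: results do not depend on growth order."""
    x = _splitmix64_py(((seed & _MASK64) << 20) ^ (tree + 1))
    x = _splitmix64_py(x)
    if x == 0:
        x = 0x6A09E667F3BCC909
    return np.array([x], dtype=np.uint64)


# ----------------------------------------------------------------------
# standalone split primitives (same kernels the forest uses)
# ----------------------------------------------------------------------


def gini_impurity(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum((n_c / n)^2) of a class-count vector."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("class counts sum to zero")
    return float(1.0 - ((counts / total) ** 2).sum())


def best_split(X: np.ndarray, y: np.ndarray, candidate_features: Sequence[int]):
    """Exhaustive best Gini split among the candidate features of one node.

    Thresholds are midpoints between consecutive distinct sorted values.
    Ties are broken by lowest feature id, then lowest threshold.  Returns
    (feature, threshold, decrease), or ``None`` when no candidate admits a
    valid split (all candidates constant).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, ycls = np.unique(y, return_inverse=True)
    m = X.shape[0]
    wts = np.ones(m)
    counts = np.bincount(ycls, minlength=classes.size).astype(float)
    best = None
    for f in sorted(int(f) for f in candidate_features):
        vals = np.ascontiguousarray(X[:, f])
        order = np.argsort(vals, kind="stable")
        dec, thr = _eval_split(vals, order, ycls.astype(np.int64), wts, counts, float(m))
        if dec >= 0.0 and (best is None or dec > best[2]):
            best = (f, float(thr), float(dec))
    return best


def find_surrogates(X: np.ndarray, primary_feature: int, primary_threshold: float, s: int):
    """Surrogate splits for a node given its primary split.

    For every feature other than the primary, finds the threshold and
    direction maximizing agreement with the primary left/right assignment
    and keeps the ``s`` features with the largest positive adjusted
    agreement, sorted descending (ties: lowest feature id).  Each entry is
    (feature, threshold, flip, adjusted_agreement); flip=1 means samples
    with value <= threshold are routed to the primary's *right* child.
    """
    X = np.asarray(X, dtype=float)
    m, p = X.shape
    go_left = X[:, primary_feature] <= primary_threshold
    left_w = float(go_left.sum())
    if left_w == 0.0 or left_w == m:
        return []
    wts = np.ones(m)
    out = []
    for f in range(p):
        if f == primary_feature:
            continue
        vals = np.ascontiguousarray(X[:, f])
        order = np.argsort(vals, kind="stable")
        adj, thr, flip = _eval_surrogate(vals, order, go_left, wts, float(m), left_w)
        if adj > 0.0:
            out.append((f, float(thr), int(flip), float(adj)))
    out.sort(key=lambda t: (-t[3], t[0]))
    return out[:s]


# ----------------------------------------------------------------------
# the forest
# ----------------------------------------------------------------------


@dataclass
class Forest:
    """A fitted ensemble, stored as flat node arrays with per-tree offsets."""

    config: ForestConfig
    classes_: np.ndarray
    feature_names: list
    node_feature: np.ndarray  # (N,) int64, -1 for leaves
    node_threshold: np.ndarray  # (N,) float64
    node_left: np.ndarray  # (N,) int64 global node ids, -1 at leaves
    node_right: np.ndarray
    node_depth: np.ndarray
    node_counts: np.ndarray  # (N, k) in-bag class weights
    tree_offsets: np.ndarray  # (ntree+1,)
    inbag: np.ndarray  # (ntree, n) uint16 bootstrap counts
    sur_feat: Optional[np.ndarray] = None  # (N, s) int64
    sur_adj: Optional[np.ndarray] = None
    sur_flip: Optional[np.ndarray] = None
    sur_count: Optional[np.ndarray] = None  # (N,)
    _leaf_prop: Optional[np.ndarray] = field(default=None, repr=False)
    _leaf_onehot: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def ntree(self) -> int:
        return len(self.tree_offsets) - 1

    @property
    def p(self) -> int:
        return len(self.feature_names)

    @property
    def k(self) -> int:
        return len(self.classes_)

    @property
    def n_samples(self) -> int:
        return self.inbag.shape[1]

    def oob_mask(self) -> np.ndarray:
        """(ntree, n) boolean: True where a sample is out-of-bag."""
        return self.inbag == 0

    def max_depth(self) -> int:
        return int(self.node_depth.max())

    def _leaf_proportions(self) -> np.ndarray:
        if self._leaf_prop is None:
            sums = self.node_counts.sum(axis=1, keepdims=True)
            self._leaf_prop = self.node_counts / np.where(sums > 0, sums, 1.0)
        return self._leaf_prop

    def _leaf_majority_onehot(self) -> np.ndarray:
        if self._leaf_onehot is None:
            major = np.argmax(self.node_counts, axis=1)  # lowest index on ties
            onehot = np.zeros_like(self.node_counts)
            onehot[np.arange(len(major)), major] = 1.0
            self._leaf_onehot = onehot
        return self._leaf_onehot

    # -- serialization -------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "config": asdict(self.config),
            "classes": [str(c) for c in self.classes_],
            "feature_names": [str(f) for f in self.feature_names],
            "node_feature": self.node_feature.tolist(),
            "node_threshold": self.node_threshold.tolist(),
            "node_left": self.node_left.tolist(),
            "node_right": self.node_right.tolist(),
            "node_depth": self.node_depth.tolist(),
            "node_counts": self.node_counts.tolist(),
            "tree_offsets": self.tree_offsets.tolist(),
            "inbag": self.inbag.tolist(),
        }
        if self.sur_feat is not None:
            payload["sur_feat"] = self.sur_feat.tolist()
            payload["sur_adj"] = self.sur_adj.tolist()
            payload["sur_flip"] = self.sur_flip.tolist()
            payload["sur_count"] = self.sur_count.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "Forest":
        with open(path) as fh:
            d = json.load(fh)
        kwargs = {}
        if "sur_feat" in d:
            kwargs = dict(
                sur_feat=np.asarray(d["sur_feat"], dtype=np.int64),
                sur_adj=np.asarray(d["sur_adj"], dtype=float),
                sur_flip=np.asarray(d["sur_flip"], dtype=np.int8),
                sur_count=np.asarray(d["sur_count"], dtype=np.int64),
            )
        return cls(
            config=ForestConfig(**d["config"]),
            classes_=np.asarray(d["classes"]),
            feature_names=list(d["feature_names"]),
            node_feature=np.asarray(d["node_feature"], dtype=np.int64),
            node_threshold=np.asarray(d["node_threshold"], dtype=float),
            node_left=np.asarray(d["node_left"], dtype=np.int64),
            node_right=np.asarray(d["node_right"], dtype=np.int64),
            node_depth=np.asarray(d["node_depth"], dtype=np.int64),
            node_counts=np.asarray(d["node_counts"], dtype=float),
            tree_offsets=np.asarray(d["tree_offsets"], dtype=np.int64),
            inbag=np.asarray(d["inbag"], dtype=np.uint16),
            **kwargs,
        )


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------


def _as_matrix(table) -> tuple[np.ndarray, list]:
    if isinstance(table, FeatureTable):
        X = table.values()
        names = list(table.feature_ids)
    else:
        X = np.asarray(table, dtype=float)
        names = list(range(X.shape[1]))
    if np.isnan(X).any():
        raise ValueError("table has missing cells; impute before fitting")
    return np.ascontiguousarray(X), names


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(pd.Series(labels).to_numpy())
    if pd.isna(y).any():
        raise ValueError("labels contain missing values")
    classes, ycls = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit a forest")
    return classes, ycls.astype(np.int64)


def case_weights(ycls: np.ndarray, k: int, mode: str) -> np.ndarray:
    """Per-sample bootstrap sampling probabilities (sum to 1)."""
    n = ycls.shape[0]
    if mode == "none":
        return np.full(n, 1.0 / n)
    counts = np.bincount(ycls, minlength=k)
    w = 1.0 / (k * counts[ycls])
    return w / w.sum()


def fit_forest(table, labels, config: ForestConfig, _air_only: bool = False):
    """Grow a forest; returns the :class:`Forest` (or AIR scores, internally).

    Bootstrap samples of size n are drawn with replacement with
    probabilities proportional to the case weights; trees are grown until
    nodes are pure or at/below ``min_node_size`` distinct in-bag samples;
    surrogates are recorded at every internal node when ``n_surrogates > 0``.
    Fully reproducible from ``config.seed``.
    """
    X, names = _as_matrix(table)
    classes, ycls = _encode_labels(labels)
    n, p = X.shape
    if ycls.shape[0] != n:
        raise ValueError("labels do not align with samples")
    cfg = config.resolve(p)
    k = classes.size
    s = int(cfg.n_surrogates)

    probs = case_weights(ycls, k, cfg.case_weight_mode)
    cum_prob = np.cumsum(probs)
    cum_prob[-1] = 1.0

    max_nodes = 2 * n + 1
    b_feature = np.empty(max_nodes, np.int64)
    b_threshold = np.empty(max_nodes)
    b_left = np.empty(max_nodes, np.int64)
    b_right = np.empty(max_nodes, np.int64)
    b_depth = np.empty(max_nodes, np.int64)
    b_counts = np.empty((max_nodes, k))
    s_alloc = max(s, 1)
    b_sur_feat = np.zeros((max_nodes, s_alloc), np.int64)
    b_sur_adj = np.zeros((max_nodes, s_alloc))
    b_sur_flip = np.zeros((max_nodes, s_alloc), np.int8)
    b_sur_count = np.zeros(max_nodes, np.int64)
    air_score = np.zeros(p)
    pool = np.arange(p, dtype=np.int64)
    sur_pool = np.arange(p, dtype=np.int64)
    w_inbag = np.empty(n)

    air_mode = 1 if _air_only else 0
    store = not _air_only

    feats, thrs, lefts, rights, depths, countss = [], [], [], [], [], []
    surfs, suradjs, surflips, surcnts = [], [], [], []
    inbag = np.zeros((cfg.ntree, n), np.uint16) if store else None
    offsets = [0]

    for t in range(cfg.ntree):
        state = _tree_state(cfg.seed, t)
        _bootstrap(cum_prob, n, state, w_inbag)
        n_nodes = _grow_tree(
            X, ycls, k, w_inbag, cfg.mtry, cfg.min_node_size, s, air_mode, state,
            b_feature, b_threshold, b_left, b_right, b_depth, b_counts,
            b_sur_feat, b_sur_adj, b_sur_flip, b_sur_count, air_score, pool, sur_pool,
        )
        if store:
            inbag[t] = w_inbag.astype(np.uint16)
            feats.append(b_feature[:n_nodes].copy())
            thrs.append(b_threshold[:n_nodes].copy())
            lefts.append(b_left[:n_nodes].copy())
            rights.append(b_right[:n_nodes].copy())
            depths.append(b_depth[:n_nodes].copy())
            countss.append(b_counts[:n_nodes].copy())
            if s > 0:
                surfs.append(b_sur_feat[:n_nodes].copy())
                suradjs.append(b_sur_adj[:n_nodes].copy())
                surflips.append(b_sur_flip[:n_nodes].copy())
                surcnts.append(b_sur_count[:n_nodes].copy())
            offsets.append(offsets[-1] + n_nodes)

    if _air_only:
        return air_score / cfg.ntree

    tree_offsets = np.asarray(offsets, dtype=np.int64)
    # globalize child pointers
    g_left = np.concatenate(lefts)
    g_right = np.concatenate(rights)
    for t in range(cfg.ntree):
        lo, hi = tree_offsets[t], tree_offsets[t + 1]
        seg_l = g_left[lo:hi]
        seg_r = g_right[lo:hi]
        seg_l[seg_l >= 0] += lo
        seg_r[seg_r >= 0] += lo

    return Forest(
        config=cfg,
        classes_=classes,
        feature_names=names,
        node_feature=np.concatenate(feats),
        node_threshold=np.concatenate(thrs),
        node_left=g_left,
        node_right=g_right,
        node_depth=np.concatenate(depths),
        node_counts=np.concatenate(countss),
        tree_offsets=tree_offsets,
        inbag=inbag,
        sur_feat=np.concatenate(surfs) if s > 0 else None,
        sur_adj=np.concatenate(suradjs) if s > 0 else None,
        sur_flip=np.concatenate(surflips) if s > 0 else None,
        sur_count=np.concatenate(surcnts) if s > 0 else None,
    )


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------


def _query_matrix(forest: Forest, table) -> np.ndarray:
    X, names = (table.values(), list(table.feature_ids)) if isinstance(table, FeatureTable) else (
        np.asarray(table, dtype=float), None,
    )
    if X.shape[1] != forest.p:
        raise ValueError(f"table has {X.shape[1]} features, forest expects {forest.p}")
    if names is not None and names != list(forest.feature_names):
        raise ValueError("feature ids do not match the forest's training features")
    return np.ascontiguousarray(X)


def _accumulate(forest: Forest, X: np.ndarray, payload: np.ndarray, oob_only: bool):
    nq = X.shape[0]
    out = np.zeros((nq, forest.k))
    used = np.zeros(nq, np.int64)
    inbag = forest.inbag
    if oob_only and nq != forest.n_samples:
        raise ValueError("oob_only prediction requires the training table")
    _accumulate_leaf(
        X, forest.node_feature, forest.node_threshold, forest.node_left,
        forest.node_right, forest.tree_offsets, payload, inbag,
        1 if oob_only else 0, out, used,
    )
    return out, used


def predict(forest: Forest, table) -> np.ndarray:
    """Plurality vote over trees; ties broken by lowest class index."""
    X = _query_matrix(forest, table)
    votes, _ = _accumulate(forest, X, forest._leaf_majority_onehot(), oob_only=False)
    return forest.classes_[np.argmax(votes, axis=1)]


def predict_proba(forest: Forest, table, oob_only: bool = False) -> np.ndarray:
    """Mean leaf class-proportion vector over (OOB) trees; rows sum to 1.

    Rows of samples that are in-bag in every tree (only possible with
    ``oob_only=True``) are returned as NaN with a warning.
    """
    if forest.config.mode != "probability":
        raise ValueError("forest was not grown in probability mode")
    X = _query_matrix(forest, table)
    out, used = _accumulate(forest, X, forest._leaf_proportions(), oob_only)
    never = used == 0
    if never.any():
        warnings.warn(f"{int(never.sum())} sample(s) in-bag in every tree; rows set to NaN")
    with np.errstate(invalid="ignore"):
        out = out / np.where(used > 0, used, 1)[:, None]
    out[never] = np.nan
    return out


def oob_votes(forest: Forest, table) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample OOB vote counts and the number of OOB trees per sample."""
    X = _query_matrix(forest, table)
    return _accumulate(forest, X, forest._leaf_majority_onehot(), oob_only=True)


def oob_confusion(forest: Forest, table, labels):
    """OOB confusion matrix: rows = true class, columns = predicted class.

    Samples that are never OOB are excluded with a warning.  Returns a
    :class:`rfrelate.evaluation.ConfusionMatrix`.
    """
    from .evaluation import ConfusionMatrix

    classes, ycls = _encode_labels(labels)
    if not np.array_equal(classes, forest.classes_):
        raise ValueError("labels do not match the forest's classes")
    votes, used = oob_votes(forest, table)
    keep = used > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} sample(s) never OOB; excluded from confusion matrix")
    pred = np.argmax(votes[keep], axis=1)
    true = ycls[keep]
    k = forest.k
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(pd.DataFrame(counts, index=forest.classes_, columns=forest.classes_))


# ----------------------------------------------------------------------
# importance
# ----------------------------------------------------------------------


def air_importance(table, labels, config: ForestConfig) -> pd.Series:
    """Actual-impurity-reduction importance (bias-corrected Gini importance).

    Scores may be negative; uninformative features score ~0 on average.
    Surrogate recording is disabled for these forests (the permuted-copy
    competition corrupts routing, which is irrelevant for importance).
    """
    cfg = ForestConfig(**{**asdict(config), "n_surrogates": 0})
    scores = fit_forest(table, labels, cfg, _air_only=True)
    names = list(table.feature_ids) if isinstance(table, FeatureTable) else range(len(scores))
    return pd.Series(scores, index=names, name="air_importance")


def permutation_importance(table, labels, config: ForestConfig, seed: int = 0) -> pd.Series:
    """OOB permutation importance: accuracy drop when one feature is shuffled."""
    cfg = ForestConfig(**{**asdict(config), "n_surrogates": 0, "mode": "classification"})
    forest = fit_forest(table, labels, cfg)
    X = _query_matrix(forest, table)
    classes, ycls = _encode_labels(labels)
    votes, used = _accumulate(forest, X, forest._leaf_majority_onehot(), oob_only=True)
    keep = used > 0
    base = np.mean(np.argmax(votes[keep], axis=1) == ycls[keep])
    rng = np.random.default_rng(seed)
    scores = np.zeros(forest.p)
    for f in range(forest.p):
        Xp = X.copy()
        Xp[:, f] = rng.permutation(Xp[:, f])
        votes_p, used_p = _accumulate(forest, Xp, forest._leaf_majority_onehot(), oob_only=True)
        kp = used_p > 0
        acc = np.mean(np.argmax(votes_p[kp], axis=1) == ycls[kp])
        scores[f] = base - acc
    names = list(table.feature_ids) if isinstance(table, FeatureTable) else range(forest.p)
    return pd.Series(scores, index=names, name="permutation_importance")
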