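"""All-relevant feature selection: Boruta with shadow variables and
Surrogate Minimal Depth (SMD).

Boruta treats features individually: each run appends one permuted
"shadow" copy per undecided feature, fits an importance forest, and
scores a *hit* for every feature whose importance exceeds the run's
maximum shadow importance; an exact two-sided binomial test on the hit
count (success probability 0.5) confirms or rejects features.

SMD treats features as collaborating groups: a single forest with
surrogate splits is grown, and a feature's value is its minimal depth
over all nodes where it appears as primary splitter *or* surrogate
(lower = more important).  Correlated companions of a strong feature are
credited even when they are never chosen as primary splitter.  The
selection threshold is estimated from permuted null copies appended to
the table before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from ._kernels import _smd_accumulate
from .forest import Forest, ForestConfig, air_importance, fit_forest, permutation_importance
from .table import FeatureTable

__all__ = [
    "BorutaConfig",
    "SMDConfig",
    "SelectionResult",
    "boruta_decision",
    "boruta_select",
    "surrogate_min_depth",
    "smd_select",
]


@dataclass
class SelectionResult:
    """Outcome of one selection method on one label scheme."""

    method: str
    scores: pd.Series  # per-feature score (importance mean or SMD value)
    threshold: float
    decisions: pd.Series  # {"confirmed", "rejected", "tentative"} per feature
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.decisions.unique()) - {"confirmed", "rejected", "tentative"}
        if bad:
            raise ValueError(f"invalid decisions {bad}")
        if not self.scores.index.equals(self.decisions.index):
            raise ValueError("scores and decisions must cover the same features")

    @property
    def selected(self) -> list:
        return list(self.decisions.index[self.decisions == "confirmed"])

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"score": self.scores, "decision": self.decisions}).rename_axis(
            "feature_id"
        ).to_csv(path)


@dataclass
class BorutaConfig:
    """Boruta parameters; ``p_value`` is the per-feature confidence level."""

    p_value: float = 0.01
    max_runs: int = 100
    importance_kind: str = "air"  # or "permutation"
    forest: ForestConfig = field(default_factory=lambda: ForestConfig(ntree=10_000))
    min_shadows: int = 5
    bonferroni: bool = False

    def validate(self) -> None:
        if not 0.0 < self.p_value < 1.0:
            raise ValueError("p_value must be in (0, 1)")
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")
        if self.importance_kind not in ("air", "permutation"):
            raise ValueError(f"unknown importance kind {self.importance_kind!r}")


@dataclass
class SMDConfig:
    """SMD parameters.

    ``s`` (surrogates stored per node) defaults to floor(0.05 * p) of the
    *augmented* table; ``null_copies`` permuted copies estimate the null
    SMD distribution, and the threshold is their mean (``null_mean``) or
    a quantile (``null_quantile``, level ``q``).
    """

    s: Optional[int] = None
    null_copies: Optional[int] = None  # default min(p, 100)
    threshold_rule: str = "null_mean"  # or "null_quantile"
    q: float = 0.05
    forest: ForestConfig = field(default_factory=lambda: ForestConfig(ntree=10_000))

    def validate(self) -> None:
        if self.s is not None and self.s < 1:
            raise ValueError("s must be >= 1 for SMD")
        if self.threshold_rule not in ("null_mean", "null_quantile"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")


# ----------------------------------------------------------------------
# Boruta
# ----------------------------------------------------------------------


def boruta_decision(hits: int, runs: int, alpha: float) -> str:
    """Exact two-sided binomial decision on a feature's hit count.

    Success probability 0.5 under the null; a significant upper tail
    confirms, a significant lower tail rejects, otherwise tentative.
    """
    if runs < 1:
        return "tentative"
    test = binomtest(int(hits), int(runs), 0.5)
    if test.pvalue < alpha:
        return "confirmed" if 2 * hits > runs else "rejected"
    return "tentative"


def _importance(X: np.ndarray, y, cfg: BorutaConfig, seed: int) -> np.ndarray:
    fc = ForestConfig(**{**asdict(cfg.forest), "seed": seed})
    if cfg.importance_kind == "air":
        return air_importance(X, y, fc).to_numpy()
    return permutation_importance(X, y, fc, seed=seed).to_numpy()


def boruta_select(table, labels, config: BorutaConfig) -> SelectionResult:
    """Boruta all-relevant selection with re-permuted shadows per run.

    Each run fits one importance forest on all real features plus one
    freshly permuted shadow per undecided feature (at least
    ``min_shadows`` shadows).  Undecided features are tested after every
    run with an exact two-sided binomial test on their hit counts; the
    loop ends when nothing is undecided or ``max_runs`` is reached, and
    survivors are labelled tentative.
    """
    config.validate()
    if isinstance(table, FeatureTable):
        X = table.values()
        names = pd.Index(table.feature_ids)
    else:
        X = np.asarray(table, dtype=float)
        names = pd.Index(range(X.shape[1]))
    y = np.asarray(pd.Series(labels).to_numpy())
    n, p = X.shape
    rng = np.random.default_rng((config.forest.seed * 7919 + 13) % 2**31)

    undecided = np.ones(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    runs_of = np.zeros(p, dtype=int)  # runs each feature was undecided in
    decisions = np.array(["tentative"] * p, dtype=object)
    imp_history = np.zeros(p)
    alpha = config.p_value / p if config.bonferroni else config.p_value

    run = 0
    while undecided.any() and run < config.max_runs:
        und_idx = np.flatnonzero(undecided)
        shadow_src = und_idx
        if shadow_src.size < config.min_shadows:
            extra = rng.choice(und_idx, size=config.min_shadows - shadow_src.size, replace=True)
            shadow_src = np.concatenate([shadow_src, extra])
        shadows = np.column_stack([rng.permutation(X[:, j]) for j in shadow_src])
        X_aug = np.hstack([X, shadows])
        imp = _importance(X_aug, y, config, seed=(config.forest.seed * 1_000_003 + run) % 2**31)
        real_imp, shadow_imp = imp[:p], imp[p:]
        imp_history += real_imp
        max_shadow = shadow_imp.max()
        hits[undecided] += (real_imp[undecided] > max_shadow).astype(int)
        runs_of[undecided] += 1
        run += 1

        for j in np.flatnonzero(undecided):
            verdict = boruta_decision(hits[j], runs_of[j], alpha)
            if verdict != "tentative":
                decisions[j] = verdict
                undecided[j] = False

    if run < 5 and undecided.all():
        warnings.warn("fewer than 5 Boruta runs completed with everything undecided")

    scores = pd.Series(imp_history / max(run, 1), index=names, name="mean_importance")
    return SelectionResult(
        method="boruta",
        scores=scores,
        threshold=float("nan"),
        decisions=pd.Series(decisions, index=names, name="decision"),
        details={
            "runs": run,
            "p_value": config.p_value,
            "hits": pd.Series(hits, index=names).to_dict(),
            "runs_per_feature": pd.Series(runs_of, index=names).to_dict(),
        },
    )


# ----------------------------------------------------------------------
# Surrogate Minimal Depth
# ----------------------------------------------------------------------


def surrogate_min_depth(forest: Forest) -> pd.Series:
    """Per-feature surrogate minimal depth, averaged over trees.

    In each tree a feature's depth is the minimal depth of the nodes
    where it is the primary splitter or appears in the surrogate list;
    features absent from a tree get that tree's maximal node depth.
    Lower values mean more important.
    """
    if forest.sur_feat is None:
        raise ValueError(
            "forest was grown without surrogates (s=0); SMD needs s >= 1 "
            "(plain minimal depth would ignore feature relations)"
        )
    sums = np.zeros(forest.p)
    _smd_accumulate(
        forest.node_feature,
        forest.node_depth,
        forest.sur_feat,
        forest.sur_count,
        forest.tree_offsets,
        forest.p,
        sums,
    )
    return pd.Series(sums / forest.ntree, index=forest.feature_names, name="smd")


def smd_select(table, labels, config: SMDConfig) -> tuple[SelectionResult, Forest]:
    """SMD selection against permuted null copies.

    The table is augmented with ``null_copies`` permuted feature copies,
    one surrogate forest is fitted on the augmented table, SMD is
    computed for every column, and real features with SMD strictly below
    the null threshold are confirmed.  Returns the result and the fitted
    forest (whose surrogate records also drive the relation analysis).
    """
    config.validate()
    if isinstance(table, FeatureTable):
        X = table.values()
        names = pd.Index(table.feature_ids)
    else:
        X = np.asarray(table, dtype=float)
        names = pd.Index(range(X.shape[1]))
    y = np.asarray(pd.Series(labels).to_numpy())
    n, p = X.shape
    n_null = config.null_copies if config.null_copies is not None else min(p, 100)
    rng = np.random.default_rng((config.forest.seed * 524287 + 101) % 2**31)
    src = rng.choice(p, size=n_null, replace=n_null > p)
    nulls = np.column_stack([rng.permutation(X[:, j]) for j in src])
    X_aug = np.hstack([X, nulls])
    p_aug = X_aug.shape[1]

    s = config.s if config.s is not None else max(1, int(0.05 * p_aug))
    fc = ForestConfig(**{**asdict(config.forest), "n_surrogates": s})
    forest = fit_forest(X_aug, y, fc)
    forest.feature_names = list(names) + [f"__null_{i}" for i in range(n_null)]
    smd = surrogate_min_depth(forest)
    real_smd = smd.iloc[:p]
    null_smd = smd.iloc[p:]
    if np.allclose(null_smd.to_numpy(), null_smd.iloc[0]):
        raise ValueError("null-copy SMD distribution is degenerate (all equal)")
    if config.threshold_rule == "null_mean":
        threshold = float(null_smd.mean())
    else:
        threshold = float(null_smd.quantile(config.q))

    decisions = pd.Series(
        np.where(real_smd.to_numpy() < threshold, "confirmed", "rejected"),
        index=names,
        name="decision",
    )
    result = SelectionResult(
        method="smd",
        scores=real_smd.set_axis(names).rename("smd"),
        threshold=threshold,
        decisions=decisions,
        details={
            "s": s,
            "null_copies": n_null,
            "threshold_rule": config.threshold_rule,
            "null_smd_mean": float(null_smd.mean()),
            "null_smd_min": float(null_smd.min()),
            "null_smd_max": float(null_smd.max()),
        },
    )
    return result, forest
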