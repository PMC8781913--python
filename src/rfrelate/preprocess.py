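"""Feature-table preprocessing: adduct consolidation, prevalence
filtering, iterative random-forest imputation and batch-wise autoscaling.

The stage order is fixed -- adducts -> prevalence -> imputation ->
autoscaling -- and imputation runs on the raw (unscaled) intensities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .table import FeatureTable

__all__ = [
    "PreprocessReport",
    "consolidate_adducts",
    "prevalence_filter",
    "impute_rf",
    "autoscale_by_batch",
    "run_preprocess",
]


@dataclass
class PreprocessReport:
    """Counts and scaling statistics accumulated across the stages."""

    n_features_in: int = 0
    n_features_after_adducts: int = 0
    n_features_after_prevalence: int = 0
    imputation_iterations: int = 0
    batch_stats: dict = field(default_factory=dict)  # batch -> {"mean": {...}, "sd": {...}}

    def validate(self) -> None:
        if not (
            self.n_features_in
            >= self.n_features_after_adducts
            >= self.n_features_after_prevalence
        ):
            raise ValueError("feature counts must be non-increasing across stages")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _is_ammonium(label) -> bool:
    return isinstance(label, str) and "NH4" in label.upper()


def consolidate_adducts(table: FeatureTable) -> FeatureTable:
    """Keep, per adduct group, only the feature with the highest mean intensity.

    Groups are given by the ``adduct_group_id`` feature-metadata column;
    features without a group id pass through unchanged, as does the whole
    table when the column is absent.  Ammonium-adduct features (adduct
    label containing "NH4") are never merged into their group: they are
    always retained separately.  "Highest intensity" is the highest mean
    over samples, missing cells ignored.
    """
    fmeta = table.feature_meta
    if "adduct_group_id" not in fmeta.columns or fmeta["adduct_group_id"].isna().all():
        return table
    means = table.intensities.mean(axis=0, skipna=True)
    keep = []
    grouped = fmeta["adduct_group_id"]
    for fid in table.feature_ids:
        gid = grouped.loc[fid]
        if pd.isna(gid) or _is_ammonium(fmeta.loc[fid].get("adduct_label")):
            keep.append(fid)
    annotated = fmeta.index[grouped.notna()]
    for gid, members in annotated.groupby(grouped.loc[annotated]).items():
        candidates = [
            f for f in members if not _is_ammonium(fmeta.loc[f].get("adduct_label"))
        ]
        if not candidates:
            continue
        group_means = means[candidates]
        if group_means.isna().all():
            warnings.warn(f"adduct group {gid!r} has all-missing features; keeping {candidates[0]!r}")
            keep.append(candidates[0])
        else:
            keep.append(group_means.idxmax())
    kept = [f for f in table.feature_ids if f in set(keep)]
    return table.select_features(kept)


def prevalence_filter(table: FeatureTable, min_fraction: float = 0.8) -> FeatureTable:
    """Keep features observed in at least ``min_fraction`` of the samples.

    The boundary is inclusive: a feature present in exactly the minimum
    fraction is kept.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = table.intensities.notna().mean(axis=0)
    kept = frac.index[frac >= min_fraction]
    if len(kept) == 0:
        warnings.warn("prevalence filter removed every feature")
    return table.select_features(kept)


def impute_rf(
    table: FeatureTable,
    seed: int,
    max_iter: int = 10,
    n_trees: int = 100,
) -> tuple[FeatureTable, PreprocessReport]:
    """Iterative random-forest imputation of missing cells.

    Missing cells are initialized with column means; then, looping over
    features in increasing-missingness order, each feature with missing
    values is regressed on all other (currently imputed) features with a
    regression forest (``n_trees`` trees, mtry = floor(sqrt(p))) fitted on
    its observed rows, and its missing cells are overwritten with the
    forest's predictions.  Sweeps repeat until the sum of squared changes
    of the imputed values increases for the first time (the previous
    iterate is returned) or ``max_iter`` sweeps are reached.  Observed
    cells are never altered.
    """
    report = PreprocessReport(
        n_features_in=table.n_features,
        n_features_after_adducts=table.n_features,
        n_features_after_prevalence=table.n_features,
    )
    intens = table.intensities
    missing = intens.isna()
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = list(intens.columns[all_missing])
        raise ValueError(f"cannot impute all-missing feature(s): {bad}")
    if not missing.any().any():
        return table, report

    order = missing.sum(axis=0).sort_values(kind="stable").index  # fewest missing first
    X = intens.to_numpy(dtype=float).copy()
    mask = missing.to_numpy()
    col_of = {f: i for i, f in enumerate(intens.columns)}
    col_means = np.nanmean(intens.to_numpy(dtype=float), axis=0)
    for j in range(X.shape[1]):
        X[mask[:, j], j] = col_means[j]

    prev_delta = np.inf
    prev_X = X.copy()
    iterations = 0
    for sweep in range(max_iter):
        before = X.copy()
        for rank, fid in enumerate(order):
            j = col_of[fid]
            miss_rows = mask[:, j]
            if not miss_rows.any():
                continue
            others = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=(seed + 1009 * sweep + rank) % (2**31 - 1),
                n_jobs=1,
            )
            rf.fit(X[~miss_rows][:, others], X[~miss_rows, j])
            X[miss_rows, j] = rf.predict(X[miss_rows][:, others])
        iterations = sweep + 1
        delta = float(((X - before)[mask] ** 2).sum())
        if delta >= prev_delta:
            X = prev_X  # stopping rule: first increase -> previous iterate
            iterations -= 1
            break
        prev_delta = delta
        prev_X = X.copy()

    report.imputation_iterations = iterations
    vals = intens.to_numpy(dtype=float).copy()
    vals[mask] = X[mask]  # observed cells untouched
    out = pd.DataFrame(vals, index=intens.index, columns=intens.columns)
    return FeatureTable(out, table.sample_meta.copy(), table.feature_meta.copy()), report


def autoscale_by_batch(table: FeatureTable, report: PreprocessReport | None = None) -> FeatureTable:
    """Standardize each feature to mean 0, sd 1 (ddof=1) within each batch.

    Columns constant within a batch become all-zero there; batches with a
    single sample are centered but not scaled (with a warning).  Requires
    a complete table and a ``batch`` sample-metadata column.
    """
    if table.has_missing():
        raise ValueError("autoscaling requires a complete table; impute first")
    if "batch" not in table.sample_meta.columns:
        raise ValueError("sample metadata lacks a 'batch' column")
    scaled = table.intensities.astype(float).copy()
    stats = {}
    for batch, idx in table.sample_meta.groupby("batch").groups.items():
        block = scaled.loc[idx]
        means = block.mean(axis=0)
        if len(idx) < 2:
            warnings.warn(f"batch {batch!r} has a single sample; centered only, not scaled")
            scaled.loc[idx] = (block - means).to_numpy()
            stats[str(batch)] = {"mean": means.round(9).to_dict(), "sd": None}
            continue
        sds = block.std(axis=0, ddof=1)
        safe = sds.replace(0.0, 1.0)
        scaled.loc[idx] = ((block - means) / safe).to_numpy()
        stats[str(batch)] = {
            "mean": means.round(9).to_dict(),
            "sd": sds.round(9).to_dict(),
        }
    if report is not None:
        report.batch_stats = stats
    return FeatureTable(scaled, table.sample_meta.copy(), table.feature_meta.copy())


def run_preprocess(
    table: FeatureTable,
    min_fraction: float = 0.8,
    seed: int = 0,
    max_iter: int = 10,
    impute_trees: int = 100,
) -> tuple[FeatureTable, PreprocessReport]:
    """Full preprocessing chain in the fixed order."""
    n_in = table.n_features
    table = consolidate_adducts(table)
    n_add = table.n_features
    table = prevalence_filter(table, min_fraction)
    n_prev = table.n_features
    table, report = impute_rf(table, seed=seed, max_iter=max_iter, n_trees=impute_trees)
    report.n_features_in = n_in
    report.n_features_after_adducts = n_add
    report.n_features_after_prevalence = n_prev
    table = autoscale_by_batch(table, report)
    report.validate()
    return table, report
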