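"""Full study pipeline from a single config.

Stages per label scheme, in fixed order: preprocessing (once, on the full
table) -> classification forest with OOB confusion metrics -> probability
forest with per-class probability summaries -> Boruta and SMD feature
selection -> relation analysis (mean adjusted agreement, clustering,
Pearson comparison, same-metabolite merge groups) -> selection-overlap
counts.  Every stochastic stage draws its seed deterministically from the
single global seed, so reruns with the same config reproduce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .evaluation import confusion_metrics, probability_summary, selection_overlap
from .forest import ForestConfig, fit_forest, oob_confusion, predict_proba
from .preprocess import run_preprocess
from .relations import cluster_relations, mean_adjusted_agreement, merge_features, pearson_relation
from .selection import BorutaConfig, SMDConfig, boruta_select, smd_select
from .synthetic import InformativeGroup, SyntheticSpec, generate_dataset
from .table import FeatureTable, read_feature_table, write_feature_table

log = logging.getLogger("rfrelate")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``from_yaml`` for the file layout."""

    output_dir: str
    seed: int = 0
    input_dir: Optional[str] = None  # directory with table CSVs ...
    input_prefix: str = "table"
    synthetic: Optional[dict] = None  # ... or a synthetic-spec mapping
    label_schemes: list = field(default_factory=lambda: ["origin"])
    preprocess: dict = field(default_factory=dict)  # min_fraction, impute_trees, max_iter
    forest: dict = field(default_factory=dict)  # ntree, mtry, min_node_size ...
    boruta: dict = field(default_factory=dict)  # p_value, max_runs, ntree
    smd: dict = field(default_factory=dict)  # s, null_copies, threshold_rule, ntree
    relations: dict = field(default_factory=dict)  # n_clusters, merge_threshold
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.label_schemes:
            raise ValueError("at least one label scheme required")
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir / synthetic must be given")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(global_seed: int, scheme: str, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    tag = zlib.crc32(f"{scheme}/{stage}".encode())
    return (global_seed * 2_654_435_761 + tag) % (2**31 - 1)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _spec_from_mapping(mapping: dict, seed: int) -> SyntheticSpec:
    m = dict(mapping)
    groups = tuple(
        InformativeGroup(tuple(g["metabolites"]), g["scheme"], tuple(g["classes"]), float(g["delta"]))
        for g in m.pop("informative_groups", [])
    )
    m.setdefault("seed", seed)
    return SyntheticSpec(informative_groups=groups, **m)


def _forest_config(overrides: dict, seed: int, **fixed) -> ForestConfig:
    kw = {"ntree": 10_000, **overrides, **fixed, "seed": seed}
    return ForestConfig(**kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage failure aborts with an error naming the stage; outputs of
    completed stages are retained next to a ``FAILED`` marker.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    from . import __version__ as version

    manifest = {
        "version": version,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
    }
    artifacts: list[str] = []
    current_stage = "load"

    def emit(name: str) -> str:
        path = os.path.join(out, name)
        artifacts.append(path)
        return path

    try:
        # ------------------------------------------------ input
        if config.synthetic is not None:
            spec = _spec_from_mapping(config.synthetic, stage_seed(config.seed, "*", "simulate"))
            table, truth = generate_dataset(spec)
            truth.to_json(emit("ground_truth.json"))
            write_feature_table(table, out, prefix="raw")
            for suffix in ("intensities", "samples", "features"):
                artifacts.append(os.path.join(out, f"raw_{suffix}.csv"))
            log.info("simulated table: %d samples x %d features", *table.intensities.shape)
        else:
            table = read_feature_table(config.input_dir, config.input_prefix)

        # ------------------------------------------------ preprocessing (once, full table)
        current_stage = "preprocess"
        pp_kw = dict(config.preprocess)
        table_pp, report = run_preprocess(
            table,
            min_fraction=pp_kw.get("min_fraction", 0.8),
            seed=stage_seed(config.seed, "*", "impute"),
            max_iter=pp_kw.get("max_iter", 10),
            impute_trees=pp_kw.get("impute_trees", 100),
        )
        report.to_json(emit("preprocess_report.json"))
        write_feature_table(table_pp, out, prefix="preprocessed")
        for suffix in ("intensities", "samples", "features"):
            artifacts.append(os.path.join(out, f"preprocessed_{suffix}.csv"))
        manifest["stages"]["preprocess"] = {
            "n_features": table_pp.n_features,
            "imputation_iterations": report.imputation_iterations,
        }

        for scheme in config.label_schemes:
            labels_full = table_pp.labels(scheme)
            sub = table_pp.select_samples(labels_full.dropna().index)
            y = sub.labels(scheme).to_numpy()
            sstage: dict = {"n_samples": sub.n_samples}
            manifest["stages"][scheme] = sstage

            # -------------------------------------------- classification
            current_stage = f"{scheme}/classify"
            cfg = _forest_config(
                config.forest, stage_seed(config.seed, scheme, "classify"),
                mode="classification", n_surrogates=0,
            )
            forest_c = fit_forest(sub, y, cfg)
            cm = oob_confusion(forest_c, sub, y)
            cm.to_csv(emit(f"{scheme}_confusion.csv"))
            metrics = confusion_metrics(cm)
            sstage["oob_error_pct"] = metrics["error"]
            with open(emit(f"{scheme}_metrics.json"), "w") as fh:
                json.dump(
                    {
                        "accuracy_pct": metrics["accuracy"],
                        "oob_error_pct": metrics["error"],
                        "sensitivity_pct": metrics["sensitivity"].round(1).to_dict(),
                        "specificity_as_printed_pct": metrics["specificity_as_printed"].round(1).to_dict(),
                    },
                    fh, indent=1,
                )
            log.info("%s: OOB error %.1f%%", scheme, metrics["error"])

            # -------------------------------------------- probabilities
            current_stage = f"{scheme}/probabilities"
            cfg_p = _forest_config(
                config.forest, stage_seed(config.seed, scheme, "probability"),
                mode="probability", n_surrogates=0,
            )
            forest_p = fit_forest(sub, y, cfg_p)
            proba = predict_proba(forest_p, sub, oob_only=True)
            pdf = pd.DataFrame(proba, index=sub.sample_ids, columns=forest_p.classes_)
            pdf.insert(0, "true_class", y)
            pdf.to_csv(emit(f"{scheme}_oob_probabilities.csv"))
            probability_summary(proba, y, classes=forest_p.classes_).to_csv(
                emit(f"{scheme}_probability_summary.csv")
            )

            # -------------------------------------------- selection
            current_stage = f"{scheme}/select_boruta"
            bkw = dict(config.boruta)
            bcfg = BorutaConfig(
                p_value=bkw.get("p_value", 0.01),
                max_runs=bkw.get("max_runs", 100),
                importance_kind=bkw.get("importance_kind", "air"),
                forest=_forest_config(
                    {**config.forest, **({"ntree": bkw["ntree"]} if "ntree" in bkw else {})},
                    stage_seed(config.seed, scheme, "boruta"),
                ),
            )
            res_b = boruta_select(sub, y, bcfg)
            res_b.to_csv(emit(f"{scheme}_boruta.csv"))
            sstage["boruta_selected"] = len(res_b.selected)

            current_stage = f"{scheme}/select_smd"
            skw = dict(config.smd)
            scfg = SMDConfig(
                s=skw.get("s"),
                null_copies=skw.get("null_copies"),
                threshold_rule=skw.get("threshold_rule", "null_mean"),
                q=skw.get("q", 0.05),
                forest=_forest_config(
                    {**config.forest, **({"ntree": skw["ntree"]} if "ntree" in skw else {})},
                    stage_seed(config.seed, scheme, "smd"),
                ),
            )
            res_s, forest_s = smd_select(sub, y, scfg)
            res_s.to_csv(emit(f"{scheme}_smd.csv"))
            sstage["smd_selected"] = len(res_s.selected)
            with open(emit(f"{scheme}_selection_summary.json"), "w") as fh:
                json.dump(
                    {
                        "boruta": {"selected": len(res_b.selected), **{k: v for k, v in res_b.details.items() if k in ("runs", "p_value")}},
                        "smd": {"selected": len(res_s.selected), "threshold": res_s.threshold, **{k: res_s.details[k] for k in ("s", "null_copies", "threshold_rule")}},
                    },
                    fh, indent=1,
                )

            # -------------------------------------------- relations
            current_stage = f"{scheme}/relations"
            rkw = dict(config.relations)
            selected = res_s.selected
            if len(selected) >= 2:
                rel = mean_adjusted_agreement(forest_s, feature_subset=selected)
                rel.to_csv(emit(f"{scheme}_relations_smd.csv"))
                n_clusters = min(rkw.get("n_clusters", 6), len(selected))
                cl = cluster_relations(rel, n_clusters)
                pd.DataFrame(
                    {"cluster": cl.labels, "leaf_rank": pd.Series(range(len(cl.leaf_order)), index=cl.leaf_order)}
                ).rename_axis("feature_id").to_csv(emit(f"{scheme}_relation_clusters.csv"))
                pearson_relation(sub, feature_subset=selected).to_csv(
                    emit(f"{scheme}_pearson.csv")
                )
                mg = merge_features(rel, threshold=rkw.get("merge_threshold", 0.9))
                with open(emit(f"{scheme}_merge_groups.json"), "w") as fh:
                    json.dump(
                        {"threshold": mg.threshold, "groups": [sorted(g) for g in mg.groups]},
                        fh, indent=1,
                    )
                sstage["merge_groups"] = len(mg.groups)
            else:
                log.warning("%s: fewer than 2 SMD-selected features; relations skipped", scheme)
                sstage["merge_groups"] = 0

            # -------------------------------------------- overlap
            current_stage = f"{scheme}/overlap"
            overlap = selection_overlap(
                [res_s.selected, res_b.selected], names=["smd", "boruta"]
            )
            with open(emit(f"{scheme}_selection_overlap.json"), "w") as fh:
                json.dump({"|".join(k): v for k, v in overlap.items()}, fh, indent=1)

        current_stage = "manifest"
        manifest["artifacts"] = {
            os.path.relpath(p, out): _sha256(p) for p in sorted(artifacts)
        }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as fh:
            fh.write(f"stage: {current_stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc
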