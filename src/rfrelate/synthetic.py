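"""Synthetic LC-MS-like feature tables with known ground truth.

The generator emulates the structure of an untargeted LC-MS feature table
after peak picking: each metabolite contributes a small block of 1-3
highly correlated features (adducts/fragments of one compound), classes
differ through mean shifts of designated "informative" metabolite groups,
samples fall into measurement batches with additive per-feature offsets,
and low-intensity cells go missing more often than high-intensity ones.

Model: one latent intensity per metabolite per sample,

    L[i, m] ~ Normal(mu[class(i), m], noise_sd^2),

and each adduct feature of metabolite m is

    x[i, f] = baseline_f + L[i, m] + eps,   eps ~ Normal(0, tau^2),

with tau chosen so that any two features of one metabolite have
correlation ``within_metabolite_corr``.  Informative groups shift
``mu`` by ``delta * noise_sd`` in their affected classes.  Missingness is
Bernoulli per cell with a logit linear in the standardized intensity.
m/z and retention-time metadata are arbitrary placeholders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .table import FeatureTable

__all__ = [
    "InformativeGroup",
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "default_spec",
    "adduct_benchmark_spec",
]

_ADDUCT_LABELS = ["[M+Na]+", "[M+NH4]+", "fragment"]


@dataclass(frozen=True)
class InformativeGroup:
    """A set of metabolites sharing a class-discriminative effect.

    ``delta`` is the mean shift in units of ``noise_sd`` applied to the
    latent intensity of every member metabolite in every listed class of
    the given label scheme.
    """

    metabolites: Tuple[int, ...]
    scheme: str
    classes: Tuple[str, ...]
    delta: float


@dataclass
class SyntheticSpec:
    """Study design of one synthetic dataset.

    ``class_schemes`` maps scheme name -> {class label -> class size}; the
    first scheme is primary and must cover every sample, further schemes
    may label a subset (remaining samples get no label for that scheme).
    ``adduct_multiplicity`` is the number of features per metabolite
    (a single int for all, or one int in {1,2,3} per metabolite).
    """

    n_samples: int
    class_schemes: Dict[str, Dict[str, int]]
    n_batches: int = 3
    n_metabolites: int = 240
    adduct_multiplicity: int | Sequence[int] = 3
    within_metabolite_corr: float = 0.95
    informative_groups: Tuple[InformativeGroup, ...] = ()
    noise_sd: float = 1.0
    batch_sd: float = 1.0
    missing_base_rate: float = 0.0
    missing_intensity_slope: float = 0.0
    annotate_adduct_groups: bool = False
    seed: int = 0

    def multiplicities(self) -> np.ndarray:
        if isinstance(self.adduct_multiplicity, (int, np.integer)):
            mult = np.full(self.n_metabolites, int(self.adduct_multiplicity))
        else:
            mult = np.asarray(list(self.adduct_multiplicity), dtype=int)
        return mult

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_metabolites < 1 or self.n_batches < 1:
            raise ValueError("counts must be positive")
        if not self.class_schemes:
            raise ValueError("at least one class scheme required")
        schemes = list(self.class_schemes)
        primary = self.class_schemes[schemes[0]]
        if sum(primary.values()) != self.n_samples:
            raise ValueError(
                f"primary scheme sizes sum to {sum(primary.values())}, expected {self.n_samples}"
            )
        for name in schemes[1:]:
            if sum(self.class_schemes[name].values()) > self.n_samples:
                raise ValueError(f"scheme {name!r} sizes exceed n_samples")
        mult = self.multiplicities()
        if mult.shape[0] != self.n_metabolites or not np.isin(mult, [1, 2, 3]).all():
            raise ValueError("adduct multiplicity must be 1, 2 or 3 per metabolite")
        if not 0.0 < self.within_metabolite_corr <= 1.0:
            raise ValueError("within_metabolite_corr must be in (0, 1]")
        for g in self.informative_groups:
            if g.delta < 0:
                raise ValueError("effect size delta must be >= 0")
            if g.scheme not in self.class_schemes:
                raise ValueError(f"informative group references unknown scheme {g.scheme!r}")
            unknown = set(g.classes) - set(self.class_schemes[g.scheme])
            if unknown:
                raise ValueError(f"informative group references unknown classes {unknown}")
            if any(m < 0 or m >= self.n_metabolites for m in g.metabolites):
                raise ValueError("informative group references unknown metabolite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_base_rate < 1.0:
            raise ValueError("missing_base_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream stages."""

    informative_feature_ids: set
    metabolite_of_feature: Dict[str, int]
    true_class_means: Dict[Tuple[str, str, int], float]
    informative_metabolites: set = field(default_factory=set)

    def to_json(self, path: str) -> None:
        payload = {
            "informative_feature_ids": sorted(self.informative_feature_ids),
            "metabolite_of_feature": self.metabolite_of_feature,
            "informative_metabolites": sorted(self.informative_metabolites),
            "true_class_means": [
                {"scheme": s, "class": c, "metabolite": m, "shift": v}
                for (s, c, m), v in sorted(self.true_class_means.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def features_of_metabolite(self, metabolite: int) -> list:
        return [f for f, m in self.metabolite_of_feature.items() if m == metabolite]


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Default design mirroring the asparagus study scale.

    317 samples in 3 batches; a 5-class provenance scheme with imbalanced
    sizes 213/25/31/13/35 and a 4-class variety scheme labelling a
    150-sample subset; 240 metabolites x 3 adduct features = 720 features.
    Six provenance-informative metabolite groups and four
    variety-informative groups, all at delta = 3 noise sds.
    """
    origin = {"Germany": 213, "Greece": 25, "Netherlands": 31, "Peru": 13, "Poland": 35}
    variety = {"Backlim": 56, "Cumulus": 23, "Gijnlim": 42, "Grolim": 29}
    origin_classes = list(origin)
    groups = []
    # six 3-metabolite groups discriminating different origin subsets
    for gi in range(6):
        mets = tuple(range(3 * gi, 3 * gi + 3))
        affected = tuple(origin_classes[j] for j in range((gi % 4) + 1)) if gi % 2 == 0 else tuple(
            origin_classes[-(j + 1)] for j in range((gi % 3) + 1)
        )
        groups.append(InformativeGroup(mets, "origin", affected, 3.0))
    variety_classes = list(variety)
    for gi in range(4):
        mets = tuple(range(18 + 2 * gi, 18 + 2 * gi + 2))
        affected = (variety_classes[gi],)
        groups.append(InformativeGroup(mets, "variety", affected, 3.0))
    return SyntheticSpec(
        n_samples=317,
        class_schemes={"origin": origin, "variety": variety},
        n_batches=3,
        n_metabolites=240,
        adduct_multiplicity=3,
        within_metabolite_corr=0.95,
        informative_groups=tuple(groups),
        noise_sd=1.0,
        batch_sd=1.0,
        missing_base_rate=0.05,
        missing_intensity_slope=1.0,
        seed=seed,
    )


def adduct_benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """Design for benchmarking same-metabolite feature merging.

    Study-scale 5-class table (317 samples, 240 metabolites x 3 adducts)
    with tightly correlated adduct triplets (rho = 0.98) and one strongly
    informative metabolite per class (delta = 5 noise sds, mildly
    jittered), each forming its own informative group.  One metabolite
    per class keeps the class-mean patterns of distinct compounds
    mutually distinct -- with k classes there are only k - 1 independent
    pattern directions, so informative metabolites that share a pattern
    are related almost as strongly as adducts of one compound and no
    threshold could separate them.  Under this design the separation that
    threshold-based merging relies on -- near-deterministic redundancy
    among adducts of one compound versus merely shared class information
    among different compounds -- is actually present, as it is in real
    LC-MS data.
    """
    origin = {"Germany": 213, "Greece": 25, "Netherlands": 31, "Peru": 13, "Poland": 35}
    classes = list(origin)
    rng = np.random.default_rng(seed + 77_000)
    groups = [
        InformativeGroup((m,), "origin", (classes[m],), float(5.0 * rng.uniform(0.9, 1.1)))
        for m in range(len(classes))
    ]
    return SyntheticSpec(
        n_samples=317,
        class_schemes={"origin": origin},
        n_batches=3,
        n_metabolites=240,
        adduct_multiplicity=3,
        within_metabolite_corr=0.98,
        informative_groups=tuple(groups),
        noise_sd=1.0,
        batch_sd=1.0,
        missing_base_rate=0.0,
        missing_intensity_slope=0.0,
        seed=seed,
    )


def generate_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one dataset; bit-reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_met = spec.n_metabolites
    mult = spec.multiplicities()
    sigma = spec.noise_sd
    rho = spec.within_metabolite_corr

    sample_ids = [f"s{i:04d}" for i in range(n)]
    schemes = list(spec.class_schemes)

    # primary scheme: contiguous class blocks in declared order
    sample_meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    primary_labels = np.concatenate(
        [np.repeat(lab, size) for lab, size in spec.class_schemes[schemes[0]].items()]
    )
    sample_meta[schemes[0]] = primary_labels
    # secondary schemes label a random subset
    for name in schemes[1:]:
        sizes = spec.class_schemes[name]
        total = sum(sizes.values())
        subset = rng.choice(n, size=total, replace=False)
        labels = pd.Series(pd.NA, index=sample_meta.index, dtype=object)
        labs = np.concatenate([np.repeat(lab, size) for lab, size in sizes.items()])
        labels.iloc[np.sort(subset)] = labs[np.argsort(np.argsort(subset))]
        sample_meta[name] = labels

    batch = rng.permutation(np.arange(n) % spec.n_batches)
    sample_meta["batch"] = batch
    sample_meta["year"] = 2016 + batch

    # latent metabolite intensities with class shifts
    mu = np.zeros((n, n_met))
    true_means: Dict[Tuple[str, str, int], float] = {}
    informative_mets: set = set()
    for g in spec.informative_groups:
        in_class = sample_meta[g.scheme].isin(g.classes).to_numpy()
        for m in g.metabolites:
            mu[in_class, m] += g.delta * sigma
            informative_mets.add(m)
            for c in g.classes:
                true_means[(g.scheme, c, m)] = true_means.get((g.scheme, c, m), 0.0) + g.delta * sigma
    latent = mu + sigma * rng.standard_normal((n, n_met))

    tau = sigma * np.sqrt((1.0 - rho) / rho)
    p = int(mult.sum())
    values = np.empty((n, p))
    feature_ids = []
    met_of_feat: Dict[str, int] = {}
    fmeta_rows = []
    met_mz = rng.uniform(150.0, 1400.0, size=n_met)
    met_rt = rng.uniform(0.5, 18.0, size=n_met)
    col = 0
    for m in range(n_met):
        baseline = rng.uniform(15.0, 60.0, size=mult[m])
        for a in range(mult[m]):
            fid = f"M{m:04d}_A{a}"
            feature_ids.append(fid)
            met_of_feat[fid] = m
            values[:, col] = baseline[a] + latent[:, m] + tau * rng.standard_normal(n)
            fmeta_rows.append(
                {
                    "mz": round(met_mz[m] + 21.98 * a, 4),
                    "rt": round(met_rt[m], 3),
                    "adduct_label": _ADDUCT_LABELS[a],
                    "adduct_group_id": m if spec.annotate_adduct_groups else pd.NA,
                }
            )
            col += 1

    # additive per-feature per-batch offsets, drawn once per table
    offsets = spec.batch_sd * sigma * rng.standard_normal((spec.n_batches, p))
    values += offsets[batch, :]
    np.maximum(values, 0.0, out=values)

    # intensity-dependent missingness
    if spec.missing_base_rate > 0.0:
        z = (values - values.mean(axis=0)) / np.where(values.std(axis=0) > 0, values.std(axis=0), 1.0)
        logit0 = np.log(spec.missing_base_rate / (1.0 - spec.missing_base_rate))
        pmiss = 1.0 / (1.0 + np.exp(-(logit0 - spec.missing_intensity_slope * z)))
        mask = rng.uniform(size=values.shape) < pmiss
        values = values.astype(float)
        values[mask] = np.nan

    intens = pd.DataFrame(values, index=sample_meta.index, columns=feature_ids)
    fmeta = pd.DataFrame(fmeta_rows, index=pd.Index(feature_ids, name="feature_id"))
    table = FeatureTable(intens, sample_meta, fmeta)

    informative_features = {f for f, m in met_of_feat.items() if m in informative_mets}
    truth = GroundTruth(
        informative_feature_ids=informative_features,
        metabolite_of_feature=met_of_feat,
        true_class_means=true_means,
        informative_metabolites=informative_mets,
    )
    return table, truth
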