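# Methods

This note documents the models and procedures implemented in `rfrelate`,
the parameters that matter, the synthetic-data model the tests run
against, and the numerical choices made where the design was open.

## Forest engine

Trees are binary classification trees grown on bootstrap samples of size
n drawn **with replacement** with per-sample probabilities proportional
to the case weights; with `case_weight_mode="inverse_class_frequency"`
(the default) the weight of sample i is `1/(k·n_class(i))`, so a sample
from a class of 13 is drawn 213/13 times as often as one from a class of
213. Weights affect only the bootstrap, not the split criterion. In-bag
multiplicities enter node statistics as counts; out-of-bag (OOB) sets are
the samples with bootstrap count zero (~e⁻¹ ≈ 36.8% per tree under
uniform weights).

Splits minimize the weighted Gini impurity of the children; thresholds
are midpoints between consecutive distinct sorted values of a candidate
feature. Nodes stop splitting when pure or at/below `min_node_size`
distinct in-bag samples (default 1, i.e. grow to purity).

Key parameters (defaults follow the application the package was built
for):

| parameter | default | meaning |
|---|---|---|
| `ntree` | 10 000 | trees; variance of every OOB/SMD/MAA estimate falls as 1/ntree. Desk-scale analyses use 10²–10³ |
| `mtry` | ⌊p^(3/4)⌋ | candidate features per node — much larger than the classical √p, appropriate when many correlated features share the signal |
| `min_node_size` | 1 | terminal node size |
| `n_surrogates` (s) | ⌊0.05·p⌋ | surrogate splits stored per internal node; 0 disables surrogate machinery |
| `case_weight_mode` | inverse class frequency | counteracts class imbalance |
| `mode` | classification / probability | voting vs leaf-proportion averaging |

**Probability machines.** Probability forests store leaf class
proportions (of the in-bag multiset) and average them over trees; a
sample's OOB probability vector averages only the trees where it was out
of bag. Rows sum to 1 by construction; a sample that is in-bag in every
tree (possible only for tiny ntree) gets a NaN row and a warning.

**Surrogates.** At every internal node (when s > 0) all p−1 other
features are scanned for the threshold and direction that best mimic the
primary split's left/right assignment of the node's samples, measured by
the in-bag-weighted agreement A. The stored quantity is the adjusted
agreement `adj = (A − maj)/(1 − maj)`, maj being the weight share of the
larger child: 1 = perfect mimic, ≤ 0 = no better than always guessing
the larger side. The s features with the largest positive adj are kept,
sorted descending. A direction flip is allowed (an anti-correlated
duplicate scores adj = 1). Surrogate candidates are all features, not the
node's mtry draw — relations must be observable between any feature pair.

**AIR importance.** The actual impurity reduction corrects the classical
Gini importance's preference for features with many split points: at
every node each candidate feature competes twice, with its actual values
and with a within-node permuted copy. The best gain among all 2·mtry
variants wins the node; a feature's score accumulates the (node-weighted)
gain when its actual values win and *loses* the gain when its permuted
copy wins. Under the null the two variants are exchangeable, so scores
are centered on zero; informative features are positive. Forests grown
for AIR are used only for importance (the permuted-copy splits corrupt
routing), and surrogates are disabled there. A plain OOB permutation
importance is available as `permutation_importance`.

**Tie-breaking (a deliberate numerical choice).** Exact ties are frequent
in small nodes: at a 2-sample node almost every feature separates the
samples perfectly, giving identical gains and identical adjusted
agreements. Any fixed preference order (e.g. lowest feature index) would
then systematically favor some columns over others — in particular real
features over appended permuted copies, which visibly distorts
permutation-based null references (Boruta shadows, SMD null copies).
Gains are therefore evaluated in the random candidate-draw order and
surrogate top-s selection iterates a per-node random feature permutation,
so ties break uniformly at random while remaining bit-reproducible from
the forest seed. The standalone `best_split` / `find_surrogates`
primitives, meant for inspection and oracle testing, keep the simpler
deterministic lowest-index/lowest-threshold rule.

Per-tree RNG streams are derived from (seed, tree index) with a
splitmix64 hash feeding an xorshift64* generator, so results are
independent of growth order and identical across runs and platforms.

## Feature selection

**Boruta** (all-relevant selection). Each run appends one freshly
permuted shadow copy per undecided feature (at least 5 shadows), fits an
importance forest (AIR by default) on real + shadow columns, and scores a
*hit* for every feature whose importance exceeds the run's maximum shadow
importance. After every run each undecided feature is tested with an
exact two-sided binomial test (success probability ½) on its hit count:
a significant upper tail confirms, a significant lower tail rejects
(default `p_value = 0.01`, per-feature; a Bonferroni switch exists but is
off by default since the operative confidence level is taken as given).
The loop ends when nothing is undecided or after `max_runs` (default
100); survivors are tentative.

**Surrogate Minimal Depth.** One forest with surrogates is fitted; a
feature's depth in a tree is the minimal depth over nodes where it is
primary splitter *or* listed surrogate, features absent from a tree get
that tree's maximal node depth, and SMD is the mean over trees (lower =
more important). Because surrogate appearances count, all members of a
correlated block inherit the block's importance even if only one of them
ever splits — the property the method exists for.

*Selection threshold.* The original method's analytic null threshold is
tied to its own package internals; here the null is estimated
empirically: `null_copies` (default min(p, 100)) permuted feature copies
are appended before fitting, and the threshold is the mean of their SMD
values (`null_mean`, default) or a lower quantile (`null_quantile`, e.g.
q = 0.05 for stricter control). Real features strictly below the
threshold are confirmed. The mean rule is permissive (on pure noise it
confirms roughly the null-distribution mass below its mean, ~40–50%); the
quantile rule controls the noise confirmation rate at ~q. `s` defaults to
⌊0.05·p⌋ of the *augmented* table, keeping the stored-surrogate fraction
constant.

## Relation analysis

The mean adjusted agreement M[i, j] averages i's recorded surrogate adj
over **all** nodes (all trees) where j is the primary splitter; nodes
where i was crowded out of the stored top-s list contribute 0, so the
estimator is an average over a fixed node set, and M[·, j] = 0 for
features that never split. M is directed; clustering and merging use the
symmetrized S = (M + Mᵀ)/2 with unit diagonal. Heatmap ordering and flat
clusters come from Ward linkage on Euclidean distances between rows of S
(the directed matrix is preserved in outputs for inspection). An
absolute-Pearson matrix over the same features is provided as the
comparison baseline.

`merge_features` thresholds S and returns connected components of size
≥ 2 as candidate same-metabolite groups (default threshold 0.9,
configurable). Two properties to keep in mind when choosing thresholds:

- For an *exact* duplicate, adj = 1 at every node, so M = 1 — but only
  when s is large enough that the duplicate is never crowded out of the
  top-s list by tied features at tiny nodes.
- For a partner correlated at ρ < 1, the expected adj at a split at
  population quantile q degrades as the split moves off the median (the
  mismatch mass shrinks more slowly than 1 − maj); at ρ = 0.98 typical
  per-node values are ~0.75–0.95. Merge thresholds in the 0.8–0.9 range
  therefore separate same-compound redundancy (ρ ≥ 0.98) from merely
  class-correlated distinct compounds, which is exactly the separation
  observed in real LC-MS data.

## Preprocessing

Fixed order: adduct consolidation → prevalence filter → imputation →
batch-wise autoscaling (imputation runs on raw intensities).

- *Adduct consolidation*: within each annotated adduct group only the
  feature with the highest mean intensity (missing cells ignored) is
  kept; ammonium-labelled features are never merged and always pass
  through. "Highest intensity" is interpreted as highest mean across
  samples — robust and deterministic. Tables without group annotations
  pass through unchanged.
- *Prevalence filter*: keep features observed in ≥ 80% of samples
  (inclusive boundary; "present in less than 80%" is excluded).
- *Imputation*: missForest-style — initialize missing cells with column
  means, then sweep features in increasing-missingness order, regressing
  each on all others with a regression forest (100 trees,
  mtry = ⌊√p⌋, via scikit-learn) fitted on its observed rows, and stop
  when the sum of squared changes of the imputed values first increases
  (returning the previous iterate) or after `max_iter` sweeps. Observed
  cells are never altered. This is the pipeline's slowest stage at full
  scale (one forest per incomplete feature per sweep — minutes for
  ~700 features, as with the original method).
- *Autoscaling*: per batch, each feature is centered and scaled to unit
  sample sd (ddof = 1); constant-within-batch columns become zero,
  single-sample batches are centered only (with a warning).

## Synthetic data model

One latent intensity per metabolite per sample,
`L[i,m] ~ N(μ(class(i), m), σ²)` with σ = `noise_sd`; each of the 1–3
adduct features of metabolite m is `baseline_f + L[·,m] + ε`,
`ε ~ N(0, τ²)` with `τ = σ·√((1−ρ)/ρ)` so that any two features of one
metabolite have population correlation ρ (`within_metabolite_corr`).
Informative groups shift μ by δ·σ in their affected classes. Batch
effects are additive per-feature per-batch offsets ~ N(0, (batch_sd·σ)²),
drawn once per table — exactly the structure batch-wise autoscaling
removes. Missingness is Bernoulli per cell with logit linear in the
per-feature standardized intensity (lower intensity → more missing),
which is what makes the prevalence filter meaningful. m/z and RT metadata
are placeholders, not simulated physics.

The default design (`default_spec`) mirrors the scale of the motivating
study: 317 samples, origin classes 213/25/31/13/35, a 4-class variety
scheme on a 150-sample subset, 3 batches, 240 metabolites × 3 features,
ρ = 0.95, δ = 3, base missingness 5% with slope 1. Defaults not dictated
by that scale (ρ, batch_sd = 1σ, missingness parameters, baseline range)
are modeling choices of what a practitioner would call realistic, chosen
once.

`adduct_benchmark_spec` is a dedicated design for the same-metabolite
merging benchmark: ρ = 0.98 triplets and **one** strongly informative
metabolite per class (δ = 5, ±10% jitter). The reason for one-per-class:
with k classes the class-mean patterns span only k−1 independent
directions, so two informative metabolites sharing a pattern are related
almost as strongly as adducts of one compound and no threshold could
separate them; distinct per-class patterns reproduce the separation real
data shows between same-compound redundancy and shared class
information. δ = 5 keeps the informative features splitting at class
boundaries (large nodes) rather than at near-pure deep nodes where
adjusted agreements of ρ = 0.98 partners degrade geometrically.

**What passing tests on synthetic data do and do not show.** The
generator produces Gaussian blocks with exactly additive batch effects
and logit-linear missingness; real LC-MS data have heavier tails,
intensity-dependent variance, drift within batches and correlated
missingness. Passing the synthetic benchmarks demonstrates that the
algorithms do what they claim under their own assumptions (recover
planted structure, calibrate against permutation nulls, reproduce
published-table arithmetic exactly); it does not certify effect-size
thresholds or error rates on real data.

## Problem sizes used in tests and the acceptance script

Fidelity to the motivating study's parameters (ntree 10 000) is kept in
the defaults; tests and the acceptance script run the same code at
desk scale as their own design choice — ntree 50–1000, tables up to
317 × 720, Boruta at ≤ 14 runs × 120 trees, merge benchmarks at 300
trees over 3 seeds — sizes at which every reported quantity is stable to
well within its assertion band (verified by running adjacent seeds).

## Known limitations

- The forest engine handles numeric features only (LC-MS intensities);
  no categorical split support.
- Surrogates are used for selection and relation analysis, not for
  handling missing values at prediction time; prediction requires a
  complete table.
- AIR forests and prediction forests are separate fits (the permuted-copy
  competition corrupts tree routing by design).
- `oob_confusion` excludes samples that were never OOB (only relevant at
  very small ntree).
- Memory for surrogate storage grows as ntree × nodes × s; at the
  default s = 0.05·p and p ≈ 700 this is why relation forests are
  typically grown with 10²–10³ trees rather than 10⁴.
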