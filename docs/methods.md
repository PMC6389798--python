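# Methods

This note documents the statistical model behind `hallmarknet`, the
parameters that matter, the synthetic-data generator used for validation,
and the numerical and design choices made where the procedure is
genuinely open. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Rank-based co-expression networks

For one cohort with expression matrix X (genes × samples, assumed
log-scale but not enforced), the sample Pearson correlation with the n−1
convention is computed for every gene pair. Each gene then nominates its
`n_neighbors` (default **10**) top-ranked partners and the network is the
undirected union of all nominations, so every node has degree at least
min(n_neighbors, genes−1). Inclusion is *relative*: a gene in a weakly
co-expressed pathway still contributes its best partners, which a global
correlation threshold would discard.

Open choices, with our defaults:

* **Ranking key.** Partners are ranked by the *signed* correlation
  (descending) — the most literal reading of "most correlated". Strong
  negative correlations therefore do not create edges unless
  `absolute_ranking=True`, which ranks by |r|. Both options are exposed
  because either reading is defensible.
* **Ties** at the rank-n boundary are broken by lexicographic gene id;
  this makes construction deterministic and order-invariant (verified by
  an exhaustive reference implementation in the tests).
* **Zero-variance genes** cannot be ranked and are excluded from the
  network with a warning. Missing values are handled at I/O time
  (default: drop any gene with a missing value in that cohort; row-mean
  imputation is available but risks biasing correlations).
* If `n_neighbors` ≥ the number of usable genes the complete graph is
  returned with a warning.

Scale-freeness is summarized by an OLS fit of log₁₀P(k) on log₁₀k over
degrees with nonzero frequency, with P(k) the raw relative frequency (no
log-binning — the simplest reproducible estimator; binned variants change
the numbers and would need their own convention). The fit requires ≥ 3
distinct degrees; its R² equals the squared correlation by construction.

## MCODE community detection

The dense-cluster detector is reimplemented from the published MCODE
description rather than wrapped, so the pipeline has no GUI dependency
and is deterministic. Stages and defaults:

| parameter | default | role |
|---|---|---|
| `degree_cutoff` | 2 | below this core level a vertex weighs 0 |
| `node_score_cutoff` | 0.2 | growth threshold fraction of seed weight |
| `k_core_filter` | 2 | complexes without a 2-core are discarded |
| `haircut` | on | iteratively strip degree-1 vertices |
| `fluff` | off | optionally add dense-neighbourhood boundary vertices |
| `max_depth` | 100 | BFS radius of complex growth |

Vertex weight = k_max × density of the highest k-core of the closed
neighbourhood. Complex growth visits seeds in descending weight and
marks included vertices, so complexes are disjoint (fluffed vertices are
the one exception, and fluff is off by default). Everything the original
leaves to hash order (seed ties, neighbour order) is fixed by
lexicographic gene id. The complex score is density × size.

One behavioural consequence worth knowing: when two dense modules are
joined by even a single high-weight connector, MCODE can grow them into
one complex. On synthetic data this shows up as a planted module being
absorbed into a larger community dominated by another module; the
conservation verdict of such a community is driven by its dominant
member. No minimum community size is applied at this stage — the ≥ 5
gene rule belongs to the conservation step.

## Conservation by permutation

For community genes G and a target cohort network, the observed statistic
is the number of edges induced by G. R (default **1000**) random gene
sets of size |G| are drawn uniformly from the *target network's node set*
and p = X/R, with X the count of random sets inducing at least as many
edges. Choices:

* **Sampling universe** — the target cohort's measured genes, not a
  global gene list: this conditions on what that cohort could show. A
  config option substitutes an explicit universe.
* **Genes absent from the target network** stay in the set size (the
  "same set of genes" is tested); `shrink_to_present=True` instead
  matches the present subset.
* p is reported **exactly as X/R**, so p = 0 is possible after 1000
  unexceeded draws; a `pseudo_p_value` (X+1)/(R+1) is provided for
  consumers that cannot tolerate zero.
* **No multiple-testing correction** across communities — raw p < 0.05
  per cohort is the published rule; a BH layer can be added downstream.
* Each (community, cohort) pair derives its own RNG stream from the
  master seed by SHA-256 hashing, so adding communities never perturbs
  another community's draws (tested).

A community is **conserved** when it has ≥ `min_size` (default 5) genes
and p < α (default 0.05) in every non-seed cohort. Whether the seed
cohort itself must also pass is ambiguous in principle (the community was
*detected* there); default is non-seed cohorts only, with
`include_seed_cohort` to flip. The permutation estimate is validated
against exhaustive enumeration on small universes, and on Erdős–Rényi
null networks the p distribution is checked to be stochastically ≥
uniform. A degree-preserving (configuration-model) null would be the
methodologically stronger reference but is deliberately not what this
pipeline computes; the uniform null is the published procedure.

## Survival validation

Per cohort: samples are split into halves of equal size (±1; the training
half gets the extra sample) with event counts matched to ±1, shuffled
reproducibly. On the training half each signature gene gets a univariate
Cox coefficient — Newton's method on the Efron-tie partial likelihood,
with the fit flagged (and the gene excluded from scoring) when the gene
has zero variance, fewer than 2 events are available, or the maximizer
diverges (monotone likelihood, e.g. perfect concordance). Test samples
are scored by GGI = Σ(expression of positive-coefficient genes) −
Σ(expression of negative-coefficient genes), deliberately *unweighted* by
coefficient magnitude. The test half is split at the median GGI score:
strictly-above-median is high-risk, exact-median ties go low-risk (for
odd n the high-risk group is the smaller half); all-equal scores raise a
"degenerate stratification" error. The two groups are compared by the
log-rank statistic (O−E)²/V accumulated over distinct event times with
the hypergeometric variance, p from χ²₁, and the hazard ratio
exp(β̂) from the same Cox routine on the group indicator (flagged → NaN
with a warning when inestimable, e.g. zero events in a group).

Both the Cox maximizer and the log-rank statistic are cross-checked in
the tests against lifelines, a grid-search likelihood oracle, and a
hand-computed O/E/V table. p-values are computed on the held-out half
only, and expression enters the score raw (not standardized) — both
points on which the procedure is otherwise underdetermined.

## Hypergeometric enrichment

All three screens — best-term annotation of a community, per-drug target
overlap, and cancer-indication enrichment among the selected drugs — use
the upper tail P(X ≥ x) of the hypergeometric distribution, accumulated
in log space (log-gamma binomial coefficients + log-sum-exp). The naive
1 − Σpmf complement loses everything below ~1e-12; the log-space tail is
exact to ~1e-9 relative down to the smallest positive doubles (verified
against big-integer arithmetic). x = 0 returns exactly 1. Although the
surrounding literature calls this stage "GSEA", the statistic is an
over-representation test, not the rank-based Kolmogorov–Smirnov GSEA.

The universe size M defaults to the union of genes measured in the
cohorts; for the term-overlap robustness comparison the universe is the
term collection. α = 0.05 uncorrected selects "appropriate" drugs; both
α and an optional BH correction are exposed. Annotation ties (equal p)
break by larger overlap, then term id. Drugs with empty target sets are
never selectable.

## The hallmark rule

"Hallmark" is operationalized as: conserved community whose gene set is
prognostic (log-rank p < α on the held-out half) in at least
`hallmark_min_cohorts` cohorts (default 4, matching the headline analyses
this pipeline mirrors; tests on three synthetic cohorts use 2).

## Synthetic data: what it does and does not emulate

`generate_cohorts` plants modules with the one-factor construction
g = √ρ·f + √(1−ρ)·ε (f a per-sample module factor, ε iid N(0,1)), which
gives *exactly* corr = ρ between module genes in expectation and costs
O(genes × samples). Shared modules appear in every cohort, cohort-specific
modules in one (their genes are pure noise elsewhere), everything else is
independent noise. Survival times are exponential with log-hazard
β × (standardized mean expression of the designated risk module);
censoring times are independent Uniform(0, c_max) with c_max solved by
Brent's method so the expected censored fraction equals the target
(empirically within ±0.1 at n ≥ 100). Defaults: 3 cohorts × 100 samples,
300 genes, shared modules of 8 and 6 genes at ρ = 0.8, one cohort-specific
module of 6 at ρ = 0.8, β = 1, 30% censoring — sizes chosen so that every
stage is exercised in seconds while module signal (ρ = 0.8 over 100
samples) is comfortably above the noise correlation scale 1/√n ≈ 0.1.

Annotation fixtures give each planted module one exact GO-like term plus
random decoys, and a drug table in which a configured fraction of drugs
draw most of their targets from a planted module, with cancer-indication
odds multiplied by a configured odds ratio for those drugs (odds ratio 1
is the null used for calibration tests).

Deliberately *not* emulated: platform/batch effects, heavy-tailed or
count-valued expression, correlated background structure, the GO DAG,
overlapping pathways, and non-proportional hazards. Passing tests
therefore demonstrate correctness of the machinery and its calibration
under the stated model — not robustness to the messiness of real tumour
cohorts.

## Problem sizes and runtime

The test-suite simulations use the generator defaults above; parameter
recovery runs 20 seeds end-to-end (networks → MCODE → conservation at
R = 1000), Cox sign recovery uses single cohorts of n = 200, log-rank
power n = 300, and type-I calibration 200 replicate null cohorts of
n = 100 with a 6-gene module over 30 genes. Null calibration of the
conservation test uses 200 random communities over twenty G(100, 0.05)
graphs. These sizes keep the whole suite around a minute on one CPU while
leaving every assertion's Monte-Carlo error far from its threshold.

## Known limitations

* The permutation null ignores degree structure; hub-heavy communities
  are easier to conserve than the uniform null admits.
* p = X/1000 has resolution 10⁻³ and a true discovery can report p = 0.
* MCODE merging (above) means a conserved community need not be a single
  functional unit.
* The GGI score is unweighted, so a gene with |β̂| ≈ 0 but the right sign
  contributes as much as a strong prognostic gene.
* Univariate Cox fits per gene ignore correlation among signature genes —
  by design, as the scoring formula requires only signs.
* The survival split is a single stratified half-split, not
  cross-validation; results depend (reproducibly) on the split seed.
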