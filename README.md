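# hallmarknet

Pan-cancer hallmark mining from gene co-expression networks.

Cancers are heterogeneous, but they share *hallmarks* — functional gene
programmes active across many tumour types. `hallmarknet` looks for such
programmes as **communities of a gene co-expression network that recur
across cancer cohorts**: a dense cluster of co-expressed genes that is
unexpectedly dense in *every* cohort's network is a candidate hallmark, and
it is validated by asking whether its genes stratify patient survival and
whether drugs targeting it are enriched for cancer indications.

The package is aimed at computational biologists who have per-cohort
expression matrices (genes × samples) with matched clinical follow-up and
want a tested, fully reproducible implementation of this mining pipeline,
together with a synthetic-data generator that plants known modules so every
stage can be benchmarked against ground truth.

## The method

1. **Co-expression networks** (`hallmarknet.network`). For each cohort,
   the Pearson correlation r = 1/(n−1) Σᵢ ((Xᵢ−X̄)/σ_X)((Yᵢ−Ȳ)/σ_Y) is
   computed for every gene pair; each gene nominates its top *n* (default
   10) most correlated partners, and the network is the union of all
   nominated pairs. Rank-based inclusion keeps weakly but consistently
   co-expressed pathways connected. Scale-freeness is checked by an OLS
   fit of log₁₀ P(k) on log₁₀ k.
2. **Dense communities** (`hallmarknet.mcode`). A from-scratch
   reimplementation of the MCODE algorithm: vertices are weighted by the
   density of the highest k-core of their closed neighbourhood, complexes
   grow from high-weight seeds over vertices scoring at least
   (1 − node score cutoff) × seed weight, and are post-processed (2-core
   filter, haircut). The complex score is density × size.
3. **Conservation test** (`hallmarknet.conservation`). For a community
   detected in the seed cohort, count the edges its genes induce in each
   other cohort's network, compare with R = 1000 uniformly drawn gene sets
   of the same size, and report p = X/R where X is the number of random
   sets with at least as many edges. A community with ≥ 5 genes and
   p < 0.05 in every non-seed cohort is a candidate hallmark.
4. **Survival validation** (`hallmarknet.survival`). Each cohort is split
   into event-ratio-matched halves; per-gene univariate Cox coefficients
   are fitted on the training half (Newton on the Efron partial
   likelihood); test patients are scored with the Gene expression Grade
   Index, GGI = Σ xᵢ − Σ yⱼ (expression summed over positive- and
   negative-coefficient genes), split at the median score, and compared by
   the two-group log-rank test with the hazard ratio from a Cox fit on the
   group indicator.
5. **Enrichment and drug screening** (`hallmarknet.enrichment`). GO-style
   annotation, drug "appropriateness" (targets overlapping a hallmark) and
   cancer-indication enrichment all use the upper-tail hypergeometric
   probability P(X ≥ x) = Σ_{i≥x} C(K,i)C(M−K,N−i)/C(M,N), evaluated in
   log space so values far below 1e-100 remain exact.

`hallmarknet.simulate` generates multi-cohort datasets with planted
modules (a one-factor model with within-module correlation exactly ρ),
exponential proportional-hazards survival driven by a designated risk
module, and toy GO/drug fixtures aligned to the planted structure.

## Worked example

```python
import hallmarknet as hn

dataset = hn.generate_cohorts(hn.SyntheticConfig(seed=7))
genesets, drugs = hn.generate_annotation_fixtures(dataset)

miner = hn.HallmarkMiner(dataset.cohorts, seed_cohort="cohort0",
                         hallmark_min_cohorts=2,
                         genesets=genesets, drugs=drugs)
results = miner.fit(seed=11)
print(results.summary())
```

```
Hallmark mining results
============================================================
cohorts: cohort0, cohort1, cohort2 (seed cohort: cohort0)
  cohort0: 300 nodes, 1775 edges; power-law r=-0.961 R2=0.924
  cohort1: 300 nodes, 1797 edges; power-law r=-0.953 R2=0.907
  cohort2: 300 nodes, 1781 edges; power-law r=-0.970 R2=0.942
communities detected in cohort0: 9
conserved communities: 2
  C000: 10 genes, max p=0.000, prognostic in 3 cohort(s), term=TERM:shared0 *hallmark*
  C002: 7 genes, max p=0.000, prognostic in 0 cohort(s), term=TERM:shared1
hallmarks (prognostic in >= 2 cohorts): C000
  drug screen C000: 18 selected, 13 cancer-indicated, indication p=0.00601
```

Reading the output: the three synthetic cohorts each yield a 300-gene
network whose degree distribution is close to a power law (R² ≈ 0.9).
Nine communities are detected in the seed cohort; exactly the two planted
shared modules survive the permutation conservation test (their largest
non-seed-cohort p-value is 0.000, i.e. no random gene set matched their
edge count in 1000 draws), and each is annotated with the GO-style term
planted for it. The module that drives the simulated survival times
(`shared0`) stratifies patients in all three cohorts and is promoted to a
hallmark; the drug screen then selects 18 drugs whose targets overlap it,
13 of them cancer-indicated — an enrichment with p ≈ 0.006. The
cohort-specific planted module is, correctly, not conserved.

The same pipeline is available from the shell:

```sh
hallmarks simulate --out data/
hallmarks run --config data/pipeline_config.json --seed 11 \
          --min-prognostic-cohorts 2 --out results/
hallmarks robustness --config data/pipeline_config.json \
          --neighbors 5 --seed-cohort cohort1 --out robustness.json
```

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.

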