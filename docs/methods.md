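# Methods

## Problem and model

Amplicon sequencing of a microbial community yields relative, not absolute,
abundances: each sample's counts are a multinomial draw from a closed
composition. Correlations computed directly on proportions are therefore
confounded — if one taxon blooms, every other proportion must fall. This
package infers correlations between the *basis* (latent absolute) abundances
from the variance of pairwise log-ratios,

&nbsp;&nbsp;&nbsp;&nbsp;t<sub>ij</sub> = Var<sub>samples</sub> log(x<sub>i</sub>/x<sub>j</sub>),

which is invariant to per-sample scaling. Writing ω<sub>i</sub>² for the
basis log-variance of taxon *i*,

&nbsp;&nbsp;&nbsp;&nbsp;t<sub>ij</sub> = ω<sub>i</sub>² + ω<sub>j</sub>² − 2ρ<sub>ij</sub>ω<sub>i</sub>ω<sub>j</sub>.

Under a sparsity assumption (most pairs uncorrelated, so the cross terms
average out), summing over *j* gives the linear system

&nbsp;&nbsp;&nbsp;&nbsp;(d − 2)·ω<sub>i</sub>² + Σ<sub>j</sub> ω<sub>j</sub>² = Σ<sub>j</sub> t<sub>ij</sub>,

i.e. M·ω² = t-row-sums with M = (d−2)·I + **1**. Correlations follow from
ρ<sub>ij</sub> = (ω<sub>i</sub>² + ω<sub>j</sub>² − t<sub>ij</sub>) / (2ω<sub>i</sub>ω<sub>j</sub>),
clipped to [−1, 1]. The sparsity assumption is refined iteratively: the
strongest not-yet-excluded pair with |ρ| above `exclusion_threshold` is
removed from the row sums (and M adjusted), and the system re-solved, up to
`n_exclusion_iter` times. Counting noise is propagated by repeating the whole
procedure on `n_estimation_iter` Dirichlet(counts + 1) posterior draws of the
fraction matrix and taking the elementwise median.

Significance is a permutation pseudo-p value: each taxon's counts are
shuffled independently across samples — destroying inter-taxon dependence
while preserving marginals — and the full estimate recomputed. We use the
two-sided add-one estimator p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + B), so
p is never 0 and FDR control stays valid. Benjamini–Hochberg is applied once
to the d(d−1)/2 unique pairs.

The downstream graph joins two OTUs by an unweighted edge when ρ ≥ `r_min`
(0.3) and q ≤ `fdr` (0.05), positive correlations only: the ecological
reading of positive and negative co-occurrence differs, and the clustering
statistics used here do not account for edge polarity. Clustering beyond
chance is the observed global transitivity (3·triangles / connected triples)
divided by the median transitivity of `n_null_graphs` uniform G(n, m) draws
with matched node and edge counts. Keystone candidates are ranked by
normalized degree (degree / (n−1)) and unnormalized shortest-path
betweenness with fractional credit across equal-length paths.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `min_prevalence` | 5 samples | OTUs present (count > 0) in fewer samples are removed before anything else |
| `rarefaction_depth` | 2,000 reads | per-sample subsampling depth, without replacement; shallower samples are dropped with a warning |
| `n_estimation_iter` | 20 | Dirichlet resampling iterations of the correlation estimate |
| `n_exclusion_iter` / `exclusion_threshold` | 10 / 0.1 | strong-pair exclusion refinement of the sparsity approximation |
| `n_permutations` | 1,000 | permutations behind the pseudo-p values (add-one floor 1/1001) |
| `permutation_estimation_iter` | 5 | Dirichlet iterations inside each permutation — cheaper than the observed estimate, configurable |
| `r_min` / `fdr` | 0.3 / 0.05 | inclusive edge thresholds on ρ and BH q |
| `n_null_graphs` | 1,000 | G(n, m) replicates behind the null transitivity distribution |

All pipeline randomness derives from one seed through fixed, named
substreams (rarefaction, Dirichlet draws, permutations, null graphs), so
changing e.g. `n_permutations` never silently alters the rarefaction.

## Design choices where the procedure is genuinely open

- **"Refining iterations".** The estimator has two nested loops; we read the
  refinement count as the Dirichlet resampling loop (`n_estimation_iter` =
  20) and keep the exclusion loop at the conventional 10 rounds with
  threshold 0.1. All three are independent knobs.
- **Which table feeds the correlation step.** The prevalence filter runs
  first, then rarefaction, and the correlation estimate consumes the
  filtered, rarefied table — matching the stated order of the upstream
  processing.
- **Median Jaccard stage.** The similarity summary is computed on the
  filtered, pre-rarefaction table by default (the stage at which such values
  are conventionally reported); `jaccard_stage="post_rarefaction"` selects
  the other reading.
- **Node retention.** Every OTU surviving the filters is a node, so a
  dominant-but-unconnected taxon appears as an isolate. The null-model
  comparison (and hence the clustering ratio) is made on the subgraph of
  nodes with at least one edge — the positive graph one actually inspects —
  while the report carries both node counts. Isolates are excluded from
  keystone ranking (their centrality is undefined in any meaningful sense)
  and emitted with empty ranks.
- **Ties and medians.** Rank ties break lexicographically by OTU id; the
  median of an even-length null vector is the mean of the central order
  statistics.
- **Null model.** G(n, m) over simple graphs, exactly matched node and edge
  counts. Degree-preserving rewiring is a deliberate non-feature: it answers
  a different question (clustering given the degree sequence).
- **Permutation scheme.** Independent within-row shuffles. A whole-column
  permutation would preserve the compositional coupling between taxa, which
  is exactly what the pairwise null must destroy.
- **Two-sided p values.** Conservative; since the graph keeps positive edges
  only, sidedness does not change the final network.

## Numerical notes

- Negative basis-variance solutions (possible under the sparsity
  approximation) are floored at 10⁻¹², the estimate flagged degenerate, and
  the affected ρ entries clipped; an all-zero variation matrix yields ρ = 1
  everywhere with the same flag.
- Components excluded from more than d−3 pairs can no longer be identified;
  they are dropped from the solve (system rebuilt over the remainder), their
  correlations reported as 0, and their identity recorded.
- A graph with no connected triples has transitivity 0 (flagged); a null
  median of 0 makes the clustering ratio undefined (reported as null, never
  infinity).
- Jaccard similarity of two empty presence sets is defined as 0.
- Rarefaction uses a multivariate hypergeometric draw — exact sampling
  without replacement from the read pool.

## What the synthetic generator does and does not emulate

`generate_table` draws per-sample log-basis abundances from a multivariate
normal with a planted correlation matrix (validated positive definite;
symmetric spectral square root, deterministic per seed), closes them to
fractions, and observes multinomial counts at a depth uniform over a range —
i.e. exactly the compositional observation model above, plus log-normal
cross-sample variation. The study-shaped scenario (`kakapo_like_scenario`)
uses 42 samples, 60 OTUs with a geometric abundance fall-off into a rare
tail, depths 2,000–10,000, a dominant OTU calibrated to ~30% of reads with
no planted partners, a second OTU (~20%) correlated r = 0.6 with one
partner, and two 5-member blocks at r = 0.75 among mid-abundance minority
OTUs. Expected shares are imposed by bisecting the target OTU's log-mean
against a Monte-Carlo estimate of its expected fraction.

What it does not emulate: sequencing error, chimeras, taxonomy, phylogenetic
structure, overdispersion beyond the log-normal, depth–composition
coupling, or temporal/host covariates. Passing tests on these tables shows
the estimator and graph statistics behave correctly under the model's own
assumptions — not that any particular real community satisfies them.

A note on detectable effects: with B permutations the smallest attainable
q value is (m/k)/(B+1) for k true pairs among m tested, so a handful of true
edges in a large table cannot clear FDR 0.05 at B = 1,000 regardless of
effect size. The study-shaped scenario plants 21 correlated pairs among
~30 filter-surviving OTUs (~450 tests), which clears the floor comfortably;
analyses of larger tables need more permutations.

## Problem sizes used in the checks

Tests and the acceptance script run at desk scale: oracle comparisons on
200 random graphs of ≤ 8 nodes; parameter recovery over 20 seeds at d = 30,
n = 50, depth 2,000; type-I control over 10 seeds with 100 permutations;
the study-shaped pipeline over 10 seeds with 1,000 permutations and 200
null graphs (the acceptance script's single pipeline run uses the full
1,000/1,000 defaults). These sizes are the package's chosen demonstration
scale; every one of them is a plain function argument.

## Known limitations

- The sparsity-approximation estimator is biased when many pairs are truly
  correlated or when d is small (d = 3 is accepted with a warning).
- Pseudo-p values inherit Monte-Carlo granularity 1/(B+1); see the floor
  note above.
- The clustering ratio compares against G(n, m) only; communities with heavy-
  tailed degree sequences may cluster above chance for degree reasons alone.
- No support for negative-edge analytics, community detection, or
  phylogenetically informed nulls.
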