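# cooccur

Compositional co-occurrence network analysis for microbiome OTU count
tables.

Amplicon sequencing yields *relative* abundances: the counts in each sample
are a closed composition, and correlations computed naively on proportions
are spurious (one taxon blooming forces every other proportion down).
`cooccur` implements the SparCC family of basis-correlation estimation —
inferring correlations between latent absolute abundances from the variance
of pairwise log-ratios t<sub>ij</sub> = Var log(x<sub>i</sub>/x<sub>j</sub>)
under a sparsity assumption, refined by iterative strong-pair exclusion and
aggregated over Dirichlet posterior resamples — together with the network
stage that makes such estimates ecologically interpretable:

1. **Table handling** — prevalence filtering (drop OTUs present in fewer
   than 5 samples), rarefaction to a common depth (2,000 reads, without
   replacement), Jaccard / Bray–Curtis sample distances.
2. **Inference** — SparCC correlations, permutation pseudo-p values (each
   OTU's counts shuffled independently across samples; add-one, two-sided),
   Benjamini–Hochberg FDR over the unique pairs.
3. **Network** — unweighted positive graph (edge iff ρ ≥ 0.3 and q ≤ 0.05),
   global transitivity against a G(n, m) null (1,000 matched random graphs,
   median), the resulting *clustering ratio*, and keystone ranking by
   normalized degree and unweighted betweenness.
4. **Synthetic truth** — a log-normal–multinomial generator with planted
   basis correlations, so every stage is testable against ground truth,
   including a study-shaped scenario (42 samples, 60 OTUs, one dominant
   uncorrelated taxon near 30% of reads, planted correlated blocks among
   minority taxa).

It is aimed at microbial ecologists analysing 16S rRNA amplicon surveys who
want the whole filter → correlate → test → graph → null-model chain
reproducible from one seed.

## Worked example

```python
import cooccur as cc

# A community with known structure: dominant uncorrelated OTU_01 (~30% of
# reads), OTU_02 (~20%) correlated with one partner, two planted blocks.
truth = cc.kakapo_like_scenario(seed=1)

report = cc.run_pipeline(truth.table, config={"seed": 1}, out_dir="run1")
s = report.network
print(s["n_nodes"], s["n_nodes_with_edges"], s["n_edges"])
print(round(s["transitivity_observed"], 3), round(s["clustering_ratio"], 2))
deg = {r["otu_id"]: r["degree"] for r in s["node_stats"]}
print(deg["OTU_01"])
```

prints

```
32 10 17
0.886 2.56
0
```

32 OTUs survive the prevalence filter; 10 of them carry the 17 significant
positive edges. The observed transitivity (0.886) is 2.56× the median of
1,000 matched random graphs — the planted blocks cluster far beyond chance —
and the dominant OTU has degree 0: despite holding ~30% of all reads it is
an isolate, exactly the topology the generator planted. `run1/` now holds
the filtered and rarefied tables, correlation/p/q matrices, edge list,
GraphML, node statistics with keystone ranks, and JSON reports, all
checksummed.

The correlation step is also available as a scikit-learn estimator
(`cc.SparCC(n_permutations=1000, random_state=1).fit(X)` with `X` of shape
samples × OTUs, fitted attributes `rho_`, `pvals_`, `qvals_`), and the whole
pipeline as a CLI:

```bash
cooccur simulate --scenario kakapo-like --out table.tsv --seed 1
cooccur run --table table.tsv --out run1 --seed 1
cooccur netstats --edges run1/edges.tsv
```

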