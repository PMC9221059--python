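# procoex

Protein co-expression network analysis for tumor proteomics.

Given a proteomic abundance matrix (gene-level protein quantifications,
"pGenes", over roughly a hundred tumor samples and a few healthy
controls), `procoex` builds a **mutual-information co-expression network**
and characterises its structure: hierarchical communities, functional
over-representation, differential-expression assortativity, and the
cis/trans chromosomal composition of edges. It is aimed at systems-biology
researchers who want a self-contained, reproducible version of this
workflow — including a planted-structure synthetic generator so every
stage can be validated without any data download.

## The method

**Edge weights** are mutual information estimated by adaptive partitioning
on copula-transformed profiles. Each protein's profile is mapped to ranks
`1/N … 1`; for a pair `(x, y)` the unit square is recursively quad-split at
cell midpoints, a cell of `n` points splitting only while the local
chi-square statistic

```
X² = Σ_quadrants (n_q − n/4)² / (n/4)
```

exceeds 7.815 (95% point, 3 df) with `n ≥ 8`. Leaf cells contribute
plug-in terms `(n/N)·ln[(n/N)/area]`, giving the MI in nats.

**Edge significance** comes from a permutation null: MI of ≥10⁵
profile pairs with one member shuffled. P-values use the empirical
survival function where permutations support it and the fitted tail law
`log₁₀ P(MI ≥ x) = a + b·x` below that, which is what a cutoff as strict
as the default `p < 10⁻⁸` requires. A top-k cut (default 10,000 edges)
gives the sparse "strongest interactions" view; optional DPI pruning
removes the weakest edge of every triangle.

**Communities** are found by greedy agglomerative modularity maximisation
(`Q = Σ_i (e_ii − a_i²)`, MI-weighted), then each community is
re-partitioned into subcommunities `SC<c>_<k>` — a two-level hierarchy
with mutually exclusive, exhaustive labels.

**Downstream statistics**: moderated-t differential expression
(tumor − healthy log2 fold change with empirical-Bayes variance
shrinkage, BH-FDR); hypergeometric over-representation of every
subcommunity against GMT gene-set collections (set sizes 5–2000, BH
within subcommunity); log–log degree-distribution power-law fit;
*expression assortativity* (`expass`: the fraction of a subcommunity's
edges joining proteins with the same fold-change sign); and cis/trans
classification of edges by chromosome.

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

Run the whole pipeline on a synthetic dataset with planted structure
(300 proteins in 5 modules × 3 submodules, 105 tumor + 3 healthy
samples, 30% differentially expressed, 5% missing values):

```python
import json
import procoex as px
from procoex.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    synthetic=px.SyntheticConfig(
        n_proteins=300, n_tumor=105, n_healthy=3,
        n_modules=5, submodules_per_module=3,
        de_fraction=0.3, missing_rate=0.05,
    ),
    seed=11,
)
cfg.mi.n_perm = 50_000
out = run_pipeline(cfg, "pcn_run")
stats = json.loads((out / "stats.json").read_text())
```

Printing the headline numbers from `stats.json` gives:

```
edges at p<1e-8       : 2128
largest component     : 53 proteins
cis fraction          : 0.041
communities Q         : 0.800
planted ARI (modules) : 0.945
planted ARI (submods) : 0.978
median expass         : 0.639
```

Reading: 2128 protein pairs pass the permutation-calibrated `10⁻⁸`
cutoff; the modularity of the level-1 partition is 0.80 and it recovers
the planted modules almost exactly (adjusted Rand index 0.945, and 0.978
for submodules at level 2); the cis fraction ≈ 0.041 matches the 1/23
expected when chromosomes are assigned independently of co-expression;
and the median same-sign edge fraction of 0.639 reflects the planted mix
of shifted and unshifted proteins. The run directory also holds the QC
report, DE table, full and top-k edge lists (TSV + Cytoscape SIF),
partition and enrichment tables, and a provenance file; rerunning with
the same config and seed reproduces every file bit-identically.

The same workflow is available from the shell:

```
procoex simulate --outdir sim --n-proteins 300 --seed 11
procoex run-all --config config.yaml --outdir pcn_run
procoex network --matrix qc.tsv --out net --p-threshold 1e-8 --top-k 10000
procoex compare --edges-a gcn.tsv --edges-b pcn.tsv --chromosome-map map.tsv --out cmp.json
```

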