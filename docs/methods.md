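# Methods

This note documents the models and procedures implemented in `procoex`,
the defaults they ship with, and the design choices made where more than
one reasonable option existed.

## Input model and quality control

The root object is a proteins × samples matrix of log-ratio abundances
with an explicit missing mask and a tumor/healthy label per sample.
Quality control runs in a fixed order:

1. **Missingness filter** — drop proteins missing in more than
   `max_missing` samples (default 60, an absolute count; a
   fraction-of-width alternative is available for matrices of other
   sizes).
2. **Flagged-sample removal** — samples marked unreliable in the
   metadata (e.g. evidence of protein decay) are dropped; the flag list
   lives in the metadata file, never in code.
3. **Control completeness** — proteins not measured in every healthy
   sample are removed: with only a handful of controls, a single missing
   control value leaves no basis for a contrast.
4. **Median imputation** — remaining gaps are filled with the
   per-protein median of observed values. The network stage works on
   ranks, so any monotone single-value fill is nearly equivalent; the
   median keeps imputed values inside the observed range and never
   touches observed entries.

Gene symbols are upper-cased on input so joins with chromosome maps and
GMT collections are case-insensitive.

## Mutual-information estimation

Profiles are copula-transformed row-wise to ranks `1/N … 1`, with ties
broken by seeded jitter ten orders of magnitude below the data scale
(reproducible, and irrelevant for continuous data). The estimator
recursively splits the unit square at cell midpoints into four
quadrants; a cell of `n` points splits while

* `X² = Σ (n_q − n/4)² / (n/4) > 7.815` (the 95% chi-square point at
  3 df — the standard stopping rule for this estimator), and
* `n ≥ min_points = 8`.

Leaves contribute `(n/N) ln[(n/N)/area]`; the sum is floored at zero. A
depth cap (60 halvings) guards against degenerate inputs with massive
coordinate duplication; rank vectors never reach it. The production code
is a single stack-based numba kernel; tests hold it against an
independent plain-recursion implementation (exact to float addition
order) and against the closed form `−½ ln(1−ρ²)` for Gaussian pairs.

## Permutation null and edge significance

The null distribution of MI is estimated from random profile pairs with
one member permuted (default 10⁵ pairs). Two properties of this null
shape the p-value model:

* On copula margins the root 2×2 table has fixed margins, so the root
  chi-square statistic has effectively one degree of freedom; tested
  against the 3-df critical value it rejects for only ~0.5–1% of null
  pairs. The null therefore has a large atom at MI = 0 and a discrete
  ladder of shallow-recursion values above it, smoothing out only deep
  in the tail.
* The log survival function is convex: a single straight line fitted
  through the whole tail systematically overestimates survival in the
  mid-tail.

P-values therefore use the **empirical survival function** wherever at
least `min_tail_count = 50` permutation values lie at or above the
observed MI, and the fitted tail law `log₁₀ P(MI ≥ x) = a + b x`
(least squares over distinct positive null values in the top tail, one
point per distinct value so heavy atoms do not dominate the slope) only
below that floor. Extrapolation is the line's entire purpose: the
default edge cutoff `p < 10⁻⁸` lies far below any feasible permutation
quantile. MI ≤ 0 maps to p = 1. The model is monotone in MI and clipped
to (0, 1].

Consequences worth knowing: realised false-edge rates are calibrated at
α = 10⁻³ (verified on fresh null pairs within three binomial standard
errors at the tested seeds), but the discreteness of the null means the
achievable rates near a nominal α jump in steps; when an atom boundary
falls unluckily the realised rate lands one step *below* nominal — the
conservative direction. At α = 10⁻² no threshold can be calibrated at
all, because fewer than 1% of null pairs have positive MI in the first
place. The 10⁻⁸ regime itself cannot be verified empirically by any
feasible permutation count; it inherits the linear-tail assumption.

**Top-k selection** keeps the k highest-MI edges (default 10,000), with
all ties at the k-th value retained. **DPI pruning** (remove the weakest
edge of each triangle when strictly below `min(other two)·(1−tol)`;
simultaneous removal, ties survive at tolerance 0) is implemented but
off by default.

## Communities

Level-1 communities come from greedy agglomerative modularity
maximisation: all nodes start as singletons and the connected pair with
the largest gain `ΔQ = 2(e_ij − a_i a_j)` merges until no positive gain
remains. Determinism: a community is named by its lexicographically
smallest member and equal gains break toward the smallest pair. Level 2
reruns the same procedure on each community's induced subgraph,
producing labels `SC<c>_<k>` numbered by descending size; the hierarchy
is exhaustive, mutually exclusive, and nested by construction.

Two deliberate choices:

* **MI-weighted modularity** (an unweighted flag exists). At a hard
  p-threshold the inside of a co-expression module is nearly a complete
  graph; only the weights still carry submodule structure, so an
  unweighted objective cannot resolve level 2.
* **Global greedy, not per-component.** Merging across components has
  negative gain, so components can never coalesce — but normalising
  modularity within each component (rather than against the whole
  network's weight) changes the objective and, on networks whose
  modules are disconnected from each other, collapses level 1 straight
  to the finest structure. The global form recovers planted modules at
  level 1 and their submodules at level 2.

## Differential expression

Per protein, an ordinary two-sample fit gives `lfc = mean(tumor) −
mean(healthy)` and the pooled variance `s²` on `n₁+n₂−2` df. Variances
are shrunk through the exchangeable model `s² ~ s₀² F(df, d₀)`, with
`(d₀, s₀²)` estimated by method of moments on log variances
(trigamma inversion by bracketed root finding; homogeneous variances
yield `d₀ = ∞`). The moderated statistic

```
t = lfc / sqrt(s̃² (1/n₁ + 1/n₂)),   s̃² = (d₀ s₀² + df s²)/(d₀ + df)
```

is referred to a t-distribution on `d₀ + df` df, two-sided (sidedness is
a convention; nothing downstream depends on it). BH step-up adjustment
controls FDR. The expression **sign** used by assortativity is
`sign(lfc)` with exactly-zero fold changes mapped to +1, keeping the
label set binary. The `d₀ → 0` limit reproduces the ordinary pooled t
(verified against an independent implementation) and `d₀ = ∞` the
fixed-variance z-like statistic.

## Enrichment

Over-representation is the exact hypergeometric upper tail
`P(X ≥ k)` for a query of `n` genes overlapping a set of `K` in a
universe of `N`, computed via the survival function (log-space stable)
and checked against exhaustive enumeration on small universes. Sets are
filtered to 5–2000 members *after* intersection with the universe;
subcommunities with fewer than 3 mapped genes are skipped; BH runs
within each subcommunity's batch (matching per-query enrichment-tool
behaviour; a global option exists). The default universe is the set of
post-QC measured proteins — testing against the whole coding genome
would conflate co-expression structure with detectability — with the
choice exposed to callers. The heatmap export is the set × subcommunity
matrix of `−log₁₀ q` with cells above the significance cut left blank.

## Network statistics

* **Degree fit**: ordinary least squares of `log₁₀ count` on `log₁₀ k`
  over non-empty histogram bins — the slope read off a log–log
  degree-distribution plot, chosen deliberately over maximum-likelihood
  tail fitting so the reported `alpha` and correlation are directly
  comparable to plot-based values; at least three points are required.
* **Expression assortativity**: per subcommunity, the fraction of
  internal edges whose endpoints share a DE sign, reported only when the
  subcommunity has strictly more than 10 internal edges. Invariant under
  a global sign flip.
* **Cis/trans**: each edge is cis (same chromosome), trans (different),
  or unmapped (an endpoint absent from the map); counts are exhaustive
  and a per-chromosome cis breakdown is emitted.
* **Components**: sizes descending, with a giant-component extractor.

## Synthetic data

The generator emulates the shape of a tumor proteomics study. Protein
`p` in module `m`, submodule `k`:

```
x[p, s] = λ f[m, s] + (λ/2) g[m, k, s] + ε,   ε ~ N(0, σ²)
```

with per-sample standard-normal factors. The submodule coefficient is
pinned at λ/2 so second-level structure is only resolvable after the
first level is found. With one submodule per module the `g` term is
omitted, making the within-module correlation exactly `λ²/(λ²+σ²)` —
the form the correlation-recovery tests check. Defaults: 2000 proteins
(thousands of rows at desk scale), 105 tumor + 3 healthy samples, 8
modules × 3 submodules, λ = 2, σ = 1, 20% of proteins shifted by ±2 in
tumors, 10% missing completely at random, 23 chromosome labels assigned
uniformly (expected cis fraction 1/23). Optional flags align DE signs
and/or chromosomes with modules, producing the contrasting regimes
(assortativity ≈ 1 vs ≈ 0.5; cis fraction ≈ 1 vs ≈ 1/23) used in the
statistics tests.

What it does **not** emulate: peptide-level artefacts, iTRAQ channel or
batch structure, intensity-dependent (non-MCAR) missingness,
heavy-tailed abundance distributions, or molecular subtypes among the
tumors. Passing tests certify the algorithms against the stated
statistical model, not against those real-data complications.

## Reproducibility and problem sizes

A single master seed fans out to named per-stage seeds through
`numpy.random.SeedSequence` children (order: synthetic, jitter, null,
misc; each reduced below 2³¹), so stages can be rerun in isolation and
a rerun of the pipeline is bit-identical — matrix and edge-list writers
serialise floats with `repr` for exact round-trips.

Tests and the acceptance script run at deliberately compact sizes
chosen to exercise every code path with comfortable statistical margins:
180–300 proteins in 4–5 modules for network recovery (the planted
contrasts are detectable at ~100 samples, mirroring the study shape),
5000–6000 proteins for error-rate checks, 10⁵ permutations for null
calibration, and N = 5000 for the Gaussian MI oracle.

## Known limitations

* The `10⁻⁸` edge cutoff rests on tail extrapolation; its literal false
  positive rate is untestable by permutation.
* Greedy modularity is a local optimiser with a resolution limit; the
  returned partition is merge-locally optimal but not guaranteed
  globally optimal, and very small planted modules may be absorbed.
* With only three healthy controls the DE contrast has little power;
  variance moderation keeps error control but cannot create power.
* Median imputation slightly attenuates MI for proteins with many
  missing values; proteins passing the default QC lose at most ~54% of
  a 111-sample width, in practice far less.
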