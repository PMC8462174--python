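# mfnet — multifunctionality network analysis

`mfnet` quantifies how groups of trait-sharing species and environmental
conditions jointly drive multiple ecosystem functions, and renders the
answer as a directed, weighted network.  It targets community ecologists
working with the classic four-table design — a fuzzy-coded species ×
trait-modality table, a sample × species abundance table, a sample ×
environment table, and a sample × function table (e.g. solute fluxes,
chlorophyll *a*, organic-matter degradation on an intertidal sandflat).

## Method

The pipeline has two stages.

**1. Reducing trait dimensionality.**  Fuzzy trait affinities are
binarized to modality sets.  For each species pair holding `n_a` and
`n_b` of the `N` modalities, the number of shared modalities under
random assignment is hypergeometric,

    P(share exactly j) = C(n_a, j) C(N − n_a, n_b − j) / C(N, n_b),

computed exactly from integer binomial coefficients.  Pairs sharing
significantly more than chance (upper tail < α, expected sharing ≥ 1)
become edges of an undirected species network weighted by Jaccard's
coefficient `JC = q / (n_a + n_b − q)`.  Louvain modularity optimization
(best of 20 seeded restarts) partitions the network into trait clusters;
clusters below the minimum size (e.g. a disconnected singleton) are
excluded, and each retained cluster becomes a per-sample abundance
predictor by summing its members' abundances.

**2. Multivariate network analysis.**  Each function is modelled with a
distance-based linear model (DistLM): the Euclidean distance matrix of
the function is Gower-centred into `G`, and the variance explained by a
centred predictor design with hat matrix `H` is `R² = tr(HGH)/tr(G)`,
tested by permutation of residuals under the reduced model.  Every
predictor enters as raw, squared (or square-root) and log10(x+1)
candidate columns; forward selection maximizes adjusted
`R²_adj = 1 − (1 − R²)(n − 1)/(n − v − 1)`, with the rule that a log
column is only admissible while no raw/square column of the same
variable is selected (and vice versa).  Stage 1 selects trait-cluster
terms; the significant ones are forced into stage 2, which adds
environmental terms.  Per function this yields row A (cluster `R²`),
row B (environmental addition) and row C = A + B.  Finally the selected
predictor → function relationships are assembled into a directed network
whose edge weights are the sequential `R²` contributions and whose node
sizes are link counts — a map of which biological and environmental
components underpin which functions.

A synthetic-study generator (`mfnet.simulate`) plants known trait
clusters and known linear cluster/environment → function effects, so the
whole chain is testable against ground truth without field data.

## Worked example

Generate a synthetic study (6 planted trait clusters × 6 species, 49
samples, one planted cluster effect and one planted environment effect
on function `f1`) and run the full pipeline:

```bash
mfnet simulate --out-dir example --seed 1
mfnet run example/config.yaml     # config listing the five input files
```

The run log reports the trait-network stage

```
nat: 86 significant pairs, 6 clusters, Q=0.8215
```

— the six planted clusters are recovered exactly — and the selection
path for the planted function:

```
traits       c1   raw     ΔR²=0.4612  p=0.001
environment  mud  square  ΔR²=0.1475  p=0.001
A=0.4612  B=0.1475  C=0.6087
```

Cluster `c1` and `%mud` are precisely the planted drivers; the ground
truth file records realized semi-partial R² of 0.459 and 0.137 for this
seed, matching the recovered contributions.  The connectivity summary
ranks nodes by link count:

```
node        role         degree  weight_sum
f1          function     2       0.608682
mud         environment  2       0.280655
c1          cluster      1       0.461228
```

All artifacts (cooccurrence scan CSV, partition CSV, DistLM report JSON,
predictor × function table with transform footnotes, and the
multifunctionality network in GraphML/GEXF/edge-CSV for Gephi) land in
the configured output directory together with a manifest and run log.

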