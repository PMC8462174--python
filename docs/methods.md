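# Methods

This note records the statistical model behind `mfnet`, the defaults and
the reasoning for every place where the design was genuinely open.

## Trait cooccurrence model

Species are reduced to modality sets by thresholding fuzzy affinities
(default: any affinity strictly above 0 counts as possession — fuzzy
coding is proportional, so any nonzero affinity is evidence the species
expresses that modality; the threshold is configurable).  Sharing between
a pair with `n_a`, `n_b` of `N` modalities is modelled as hypergeometric,
i.e. modality sets of the observed sizes placed uniformly at random.
Probabilities are computed from exact integer binomial coefficients; the
only rounding is the final float division, so tail sums match brute-force
enumeration to machine precision (≪ 1e−12).

Decisions:

- **Positive associations only** (`P(share ≥ q_obs) < α`, default
  α = 0.05, one-sided) form network edges.  Observed Jaccard strengths in
  this kind of analysis span roughly 0.4–1, which is only consistent with
  retaining positive associations; negative associations are still
  reported in the scan output.
- **Expected-sharing filter** `n_a n_b / N ≥ 1` by default, the
  conventional filter of probabilistic cooccurrence analysis; set
  `min_expected = 0` to disable.
- **No multiple-testing correction by default** (raw significant pairs
  are the standard report); a Benjamini–Hochberg option exists
  (`fdr=True`) via `scipy.stats.false_discovery_control`.
- Trait-empty species are flagged and excluded from testing, not errors.
- Each input row is one network node.  When rows are size classes of one
  species, abundance aggregation requires an explicit node → column
  mapping; prefix guessing is refused because silent mis-mapping would
  corrupt cluster abundances.

## Modularity clustering

The species network (nodes = all species, isolates kept; edge weight =
Jaccard coefficient) is partitioned by Louvain optimization of weighted
Newman–Girvan modularity `Q = Σ_c [w_c/W − (s_c/2W)²]`.  Louvain is
greedy and seed-dependent, so `detect_clusters` runs 20 seeded restarts
and keeps the best `Q`, breaking ties by fewest clusters and then by the
lexicographically smallest canonical assignment — the result is a pure
function of (graph, resolution, seed, restarts).  Resolution defaults
to 1.0.  Isolated nodes become singleton clusters; clusters below
`min_cluster_size = 2` (including such singletons) are excluded from the
downstream model and logged, mirroring the removal of a disconnected
single-species cluster from an analysis before modelling.

Cluster abundance is the unweighted **sum** of member-species abundances
per sample (configurable to mean).  Sum is the natural reading of "the
abundance in the cluster" as a predictor; a mean would weight rare and
dominant members equally.

## Distance-based linear models

For each function independently, the Euclidean distance matrix of the
raw (untransformed, unstandardized) function values is Gower-centred:
`G = (I − J/n)(−½ D∘D)(I − J/n)`.  With `H` the hat matrix of the
centred predictor columns, `R² = tr(HGH)/tr(G)` and

    pseudo-F = [tr(HGH)/m] / [tr((I−H)G(I−H))/(n−m−1)].

For a univariate Euclidean response this is algebraically identical to
ordinary least squares; the test suite checks agreement to 1e−8 against
`numpy.linalg.lstsq` over 1,000 random fixtures.  Per-function modelling
makes response standardization irrelevant to `R²`, hence none is applied.

**Transforms.**  Each base variable contributes up to three centred
candidate columns: raw, a second power-family transform, and
log10(x+1).  The second transform defaults to the **square** (x²) —
raw + square approximates a two-degree polynomial response — with
square-root available as `transform_family="sqrt"`; both conventions
appear in practice and the choice is logged.  Constant columns are
excluded as degenerate with a warning; negative values are an error for
sqrt/log.

**Admissibility.**  Under the default `strict` constraint a log column
may be selected only while no raw/square column of the same base
variable is in the model, and raw/square are inadmissible once the log
is in.  A `lenient` mode lifts the restriction, because published
selection tables do occasionally record log together with raw/square.

**Forward selection** adds, at each step, the admissible candidate that
maximizes the adjusted R² of the enlarged model, and stops when no
admissible candidate increases it.  (Only the stopping criterion is
universally stated for this protocol; maximizing adjusted R² at each
step is this package's documented choice, and with it stopping is
equivalent to "best candidate no longer improves".)  Ties are broken
lexicographically by (base variable, transform); candidates collinear
with the current model are skipped.  The degrees-of-freedom count `v`
in `R²_adj = 1 − (1−R²)(n−1)/(n−v−1)` counts selected transform
columns, not base variables — each column consumes a model degree of
freedom regardless of its base.

**Permutation tests.**  Each accepted step gets a sequential p-value by
permutation of residuals under the reduced model (Freedman–Lane): the
residual Gram `(I−H0) G (I−H0)` of the previously selected columns has
rows and columns permuted simultaneously and the partial pseudo-F is
recomputed; `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`.  This scheme
keeps conditional error rates correct in the presence of forced terms;
default 9,999 permutations (the verification runs use 199 to keep the
simulations quick — calibration is checked at that setting).

**Two-stage protocol.**  Stage 1 selects over trait-cluster columns with
nothing forced.  A step counts as *significant* under the default rule
`selected_and_p` (selected by adjusted R² AND sequential p ≤ α); the
rule is applied in both stages, since the stage totals are defined as
"all significant" terms per stage; `significance_rule="selected"`
reduces it to selection alone.  Retained stage-1 columns are forced into
stage 2, which selects over environmental columns.  After the
significance filter, sequential ΔR² are **recomputed** over the retained
columns in selection order, so that ΣΔR² telescopes exactly to the model
R²: row A = R² of retained cluster terms, row B = R² added by retained
environmental terms, row C = A + B, all exact to 1e−12 by construction.
The original sequential p-values (computed at selection time) are kept.
No correction is applied across functions.

## Multifunctionality network

One directed edge per (retained base predictor, function) with weight =
summed sequential ΔR² (proportion scale, 0–1; percent is a display
choice).  Environmental edge weights are the stage-2 conditional
contributions exactly as reported — no marginal refit.  Node size is the
out-degree (sources) or in-degree (functions); a function's incoming
weight sum equals its row C exactly.  Excluded clusters never appear.
Source–source and function–function edges cannot be created.  Whether an
edge additionally required p ≤ α is governed by `significance_rule`.

## Synthetic study generator

`simulate_dataset` plants: (i) disjoint core modality sets per cluster,
members carrying each core modality with probability `within_overlap`
(default 0.8) and each foreign modality with `between_noise` (0.2);
(ii) negative-binomial abundances (dispersion k = 2 — ecological counts
are overdispersed; k = ∞ gives the Poisson limit); (iii) uniform
environmental variables on ranges typical of sediment percentages;
(iv) functions as linear combinations of standardized predictors plus
Gaussian noise, with coefficient √p planting a partial R² of ≈ p
(default: one cluster effect 0.3 and one environment effect 0.2 on the
first of eight functions, n = 49 samples; remaining functions are pure
noise).  Generators are pure functions of (params, seed), and the
realized semi-partial R² of every planted effect is returned so recovery
can be judged against the realized rather than the nominal target.

**Modality-pool size.**  The default is `n_modalities = 180` (cores of
30 per cluster).  This follows from a power analysis of the
hypergeometric pair test under random per-modality carriage: the
within-block excess sharing grows like the core size `c` (≈ 0.3c)
while the null standard deviation grows like √c (≈ 0.58√c), so
per-pair power ≥ 95% requires cores of roughly 25–30 modalities.  With
small pools (tens of modalities) the random-carriage model is
underpowered even though real trait tables of that size work well —
real species share *whole category patterns*, a dependence structure
this generator deliberately does not emulate.  Consequently, passing
recovery tests demonstrates that the chain recovers planted block
structure when the pairwise signal is identifiable; it does not certify
power on small, structured real-world tables.

Other real-data features the generator omits: spatial autocorrelation
among samples, zero-inflation, correlated environmental gradients, and
nonlinear (saturating) function responses.

## Numerical choices and degenerate inputs

- Rank decisions use QR with tolerance 1e−10 relative to the largest
  diagonal; collinear columns are named in the error.
- `tr(G) = 0` (constant function) is a hard error, not a zero R².
- Perfect fits give `pseudo-F = ∞`; permutation p-values then take the
  minimum value `1/(n_perm+1)`.
- Modularity tie-breaking rounds Q to 12 decimals before comparison to
  avoid float-ordering artifacts between restarts.
- Missing cells in any input table are hard errors, never imputed — the
  target designs are complete, and silent imputation would corrupt
  cooccurrence counts.
- Whether rows are plots or chambers (e.g. 49 vs 98) is the user's
  choice at table-construction time; the pipeline never merges or
  splits samples itself.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` use: exhaustive enumeration
of all modality placements for N ≤ 10; 1,000 random OLS-agreement
fixtures (n = 50, m ≤ 4); 500 null permutation simulations (n = 30,
199 permutations); 100 seeds of planted-cluster recovery (6 × 6 blocks);
and 100 replicates of planted-effect recovery (n = 49, 199
permutations).  These sizes make the whole verification run in well
under a minute while keeping Monte-Carlo error far below the margins
being checked.

## Known limitations

- Louvain is a heuristic; the restart/tie-break scheme makes it
  reproducible, not provably optimal, and the number of detected
  clusters can depend on the resolution parameter.
- Sequential ΔR² attributions depend on selection order, as in any
  forward-selection report; correlated predictors share credit
  accordingly.
- Permutation p-values are computed sequentially at selection time; when
  the significance filter later drops a step, the surviving steps' p
  refer to their original conditioning set.
- The two-stage protocol conditions environment on clusters by design;
  it does not estimate marginal environmental effects.
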