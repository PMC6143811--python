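# Methods

This note documents the statistical model implemented by `reporternet`,
the parameters that matter, the synthetic-data generator used for
validation, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` do not themselves compute.

## 1. From expression to per-gene p-values

Input is a probes/genes × samples intensity matrix with a sample sheet
assigning each sample a group (control/treatment) and a time point.
Processing follows the standard microarray path:

- **Quantile normalization** forces every sample column onto the shared
  reference profile (the across-column mean of within-column order
  statistics). Tied values within a column receive the mean of their tied
  reference values, so ties stay tied. Note that tie-averaging breaks
  exact idempotence when columns have different tie patterns; on
  continuous (tie-free) data the transform is idempotent to numerical
  precision, and the property test checks exactly that case.
- **log2 transform** per time point, with treatment samples recorded
  against their matching control group. PCA scores (samples as
  observations) support the usual outlier screen.
- **Differential testing** is the pooled-variance (equal-variance)
  two-sample t-test, two-sided, with sign convention treatment − control.
  Rows with missing values are dropped with a logged count. A row with
  zero variance in both groups gets p = 1 when the means agree, and p = 0
  flagged `degenerate` otherwise.
- **Probe collapse**: when several probe sets represent one gene, the
  default rule takes the minimum p across the gene's probes (the most
  favorable probe, consistent with the isozyme rule below); a `rank` mode
  takes the probe with the smallest declared rank instead. No
  multiple-testing correction is applied to gene p-values — downstream
  calls threshold raw p at 0.05 — but a Benjamini–Hochberg helper is
  provided for users who want it.

## 2. The metabolic association model

The model is two association layers — gene↔metabolite and
metabolite↔pathway — with an optional gene→reaction→metabolite layer.
Associations are undirected (production vs. consumption is deliberately
ignored) and unweighted. A **currency list** marks ubiquitous
cofactors/carriers (proton, water, oxygen molecule, NADH, NAD+, NADPH,
NADP+, ATP, ADP, AMP, GTP, GDP, UDP, CoA, FAD, diphosphate, carbon
dioxide, carbon monoxide, phosphate, ammonia, hydrogen peroxide, and the
oxidized/reduced generic electron acceptors) whose extreme connectivity
would otherwise dominate neighborhood aggregation; currency metabolites
are excluded from all scoring views but their associations are retained so
original membership counts stay reportable. Currency marking is
idempotent and user-overridable.

## 3. Reporter scoring

1. **p → Z.** Gene (or reaction) p-values are clamped to
   [1e-15, 1 − 1e-15] (the clamp count is reported) and converted with the
   inverse standard-normal CDF. The default is one-tailed,
   `Z = Φ⁻¹(1 − p)`, the convention of the reporter-metabolite
   literature; a two-tailed option `Φ⁻¹(1 − p/2)` is provided (it is the
   convention under which Z = 1.96 corresponds exactly to p = 0.05).
2. **Isozyme collapse.** With a reaction layer, each reaction takes the
   minimum p over its catalysing genes and reactions become the scoring
   units; flat models score genes directly. Granularity is per reaction
   (not per enzyme complex), the finest level the association tables
   support.
3. **Aggregation.** A metabolite with `k` scored neighbors gets
   `Z_raw = Σ Z_i / √k` (Stouffer). Under the null with i.i.d. standard
   normal unit scores this is standard normal *independently of k*, which
   is what makes metabolites of different connectivity comparable. The
   arithmetic-mean variant `Σ Z_i / k` is first-class (`mode="mean"`) but
   its null shrinks with k; the test suite contains a pair of KS tests
   that distinguish the two modes by exactly this property.
4. **Background correction.** For each occurring size `k`, the null mean
   `μ_k` and population standard deviation `σ_k` are estimated from
   10,000 aggregates of random size-`k` subsets drawn without replacement
   (within a draw) from the pool of *all* unit scores. An exhaustive mode
   enumerates all C(|pool|, k) subsets and is used as the oracle in tests.
   `Z′ = (Z_raw − μ_k)/σ_k` and `p = 1 − Φ(Z′)` (upper tail only: gene
   p-values are signless, so a high Z′ means coordinated change in either
   direction). A constant score pool makes σ_k = 0 and raises a
   degenerate-null error rather than silently dividing.
5. **Pathways.** Scored identically one level up: a pathway with `n`
   scored member metabolites aggregates their *corrected* Z′ values
   against a background pool of all metabolites' Z′ (using corrected
   scores is configurable; corrected is the default because the pathway
   statistic should not re-reward metabolite connectivity).
6. **Calls.** `p ≤ 0.05`, inclusive.

Determinism: one master seed; the background for size `k` uses the
deterministic sub-seed sequence `[master, k]`, so adding one metabolite
never perturbs another metabolite's null. The sampled background sd is the
population sd (ddof = 0); at 10,000 draws the difference from the sample
sd is negligible.

Sampling implementation: each draw takes the k smallest entries of a row
of i.i.d. uniforms (argpartition), which is uniform over size-k subsets
and vectorizes over all 10,000 draws.

## 4. Tripartite networks

Nodes are the significant genes, metabolites and pathways at α = 0.05;
edges exist only between significant genes and significant metabolites
associated in the model, and between significant metabolites and the
significant pathways containing them. Same-set and gene–pathway edges are
rejected at construction (*open* tripartite). Isolated significant nodes
are kept by default (they affect density and averages); `drop_isolated`
removes them.

Topology panel: density uses the pooled denominator n(n−1)/2 over all
node types; the average local clustering coefficient counts degree-<2
vertices as 0; diameter and average path length are computed on the
largest connected component (components tie-broken by node count, then
edge count, then smallest node id) since real tripartite runs are
disconnected but a single finite value is wanted. Edgeless graphs report
NaN for the path statistics. Overlays of time-resolved networks count
exclusive (present in exactly one network) and shared-by-all nodes and
edges by string-id identity, and annotate a union graph with per-element
presence vectors. Export formats: GraphML (lossless round trip with
set/p/degree attributes), SIF with `gm`/`mp` interaction labels, TSV edge
list.

## 5. Degree-distribution and community statistics

Two power-law assessments are reported side by side, never conflated:

- **Regression**: OLS on (log k, log P(k)) over degrees ≥ 1 with
  P(k) > 0; γ is the negative slope, with its R². At least three usable
  points are required. Zero-degree nodes count in the P(k) denominator.
- **MLE + KS**: continuous MLE `γ̂ = 1 + n (Σ ln(x_i/x_min))⁻¹`; for
  integer data the standard continuous approximation shifts the cutoff to
  `x_min − 0.5`. The KS statistic compares the fitted and empirical CDFs
  above `x_min`; its p-value comes from a semi-parametric bootstrap
  (default B = 1000) in which each replicate is drawn from the fitted
  law, refitted, and measured. A bootstrap count of zero is reported as
  "< 1/B" rather than 0. `x_min` defaults to 1 (tripartite degree
  distributions are small and untruncated); `x_min="auto"` scans distinct
  values and minimizes KS, and is what Barabási–Albert reference graphs
  need, because their low-degree body deviates from the asymptotic k⁻³
  tail.

Communities: modularity `Q = Σ_c [e_c/m − (d_c/2m)²]` is computed by a
direct implementation and cross-checked in tests against an independent
library oracle. Fast-greedy agglomeration is delegated to igraph
(Clauset–Newman–Moore), cut at the maximal-Q point of the dendrogram.
Girvan–Newman is implemented directly: repeatedly remove the edge of
maximal betweenness (recomputed after every removal; ties broken by
lexicographically smallest edge id for determinism), score the component
partition after every split by Q *on the original graph*, and return the
first maximal-Q partition. MCODE follows the published algorithm: vertex
weight = highest-core number of the closed neighborhood × density of that
core; clusters grow from the highest-weight unused seed, admitting
vertices within `node_score_cutoff` (default 0.2) of the seed weight;
post-processing requires a 2-core, haircuts singly connected members, and
ranks clusters by density × size. Note that on two equal-density cliques
joined by a *direct* bridge every vertex carries the same weight, so MCODE
expansion legitimately crosses the bridge and returns one cluster; only a
low-weight linker (e.g. a degree-2 node between the cliques) separates
them. The unit tests assert both behaviors.

## 6. The synthetic-data generator

`make_model` draws a random bipartite gene–metabolite and
metabolite–pathway structure with Poisson-distributed degrees (means 3
genes/metabolite and 5 metabolites/pathway by default, minimum 1, matching
the sparse connectivity of curated plant pathway databases).
`make_expression` gives every gene a baseline ~ Normal(8, 2) on the log2
scale (typical microarray intensity range) and replicated
control/treatment values ~ Normal(baseline, noise_sd), shifting planted
genes' treatment mean by `effect_size × noise_sd`. Ground truth follows
the neighborhood logic of the scoring: a metabolite is *planted truth*
when >50% of its neighbor genes are planted, a pathway when >50% of its
members are planted metabolites. All generators are pure functions of
their parameters and seed.

What the generator does **not** emulate: probe-level artifacts, batch
effects, intensity-dependent variance, correlated noise between genes, and
the heavy-tailed degree distribution of real metabolic networks (degrees
are Poisson, not scale-free). Passing recovery tests therefore shows the
statistic behaves as designed under its own assumptions, not that any
particular biological dataset will yield a given number of reporters.

### The planted-recovery benchmark

`planted_recovery` is the standard validation run (model 500 genes / 100
metabolites / 20 pathways; 3 replicates per group). Its design follows
three constraints, in order:

1. *Pathway-coherent planting.* Targets are the multi-gene member
   metabolites of 3 randomly chosen pathways (drawn among pathways whose
   multi-gene members form a strict majority), topped up with random
   multi-gene metabolites to 25 targets; the complete neighbor gene set of
   every target is planted. This mirrors a real perturbation (whole
   pathways shift) and guarantees the majority rule recovers both the
   targets and the target pathways as truth.
2. *Planted fraction.* The corrected scores are calibrated, so under any
   planting a fraction α of the null metabolites is called by chance;
   with N_planted true and N_null null metabolites the false-discovery
   floor is `α·N_null / (N_planted + α·N_null)`. An FDR bound of 0.1 at
   α = 0.05 therefore *requires* a planted fraction of roughly a quarter
   to a third of metabolites — 25 targets out of 100 (plus majority-rule
   spillover).
3. *Effect size.* The benchmark's planted effect is 6 within-group
   standard deviations, which at 3 replicates per group drives planted
   gene p-values to ≈ 0.001. A large planted fraction raises the
   background pool's μ_k and σ_k — the method deliberately normalizes
   global shifts away — so weaker effects (e.g. 4 sd ≈ p 0.008) leave
   two-gene reporters under-powered against the inflated background.
   The generator's own default effect remains 4 sd, a moderate and
   realistic stress response, and the end-to-end test of the generator
   uses it with a smaller planted set.

Metabolites with a single associated gene are not eligible as targets: a
k = 1 reporter is statistically identical to its one gene, so planting it
tests nothing about aggregation.

## 7. Numerical choices and degenerate inputs

- p-value clamp at 1e-15 keeps Z finite; clamp counts are reported.
- Background σ uses ddof = 0; exhaustive enumeration is exact and tested
  against brute force at 1e-12.
- Quantile normalization uses a stable mergesort ranking; tie groups are
  averaged per column.
- Girvan–Newman and MCODE break all ties lexicographically on string ids,
  making every run reproducible.
- Edgeless graphs: community detection and modularity raise; metric
  panels return NaN path statistics; MCODE returns an empty list.
- All stochastic operations take explicit seeds; the pipeline derives
  per-stage sub-seeds from one master seed.

## 8. Known limitations

- The reporter statistic assumes unit scores are i.i.d. under the null;
  genes shared between metabolites violate independence mildly and the
  calibration test bounds the practical effect.
- The background is estimated per size k by Monte Carlo; extremely small
  pools (|pool| close to k) have few distinct subsets and the correction
  degenerates (k = |pool| is refused).
- The mean aggregation mode is provided for literal reproduction of the
  printed formula but is not calibrated across k; the Stouffer mode is
  the default for all pipelines.
- Bootstrap KS p-values keep `x_min` fixed during refitting; a full
  joint (γ, x_min) bootstrap would be slightly more conservative.
- Tripartite density uses the pooled denominator; a bipartite-feasible
  denominator variant is a one-line change but alters comparability with
  the panel layout used here.
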