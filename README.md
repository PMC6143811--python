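# reporternet

Reporter metabolite and reporter pathway analysis of transcriptome data on
genome-scale metabolic associations, with downstream tripartite
gene–metabolite–pathway network topology tools.

## The problem

Differential-expression analysis ranks genes one at a time, but metabolic
regulation is a neighborhood phenomenon: the enzymes that produce and
consume a metabolite tend to shift together, even when no single transcript
clears a significance threshold. Reporter analysis turns per-gene p-values
into metabolite-level and pathway-level statistics by aggregating over the
gene–metabolite associations of a genome-scale metabolic model, and judges
each aggregate against an empirical background null, so that highly
connected entities are not rewarded for connectivity alone.

`reporternet` is aimed at systems biologists who have (i) a control vs.
treatment expression matrix (e.g. a stress time course) and (ii)
gene↔metabolite and metabolite↔pathway association tables (AraCyc-style
exports, or any flat TSV). Everything runs offline; a synthetic-data module
generates models and replicated expression with planted signal so the whole
pipeline is testable without any download.

## The statistic

Per gene, a two-sample pooled-variance t-test gives a p-value, converted to
a standard-normal score `Z_i = Φ⁻¹(1 − p_i)`. Isozymes catalysing the same
reaction are collapsed by the minimum p-value. A metabolite with `k`
associated scoring units gets the Stouffer aggregate

    Z_metabolite = Σ Z_i / √k

whose null is standard normal independent of `k` (an arithmetic-mean mode,
`Σ Z_i / k`, is available for strict-literal reproduction; its null shrinks
with `k`). The aggregate is standardized against an empirical background —
the mean `μ_k` and standard deviation `σ_k` of the same aggregate over
10,000 random size-`k` subsets of all unit scores:

    Z′_metabolite = (Z_metabolite − μ_k) / σ_k,   p = 1 − Φ(Z′_metabolite)

Entities with `p ≤ 0.05` are the *reporter metabolites*. Pathways are
scored identically from their member metabolites' corrected scores.
Ubiquitous currency metabolites (ATP, NADH, water, proton, …) are excluded
before scoring. Significant genes, metabolites and pathways then form an
*open tripartite network* (edges only gene–metabolite and
metabolite–pathway), for which the package computes the standard topology
panel (density, clustering, diameter, path length), time-point overlays
(exclusive/shared nodes and edges), power-law degree-distribution tests
(log-log regression γ/R² side by side with MLE + KS bootstrap),
Fast-Greedy and Girvan–Newman modularity, and MCODE dense-cluster
extraction.

## Worked example

```python
import numpy as np
from reporternet import (
    make_model, make_truth_for_targets, make_expression,
    ttest_pvalues, collapse_isozymes, score_metabolites, score_pathways,
    significant, build_tripartite, network_metrics,
)

model = make_model(n_genes=500, n_metabolites=100, n_pathways=20, seed=0)
truth = make_truth_for_targets(model, effect_size=6.0, seed=1)
control, treatment, truth = make_expression(model, truth)

diff = ttest_pvalues(control, treatment)
units = collapse_isozymes(diff["p"], model)
mets = score_metabolites(units, model, n_samples=10_000, seed=2)
paths = score_pathways(mets, model, n_samples=10_000, seed=3)

print("reporter metabolites:", len(significant(mets)), "of", len(mets))
print("reporter pathways:   ", len(significant(paths)), "of", len(paths))
print(mets.sort_values("p").head(3).round(3))

net = build_tripartite(diff["p"], mets, paths, model, time_label="t1")
m = network_metrics(net.to_graph())
print(f"tripartite: {m.total_nodes} nodes, {m.total_edges} edges, "
      f"density {m.density:.3f}, diameter {m.diameter:.0f}")
```

Output:

```
reporter metabolites: 31 of 100
reporter pathways:    5 of 20
               k  z_raw   mu_k  sigma_k  z_corrected    p
metabolite_id
m0012          6  7.917  1.279    1.436        4.622  0.0
m0040          6  7.635  1.279    1.436        4.426  0.0
m0038          5  7.446  1.166    1.432        4.385  0.0
tripartite: 146 nodes, 119 edges, density 0.011, diameter 14
```

Reading it: 31 of 100 metabolites score `p ≤ 0.05`; the top hits carry six
neighboring genes whose Stouffer aggregate (`z_raw ≈ 7.9`) stands 4.6
background standard deviations above the size-6 null mean. Of the 29
metabolites this simulation actually planted, 28 are recovered. The
significant entities form a sparse (density 0.011), elongated (diameter 14)
tripartite graph.

Two shell commands wrap the same pipeline for TSV inputs:

```sh
reporternet simulate --seed 0 --out-dir data/          # synthetic dataset + truth
reporternet score --pvalues data/gene_pvalues.tsv \
    --gene-metabolite data/gene_metabolite.tsv \
    --metabolite-pathway data/metabolite_pathway.tsv --out-dir out/
```

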