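"""Synthetic metabolic models and replicated expression data.

Every pipeline stage is testable offline: :func:`make_model` draws a
random bipartite gene–metabolite / metabolite–pathway association
structure, :func:`make_expression` produces replicated control/treatment
intensity matrices with a planted differentially expressed gene subset,
and :func:`make_null_pvalues` feeds the reporter layer directly with
uniform nulls.  All generators are pure functions of their parameters and
seed.

The planted ground truth follows the neighborhood logic of reporter
scoring: a metabolite (pathway) counts as planted when more than half of
its neighbor genes (member metabolites) are planted, because
majority-planted neighborhoods are what aggregation can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .expression import CONTROL, TREATMENT, ExpressionMatrix
from .model import MetabolicModel

#: Baseline log2-intensity distribution mimicking microarray ranges.
BASELINE_MEAN = 8.0
BASELINE_SD = 2.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a planted-signal simulation."""

    planted_genes: frozenset[str]
    effect_size: float
    n_replicates: int
    noise_sd: float
    seed: int
    planted_metabolites: frozenset[str] = field(default_factory=frozenset)
    planted_pathways: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.n_replicates < 2:
            raise ValidationError("need at least 2 replicates per group")


def make_model(
    n_genes: int,
    n_metabolites: int,
    n_pathways: int,
    mean_genes_per_metabolite: float = 3.0,
    mean_metabolites_per_pathway: float = 5.0,
    seed: int = 0,
) -> MetabolicModel:
    """Random flat metabolic model with Poisson-distributed degrees.

    Each metabolite links to max(1, Poisson(mean)) distinct genes and each
    pathway to max(1, Poisson(mean)) distinct metabolites, so every
    metabolite has a gene and every pathway a member.  Deterministic given
    the seed.
    """
    for name, v in (("n_genes", n_genes), ("n_metabolites", n_metabolites), ("n_pathways", n_pathways)):
        if v < 1:
            raise ValidationError(f"{name} must be >= 1")
    if mean_genes_per_metabolite > n_genes:
        raise ValidationError("mean_genes_per_metabolite exceeds the gene pool")
    if mean_metabolites_per_pathway > n_metabolites:
        raise ValidationError("mean_metabolites_per_pathway exceeds the metabolite pool")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    mets = [f"m{i:04d}" for i in range(n_metabolites)]
    paths = [f"pw{i:03d}" for i in range(n_pathways)]
    gm = set()
    for m in mets:
        d = min(max(1, rng.poisson(mean_genes_per_metabolite)), n_genes)
        for g in rng.choice(n_genes, size=d, replace=False):
            gm.add((genes[g], m))
    mp = set()
    for p in paths:
        d = min(max(1, rng.poisson(mean_metabolites_per_pathway)), n_metabolites)
        for m in rng.choice(n_metabolites, size=d, replace=False):
            mp.add((mets[m], p))
    return MetabolicModel(
        genes=frozenset(genes),
        metabolites=frozenset(mets),
        pathways=frozenset(paths),
        gene_metabolite=frozenset(gm),
        metabolite_pathway=frozenset(mp),
    )


def derive_planted(model: MetabolicModel, planted_genes: frozenset[str]) -> tuple[frozenset[str], frozenset[str]]:
    """Majority rule: entities whose neighbors are >50% planted."""
    mets = set()
    for m in model.scoreable_metabolites:
        nb = model.neighbors(m)
        if nb and sum(g in planted_genes for g in nb) * 2 > len(nb):
            mets.add(m)
    paths = set()
    for p in model.pathways:
        members = model.pathway_members(p)
        if members and sum(m in mets for m in members) * 2 > len(members):
            paths.add(p)
    return frozenset(mets), frozenset(paths)


def make_expression(
    model: MetabolicModel,
    truth: SyntheticTruth,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Replicated control/treatment matrices with a planted mean shift.

    Per gene: baseline ~ Normal(8, 2) on the log2 scale; control and
    treatment replicates ~ Normal(baseline, noise_sd), except planted
    genes whose treatment mean is shifted by effect_size x noise_sd.
    Returns the truth with planted metabolites/pathways filled in by the
    majority rule.
    """
    missing = truth.planted_genes - model.genes
    if missing:
        raise ValidationError(f"planted genes absent from model: {sorted(missing)[:5]}")
    rng = np.random.default_rng(truth.seed)
    genes = sorted(model.genes)
    n = len(genes)
    r = truth.n_replicates
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n)
    ctl = baseline[:, None] + rng.normal(0.0, truth.noise_sd, size=(n, r))
    shift = np.array([truth.effect_size * truth.noise_sd if g in truth.planted_genes else 0.0 for g in genes])
    trt = (baseline + shift)[:, None] + rng.normal(0.0, truth.noise_sd, size=(n, r))
    ctl_ids = [f"ctl_{i + 1}" for i in range(r)]
    trt_ids = [f"trt_{i + 1}" for i in range(r)]
    sheet_c = pd.DataFrame({"group": CONTROL, "time_point": "t1"}, index=pd.Index(ctl_ids, name="sample_id"))
    sheet_t = pd.DataFrame({"group": TREATMENT, "time_point": "t1"}, index=pd.Index(trt_ids, name="sample_id"))
    control = ExpressionMatrix(pd.DataFrame(ctl, index=genes, columns=ctl_ids), sheet_c)
    treatment = ExpressionMatrix(pd.DataFrame(trt, index=genes, columns=trt_ids), sheet_t)
    mets, paths = derive_planted(model, truth.planted_genes)
    return control, treatment, replace(truth, planted_metabolites=mets, planted_pathways=paths)


def make_truth_for_targets(
    model: MetabolicModel,
    n_target_metabolites: int = 25,
    n_target_pathways: int = 3,
    effect_size: float = 4.0,
    n_replicates: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant the complete neighbor gene sets of a coherent target group.

    Targets are the scoreable member metabolites of ``n_target_pathways``
    randomly chosen pathways (so the planted signal is pathway-coherent,
    as a real perturbation would be), topped up with extra random
    metabolites until ``n_target_metabolites`` targets exist.  Every
    neighbor gene of every target is planted, so the majority rule
    recovers the targets and the target pathways as ground truth.

    Only metabolites with at least two associated genes are eligible as
    targets: reporter scoring aggregates neighborhoods, and a single-gene
    metabolite is statistically identical to its one gene, so the
    benchmark plants signal where aggregation is actually exercised.
    Target pathways are drawn among pathways whose multi-gene members form
    a strict majority, which guarantees the chosen pathways are themselves
    recovered as planted truth.
    """
    rng = np.random.default_rng(seed)
    multi = {m for m in model.scoreable_metabolites if len(model.neighbors(m)) >= 2}
    eligible_paths = sorted(
        p for p in model.pathways
        if len(model.pathway_members(p)) >= 2
        and 2 * len(model.pathway_members(p) & multi) > len(model.pathway_members(p))
    )
    if len(eligible_paths) < n_target_pathways:
        raise ValidationError(
            "not enough pathways with a multi-gene-member majority to plant targets"
        )
    chosen = rng.choice(len(eligible_paths), size=n_target_pathways, replace=False)
    targets = set()
    for i in chosen:
        targets |= model.pathway_members(eligible_paths[i]) & multi
    eligible = sorted(multi - targets)
    n_extra = max(0, n_target_metabolites - len(targets))
    if n_extra > len(eligible):
        raise ValidationError("not enough multi-gene metabolites to plant targets")
    if n_extra:
        for i in rng.choice(len(eligible), size=n_extra, replace=False):
            targets.add(eligible[i])
    planted = frozenset(g for m in targets for g in model.neighbors(m))
    return SyntheticTruth(
        planted_genes=planted,
        effect_size=effect_size,
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_null_pvalues(n: int, seed: int = 0) -> pd.Series:
    """n i.i.d. Uniform(0, 1) p-values indexed g00000, g00001, ..."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.Series(rng.random(n), index=[f"g{i:05d}" for i in range(n)], name="p")


# ------------------------------------------------------------ benchmark


def planted_recovery(
    n_genes: int = 500,
    n_metabolites: int = 100,
    n_pathways: int = 20,
    mean_genes_per_metabolite: float = 3.0,
    mean_metabolites_per_pathway: float = 5.0,
    n_target_metabolites: int = 25,
    effect_size: float = 6.0,
    n_replicates: int = 3,
    alpha: float = 0.05,
    n_samples: int = 10_000,
    seed: int = 0,
) -> dict:
    """One end-to-end planted-signal run; returns recovery diagnostics.

    The pipeline (t-tests -> unit scores -> reporter metabolites ->
    reporter pathways) runs on a fresh model/expression draw and is scored
    against the majority-rule planted truth:
    sensitivity = called & planted / planted, fdr = called & not planted /
    called, plus the rank of the best planted pathway by p-value.
    """
    from .expression import ttest_pvalues
    from .reporter import collapse_isozymes, score_metabolites, score_pathways, significant

    model = make_model(
        n_genes, n_metabolites, n_pathways,
        mean_genes_per_metabolite, mean_metabolites_per_pathway, seed=seed,
    )
    truth = make_truth_for_targets(
        model,
        n_target_metabolites=n_target_metabolites,
        effect_size=effect_size,
        n_replicates=n_replicates,
        seed=seed + 1,
    )
    control, treatment, truth = make_expression(model, truth)
    diff = ttest_pvalues(control, treatment)
    units = collapse_isozymes(diff["p"], model)
    met_scores = score_metabolites(units, model, n_samples=n_samples, seed=seed + 2)
    path_scores = score_pathways(met_scores, model, n_samples=n_samples, seed=seed + 3)
    called = set(significant(met_scores, alpha).index)
    planted = set(truth.planted_metabolites)
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = (len(called) - tp) / len(called) if called else 0.0
    ranked = path_scores.sort_values("p").index.tolist()
    planted_path_rank = min(
        (ranked.index(p) + 1 for p in truth.planted_pathways if p in ranked),
        default=None,
    )
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_called": len(called),
        "n_planted": len(planted),
        "best_planted_pathway_rank": planted_path_rank,
        "truth": truth,
        "met_scores": met_scores,
        "path_scores": path_scores,
        "model": model,
        "gene_pvalues": diff["p"],
    }


def null_false_positive_rate(
    n_genes: int = 3000,
    n_metabolites: int = 600,
    n_pathways: int = 30,
    alpha: float = 0.05,
    n_samples: int = 10_000,
    seed: int = 0,
) -> dict:
    """Reporter-metabolite false-positive fraction under uniform gene p-values.

    With no signal anywhere, the corrected scores should be calibrated:
    the fraction of metabolites called at ``alpha`` should match ``alpha``
    up to binomial noise.  Returns the fraction, the number of scored
    metabolites, and the binomial standard error sqrt(alpha(1-alpha)/n).
    """
    from .reporter import collapse_isozymes, score_metabolites

    model = make_model(n_genes, n_metabolites, n_pathways, seed=seed)
    pv = make_null_pvalues(n_genes, seed=seed + 1)
    units = collapse_isozymes(pv, model)
    mets = score_metabolites(units, model, n_samples=n_samples, seed=seed + 2)
    n = len(mets)
    return {
        "fraction": float((mets["p"] <= alpha).mean()),
        "n_metabolites": n,
        "se": float(np.sqrt(alpha * (1 - alpha) / n)),
    }
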