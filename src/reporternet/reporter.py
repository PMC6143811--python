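"""Reporter metabolite and reporter pathway scoring.

Per-gene differential-expression p-values are converted to standard-normal
Z scores with the inverse normal CDF, collapsed over isozymes (minimum p
per reaction when a reaction layer exists), aggregated over each
metabolite's neighboring scoring units, and standardized against an
empirical background null: the mean mu_k and standard deviation sigma_k of
the same aggregate over random size-k subsets of the full score pool
(10,000 sampling rounds by default).  Pathways are scored identically from
their member metabolites' corrected scores.  A corrected score

    Z' = (Z_raw - mu_k) / sigma_k

is finally mapped to an upper-tail normal p-value; entities with p <= 0.05
are the reporter metabolites / reporter pathways.

Two aggregation modes are provided.  ``sqrt_k`` (default) divides the sum
of Z scores by sqrt(k) — the Stouffer combination, whose null is standard
normal independent of k.  ``mean`` divides by k; its null shrinks with k
and relies entirely on the background correction to stay calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateNullError, ValidationError
from .model import MetabolicModel

P_CLAMP = 1e-15

Tail = Literal["one_tailed", "two_tailed"]
Mode = Literal["sqrt_k", "mean"]


def p_to_z(p, tail: Tail = "one_tailed"):
    """Inverse-normal conversion of p-values to Z scores.

    ``one_tailed`` maps p to the (1 - p) normal quantile; ``two_tailed``
    maps p to the (1 - p/2) quantile, so p = 0.05 gives Z = 1.96.  Values
    are clamped to [1e-15, 1 - 1e-15] before conversion.  Accepts scalars
    or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    clamped = np.clip(arr, P_CLAMP, 1.0 - P_CLAMP)
    if tail == "one_tailed":
        z = stats.norm.isf(clamped)
    elif tail == "two_tailed":
        z = stats.norm.isf(clamped / 2.0)
    else:
        raise ValidationError(f"unknown tail convention {tail!r}")
    return float(z) if np.isscalar(p) else z


def clamp_count(p) -> int:
    """Number of p-values altered by the clamp (reported in run manifests)."""
    arr = np.asarray(p, dtype=float)
    return int(np.sum((arr < P_CLAMP) | (arr > 1.0 - P_CLAMP)))


@dataclass(frozen=True)
class GeneScores:
    """Scoring units after isozyme collapse.

    ``level`` is ``"reaction"`` when the model's reaction layer was used
    (each reaction takes the minimum p over its genes) and ``"gene"`` for
    flat models.  ``scores`` is indexed by unit id with columns ``p``, ``z``.
    """

    scores: pd.DataFrame
    level: Literal["gene", "reaction"]


def collapse_isozymes(
    gene_pvalues: Mapping[str, float] | pd.Series,
    model: MetabolicModel,
    tail: Tail = "one_tailed",
) -> GeneScores:
    """Collapse gene p-values onto scoring units (min-p over isozymes).

    With a reaction layer, a reaction catalysed by several isozymes (or an
    enzyme complex) takes the lowest p-value among its genes and units are
    reactions; otherwise units are the genes themselves.
    """
    pv = pd.Series(gene_pvalues, dtype=float)
    if len(pv) == 0:
        raise ValidationError("no gene p-values supplied")
    if model.has_reaction_layer:
        rows = {}
        for gene, rxn in model.gene_reaction:
            if gene in pv.index:
                p = float(pv[gene])
                if rxn not in rows or p < rows[rxn]:
                    rows[rxn] = p
        if not rows:
            import logging

            logging.getLogger(__name__).warning(
                "collapse_isozymes: no overlap between p-value genes and model genes"
            )
        scores = pd.Series(rows, dtype=float).sort_index()
        level = "reaction"
    else:
        scores = pv[pv.index.isin(model.genes)].sort_index()
        if scores.empty:
            import logging

            logging.getLogger(__name__).warning(
                "collapse_isozymes: no overlap between p-value genes and model genes"
            )
        level = "gene"
    df = pd.DataFrame({"p": scores})
    df["z"] = p_to_z(df["p"].to_numpy(), tail) if len(df) else np.array([])
    return GeneScores(df, level)


def aggregate(z_values: Iterable[float], mode: Mode = "sqrt_k") -> float:
    """Combine unit Z scores: sum/sqrt(k) (Stouffer, default) or sum/k."""
    z = np.asarray(list(z_values) if not isinstance(z_values, np.ndarray) else z_values, dtype=float)
    if z.size == 0:
        raise ValidationError("aggregate requires a non-empty list of z scores")
    if mode == "sqrt_k":
        return float(z.sum() / math.sqrt(z.size))
    if mode == "mean":
        return float(z.mean())
    raise ValidationError(f"unknown aggregation mode {mode!r}")


@dataclass(frozen=True)
class BackgroundNull:
    """Mean/sd of aggregate scores over random size-k subsets of a pool."""

    size: int
    mu: float
    sigma: float
    n_samples: int
    seed: int | None

    def __post_init__(self):
        if self.sigma <= 0:
            raise DegenerateNullError(self.size)


def _subset_sums(pool: np.ndarray, size: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    # k distinct indices per draw via argpartition of a random matrix:
    # uniform over size-k subsets, vectorized over all draws.
    u = rng.random((n_samples, pool.size))
    idx = np.argpartition(u, size - 1, axis=1)[:, :size]
    return pool[idx].sum(axis=1)


def background(
    pool: Iterable[float],
    size: int,
    n_samples: int = 10_000,
    seed: int | None = None,
    mode: Mode = "sqrt_k",
    exhaustive: bool = False,
) -> BackgroundNull:
    """Empirical null for aggregates of ``size`` scores drawn from ``pool``.

    Draws ``n_samples`` subsets without replacement (within a draw),
    aggregates each, and returns the mean and population standard deviation
    of the sampled aggregates.  ``exhaustive=True`` enumerates every
    C(|pool|, size) subset instead (small pools only).  Deterministic given
    ``seed``.
    """
    arr = np.asarray(list(pool) if not isinstance(pool, np.ndarray) else pool, dtype=float)
    if size < 1:
        raise ValidationError("subset size must be >= 1")
    if arr.size < size:
        raise ValidationError(f"pool of {arr.size} scores is smaller than k={size}")
    denom = math.sqrt(size) if mode == "sqrt_k" else float(size)
    if mode not in ("sqrt_k", "mean"):
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    if exhaustive:
        sums = np.array([sum(c) for c in combinations(arr, size)], dtype=float)
        n_used = sums.size
    else:
        if n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        sums = _subset_sums(arr, size, n_samples, rng)
        n_used = n_samples
    agg = sums / denom
    mu = float(agg.mean())
    sigma = float(agg.std(ddof=0))  # population sd
    if sigma == 0:
        raise DegenerateNullError(size)
    return BackgroundNull(size=size, mu=mu, sigma=sigma, n_samples=n_used, seed=seed)


class _BackgroundCache:
    """Per-size background nulls with deterministic (master seed, k) sub-seeds."""

    def __init__(self, pool: np.ndarray, n_samples: int, seed: int | None, mode: Mode):
        self.pool = pool
        self.n_samples = n_samples
        self.seed = seed
        self.mode = mode
        self._cache: dict[int, BackgroundNull] = {}

    def get(self, size: int) -> BackgroundNull:
        if size not in self._cache:
            sub_seed = None if self.seed is None else np.random.SeedSequence([self.seed, size])
            rng = np.random.default_rng(sub_seed)
            denom = math.sqrt(size) if self.mode == "sqrt_k" else float(size)
            if self.pool.size < size:
                raise ValidationError(f"pool of {self.pool.size} scores is smaller than k={size}")
            if size == self.pool.size:
                sums = np.full(1, self.pool.sum())
            else:
                sums = _subset_sums(self.pool, size, self.n_samples, rng)
            agg = sums / denom
            sigma = float(agg.std(ddof=0))
            if sigma == 0:
                raise DegenerateNullError(size)
            self._cache[size] = BackgroundNull(size, float(agg.mean()), sigma, self.n_samples, self.seed)
        return self._cache[size]


def score_metabolites(
    units: GeneScores,
    model: MetabolicModel,
    n_samples: int = 10_000,
    seed: int | None = 0,
    mode: Mode = "sqrt_k",
) -> pd.DataFrame:
    """Reporter-metabolite scores for every metabolite with scored neighbors.

    For each non-currency metabolite with k >= 1 neighbors among the
    scoring units, the raw aggregate of the neighbors' Z scores is
    standardized against the size-k background null drawn from the pool of
    all unit Z scores, and converted to an upper-tail normal p-value.
    Returns a DataFrame indexed by metabolite id with columns
    ``k, z_raw, mu_k, sigma_k, z_corrected, p``.
    """
    scores = units.scores
    if scores.empty:
        raise ValidationError("no scoring units supplied")
    z = scores["z"]
    pool = z.to_numpy(dtype=float)
    cache = _BackgroundCache(pool, n_samples, seed, mode)
    neighbor_fn = model.reaction_neighbors if units.level == "reaction" else model.neighbors
    rows = []
    for met in sorted(model.scoreable_metabolites):
        nb = [u for u in neighbor_fn(met) if u in z.index]
        if not nb:
            continue
        zs = z.loc[nb].to_numpy(dtype=float)
        z_raw = aggregate(zs, mode)
        null = cache.get(len(nb))
        z_corr = (z_raw - null.mu) / null.sigma
        rows.append((met, len(nb), z_raw, null.mu, null.sigma, z_corr, float(stats.norm.sf(z_corr))))
    df = pd.DataFrame(
        rows, columns=["metabolite_id", "k", "z_raw", "mu_k", "sigma_k", "z_corrected", "p"]
    ).set_index("metabolite_id")
    return df


def score_pathways(
    met_scores: pd.DataFrame,
    model: MetabolicModel,
    n_samples: int = 10_000,
    seed: int | None = 0,
    mode: Mode = "sqrt_k",
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Reporter-pathway scores from member metabolites' (corrected) scores.

    The background pool is the corrected Z of every scored metabolite
    (``use_corrected=False`` switches both members and pool to raw Z).
    Returns a DataFrame indexed by pathway id with columns
    ``n, z_raw, mu_n, sigma_n, z_corrected, p``.
    """
    if met_scores.empty:
        raise ValidationError("no metabolite scores supplied")
    col = "z_corrected" if use_corrected else "z_raw"
    z = met_scores[col]
    pool = z.to_numpy(dtype=float)
    cache = _BackgroundCache(pool, n_samples, seed, mode)
    rows = []
    for pw in sorted(model.pathways):
        members = [m for m in model.pathway_members(pw) if m in z.index]
        if not members:
            continue
        z_raw = aggregate(z.loc[members].to_numpy(dtype=float), mode)
        null = cache.get(len(members))
        z_corr = (z_raw - null.mu) / null.sigma
        rows.append((pw, len(members), z_raw, null.mu, null.sigma, z_corr, float(stats.norm.sf(z_corr))))
    return pd.DataFrame(
        rows, columns=["pathway_id", "n", "z_raw", "mu_n", "sigma_n", "z_corrected", "p"]
    ).set_index("pathway_id")


def significant(scores: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Records with p <= alpha (inclusive, matching the P <= 0.05 rule)."""
    if "p" not in scores.columns:
        raise ValidationError("scores frame lacks a 'p' column")
    return scores[scores["p"] <= alpha]
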