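"""Degree-distribution statistics and graph clustering.

Scale-free behavior is assessed two independent ways, reported side by
side and never conflated: (i) ordinary least squares on log P(k) vs log k,
whose negative slope is the regression exponent gamma with its R^2, and
(ii) maximum-likelihood fitting of P(k) ~ k^-gamma above a lower cutoff
x_min, with a Kolmogorov–Smirnov distance between fitted and empirical
distributions and a semi-parametric bootstrap p-value for the hypothesis
that the data were drawn from the fitted power law.  Barabási–Albert
preferential-attachment graphs serve as scale-free reference networks.

Community structure is quantified by modularity Q via fast-greedy
agglomeration (Clauset–Newman–Moore, through igraph) and the
Girvan–Newman edge-betweenness removal process; dense subgraphs are
extracted with the MCODE seeded-expansion algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import zeta

from .exceptions import InsufficientDataError, ValidationError

# --------------------------------------------------------------- degrees


def degree_distribution(graph: nx.Graph) -> dict[int, float]:
    """Empirical P(k) over observed degrees; probabilities sum to 1.

    Zero-degree nodes are part of the denominator (and of the support).
    """
    if graph.number_of_nodes() < 1:
        raise ValidationError("degree_distribution requires at least one node")
    degrees = [d for _, d in graph.degree()]
    n = len(degrees)
    counts: dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    return {k: c / n for k, c in sorted(counts.items())}


def powerlaw_regression(dist: dict[int, float]) -> tuple[float, float]:
    """OLS on (log k, log P(k)); returns (gamma = -slope, R^2).

    Degree 0 and zero-probability entries are excluded (log undefined); at
    least 3 usable points are required.
    """
    pts = [(k, p) for k, p in dist.items() if k >= 1 and p > 0]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"power-law regression needs >= 3 usable (k, P(k)) points, got {len(pts)}"
        )
    logk = np.log([k for k, _ in pts])
    logp = np.log([p for _, p in pts])
    res = stats.linregress(logk, logp)
    return float(-res.slope), float(res.rvalue**2)


# --------------------------------------------------------------- MLE fit


@dataclass(frozen=True)
class PowerLawFit:
    """Joint report of the regression and maximum-likelihood fits."""

    gamma_mle: float
    log_likelihood: float
    ks_stat: float
    ks_p: Optional[float]
    x_min: float
    n_tail: int
    discrete: bool
    n_bootstrap: int
    gamma_regression: Optional[float] = None
    r_squared: Optional[float] = None

    @property
    def ks_p_label(self) -> str:
        """Bootstrap zeroes are reported as a bound, not as exactly 0."""
        if self.ks_p is None:
            return "NA"
        if self.ks_p == 0 and self.n_bootstrap > 0:
            return f"<{1.0 / self.n_bootstrap:g}"
        return f"{self.ks_p:g}"


def _fit_gamma(x: np.ndarray, x_min: float, discrete: bool) -> float:
    # Continuous MLE: 1 + n / sum ln(x/x_min).  For integer data the
    # standard continuous approximation shifts the cutoff by 0.5.
    shift = x_min - 0.5 if discrete else x_min
    s = np.log(x / shift).sum()
    if s <= 0:
        raise ValidationError("divergent MLE: degree values carry no spread above x_min")
    return 1.0 + x.size / s


def _loglik(x: np.ndarray, gamma: float, x_min: float, discrete: bool) -> float:
    n = x.size
    if discrete:
        return float(-gamma * np.log(x).sum() - n * math.log(zeta(gamma, x_min)))
    return float(n * math.log((gamma - 1) / x_min) - gamma * np.log(x / x_min).sum())


def _ks(x: np.ndarray, gamma: float, x_min: float, discrete: bool) -> float:
    xs = np.sort(x)
    n = xs.size
    if discrete:
        support = np.arange(int(x_min), int(xs.max()) + 1)
        pmf = support.astype(float) ** (-gamma) / zeta(gamma, x_min)
        cdf_at = np.cumsum(pmf)
        cdf = cdf_at[np.searchsorted(support, xs)]
        ecdf_hi = np.arange(1, n + 1) / n
        # step ECDF vs step CDF: compare at observed points only
        ecdf_lo = np.searchsorted(xs, xs, side="left") / n
        return float(max(np.abs(ecdf_hi - cdf).max(), np.abs(ecdf_lo - (cdf - pmf[np.searchsorted(support, xs)])).max()))
    cdf = 1.0 - (xs / x_min) ** (1.0 - gamma)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.abs(ecdf_hi - cdf).max(), np.abs(ecdf_lo - cdf).max()))


def _sample_powerlaw(n: int, gamma: float, x_min: float, discrete: bool, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    if discrete:
        # Clauset et al.'s continuous approximation to the discrete law
        return np.floor((x_min - 0.5) * (1.0 - u) ** (-1.0 / (gamma - 1.0)) + 0.5)
    return x_min * (1.0 - u) ** (-1.0 / (gamma - 1.0))


def powerlaw_mle(
    degrees: Sequence[float],
    x_min: Union[float, str] = 1,
    discrete: Optional[bool] = None,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
    min_tail: int = 10,
) -> PowerLawFit:
    """Maximum-likelihood power-law fit with KS goodness of fit.

    ``x_min`` is the lower cutoff (values below it are discarded before
    fitting); ``"auto"`` scans the distinct observed values and keeps the
    cutoff minimizing the KS distance.  ``discrete`` defaults to True when
    every value is an integer; discrete data use the continuous
    approximation gamma = 1 + n / sum ln(x_i / (x_min - 0.5)).  The KS
    p-value comes from ``n_bootstrap`` samples of size n drawn from the
    fitted law, each refitted before measuring its KS distance
    (``n_bootstrap=0`` skips the bootstrap and reports None).
    """
    x_all = np.asarray(degrees, dtype=float)
    x_all = x_all[np.isfinite(x_all)]
    if discrete is None:
        discrete = bool(np.all(x_all == np.round(x_all)))

    def tail(cut: float) -> np.ndarray:
        return x_all[x_all >= cut]

    if isinstance(x_min, str):
        if x_min != "auto":
            raise ValidationError(f"x_min must be a number or 'auto', got {x_min!r}")
        candidates = sorted({float(v) for v in x_all if v >= 1})[:-1] or [1.0]
        best = None
        for cut in candidates:
            xt = tail(cut)
            if xt.size < min_tail or np.all(xt == xt[0]):
                continue
            g = _fit_gamma(xt, cut, discrete)
            d = _ks(xt, g, cut, discrete)
            if best is None or d < best[0]:
                best = (d, cut, g, xt)
        if best is None:
            raise InsufficientDataError("no candidate x_min leaves enough tail data")
        ks_stat, xm, gamma, x = best
    else:
        xm = float(x_min)
        if xm < 1:
            raise ValidationError("x_min must be >= 1")
        x = tail(xm)
        if x.size < min_tail:
            raise InsufficientDataError(f"need >= {min_tail} values >= x_min, got {x.size}")
        if np.all(x == x[0]):
            raise ValidationError("divergent MLE: all values above x_min are equal")
        gamma = _fit_gamma(x, xm, discrete)
        ks_stat = _ks(x, gamma, xm, discrete)

    loglik = _loglik(x, gamma, xm, discrete)

    ks_p: Optional[float] = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        worse = 0
        for _ in range(n_bootstrap):
            xb = _sample_powerlaw(x.size, gamma, xm, discrete, rng)
            xb = xb[xb >= xm]
            if xb.size < 2 or np.all(xb == xb[0]):
                continue
            gb = _fit_gamma(xb, xm, discrete)
            if _ks(xb, gb, xm, discrete) >= ks_stat:
                worse += 1
        ks_p = worse / n_bootstrap

    gamma_reg = r2 = None
    try:
        counts: dict[int, float] = {}
        for v in x_all:
            counts[int(v)] = counts.get(int(v), 0) + 1
        dist = {k: c / x_all.size for k, c in counts.items()}
        gamma_reg, r2 = powerlaw_regression(dist)
    except (InsufficientDataError, ValidationError):
        pass

    return PowerLawFit(
        gamma_mle=float(gamma),
        log_likelihood=loglik,
        ks_stat=float(ks_stat),
        ks_p=ks_p,
        x_min=xm,
        n_tail=int(x.size),
        discrete=discrete,
        n_bootstrap=n_bootstrap,
        gamma_regression=gamma_reg,
        r_squared=r2,
    )


def fit_report(fits: dict) -> "pd.DataFrame":
    """Power-law fit panel, one column per labelled graph/fit.

    Rows: KS fit statistic, P-value, Gamma (regression), Gamma (MLE),
    Log-likelihood, R^2.  Bootstrap-zero p-values appear as '<1/B'.
    """
    import pandas as pd

    cols = {}
    for label, fit in fits.items():
        cols[str(label)] = {
            "ks_stat": fit.ks_stat,
            "ks_p": fit.ks_p_label,
            "gamma_regression": fit.gamma_regression,
            "gamma_mle": fit.gamma_mle,
            "log_likelihood": fit.log_likelihood,
            "r_squared": fit.r_squared,
        }
    order = ["ks_stat", "ks_p", "gamma_regression", "gamma_mle", "log_likelihood", "r_squared"]
    return pd.DataFrame(cols).reindex(order)


def barabasi_graph(n: int, m: int, seed: int) -> nx.Graph:
    """Preferential-attachment reference graph (n nodes, m edges per new node)."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m >= n:
        raise ValidationError(f"m={m} must be smaller than n={n}")
    return nx.barabasi_albert_graph(n, m, seed=seed)


# --------------------------------------------------------------- modularity


def modularity(graph: nx.Graph, communities: dict) -> float:
    """Q = sum_c [e_c/m - (d_c/2m)^2] on the simple undirected graph."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValidationError("modularity undefined for edgeless graphs")
    labels = set(communities.values())
    q = 0.0
    for c in labels:
        members = {v for v, lab in communities.items() if lab == c}
        e_c = sum(1 for a, b in graph.edges() if a in members and b in members)
        d_c = sum(d for v, d in graph.degree() if v in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


@dataclass
class ModularityResult:
    """Best-Q partition of a graph plus the merge/split sequence behind it."""

    algorithm: str
    communities: dict
    q: float
    dendrogram: list = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.communities.values()))

    def to_frame(self):
        """Membership table (node_id, community), sorted by node id."""
        import pandas as pd

        return pd.DataFrame(
            sorted(self.communities.items(), key=lambda kv: str(kv[0])),
            columns=["node_id", "community"],
        )


def _check_community_input(graph: nx.Graph) -> None:
    if graph.is_multigraph():
        raise ValidationError("multigraphs are not supported")
    if graph.number_of_edges() == 0:
        raise ValidationError("community detection requires at least one edge")


def fastgreedy(graph: nx.Graph) -> ModularityResult:
    """Clauset–Newman–Moore greedy modularity agglomeration (via igraph).

    Returns the partition at the maximal-Q cut of the merge dendrogram; Q
    is re-evaluated with the direct modularity formula.
    """
    import igraph as ig

    _check_community_input(graph)
    nodes = sorted(graph.nodes(), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[a], index[b]) for a, b in graph.edges()])
    dend = g.community_fastgreedy()
    clustering = dend.as_clustering()
    communities = {nodes[i]: c for i, c in enumerate(clustering.membership)}
    return ModularityResult(
        algorithm="fgc",
        communities=communities,
        q=modularity(graph, communities),
        dendrogram=[(nodes[a] if a < len(nodes) else a, nodes[b] if b < len(nodes) else b) for a, b in dend.merges],
    )


def girvan_newman(graph: nx.Graph) -> ModularityResult:
    """Edge-betweenness removal with max-Q partition selection.

    Repeatedly removes the edge of highest betweenness (recomputed after
    every removal; ties broken by lexicographically smallest edge id) and
    scores the component partition after each split by modularity on the
    ORIGINAL graph.  Returns the first partition attaining the maximal Q.
    """
    _check_community_input(graph)
    work = nx.Graph(graph)
    removed: list[tuple] = []

    def partition_of(g: nx.Graph) -> dict:
        return {v: i for i, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(map(str, c)))) for v in comp}

    best_part = partition_of(work)
    best_q = modularity(graph, best_part)
    n_comps = len(set(best_part.values()))
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, normalized=False)
        target = min(eb, key=lambda e: (-eb[e], tuple(sorted(map(str, e)))))
        work.remove_edge(*target)
        removed.append(tuple(sorted(map(str, target))))
        part = partition_of(work)
        k = len(set(part.values()))
        if k > n_comps:  # a split happened: score this partition
            n_comps = k
            q = modularity(graph, part)
            if q > best_q + 1e-12:
                best_q = q
                best_part = part
    return ModularityResult(algorithm="ng", communities=best_part, q=best_q, dendrogram=removed)


# --------------------------------------------------------------- MCODE


@dataclass(frozen=True)
class McodeCluster:
    """A dense subgraph found by MCODE; score = density x size."""

    members: frozenset
    seed: object
    score: float

    @property
    def size(self) -> int:
        return len(self.members)


def _subgraph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(graph: nx.Graph) -> dict:
    # weight(v) = k_max(N[v]) * density of the highest k-core of N[v]
    weights = {}
    for v in graph.nodes():
        nbhd = graph.subgraph(list(graph.neighbors(v)) + [v])
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_nums = nx.core_number(nbhd)
        k_max = max(core_nums.values())
        core = nbhd.subgraph([u for u, c in core_nums.items() if c >= k_max])
        weights[v] = k_max * _subgraph_density(core)
    return weights


def mcode(
    graph: nx.Graph,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density_cutoff: float = 0.5,
    max_depth: int = 100,
) -> list[McodeCluster]:
    """MCODE dense-cluster extraction with the published default cutoffs.

    Vertices are weighted by the core-clustering coefficient (density of
    the highest k-core of the closed neighborhood) times the highest core
    number; clusters grow outward from the highest-weight unused seed,
    admitting vertices whose weight is within ``node_score_cutoff`` of the
    seed weight, to at most ``max_depth`` hops.  Post-processing discards
    clusters without a ``k_core``-core, ``haircut`` trims singly connected
    members (2-core), and ``fluff`` optionally adds dense halo neighbors.
    Clusters are ranked by density x size.
    """
    if graph.is_multigraph():
        raise ValidationError("MCODE requires a simple graph")
    weights = _vertex_weights(graph)
    order = sorted(graph.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    clusters: list[McodeCluster] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        visited.add(seed)
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in graph.neighbors(v):
                    if u not in visited and weights[u] >= threshold:
                        visited.add(u)
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        sub = graph.subgraph(members)
        core_nums = nx.core_number(sub) if sub.number_of_edges() else {v: 0 for v in members}
        if not core_nums or max(core_nums.values()) < k_core:
            continue
        if haircut:
            members = {v for v, c in core_nums.items() if c >= 2}
            sub = graph.subgraph(members)
            if seed not in members or sub.number_of_nodes() == 0:
                continue
            # keep the component containing the seed (2-coring can split)
            comp = nx.node_connected_component(sub, seed)
            members = set(comp)
            sub = graph.subgraph(members)
        if fluff:
            halo = set()
            for v in members:
                for u in graph.neighbors(v):
                    if u in members or u in halo:
                        continue
                    nb = graph.subgraph(list(graph.neighbors(u)) + [u])
                    if _subgraph_density(nb) > fluff_density_cutoff:
                        halo.add(u)
            members = members | halo
            sub = graph.subgraph(members)
        score = _subgraph_density(sub) * sub.number_of_nodes()
        clusters.append(McodeCluster(frozenset(members), seed, score))
    clusters.sort(key=lambda c: (-c.score, -c.size, str(sorted(map(str, c.members))[0])))
    return clusters


def cluster_table(clusters: list) -> "pd.DataFrame":
    """Membership table for MCODE clusters (cluster rank, node, seed flag, score)."""
    import pandas as pd

    rows = []
    for rank, c in enumerate(clusters, start=1):
        for node in sorted(c.members, key=str):
            rows.append((rank, node, node == c.seed, c.score))
    return pd.DataFrame(rows, columns=["cluster", "node_id", "is_seed", "score"])
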