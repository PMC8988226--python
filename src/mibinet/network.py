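"""Co-occurrence network inference and analysis.

The chain is: compositional (log-ratio) correlation estimation with
iterative strong-pair exclusion; a permutation-derived edge threshold
from column-shuffled null data; a positive-edge network; two-level
map-equation community detection; and betweenness-centrality keystone
identification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .feature_table import CountTable

__all__ = [
    "CorrelationEstimate",
    "NullDistribution",
    "MicrobialNetwork",
    "PartitionResult",
    "CentralitySummary",
    "sparcc",
    "permutation_threshold",
    "build_network",
    "map_equation",
    "detect_communities",
    "modularity",
    "normalized_connectance",
    "betweenness",
    "keystone_taxa",
    "neighbor_correlations",
]


@dataclass
class CorrelationEstimate:
    taxon_ids: list
    correlation: np.ndarray  # symmetric, unit diagonal, values in [-1, 1]
    n_inner_resamples: int
    exclusions: list = field(default_factory=list)  # per-resample excluded pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.correlation, index=self.taxon_ids, columns=self.taxon_ids
        )


@dataclass
class NullDistribution:
    values: np.ndarray  # pooled off-diagonal null correlations
    n_trials: int
    quantile: float
    threshold: float


@dataclass
class MicrobialNetwork:
    """Undirected weighted graph over taxa with at least one retained edge."""

    graph: nx.Graph
    threshold: float | None = None

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self):
        return [
            (u, v, float(d["weight"])) for u, v, d in self.graph.edges(data=True)
        ]


@dataclass
class PartitionResult:
    modules: dict  # node -> module id (0..K-1)
    codelength: float
    modularity: float
    n_trials: int
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.modules.values()))


@dataclass
class CentralitySummary:
    betweenness: pd.Series  # node -> normalized value in [0, 1]
    cutoff: float | None = None


# ---------------------------------------------------------------------------
# SparCC-style compositional correlation


def _variation_matrix(log_fracs: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of log(f_i / f_j), via the covariance matrix."""
    cov = np.cov(log_fracs, rowvar=False, ddof=1)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2 * cov


def _basis_correlations(
    t: np.ndarray, exclusion_threshold: float, exclusion_iterations: int
):
    """Solve the sparse-approximation basis system for one variation matrix.

    Basis variances solve M w = rowsum(T') with M = (D-2) I + 1 (ones);
    iteratively, the strongest pair with |rho| above the exclusion
    threshold is removed from the system (one pair per iteration) and it
    is re-solved.
    """
    d = t.shape[0]
    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_work = t.copy()
    excluded = []
    excluded_mask = np.zeros_like(t, dtype=bool)
    exclusion_count = np.zeros(d, dtype=int)
    rho = None
    for _ in range(exclusion_iterations + 1):
        # lstsq: exclusions can make the system rank-deficient at small D
        omega2 = np.linalg.lstsq(m, t_work.sum(axis=1), rcond=None)[0]
        omega2 = np.clip(omega2, 1e-12, None)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t) / (2 * np.outer(omega, omega))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        if len(excluded) >= exclusion_iterations:
            break
        cand = np.abs(rho.copy())
        np.fill_diagonal(cand, 0.0)
        cand[excluded_mask] = 0.0
        # taxa nearly fully excluded would make the system singular
        saturated = exclusion_count >= d - 3
        cand[saturated, :] = 0.0
        cand[:, saturated] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded.append((int(i), int(j)))
        excluded_mask[i, j] = excluded_mask[j, i] = True
        exclusion_count[i] += 1
        exclusion_count[j] += 1
        m[i, i] -= 1
        m[j, j] -= 1
        m[i, j] -= 1
        m[j, i] -= 1
        t_work[i, j] = t_work[j, i] = 0.0
    return rho, excluded


def sparcc(
    table: CountTable,
    inner_resamples: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_iterations: int = 10,
    seed=None,
) -> CorrelationEstimate:
    """Compositional correlation estimate from a count table.

    Per inner resample, per-sample fractions are drawn from a Dirichlet
    posterior with a unit pseudocount over the observed counts; the
    log-ratio variation matrix is formed and the sparse basis system is
    solved with iterative strong-pair exclusion. The element-wise median
    over resamples is returned.
    """
    if table.n_taxa < 4:
        raise ValueError("need at least 4 taxa (basis system underdetermined)")
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    all_zero = [
        t for t, c in zip(table.taxon_ids, table.counts.sum(axis=0)) if c == 0
    ]
    if all_zero:
        raise ValueError(f"taxa with all-zero counts: {all_zero}")
    rng = np.random.default_rng(seed)
    estimates = np.empty((inner_resamples, table.n_taxa, table.n_taxa))
    exclusions = []
    for r in range(inner_resamples):
        fracs = np.vstack(
            [rng.dirichlet(row + 1.0) for row in table.counts]
        )
        t = _variation_matrix(np.log(fracs))
        rho, excl = _basis_correlations(t, exclusion_threshold, exclusion_iterations)
        estimates[r] = rho
        exclusions.append(excl)
    corr = np.median(estimates, axis=0)
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return CorrelationEstimate(
        taxon_ids=list(table.taxon_ids),
        correlation=corr,
        n_inner_resamples=inner_resamples,
        exclusions=exclusions,
    )


def permutation_threshold(
    table: CountTable,
    trials: int = 1000,
    tail: float = 0.05,
    seed=None,
    **sparcc_params,
) -> NullDistribution:
    """Permutation-null edge threshold.

    Each trial independently shuffles every taxon's column across samples
    (destroying inter-taxon association, preserving marginals), re-runs
    the correlation estimator, and pools all off-diagonal values. The
    threshold is the empirical (1 - tail) quantile of the pooled null.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= tail < 1:
        raise ValueError("tail must be in [0, 1)")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(table.n_taxa, k=1)
    pooled = []
    for _ in range(trials):
        shuffled = np.column_stack(
            [rng.permutation(table.counts[:, j]) for j in range(table.n_taxa)]
        )
        perm_table = CountTable(
            list(table.sample_ids), list(table.taxon_ids), shuffled
        )
        est = sparcc(perm_table, seed=rng.integers(2**32), **sparcc_params)
        pooled.append(est.correlation[iu])
    values = np.concatenate(pooled)
    if tail == 0:
        threshold = float(values.max())
    else:
        threshold = float(np.quantile(values, 1 - tail))
    return NullDistribution(
        values=values, n_trials=trials, quantile=1 - tail, threshold=threshold
    )


# ---------------------------------------------------------------------------
# Network construction and summaries


def build_network(corr: CorrelationEstimate, threshold: float) -> MicrobialNetwork:
    """Positive-edge network: edge (i, j) iff rho_ij > threshold.
    Isolated taxa are excluded from the node set."""
    if threshold <= 0:
        raise ValueError("threshold must be positive (positive-edge network)")
    g = nx.Graph()
    d = len(corr.taxon_ids)
    for i in range(d):
        for j in range(i + 1, d):
            w = corr.correlation[i, j]
            if w > threshold:
                g.add_edge(corr.taxon_ids[i], corr.taxon_ids[j], weight=float(w))
    if g.number_of_nodes() == 0:
        warnings.warn("no correlation exceeds the threshold; network is empty")
    return MicrobialNetwork(graph=g, threshold=threshold)


def normalized_connectance(network: MicrobialNetwork) -> float:
    """Realized edges over possible undirected edges, E / (N(N-1)/2)."""
    n = network.n_nodes
    if n < 2:
        raise ValueError("connectance undefined for fewer than 2 nodes")
    return network.n_edges / (n * (n - 1) / 2)


def modularity(network: MicrobialNetwork, partition: dict) -> float:
    """Weighted Newman-Girvan modularity of ``partition``."""
    g = network.graph
    uncovered = [v for v in g.nodes if v not in partition]
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {uncovered}")
    w_total = g.size(weight="weight")
    if w_total == 0:
        return 0.0
    within = {}
    strength = {}
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        if partition[u] == partition[v]:
            within[partition[u]] = within.get(partition[u], 0.0) + w
        strength[partition[u]] = strength.get(partition[u], 0.0) + w
        strength[partition[v]] = strength.get(partition[v], 0.0) + w
    q = 0.0
    for m in set(partition[v] for v in g.nodes):
        q += within.get(m, 0.0) / w_total - (strength.get(m, 0.0) / (2 * w_total)) ** 2
    return float(q)


# ---------------------------------------------------------------------------
# Map equation


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0 else 0.0


def map_equation(network: MicrobialNetwork, partition: dict) -> float:
    """Two-level map-equation codelength (bits) of a hard partition.

    For an undirected weighted graph: node visit rates are
    p_i = strength_i / 2W; module exit rates q_m are the boundary-crossing
    weight over 2W; L = q H(Q) + sum_m p_m_around H(P_m), with
    p_m_around = q_m + sum_{i in m} p_i.
    """
    g = network.graph
    uncovered = [v for v in g.nodes if v not in partition]
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {uncovered}")
    two_w = 2.0 * g.size(weight="weight")
    if two_w == 0:
        return 0.0
    p = {v: g.degree(v, weight="weight") / two_w for v in g.nodes}
    q_m: dict = {}
    p_in: dict = {}
    for v in g.nodes:
        p_in[partition[v]] = p_in.get(partition[v], 0.0) + p[v]
        q_m.setdefault(partition[v], 0.0)
    for u, v, d in g.edges(data=True):
        if partition[u] != partition[v]:
            w = d.get("weight", 1.0) / two_w
            q_m[partition[u]] += w
            q_m[partition[v]] += w
    q = sum(q_m.values())
    index_term = _plogp(q) - sum(_plogp(x) for x in q_m.values())
    module_term = (
        -sum(_plogp(x) for x in q_m.values())
        - sum(_plogp(x) for x in p.values())
        + sum(_plogp(q_m[m] + p_in[m]) for m in q_m)
    )
    return index_term + module_term


class _MapState:
    """Mutable partition state for greedy codelength minimization.

    Tracks per-module exit rate (q_m) and internal visit rate so that the
    codelength can be recomputed from module aggregates after local moves;
    the node-level entropy term is constant.
    """

    def __init__(self, network: MicrobialNetwork):
        g = network.graph
        self.g = g
        self.two_w = 2.0 * g.size(weight="weight")
        self.p = {v: g.degree(v, weight="weight") / self.two_w for v in g.nodes}
        self.node_term = -sum(_plogp(x) for x in self.p.values())
        self.module_of = {v: i for i, v in enumerate(g.nodes)}
        self.q_m = {}
        self.p_in = {}
        for v in g.nodes:
            m = self.module_of[v]
            self.p_in[m] = self.p[v]
            self.q_m[m] = 0.0
        for u, v, d in g.edges(data=True):
            w = d.get("weight", 1.0) / self.two_w
            if self.module_of[u] != self.module_of[v]:
                self.q_m[self.module_of[u]] += w
                self.q_m[self.module_of[v]] += w

    def codelength(self) -> float:
        q = sum(self.q_m.values())
        return (
            _plogp(q)
            - 2 * sum(_plogp(x) for x in self.q_m.values())
            + self.node_term
            + sum(_plogp(self.q_m[m] + self.p_in[m]) for m in self.q_m)
        )

    def _link_to_module(self, v, module) -> float:
        w = 0.0
        for u, d in self.g[v].items():
            if self.module_of[u] == module and u != v:
                w += d.get("weight", 1.0)
        return w / self.two_w

    def move(self, v, target) -> None:
        src = self.module_of[v]
        if src == target:
            return
        w_src = self._link_to_module(v, src)
        w_tgt = self._link_to_module(v, target)
        self.q_m[src] += 2 * w_src - self.p[v]  # leaving: internal links now cross
        self.p_in[src] -= self.p[v]
        if self.p_in[src] <= 1e-15 and abs(self.q_m[src]) <= 1e-12:
            del self.p_in[src], self.q_m[src]
        self.q_m[target] = self.q_m.get(target, 0.0) + self.p[v] - 2 * w_tgt
        self.p_in[target] = self.p_in.get(target, 0.0) + self.p[v]
        self.module_of[v] = target


def detect_communities(
    network: MicrobialNetwork, trials: int = 10, seed=None
) -> PartitionResult:
    """Greedy two-level map-equation minimization with seeded restarts.

    Each restart sweeps nodes in random order, moving each to the
    neighboring module giving the largest codelength decrease, until no
    move helps; then tries merging connected module pairs; then re-sweeps.
    The best partition over restarts (and over the trivial one-module
    partition) is returned with its codelength and modularity.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    rng = np.random.default_rng(seed)
    nodes = list(network.graph.nodes)
    best_part, best_len = None, np.inf

    for _ in range(max(1, trials)):
        state = _MapState(network)
        improved = True
        while improved:
            improved = False
            # node-level sweep
            moved = True
            while moved:
                moved = False
                for v in rng.permutation(nodes):
                    current = state.codelength()
                    src = state.module_of[v]
                    candidates = {state.module_of[u] for u in state.g[v]}
                    candidates.discard(src)
                    best_delta, best_target = 0.0, None
                    for tgt in candidates:
                        state.move(v, tgt)
                        delta = state.codelength() - current
                        state.move(v, src)
                        if delta < best_delta - 1e-12:
                            best_delta, best_target = delta, tgt
                    if best_target is not None:
                        state.move(v, best_target)
                        moved = improved = True
            # module-merge sweep
            merged = True
            while merged:
                merged = False
                pairs = set()
                for u, v in state.g.edges:
                    a, b = state.module_of[u], state.module_of[v]
                    if a != b:
                        pairs.add((min(a, b), max(a, b)))
                current = state.codelength()
                best_delta, best_pair = 0.0, None
                for a, b in sorted(pairs):
                    members = [v for v in nodes if state.module_of[v] == b]
                    for v in members:
                        state.move(v, a)
                    delta = state.codelength() - current
                    for v in members:
                        state.move(v, b)
                    if delta < best_delta - 1e-12:
                        best_delta, best_pair = delta, (a, b, members)
                if best_pair is not None:
                    a, _b, members = best_pair
                    for v in members:
                        state.move(v, a)
                    merged = improved = True
        length = state.codelength()
        if length < best_len - 1e-12:
            best_len = length
            best_part = dict(state.module_of)

    one_module = {v: 0 for v in nodes}
    one_len = map_equation(network, one_module)
    if one_len < best_len - 1e-12:
        best_part, best_len = one_module, one_len

    # relabel modules 0..K-1 by node order
    remap = {}
    modules = {}
    for v in nodes:
        m = best_part[v]
        if m not in remap:
            remap[m] = len(remap)
        modules[v] = remap[m]
    return PartitionResult(
        modules=modules,
        codelength=float(best_len),
        modularity=modularity(network, modules),
        n_trials=trials,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Centrality


def betweenness(network: MicrobialNetwork) -> CentralitySummary:
    """Shortest-path betweenness on the unweighted topology (Brandes'
    accumulation), normalized by (N-1)(N-2)/2 to lie in [0, 1]."""
    g = network.graph
    n = g.number_of_nodes()
    if n < 3:
        warnings.warn("betweenness undefined for < 3 nodes; returning zeros")
        return CentralitySummary(
            betweenness=pd.Series(0.0, index=list(g.nodes), dtype=float)
        )
    cb = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        stack = []
        pred = {v: [] for v in g.nodes}
        sigma = {v: 0.0 for v in g.nodes}
        dist = {v: -1 for v in g.nodes}
        sigma[s], dist[s] = 1.0, 0
        queue = [s]
        while queue:
            v = queue.pop(0)
            stack.append(v)
            for w in g[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in g.nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w != s:
                cb[w] += delta[w]
        # undirected: each pair counted twice over sources
    norm = (n - 1) * (n - 2)  # == 2 * (N-1)(N-2)/2, absorbing the double count
    values = pd.Series({v: cb[v] / norm for v in g.nodes}, dtype=float)
    return CentralitySummary(betweenness=values.loc[list(g.nodes)])


def keystone_taxa(centrality: CentralitySummary, cutoff: float = 0.10) -> list:
    """Taxa with betweenness strictly above ``cutoff``, descending;
    ties break alphabetically."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    above = centrality.betweenness[centrality.betweenness > cutoff]
    ordered = sorted(above.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ordered]


def neighbor_correlations(network: MicrobialNetwork, focal: str, top_n: int = 10):
    """Neighbors of ``focal`` sorted by descending edge weight, truncated
    to ``top_n``."""
    if focal not in network.graph:
        raise KeyError(f"taxon {focal!r} not in network")
    nbrs = [
        (u, float(d["weight"])) for u, d in network.graph[focal].items()
    ]
    nbrs.sort(key=lambda kv: (-kv[1], kv[0]))
    return nbrs[:top_n]
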