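"""Shared helpers and independent oracles used across the test suite."""

import numpy as np

from mibinet import CountTable


def random_count_table(rng, n_samples=8, n_taxa=6, depth=200):
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_taxa)), size=n_samples)
    return CountTable(
        [f"s{i}" for i in range(n_samples)],
        [f"t{j}" for j in range(n_taxa)],
        counts,
    )


# ---------------------------------------------------------------------------
# Independent oracles


def weighted_unifrac_oracle(table, tree, normalized=True):
    """Naive per-branch accumulation: for every node, recompute the
    descendant tip set from scratch and accumulate l * |pA - pB|."""
    from mibinet import relative_abundance

    fracs = np.asarray(relative_abundance(table))
    idx = {t: i for i, t in enumerate(table.taxon_ids)}
    n = table.n_samples
    d = np.zeros((n, n))
    branches = []
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in ([node] if node.is_tip() else node.tips())]
        cols = [idx[t] for t in tips if t in idx]
        branches.append((float(node.length or 0.0), cols))
    depth = {}
    for tip in tree.tips():
        dist, node = 0.0, tip
        while node.parent is not None:
            dist += float(node.length or 0.0)
            node = node.parent
        depth[tip.name] = dist
    tip_depth = np.array([depth[t] for t in table.taxon_ids])
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            for length, cols in branches:
                pa = sum(fracs[i, c] for c in cols)
                pb = sum(fracs[j, c] for c in cols)
                num += length * abs(pa - pb)
            if normalized:
                den = float(np.sum(tip_depth * (fracs[i] + fracs[j])))
                d[i, j] = num / den if den > 0 else 0.0
            else:
                d[i, j] = num
    return d + d.T


def betweenness_oracle(graph):
    """Exhaustive geodesic enumeration via explicit shortest-path listing."""
    import networkx as nx

    nodes = list(graph.nodes)
    n = len(nodes)
    counts = {v: 0.0 for v in nodes}
    for a_i in range(n):
        for b_i in range(a_i + 1, n):
            a, b = nodes[a_i], nodes[b_i]
            try:
                paths = list(nx.all_shortest_paths(graph, a, b))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    counts[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: c / norm for v, c in counts.items()}


def ward_d2_oracle(d):
    """Naive Lance-Williams agglomeration with the Ward.D2 update on
    squared dissimilarities (square-rooted merge heights). Returns the
    sorted list of merge heights."""
    d = np.array(d, dtype=float)
    n = d.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dd = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[(i, j)] = d[i, j]
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), dij = min(
            ((p, v) for p, v in dd.items() if p[0] in active and p[1] in active),
            key=lambda kv: kv[1],
        )
        heights.append(dij)
        ni, nj = sizes[i], sizes[j]
        merged = next_id
        next_id += 1
        sizes[merged] = ni + nj
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dd[tuple(sorted((i, k)))]
            djk = dd[tuple(sorted((j, k)))]
            new2 = (
                (ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2
            ) / (ni + nj + nk)
            dd[tuple(sorted((merged, k)))] = np.sqrt(max(new2, 0.0))
        active = [k for k in active if k not in (i, j)] + [merged]
    return sorted(heights)


def iter_partitions(items):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over all tables with
    the observed margins, point-probability criterion."""
    from math import lgamma

    def log_comb(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(x):
        return (
            log_comb(r1, x)
            + log_comb(r2, c1 - x)
            - log_comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= obs + 1e-9:
            total += np.exp(lp)
    return min(total, 1.0)
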