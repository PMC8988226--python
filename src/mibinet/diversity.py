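"""Alpha diversity, phylogenetic and non-phylogenetic beta diversity,
principal coordinates, and distance-based permutational ANOVA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .feature_table import CountTable, relative_abundance

__all__ = [
    "observed_taxa",
    "inverse_simpson",
    "pielou_evenness",
    "alpha_diversity_frame",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "permanova",
    "OrdinationResult",
]


def _as_probs(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    return x / total


def observed_taxa(counts) -> int:
    """Number of taxa with nonzero count."""
    x = np.asarray(counts)
    if x.sum() <= 0:
        raise ValueError("sample has zero total count")
    return int((x > 0).sum())


def inverse_simpson(counts) -> float:
    """1 / sum(p_i^2)."""
    p = _as_probs(counts)
    return float(1.0 / np.sum(p**2))


def pielou_evenness(counts) -> float:
    """Shannon entropy divided by log(richness); NaN for single-taxon samples."""
    p = _as_probs(counts)
    s = observed_taxa(counts)
    if s == 1:
        return float("nan")
    p = p[p > 0]
    h = -np.sum(p * np.log(p))
    return float(h / np.log(s))


def alpha_diversity_frame(table: CountTable) -> pd.DataFrame:
    rows = {
        sid: {
            "observed_taxa": observed_taxa(row),
            "inverse_simpson": inverse_simpson(row),
            "pielou_evenness": pielou_evenness(row),
        }
        for sid, row in zip(table.sample_ids, table.counts)
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """d(x, y) = sum|x_i - y_i| / sum(x_i + y_i) on raw counts."""
    x = table.counts.astype(float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("zero-total sample in Bray-Curtis input")
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        denom = (x[i] + x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = diff / denom
    d = d + d.T
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# UniFrac


def _branch_structure(tree: TreeNode, taxon_ids):
    """Per-branch lengths and tip-membership indicators.

    Returns (lengths, membership) where membership is a
    (n_branches, n_taxa) 0/1 matrix marking taxa descending from each
    branch; the root (no branch) is excluded.
    """
    taxon_index = {t: i for i, t in enumerate(taxon_ids)}
    tips = {tip.name for tip in tree.tips()}
    missing = [t for t in taxon_ids if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    lengths, rows = [], []
    membership_cache = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(taxon_ids))
            if node.name in taxon_index:
                vec[taxon_index[node.name]] = 1.0
            membership_cache[id(node)] = vec
        else:
            vec = np.zeros(len(taxon_ids))
            for child in node.children:
                vec += membership_cache[id(child)]
            membership_cache[id(node)] = vec
        if node.parent is not None:
            lengths.append(float(node.length or 0.0))
            rows.append(vec)
    return np.array(lengths), np.array(rows)


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Branch-length-weighted difference of descendant read fractions.

    Raw form: sum_b l_b |p_A(b) - p_B(b)|. The normalized form divides by
    sum over tips of the root-to-tip length times (p_A + p_B), bounding
    the distance in [0, 1].
    """
    lengths, member = _branch_structure(tree, table.taxon_ids)
    fracs = np.asarray(relative_abundance(table))
    branch_p = fracs @ member.T  # samples x branches
    n = table.n_samples
    d = np.zeros((n, n))
    if normalized:
        depth = {t: 0.0 for t in table.taxon_ids}
        for tip in tree.tips():
            if tip.name in depth:
                dist = 0.0
                node = tip
                while node.parent is not None:
                    dist += float(node.length or 0.0)
                    node = node.parent
                depth[tip.name] = dist
        tip_depth = np.array([depth[t] for t in table.taxon_ids])
    for i in range(n):
        for j in range(i + 1, n):
            num = float(np.sum(lengths * np.abs(branch_p[i] - branch_p[j])))
            if normalized:
                den = float(np.sum(tip_depth * (fracs[i] + fracs[j])))
                d[i, j] = num / den if den > 0 else 0.0
            else:
                d[i, j] = num
    d = d + d.T
    return DistanceMatrix(d, ids=table.sample_ids)


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Unique-branch-length fraction: branches leading exclusively to one
    sample's taxa, over branches spanned by either sample."""
    lengths, member = _branch_structure(tree, table.taxon_ids)
    presence = (table.counts > 0).astype(float)
    branch_has = (presence @ member.T) > 0  # samples x branches
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            either = branch_has[i] | branch_has[j]
            xor = branch_has[i] ^ branch_has[j]
            total = float(np.sum(lengths[either]))
            d[i, j] = float(np.sum(lengths[xor])) / total if total > 0 else 0.0
    d = d + d.T
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Ordination


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling: eigendecomposition of the Gower-centered
    squared-distance matrix. Axes with nonpositive eigenvalues are
    reported in ``eigenvalues`` but excluded from coordinates."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else vals[pos]
    cols = [f"PC{k + 1}" for k in range(int(pos.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=vals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    col = metadata[term]
    if col.dtype == bool or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(col.astype(str), drop_first=True)
        return dummies.to_numpy(dtype=float)
    return col.to_numpy(dtype=float)[:, None]


def _trace_hat(g: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Trace of H G for the projection onto columns of x, and rank(x)."""
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank] if rank < q.shape[1] else q
    return float(np.trace(q.T @ g @ q)), rank


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms,
    test_term: str | None = None,
    permutations: int = 999,
    seed=None,
):
    """Distance-based permutational multivariate ANOVA with sequential
    (order-of-entry) sums of squares.

    ``terms`` is the ordered covariate list; ``test_term`` (default: the
    last term) is assessed by permuting raw sample labels. Returns a dict
    with pseudo-F, p-value, and the sequential SS decomposition.
    """
    terms = list(terms)
    if test_term is None:
        test_term = terms[-1]
    if test_term not in terms:
        raise ValueError(f"test term {test_term!r} not among terms {terms}")
    md = metadata.loc[list(dm.ids)]
    if md[test_term].nunique() < 2:
        raise ValueError(f"test term {test_term!r} is constant")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")

    n = len(dm.ids)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ (-0.5 * d2) @ j
    ss_total = float(np.trace(g))

    blocks = [_design_columns(md, t) for t in terms]

    def stats_for(g_mat):
        intercept = np.ones((n, 1))
        x = intercept
        prev_tr, prev_rank = _trace_hat(g_mat, x)
        ss, dfs = {}, {}
        for t, b in zip(terms, blocks):
            x = np.hstack([x, b])
            tr, rank = _trace_hat(g_mat, x)
            ss[t] = tr - prev_tr
            dfs[t] = rank - prev_rank
            prev_tr, prev_rank = tr, rank
        ss_resid = float(np.trace(g_mat)) - prev_tr
        df_resid = n - prev_rank
        if dfs[test_term] == 0 or df_resid <= 0 or ss_resid <= 0:
            raise ValueError("degenerate design for PERMANOVA")
        f = (ss[test_term] / dfs[test_term]) / (ss_resid / df_resid)
        return f, ss, dfs, ss_resid, df_resid

    f_obs, ss, dfs, ss_resid, df_resid = stats_for(g)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        g_perm = g[np.ix_(perm, perm)]
        f_perm, *_ = stats_for(g_perm)
        if f_perm >= f_obs:
            count += 1
    p = (count + 1) / (permutations + 1)
    return {
        "pseudo_F": f_obs,
        "p_value": p,
        "ss": ss,
        "df": dfs,
        "ss_residual": ss_resid,
        "df_residual": df_resid,
        "ss_total": ss_total,
        "permutations": permutations,
        "test_term": test_term,
    }
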