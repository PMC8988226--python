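"""Community-state typing: Ward.D2 hierarchical clustering, silhouette
k-selection, and exact/Monte-Carlo cluster-metadata association tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import random_table
from skbio import DistanceMatrix

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "ward_d2_linkage",
    "cut_k",
    "mean_silhouette",
    "select_k",
    "fisher_exact_2x2",
    "cluster_association",
]


@dataclass
class Dendrogram:
    """Agglomeration record: scipy-style linkage plus sample order."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    sample_ids: list

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> 1..k
    k: int
    mean_silhouette: float | None = None
    silhouette_by_k: dict = field(default_factory=dict)

    def groups(self) -> dict:
        out = {}
        for sid, lab in self.labels.items():
            out.setdefault(int(lab), []).append(sid)
        return out


def ward_d2_linkage(
    dm: DistanceMatrix, method: str = "ward"
) -> Dendrogram:
    """Agglomerative clustering with the Ward.D2 criterion (scipy's
    ``ward`` on a condensed distance matrix; equivalent to the
    Lance-Williams update on squared dissimilarities with square-rooted
    merge heights). ``method='complete'`` is available as an alternative."""
    if len(dm.ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    condensed = squareform(np.asarray(dm.data), checks=False)
    z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(linkage=z, sample_ids=list(dm.ids))


def cut_k(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into exactly k clusters by removing the k-1 highest merges."""
    n = len(dend.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    flat = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    # relabel to 1..k in order of first appearance for determinism
    remap, labels = {}, []
    for lab in flat:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels.append(remap[lab])
    return ClusterAssignment(
        labels=pd.Series(labels, index=dend.sample_ids), k=len(remap)
    )


def mean_silhouette(dm: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """Mean of s(i) = (b(i) - a(i)) / max(a(i), b(i)); members of
    singleton clusters contribute s(i) = 0."""
    labels = assignment.labels.loc[list(dm.ids)].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = np.asarray(dm.data)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def select_k(dm: DistanceMatrix, k_range=range(2, 7), method: str = "ward") -> ClusterAssignment:
    """Cut maximizing mean silhouette over ``k_range`` (default 2..6);
    ties break toward smaller k."""
    n = len(dm.ids)
    ks = [k for k in k_range if 2 <= k < n]
    if not ks:
        raise ValueError("no feasible k in range")
    dend = ward_d2_linkage(dm, method=method)
    best, by_k = None, {}
    for k in ks:
        assignment = cut_k(dend, k)
        if assignment.k < 2:  # ties in heights can collapse clusters
            continue
        sil = mean_silhouette(dm, assignment)
        by_k[k] = sil
        if best is None or sil > best[0] + 1e-12:
            best = (sil, assignment)
    sil, assignment = best
    assignment.mean_silhouette = sil
    assignment.silhouette_by_k = by_k
    return assignment


# ---------------------------------------------------------------------------
# Exact association tests


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]]
    (point-probability criterion). All-zero table returns 1."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue)


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric point probability for fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def cluster_association(
    assignment: ClusterAssignment,
    metadata: pd.DataFrame,
    variable: str,
    n_draws: int = 100_000,
    seed=None,
):
    """Association of cluster membership with a categorical variable.

    2x2 tables use Fisher's exact test; larger tables use a seeded Monte
    Carlo version of the same point-probability criterion (tables drawn
    with fixed margins). Returns ``(p, contingency_table)``.
    """
    md = metadata.loc[assignment.labels.index]
    var = md[variable].astype(str)
    table = pd.crosstab(assignment.labels, var)
    if table.shape[1] < 2 or table.shape[0] < 2:
        warnings.warn(f"variable {variable!r} or clustering is constant; p = 1")
        return 1.0, table
    obs = table.to_numpy()
    if obs.shape == (2, 2):
        p = fisher_exact_2x2(obs[0, 0], obs[0, 1], obs[1, 0], obs[1, 1])
        return p, table
    rng = np.random.default_rng(seed)
    log_obs = _log_table_prob(obs)
    sampler = random_table(obs.sum(axis=1), obs.sum(axis=0))
    draws = sampler.rvs(n_draws, random_state=rng)
    log_probs = np.array([_log_table_prob(t) for t in draws])
    hits = int(np.sum(log_probs <= log_obs + 1e-9))
    p = (hits + 1) / (n_draws + 1)
    return float(p), table
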