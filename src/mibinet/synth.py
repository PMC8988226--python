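"""Ground-truth-annotated synthetic data generators.

The generators produce compositional count tables with planted basis
correlations (matching the generative assumptions of the compositional
correlation estimator), community state types, random bifurcating trees,
and concentration-dependent contaminant spikes, so that every downstream
stage can be tested against known structure.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .feature_table import CountTable

__all__ = [
    "GroundTruth",
    "simulate_counts",
    "simulate_state_types",
    "simulate_tree",
    "spike_contaminants",
    "simulate_study",
]


@dataclass
class GroundTruth:
    """Record of all planted structure in a synthetic dataset."""

    seed: int | None = None
    basis_correlation: pd.DataFrame | None = None
    state_type_labels: dict = field(default_factory=dict)  # sample -> dominated|diverse
    contaminant_flags: dict = field(default_factory=dict)  # taxon -> bool
    cohort_labels: dict = field(default_factory=dict)  # sample -> case|control
    site_labels: dict = field(default_factory=dict)  # sample -> vaginal|bladder
    tree: TreeNode | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "state_type_labels": self.state_type_labels,
            "contaminant_flags": self.contaminant_flags,
            "cohort_labels": self.cohort_labels,
            "site_labels": self.site_labels,
            "tree": str(self.tree).strip() if self.tree is not None else None,
            "basis_correlation": (
                None
                if self.basis_correlation is None
                else {
                    "taxa": list(self.basis_correlation.columns),
                    "matrix": self.basis_correlation.to_numpy().tolist(),
                }
            ),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("basis correlation must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("basis correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("basis correlation must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("basis correlation is not positive semidefinite")
    return corr


def simulate_counts(
    n_samples: int,
    taxa,
    basis_correlation,
    depth_mean: int = 5000,
    seed=None,
    log_sigma: float = 1.0,
    mean_log=None,
    depth_sigma: float = 0.25,
):
    """Compositional counts with planted log-scale basis correlations.

    Latent basis abundances are multivariate log-normal: log-abundances
    are Gaussian with correlation ``basis_correlation`` and standard
    deviation ``log_sigma`` (optionally shifted by per-taxon ``mean_log``).
    Each sample's counts are a multinomial draw from the normalized basis
    at a depth drawn log-normally around ``depth_mean``.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    taxa = list(taxa)
    corr = _check_correlation(basis_correlation)
    if corr.shape[0] != len(taxa):
        raise ValueError("correlation dimension does not match taxa")
    mu = np.zeros(len(taxa)) if mean_log is None else np.asarray(mean_log, dtype=float)
    rng = np.random.default_rng(seed)
    cov = corr * log_sigma**2
    z = rng.multivariate_normal(mu, cov, size=n_samples, method="svd")
    basis = np.exp(z)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    depths = np.maximum(
        1, np.round(rng.lognormal(np.log(depth_mean), depth_sigma, n_samples))
    ).astype(int)
    counts = np.vstack(
        [rng.multinomial(depths[i], fractions[i]) for i in range(n_samples)]
    )
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    table = CountTable(samples, taxa, counts)
    truth = GroundTruth(
        seed=seed,
        basis_correlation=pd.DataFrame(corr, index=taxa, columns=taxa),
    )
    return table, truth


def simulate_state_types(
    n_dominated: int,
    n_diverse: int,
    dominant_taxon: str,
    seed=None,
    taxa=None,
    depth: int = 5000,
):
    """Two community state types: one dominated by ``dominant_taxon``
    (relative abundance above 0.7), one drawn from a flat symmetric
    Dirichlet composition."""
    if n_dominated < 2 or (n_diverse != 0 and n_diverse < 2):
        raise ValueError("group sizes must be >= 2 (n_diverse may be 0)")
    if taxa is None:
        taxa = [dominant_taxon] + [f"G{i:02d}" for i in range(1, 13)]
    taxa = list(taxa)
    if dominant_taxon not in taxa:
        raise ValueError(f"dominant taxon {dominant_taxon!r} not in taxon list")
    rng = np.random.default_rng(seed)
    d_idx = taxa.index(dominant_taxon)
    rows, labels = [], {}
    n_total = n_dominated + n_diverse
    for i in range(n_total):
        sid = f"S{i + 1:03d}"
        if i < n_dominated:
            p_dom = rng.uniform(0.75, 0.95)
            rest = rng.dirichlet(np.ones(len(taxa) - 1)) * (1 - p_dom)
            comp = np.insert(rest, d_idx, p_dom)
            labels[sid] = "dominated"
        else:
            comp = rng.dirichlet(np.ones(len(taxa)))
            labels[sid] = "diverse"
        rows.append(rng.multinomial(depth, comp))
    table = CountTable([f"S{i + 1:03d}" for i in range(n_total)], taxa, np.array(rows))
    return table, GroundTruth(seed=seed, state_type_labels=labels)


def simulate_tree(taxa, seed=None) -> TreeNode:
    """Random rooted bifurcating tree over ``taxa`` with exponential
    branch lengths (all strictly positive)."""
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon names")
    rng = np.random.default_rng(seed)
    # quote labels so underscores survive the Newick round trip
    subtrees = ["'" + t.replace("'", "''") + "'" for t in taxa]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        la, lb = rng.exponential(1.0, size=2) + 1e-3
        subtrees.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return TreeNode.read(io.StringIO(subtrees[0] + ";"))


def spike_contaminants(
    table: CountTable,
    dna_concentration,
    n_contaminants: int,
    seed=None,
    mean_fraction: float = 0.05,
    noise_sigma: float = 0.0,
):
    """Add contaminant taxa whose expected relative abundance scales with
    the inverse of each sample's DNA concentration (with optional
    multiplicative log-normal noise)."""
    conc = pd.Series(dna_concentration).loc[table.sample_ids].to_numpy(dtype=float)
    if (conc <= 0).any() or np.isnan(conc).any():
        raise ValueError("DNA concentrations must be strictly positive")
    if n_contaminants == 0:
        return table, GroundTruth(seed=seed, contaminant_flags={})
    rng = np.random.default_rng(seed)
    totals = table.sample_totals().astype(float)
    inv = 1.0 / conc
    scale = mean_fraction / inv.mean()
    new_cols = []
    names = [f"contaminant_{k + 1}" for k in range(n_contaminants)]
    for _ in names:
        frac = scale * inv
        if noise_sigma > 0:
            frac = frac * rng.lognormal(0.0, noise_sigma, size=len(frac))
        # added on top of existing reads so resident composition scales down uniformly
        extra = np.round(totals * frac / (1 - np.minimum(frac, 0.9))).astype(np.int64)
        new_cols.append(extra)
    counts = np.hstack([table.counts, np.column_stack(new_cols)])
    flags = {t: False for t in table.taxon_ids}
    flags.update({n: True for n in names})
    out = CountTable(list(table.sample_ids), list(table.taxon_ids) + names, counts)
    return out, GroundTruth(seed=seed, contaminant_flags=flags)


def _block_correlation(n_taxa: int, pairs, rho: float) -> np.ndarray:
    corr = np.eye(n_taxa)
    for i, j in pairs:
        corr[i, j] = corr[j, i] = rho
    return corr


def simulate_study(
    seed=None,
    n_case: int = 20,
    n_control: int = 30,
    n_vaginal_taxa: int = 66,
    n_bladder_taxa: int = 131,
    n_shared_taxa: int = 30,
    vaginal_depth_mean: int = 20000,
    bladder_depth_mean: int = 4000,
    n_planted_pairs: int = 5,
    planted_rho: float = 0.7,
    n_contaminants: int = 3,
):
    """Study-shaped scenario: two cohorts x two body sites.

    Returns a dict with per-site count tables, a combined metadata frame,
    a tree over the taxon union, and a :class:`GroundTruth`.

    The two sites share ``n_shared_taxa`` genera; each site has a handful
    of planted positively correlated basis pairs; bladder samples carry
    contaminant taxa scaling inversely with DNA concentration; vaginal
    samples split into a dominated and a diverse community state type.
    """
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    shared = [f"Shared{k:03d}" for k in range(n_shared_taxa)]
    shared[0] = "Lactobacillus"
    vag_taxa = shared + [f"Vag{k:03d}" for k in range(n_vaginal_taxa - n_shared_taxa)]
    blad_taxa = shared + [f"Blad{k:03d}" for k in range(n_bladder_taxa - n_shared_taxa)]

    samples = [f"P{i + 1:03d}" for i in range(n)]
    cohorts = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}

    def site_table(taxa, depth_mean, site_seed, dominated_mask):
        d = len(taxa)
        pairs = [(2 * k + 1, 2 * k + 2) for k in range(n_planted_pairs)]
        corr = _block_correlation(d, pairs, planted_rho)
        mu = rng.normal(0.0, 1.0, size=d)
        tbl, truth = simulate_counts(
            n, taxa, corr, depth_mean=depth_mean, seed=site_seed, mean_log=mu
        )
        # impose state types by boosting the dominant taxon in dominated samples
        counts = tbl.counts.astype(float)
        sub_rng = np.random.default_rng(site_seed + 1)
        for i in range(n):
            if dominated_mask[i]:
                total = counts[i].sum()
                p_dom = sub_rng.uniform(0.75, 0.95)
                counts[i] = counts[i] * (1 - p_dom) / max(total, 1)
                counts[i, 0] += p_dom
                counts[i] = np.round(counts[i] / counts[i].sum() * total)
        tbl = CountTable(tbl.sample_ids, tbl.taxon_ids, counts.astype(np.int64))
        tbl = CountTable(samples, tbl.taxon_ids, tbl.counts)
        return tbl, corr

    dominated = rng.random(n) < 0.5
    dominated[:2] = True  # guarantee both states occur
    dominated[-2:] = False
    seed0 = 0 if seed is None else int(seed)
    vag_table, vag_corr = site_table(vag_taxa, vaginal_depth_mean, seed0 + 11, dominated)
    blad_table, blad_corr = site_table(blad_taxa, bladder_depth_mean, seed0 + 13, dominated)

    conc = pd.Series(rng.lognormal(1.0, 0.8, size=n), index=samples)
    blad_table, contam_truth = spike_contaminants(
        blad_table, conc, n_contaminants, seed=seed0 + 17, noise_sigma=0.2
    )

    all_taxa = list(dict.fromkeys(vag_taxa + list(blad_table.taxon_ids)))
    tree = simulate_tree(all_taxa, seed=seed0 + 19)

    menopause = rng.random(n) < 0.6
    metadata = pd.DataFrame(
        {
            "cohort": [cohorts[s] for s in samples],
            "age": np.round(rng.normal(60, 10, size=n), 1),
            "bmi": np.round(rng.normal(27, 4, size=n), 1),
            "menopause": menopause,
            "estrogen_use": rng.random(n) < 0.3,
            "vaginal_product_use": (~dominated) ^ (rng.random(n) < 0.15),
            "dna_concentration": np.round(conc.to_numpy(), 4),
        },
        index=samples,
    )

    truth = GroundTruth(
        seed=seed,
        basis_correlation=pd.DataFrame(vag_corr, index=vag_taxa, columns=vag_taxa),
        state_type_labels={
            s: ("dominated" if d else "diverse") for s, d in zip(samples, dominated)
        },
        contaminant_flags=contam_truth.contaminant_flags,
        cohort_labels=cohorts,
        site_labels={},  # sites are separate tables; see keys below
        tree=tree,
    )
    return {
        "vaginal": vag_table,
        "bladder": blad_table,
        "metadata": metadata,
        "tree": tree,
        "truth": truth,
        "bladder_basis_correlation": pd.DataFrame(
            blad_corr, index=blad_taxa, columns=blad_taxa
        ),
    }
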