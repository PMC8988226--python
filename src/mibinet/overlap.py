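"""Cross-compartment genus overlap: shared/unique sets between two body
sites, Venn counts, and per-genus median relative-abundance tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import CountTable, TaxonomyMap, relative_abundance

__all__ = ["OverlapReport", "presence_set", "overlap", "median_abundance_table"]


@dataclass
class OverlapReport:
    cohort: str | None
    shared: set
    unique_a: set
    unique_b: set
    shared_fraction: float | None  # |intersection| / |union|
    fraction_of_a: float | None  # |intersection| / |set_a|
    fraction_of_b: float | None
    table: pd.DataFrame | None = None  # genus, phylum, medians per site

    def venn_counts(self) -> dict:
        return {
            "shared": len(self.shared),
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
            "union": len(self.shared) + len(self.unique_a) + len(self.unique_b),
        }


def presence_set(table: CountTable, samples=None) -> set:
    """Genera with nonzero count in at least one of the selected samples."""
    if samples is None:
        samples = table.sample_ids
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample subset")
    sub = table.select_samples(samples)
    present = sub.counts.sum(axis=0) > 0
    return {t for t, p in zip(sub.taxon_ids, present) if p}


def overlap(set_a: set, set_b: set):
    """Intersection, per-side unique sets, and |intersection| / |union|."""
    set_a, set_b = set(set_a), set(set_b)
    shared = set_a & set_b
    union = set_a | set_b
    frac = len(shared) / len(union) if union else None
    return (
        shared,
        set_a - set_b,
        set_b - set_a,
        frac,
    )


def median_abundance_table(
    table_a: CountTable,
    table_b: CountTable,
    shared,
    taxonomy: TaxonomyMap,
    site_a: str = "vaginal",
    site_b: str = "bladder",
    presence_only: bool = True,
) -> pd.DataFrame:
    """Per-genus median percent relative abundance by site, grouped by
    phylum and sorted descending by the ``site_a`` median within phylum.

    Medians are taken over the samples where the genus is nonzero
    (``presence_only=False`` uses all samples).
    """
    shared = list(shared)
    missing = [g for g in shared if g not in taxonomy.assignments]
    if missing:
        raise ValueError(f"genera absent from taxonomy: {missing}")

    def site_median(table: CountTable, genus: str) -> float:
        if genus not in table.taxon_ids:
            return float("nan")
        rel = np.asarray(relative_abundance(table))[:, table.taxon_ids.index(genus)]
        vals = rel[rel > 0] if presence_only else rel
        if len(vals) == 0:
            return float("nan")
        return float(np.median(vals) * 100.0)

    rows = []
    for genus in shared:
        rows.append(
            {
                "genus": genus,
                "phylum": taxonomy.assignments[genus].get("phylum") or "unassigned",
                f"{site_a}_median": site_median(table_a, genus),
                f"{site_b}_median": site_median(table_b, genus),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    # order phyla by their best site_a median, then genera within phylum
    key = df.groupby("phylum")[f"{site_a}_median"].max().sort_values(ascending=False)
    df["_phylum_rank"] = df["phylum"].map({p: i for i, p in enumerate(key.index)})
    df = df.sort_values(
        ["_phylum_rank", f"{site_a}_median"], ascending=[True, False]
    ).drop(columns="_phylum_rank")
    return df.reset_index(drop=True)


def overlap_report(
    table_a: CountTable,
    table_b: CountTable,
    taxonomy: TaxonomyMap,
    cohort: str | None = None,
    samples_a=None,
    samples_b=None,
    **kwargs,
) -> OverlapReport:
    """Full overlap analysis between two site tables for one cohort."""
    set_a = presence_set(table_a, samples_a)
    set_b = presence_set(table_b, samples_b)
    shared, ua, ub, frac = overlap(set_a, set_b)
    table = median_abundance_table(table_a, table_b, sorted(shared), taxonomy, **kwargs)
    return OverlapReport(
        cohort=cohort,
        shared=shared,
        unique_a=ua,
        unique_b=ub,
        shared_fraction=frac,
        fraction_of_a=len(shared) / len(set_a) if set_a else None,
        fraction_of_b=len(shared) / len(set_b) if set_b else None,
        table=table,
    )
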