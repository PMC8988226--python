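"""Count-table container, I/O, and the preprocessing chain.

Preprocessing mirrors a standard genus-level 16S workflow: taxonomic
agglomeration, rarefaction without replacement, per-sample maximum
relative-abundance filtering, and frequency-based contaminant screening
against DNA concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus")

__all__ = [
    "CountTable",
    "TaxonomyMap",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "agglomerate",
    "rarefy",
    "abundance_filter",
    "decontam_frequency",
    "relative_abundance",
]


class CountTableError(ValueError):
    """Raised for malformed or inconsistent count tables."""


@dataclass
class CountTable:
    """Integer abundance matrix, samples (rows) x taxa (columns).

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers.
    taxon_ids : list of str
        Ordered, unique taxon identifiers.
    counts : ndarray of int, shape (n_samples, n_taxa)
        Nonnegative counts.
    """

    sample_ids: list
    taxon_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(map(str, self.sample_ids))
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountTableError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise CountTableError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CountTableError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise CountTableError("duplicate taxon identifiers")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise CountTableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise CountTableError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(sample_ids), list(self.taxon_ids), self.counts[idx])

    def select_taxa(self, taxon_ids) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(list(self.sample_ids), list(taxon_ids), self.counts[:, idx])

    def __eq__(self, other):
        return (
            isinstance(other, CountTable)
            and self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class TaxonomyMap:
    """Per-taxon rank labels; missing labels are None.

    ``assignments`` maps taxon_id -> dict with keys from RANKS.
    """

    assignments: dict = field(default_factory=dict)

    def label(self, taxon_id: str, rank: str):
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.assignments[taxon_id].get(rank)

    def group_key(self, taxon_id: str, rank: str) -> str:
        """Grouping label at ``rank``; unassigned taxa fall back to
        ``unclassified_<lowest assigned rank>_<label>``."""
        lab = self.label(taxon_id, rank)
        if lab:
            return lab
        ranks = self.assignments[taxon_id]
        for r in reversed(RANKS[: RANKS.index(rank)]):
            if ranks.get(r):
                return f"unclassified_{r}_{ranks[r]}"
        return "unclassified_unassigned"

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.assignments, orient="index")
        return df.reindex(columns=list(RANKS))


# ---------------------------------------------------------------------------
# I/O


def read_count_table(path, delimiter: str = "\t") -> CountTable:
    """Read a delimited count table with samples as rows, taxa as columns."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise CountTableError(f"{path}: empty or header-only count table")
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            raise CountTableError(
                f"{path}: missing/non-numeric value for taxon {col!r}, "
                f"sample {df.index[bad.argmax()]!r}"
            )
    return CountTable(list(df.index), list(df.columns), df.to_numpy())


def write_count_table(table: CountTable, path, delimiter: str = "\t") -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter)


def read_metadata(path, delimiter: str = "\t") -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CountTableError(f"{path}: duplicate sample id {dup!r}")
    df.index = df.index.astype(str)
    return df


def write_metadata(metadata: pd.DataFrame, path, delimiter: str = "\t") -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=delimiter)


def read_taxonomy(path, delimiter: str = "\t") -> TaxonomyMap:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    assignments = {}
    for taxon, row in df.iterrows():
        assignments[str(taxon)] = {
            r: (None if pd.isna(row.get(r)) else str(row.get(r))) for r in RANKS
        }
    return TaxonomyMap(assignments)


def write_taxonomy(taxonomy: TaxonomyMap, path, delimiter: str = "\t") -> None:
    df = taxonomy.to_dataframe()
    df.index.name = "taxon_id"
    df.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# Preprocessing operations


def agglomerate(table: CountTable, taxonomy: TaxonomyMap, rank: str) -> CountTable:
    """Sum counts of taxa sharing a label at ``rank``.

    Taxa unassigned at ``rank`` are grouped under
    ``unclassified_<lowest assigned rank>_<label>``. Per-sample totals are
    conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    missing = [t for t in table.taxon_ids if t not in taxonomy.assignments]
    if missing:
        raise CountTableError(f"taxa missing from taxonomy: {missing}")
    keys = [taxonomy.group_key(t, rank) for t in table.taxon_ids]
    order = list(dict.fromkeys(keys))  # first-appearance order
    out = np.zeros((table.n_samples, len(order)), dtype=np.int64)
    col = {k: i for i, k in enumerate(order)}
    for j, k in enumerate(keys):
        out[:, col[k]] += table.counts[:, j]
    return CountTable(list(table.sample_ids), order, out)


def rarefy(table: CountTable, depth: int, seed=None) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged, not an
    error). Uses a multivariate hypergeometric draw per sample.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    keep, rows = [], []
    dropped = []
    totals = table.sample_totals()
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append((sid, int(totals[i])))
            continue
        rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        keep.append(sid)
    if dropped:
        logger.info(
            "rarefy: dropped %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    if not keep:
        raise CountTableError(f"no sample has >= {depth} reads")
    out = CountTable(keep, list(table.taxon_ids), np.array(rows, dtype=np.int64))
    return out


def abundance_filter(table: CountTable, threshold: float = 0.05) -> CountTable:
    """Keep taxa whose relative abundance strictly exceeds ``threshold``
    in at least one sample. The sample set is unchanged."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    rel = relative_abundance(table)
    keep = np.asarray(rel).max(axis=0) > threshold
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return table.select_taxa(kept)


def decontam_frequency(
    table: CountTable,
    metadata: pd.DataFrame,
    score_threshold: float = 0.3,
    min_prevalence: int = 5,
):
    """Frequency-based contaminant screen against DNA concentration.

    For each taxon present in >= ``min_prevalence`` samples, compares (in
    log-log space, on presence samples only) the fit of a contaminant model
    -- log frequency linear in log concentration with slope fixed at -1 --
    against a constant-frequency null. The score is the F-distribution CDF
    of the residual-sum-of-squares ratio SS_contam/SS_null with (n-1, n-1)
    degrees of freedom: small scores indicate contaminant-like behaviour.
    Taxa scoring below ``score_threshold`` are removed.

    Returns
    -------
    (CountTable, DataFrame)
        The screened table and a per-taxon frame with columns
        ``score`` (NaN if below the prevalence floor) and ``contaminant``.
    """
    if "dna_concentration" not in metadata.columns:
        raise CountTableError("metadata lacks a dna_concentration column")
    conc = metadata.loc[table.sample_ids, "dna_concentration"].to_numpy(dtype=float)
    if np.isnan(conc).any() or (conc <= 0).any():
        raise CountTableError("dna_concentration must be present and positive for all samples")
    rel = np.asarray(relative_abundance(table))
    scores = np.full(table.n_taxa, np.nan)
    for j in range(table.n_taxa):
        nz = table.counts[:, j] > 0
        if nz.sum() < min_prevalence:
            continue
        log_f = np.log(rel[nz, j])
        log_c = np.log(conc[nz])
        n = nz.sum()
        ss_null = np.sum((log_f - log_f.mean()) ** 2)
        resid = log_f + log_c
        ss_contam = np.sum((resid - resid.mean()) ** 2)
        eps = 1e-10 * n
        if ss_null <= eps and ss_contam <= eps:
            scores[j] = 1.0  # constant frequency: null model fits perfectly
        elif ss_contam <= eps:
            scores[j] = 0.0
        elif ss_null <= eps:
            scores[j] = 1.0
        else:
            scores[j] = f_dist.cdf(ss_contam / ss_null, n - 1, n - 1)
    flagged = np.nan_to_num(scores, nan=1.0) < score_threshold
    report = pd.DataFrame(
        {"score": scores, "contaminant": flagged}, index=table.taxon_ids
    )
    kept = [t for t, f in zip(table.taxon_ids, flagged) if not f]
    if flagged.any():
        logger.info(
            "decontam_frequency: removed %d contaminant taxa: %s",
            int(flagged.sum()),
            [t for t, f in zip(table.taxon_ids, flagged) if f],
        )
    return table.select_taxa(kept), report


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Row-normalized fractions; fails on any zero-total sample."""
    totals = table.sample_totals()
    if (totals == 0).any():
        sid = table.sample_ids[int(np.argmax(totals == 0))]
        raise CountTableError(f"sample {sid!r} has zero total count")
    frac = table.counts / totals[:, None]
    return pd.DataFrame(frac, index=table.sample_ids, columns=table.taxon_ids)
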