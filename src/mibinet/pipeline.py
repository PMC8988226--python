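"""End-to-end orchestration: simulate/load -> preprocess -> diversity ->
community-state clustering -> per-cohort co-occurrence networks -> overlap.

Every stage derives its own seed from the global seed, so stages rerun in
isolation reproduce the full run. Default parameters follow the published
workflow: rarefaction depths 15,000 (vaginal) / 2,500 (bladder), a 5%
maximum-abundance filter, contaminant score thresholds 0.5 (vaginal) /
0.3 (bladder), silhouette k in 2..6, 1,000 permutation trials at a 5%
tail, and a 0.10 betweenness keystone cutoff.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import clustering as cl
from . import diversity as dv
from . import network as nw
from .overlap import overlap_report
from .feature_table import (
    CountTable,
    TaxonomyMap,
    abundance_filter,
    decontam_frequency,
    rarefy,
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_count_table,
    write_metadata,
)
from .synth import simulate_study

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "mibinet_out",
    "sites": ["vaginal", "bladder"],
    "rarefaction_depth": {"vaginal": 15000, "bladder": 2500},
    "filter_threshold": 0.05,
    "decontam_threshold": {"vaginal": 0.5, "bladder": 0.3},
    "decontam": True,
    "k_range": [2, 6],
    "sparcc": {
        "inner_resamples": 20,
        "exclusion_threshold": 0.1,
        "exclusion_iterations": 10,
    },
    "permutation": {"trials": 1000, "tail": 0.05},
    "betweenness_cutoff": 0.10,
    "community_trials": 10,
    "permanova": {
        "permutations": 999,
        "terms": ["age", "bmi", "menopause", "estrogen_use", "cohort"],
        "test_term": "cohort",
    },
    "simulate": None,  # dict of simulate_study kwargs, or None to read inputs
    "inputs": None,  # dict: counts per site, metadata, tree, taxonomy
}


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the global seed."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
    )


def merge_config(config: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def _default_taxonomy(taxa) -> TaxonomyMap:
    """Placeholder taxonomy for simulated genera: phylum blocks, genus = id."""
    phyla = ["PhylumA", "PhylumB", "PhylumC", "PhylumD"]
    return TaxonomyMap(
        {
            t: {
                "phylum": phyla[i % len(phyla)],
                "class": None,
                "order": None,
                "family": None,
                "genus": t,
            }
            for i, t in enumerate(sorted(taxa))
        }
    )


def _load_inputs(cfg: dict):
    if cfg.get("simulate") is not None:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", stage_seed(cfg["seed"], "simulate"))
        data = simulate_study(**sim)
        taxa = set(data["vaginal"].taxon_ids) | set(data["bladder"].taxon_ids)
        taxonomy = _default_taxonomy(taxa)
        return (
            {"vaginal": data["vaginal"], "bladder": data["bladder"]},
            data["metadata"],
            data["tree"],
            taxonomy,
            data["truth"],
        )
    inputs = cfg.get("inputs") or {}
    tables = {}
    for site in cfg["sites"]:
        path = inputs.get(f"counts_{site}")
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing count table for site {site!r}: {path}")
    for site in cfg["sites"]:
        tables[site] = read_count_table(inputs[f"counts_{site}"])
    metadata = read_metadata(inputs["metadata"])
    tree = None
    if inputs.get("tree"):
        tree_path = Path(inputs["tree"])
        if not tree_path.exists():
            raise FileNotFoundError(f"tree file not found: {tree_path}")
        tree = TreeNode.read(str(tree_path))
    taxonomy = (
        read_taxonomy(inputs["taxonomy"])
        if inputs.get("taxonomy")
        else _default_taxonomy(
            set().union(*(set(t.taxon_ids) for t in tables.values()))
        )
    )
    return tables, metadata, tree, taxonomy, None


def preprocess_site(table: CountTable, metadata: pd.DataFrame, site: str, cfg: dict):
    """Rarefy, abundance-filter, and (optionally) decontaminate one site."""
    depth = cfg["rarefaction_depth"][site]
    table = rarefy(table, depth, seed=stage_seed(cfg["seed"], f"rarefy_{site}"))
    table = abundance_filter(table, cfg["filter_threshold"])
    decontam_report = None
    if cfg.get("decontam") and "dna_concentration" in metadata.columns:
        table, decontam_report = decontam_frequency(
            table, metadata, cfg["decontam_threshold"][site]
        )
    return table, decontam_report


def analyze_network(table: CountTable, threshold: float, cfg: dict, label: str):
    """SparCC -> thresholded positive network -> communities -> centrality."""
    est = nw.sparcc(
        table,
        seed=stage_seed(cfg["seed"], f"sparcc_{label}"),
        **cfg["sparcc"],
    )
    net = nw.build_network(est, threshold)
    summary = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "threshold": threshold,
    }
    if net.n_nodes >= 2:
        summary["normalized_connectance"] = round(nw.normalized_connectance(net), 6)
    if net.n_nodes > 0:
        part = nw.detect_communities(
            net,
            trials=cfg["community_trials"],
            seed=stage_seed(cfg["seed"], f"infomap_{label}"),
        )
        cent = nw.betweenness(net)
        keystones = nw.keystone_taxa(cent, cfg["betweenness_cutoff"])
        summary.update(
            {
                "n_modules": part.n_modules,
                "codelength_bits": round(part.codelength, 6),
                "modularity": round(part.modularity, 6),
                "keystone_taxa": keystones,
                "betweenness": {
                    k: round(float(v), 6) for k, v in cent.betweenness.items()
                },
            }
        )
    else:
        part, cent = None, None
    return est, net, part, cent, summary


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full analysis; writes artifacts and returns the summary."""
    cfg = merge_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    tables, metadata, tree, taxonomy, truth = _load_inputs(cfg)
    write_metadata(metadata, out / "metadata.tsv")
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())
    if tree is not None:
        tree.write(str(out / "tree.nwk"))

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": cfg["seed"],
        "parameters": {
            k: cfg[k]
            for k in (
                "rarefaction_depth",
                "filter_threshold",
                "decontam_threshold",
                "k_range",
                "sparcc",
                "permutation",
                "betweenness_cutoff",
            )
        },
        "sites": {},
        "networks": {},
        "overlap": {},
    }

    processed = {}
    for site in cfg["sites"]:
        logger.info("preprocessing %s", site)
        table, decontam_report = preprocess_site(tables[site], metadata, site, cfg)
        processed[site] = table
        write_count_table(table, out / f"counts_{site}_processed.tsv")
        site_summary = {
            "n_samples": table.n_samples,
            "n_taxa": table.n_taxa,
        }
        if decontam_report is not None:
            site_summary["n_contaminants_removed"] = int(
                decontam_report["contaminant"].sum()
            )

        # alpha diversity
        alpha = dv.alpha_diversity_frame(table)
        alpha.to_csv(out / f"alpha_{site}.tsv", sep="\t")

        # beta diversity + clustering on weighted UniFrac
        if tree is not None:
            dm = dv.weighted_unifrac(table, tree)
        else:
            dm = dv.bray_curtis(table)
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out / f"wunifrac_{site}.tsv", sep="\t"
        )
        k_lo, k_hi = cfg["k_range"]
        assignment = cl.select_k(dm, range(k_lo, k_hi + 1))
        assignment.labels.rename("cluster").to_csv(
            out / f"clusters_{site}.tsv", sep="\t"
        )
        site_summary["clusters"] = {
            "k": assignment.k,
            "mean_silhouette": round(assignment.mean_silhouette, 6),
            "silhouette_by_k": {
                str(k): round(v, 6) for k, v in assignment.silhouette_by_k.items()
            },
        }
        md = metadata.loc[assignment.labels.index]
        for var in ("cohort", "menopause", "vaginal_product_use"):
            if var in md.columns and md[var].nunique() > 1:
                p, _ = cl.cluster_association(
                    assignment,
                    md,
                    var,
                    seed=stage_seed(cfg["seed"], f"assoc_{site}_{var}"),
                )
                site_summary["clusters"][f"association_{var}_p"] = round(p, 6)

        # PERMANOVA: cohort effect adjusted for the configured covariates
        terms = [t for t in cfg["permanova"]["terms"] if t in metadata.columns]
        if cfg["permanova"]["test_term"] in terms and len(set(md["cohort"])) > 1:
            res = dv.permanova(
                dm,
                md,
                terms,
                test_term=cfg["permanova"]["test_term"],
                permutations=cfg["permanova"]["permutations"],
                seed=stage_seed(cfg["seed"], f"permanova_{site}"),
            )
            site_summary["permanova"] = {
                "pseudo_F": round(res["pseudo_F"], 6),
                "p_value": round(res["p_value"], 6),
            }
        summary["sites"][site] = site_summary

        # permutation-null threshold on the pooled site data
        null = nw.permutation_threshold(
            table,
            trials=cfg["permutation"]["trials"],
            tail=cfg["permutation"]["tail"],
            seed=stage_seed(cfg["seed"], f"null_{site}"),
            **cfg["sparcc"],
        )
        summary["sites"][site]["edge_threshold"] = round(null.threshold, 6)

        # per-cohort networks at the pooled-site threshold
        for cohort in sorted(set(metadata["cohort"])):
            cohort_samples = [
                s for s in table.sample_ids if metadata.loc[s, "cohort"] == cohort
            ]
            sub = table.select_samples(cohort_samples)
            sub = abundance_filter(sub, 0.0)  # drop taxa absent from this cohort
            label = f"{cohort}_{site}"
            est, net, part, cent, net_summary = analyze_network(
                sub, null.threshold, cfg, label
            )
            est.to_frame().to_csv(out / f"sparcc_{label}.tsv", sep="\t")
            with open(out / f"edges_{label}.tsv", "w") as fh:
                fh.write("taxon_a\ttaxon_b\tweight\n")
                for u, v, w in sorted(net.edge_list()):
                    fh.write(f"{u}\t{v}\t{w:.6f}\n")
            summary["networks"][label] = net_summary

    # cross-site overlap per cohort
    if len(cfg["sites"]) == 2:
        site_a, site_b = cfg["sites"]
        for cohort in sorted(set(metadata["cohort"])):
            sel = lambda tbl: [
                s for s in tbl.sample_ids if metadata.loc[s, "cohort"] == cohort
            ]
            report = overlap_report(
                processed[site_a],
                processed[site_b],
                taxonomy,
                cohort=cohort,
                samples_a=sel(processed[site_a]),
                samples_b=sel(processed[site_b]),
                site_a=site_a,
                site_b=site_b,
            )
            report.table.to_csv(
                out / f"overlap_{cohort}.tsv", sep="\t", index=False
            )
            summary["overlap"][cohort] = {
                **report.venn_counts(),
                "shared_fraction": round(report.shared_fraction, 6),
                f"fraction_of_{site_a}": round(report.fraction_of_a, 6),
                f"fraction_of_{site_b}": round(report.fraction_of_b, 6),
            }

    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1) + "\n"
    )
    return summary
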