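# mibinet

Co-occurrence network analysis of paired-site microbial communities.

`mibinet` implements a genus-level 16S analysis chain for comparing two
adjacent body-site microbiomes (e.g., vaginal and bladder) across two
cohorts:

- **Preprocessing** — count-table I/O, taxonomic agglomeration, rarefaction
  without replacement, per-sample maximum-abundance filtering, and
  frequency-based contaminant screening against DNA concentration.
- **Diversity** — observed taxa, inverse Simpson, Pielou evenness;
  Bray-Curtis and weighted/unweighted UniFrac distances; PCoA; PERMANOVA
  with sequential (order-of-entry) sums of squares.
- **Community-state typing** — Ward.D2 hierarchical clustering on weighted
  UniFrac, silhouette-based selection of k in 2..6, and exact/Monte-Carlo
  cluster-metadata association tests.
- **Co-occurrence networks** — compositional (log-ratio) correlation
  estimation with Dirichlet resampling and iterative strong-pair exclusion;
  a permutation-null edge threshold (column-shuffled data, top-5% tail);
  positive-edge networks; two-level map-equation community detection;
  modularity and normalized connectance; betweenness-centrality keystone
  taxa (cutoff 0.10); per-taxon neighbor reports.
- **Overlap analysis** — shared/unique genus sets between sites per cohort,
  Venn counts, and per-genus median relative-abundance tables grouped by
  phylum.
- **Synthetic data** — seeded generators for compositional counts with
  planted basis correlations, dominated/diverse community state types,
  random bifurcating trees, and concentration-dependent contaminant spikes,
  so the full pipeline is testable against known ground truth.

## Test

```sh
python -m pytest tests/
```

The suite includes property tests (hypothesis), independent brute-force
oracles (geodesic enumeration for betweenness, exhaustive partition search
for the map-equation optimizer, naive Lance-Williams agglomeration, a
per-branch UniFrac oracle, Fisher-test enumeration), and an acceptance
suite (`tests/test_acceptance.py`) covering parameter recovery and
calibration on synthetic data.

## Command line

```sh
mibinet simulate --seed 1 --out data/           # synthetic two-site scenario
mibinet preprocess --counts data/counts_vaginal.tsv \
    --metadata data/metadata.tsv --site vaginal --out processed.tsv
mibinet diversity --counts processed.tsv --tree data/tree.nwk --out div/
mibinet cluster --distances div/weighted_unifrac.tsv --out clusters.tsv
mibinet network --counts processed.tsv --trials 1000 --seed 1 --out net/
mibinet overlap --counts-a vag.tsv --counts-b blad.tsv --out overlap.json
mibinet all --seed 1 --out run/ --fast          # full pipeline end to end
```

`mibinet all` accepts a YAML config (`--config`) whose keys mirror the
defaults in `mibinet.pipeline.DEFAULT_CONFIG`: rarefaction depths per site
(15000 vaginal / 2500 bladder), 5% abundance filter, contaminant score
thresholds (0.5 vaginal / 0.3 bladder), silhouette k range 2..6, 1000
permutation trials at a 5% tail, and a 0.10 betweenness keystone cutoff.
A single global seed is fanned out to every stage, so stages rerun in
isolation (e.g., `mibinet network` on a saved correlation matrix)
reproduce the corresponding outputs of a full run, and reruns are
byte-identical.

Outputs are plain text: TSV tables (counts, distance matrices, edge
lists, cluster assignments, centralities), Newick trees, and a versioned
`summary.json` with node/edge counts, modularity, connectance,
codelength, silhouettes, keystone lists, and overlap fractions.
Dendrograms are written as scipy-style merge tables (columns: left,
right, height, size).

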