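# presynet

From differential stable-isotope-labeling proteomics to overlapping
protein–protein-interaction (PPI) network communities.

`presynet` is for systems-biology analysts who have quantitative
light/heavy peptide-level measurements (e.g. succinic-anhydride d0/d4
labeling of a presynaptic membrane fraction under a drug treatment) and
want to go from raw feature tables to a ranked, clustered network of
candidate regulated protein complexes. The package also ships a synthetic
study generator with planted ground truth, so every stage can be
validated end to end.

## The pipeline

1. **Peak-pair quantification** — light/heavy features of the same
   peptide are paired when their m/z separation equals `4·s/z` Th
   (`s` label sites, `z` charge; implied mass difference ∈ {2, 4, 8} Da),
   retention times agree within 30 s, and both signal-to-noise ratios
   exceed 10. Per-protein treatment/control ratios are arithmetic means
   of peptide ratios (reverse-labeled runs are inverted first); proteins
   with any peptide identified below a Mascot-style score of 60 are
   dropped.
2. **Seed selection** — per experiment, a protein "changes" when its
   log-ratio deviates from the across-protein mean by ≥ 0.5 SD; proteins
   changing in ≥ 2 experiments, always in the same direction, form the
   *seed list*.
3. **Background consolidation and literature filter** — interaction
   records from multiple source datasets are merged into one simple
   undirected graph; edges whose only literature support comes from
   articles contributing ≥ 5 interactions (high-throughput screens) are
   removed.
4. **Subnetwork expansion** — seed pairs are connected through every
   simple path of ≤ 3 links whose interior nodes (≤ 2 *intermediates*)
   are non-seeds.
5. **Intermediate enrichment** — each intermediate with background degree
   `d` and `s` seed neighbors is scored against the background seed
   fraction (`S` of `N` nodes) with the pooled two-proportion z

   `z = (s/d − S/N) / sqrt(p̄(1−p̄)(1/d + 1/N))`,  `p̄ = (s+S)/(d+N)`;

   `z > 2` is significant, `z > 3` highly significant.
6. **Topology null test** — the subnetwork's average clustering
   coefficient is compared with degree-preserving double-edge-swap
   shuffles (add-one empirical p over 100 replicates).
7. **k-clique percolation** — overlapping clusters are maximal unions of
   k-cliques connected through shared (k−1)-node overlaps (k = 3, 4 by
   default), the candidate protein complexes.

## Worked example

Run the synthetic study end to end (5 experiments with alternating
forward/reverse labeling, 175 identified / 143 quantifiable proteins, 30
regulated of which 23 down, a 3000-node provenance-annotated background):

```sh
presynet run --seed 1 --outdir out
```

The run report (abridged; also written to `out/run_report.json`) prints:

```
"quantify":  {"n_proteins_quantified": 143}
"seeds":     {"n_seeds": 34, "directions": {"down": 23, "up": 11},
              "recovery": {"sensitivity": 1.0, "fdp": 0.118}}
"background":{"pre_filter": {"n_nodes": 2652, "n_edges": 12270},
              "post_filter": {"n_nodes": 2633, "n_edges": 11615}}
"expand":    {"n_seed_connected": 27, "n_intermediates": 144, "n_edges": 402}
"score":     {"n_score_gt2": 68, "n_score_gt3": 24, "max_z": 15.01}
"topology":  {"c_observed": 0.0562, "null_mean": 0.0706, "p_empirical": 0.88}
"clusters":  {"3": 6, "4": 1}
```

Reading: all 143 quantifiable proteins got ratios; the 0.5-SD/2-experiment
rule selected 34 seeds, recovering all 30 planted regulated proteins with
4 false positives; the literature filter removed 80 high-throughput
articles (12270 → 11615 edges); 27 seeds were connected through 144
intermediates and 402 interactions; 68 intermediates scored z > 2 (24 of
them z > 3, best 15.0 — heavily seed-connected hubs); the subnetwork's
clustering is not elevated over its degree-preserving null in this
synthetic instance (p = 0.88); and percolation found 6 overlapping
clusters at k = 3 and 1 at k = 4. Artifacts (ratio matrix, seed list,
SIF networks, enrichment table, null distribution, cluster membership)
are written under `out/`.

Each stage is also available as a subcommand (`simulate`, `quantify`,
`seeds`, `background`, `expand`, `score`, `nulltest`, `clusters`) reading
the artifacts of the previous one, and as plain library functions.

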