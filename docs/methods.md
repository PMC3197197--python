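# Methods

## Quantification model

A differential-labeling experiment tags the control sample's tryptic
peptides with a light reagent and the treatment sample's with a heavy
one (or the reverse), so each peptide appears as a *peak pair*. The
reagent adds 4 Da per label site; tryptic peptides carry one site
(N-terminus) or two (N-terminus plus a C-terminal lysine), so at charges
1–2 pair separations are 2, 4 or 8 Th and the implied mass difference
(separation × charge) lies in {2, 4, 8} Da.

Pair matching requires, for two features of the same protein, peptide,
charge and site count with the lighter member taken as the light channel:

* |observed − expected (4·s/z)| m/z separation ≤ `mz_tol` (default
  0.05 Th, a generous ion-trap-level tolerance);
* retention-time separation ≤ `rt_window` (default 30 s);
* both signal-to-noise ratios > `snr_min` (default 10).

Each feature joins at most one pair. Candidates are ranked by m/z
agreement, then RT separation, then feature order, and matched greedily —
a deterministic assignment that the test suite checks against an
exhaustive all-pairs oracle.

Peptide ratios are expressed as treatment/control: heavy/light intensity
in forward runs, light/heavy in reverse runs, making the forward/reverse
designs reciprocal (exactly so in noiseless data; an acceptance test
asserts agreement to 1e−12 in log space). Protein ratios are arithmetic
means of peptide ratios per experiment; proteins with any peptide
identified below `min_id_score` (default 60, a Mascot-style gate applied
to every peptide) are excluded.

## Seed selection

Per experiment, the mean and sample SD (ddof = 1) of **natural-log**
ratios are computed across quantified proteins. A protein changes when
|log r − mean| ≥ `sd_multiple`·SD (default 0.5), with direction the sign
of the deviation; selection requires ≥ `min_consistent` (default 2)
changes, all of one sign, with any opposite-sign change disqualifying.
The log scale is a deliberate choice: it makes 0.5× and 2× symmetric
around no-change and matches the reciprocal forward/reverse structure.
An experiment with zero SD (all ratios identical) contributes no changes.
If fewer than 2 proteins are quantified in an experiment the SD is
undefined and an error is raised.

A known property of this mean-centered rule: when regulation is strongly
asymmetric (here 23 down vs 7 up by default), the per-experiment mean is
pulled toward the majority direction, which moves unregulated proteins
closer to the minority-direction threshold. At ratio noise CV 0.15 this
yields a non-trivial false-discovery proportion (~0.25 in the packaged
study conditions, essentially all minority-direction calls and
concentrated in single-peptide proteins) while sensitivity stays at 1.0.
With no noise, recovery of the planted truth is exact. This is inherent
to the selection rule, not to its implementation.

## Background network and literature filter

Records (`node_a, node_b, dataset, article_id`) are merged
case-insensitively into a simple undirected graph; (A,B)/(B,A) collapse
to one edge carrying the union of supporting articles; self-loops drop.
An article supporting ≥ `max_per_article` + 1 distinct edges (default
boundary: five or more) is flagged high-throughput; an edge is removed
only when *all* its supporting articles are flagged — one low-throughput
citation rescues an edge. The filter is idempotent, article counts are
taken after deduplication, and isolated nodes are removed.

## Subnetwork expansion

For every unordered pair of mapped seeds, a bounded depth-first search
enumerates all simple paths of ≤ `max_intermediates` + 1 links (default
3) whose interior nodes are all non-seeds; interior nodes become
intermediates and all path edges (plus direct seed–seed edges) form the
subnetwork. Paths through another seed are not counted as single paths;
their seed-to-seed segments qualify separately, so "intermediate" status
is unambiguous. With `max_intermediates` = 0 the result is exactly the
background's induced seed–seed edge set, and output grows monotonically
with the bound.

## Enrichment score

The score is the textbook pooled two-sample binomial-proportions z
comparing a node's fraction of seed neighbors (s of d) with the
background seed fraction (S of N):

    z = (s/d − S/N) / sqrt(p̄(1−p̄)(1/d + 1/N)),   p̄ = (s+S)/(d+N)

z is reported as 0 when the pooled variance vanishes (p̄ ∈ {0, 1}).
Tiers are strict: z > 3 highly significant, 2 < z ≤ 3 significant,
otherwise none (z = 2 → none, z = 3 → significant). No multiple-testing
correction is applied; the score ranks candidates rather than testing a
family-wise hypothesis. Degrees and seed counts are taken in the filtered
background, and only non-seed intermediates are scored.

## Topology null

The observed statistic is the mean local clustering coefficient with
degree < 2 nodes counted as 0 (networkx `average_clustering`). Each null
replicate applies `swaps_per_edge`·|E| accepted double-edge swaps
((a,b),(c,d) → (a,d),(c,b); self-loops and duplicates rejected; attempt
budget 100× the target, with a saturation flag when a graph such as a
triangle admits no valid swap). Degree preservation is asserted on every
replicate. The master seed spawns independent substreams per replicate;
the empirical p-value is add-one, (#{null ≥ observed} + 1)/(n + 1), so it
is never 0. Both 10 swaps per edge and 100 shuffles are conventional
choices balancing mixing against runtime.

A caveat established while validating: mean local clustering against a
degree-preserving null has little power when the clustered nodes dominate
the degree sequence, because hub-heavy degree sequences reproduce
triangles under rewiring alone. A planted 10-clique is reliably detected
(p ≤ 0.01) inside a sparse 200-node periphery, but not when the clique
nodes are the graph's main hubs — which is also why the expanded
synthetic subnetwork in the worked example is *not* called significant:
its triangles sit on high-degree intermediates.

## k-clique percolation

A cluster is the node union of a maximal family of k-cliques chained by
(k−1)-node overlaps. The implementation never materializes all k-subsets:
maximal cliques of size ≥ k (Bron–Kerbosch via networkx `find_cliques`)
are joined by union-find whenever two overlap in ≥ k−1 nodes, and each
component's node union is one cluster. This is equivalent to exhaustive
k-subset percolation — any two k-subsets of one clique are chain-connected,
and two adjacent k-cliques force a ≥(k−1)-overlap between their maximal
cliques — and the tests verify the equivalence against a brute-force
oracle on hundreds of random graphs, plus the independent networkx
`k_clique_communities` implementation. Clusters are ordered by size,
then lexicographically smallest member. At k = 2 clusters coincide with
connected components having at least one edge.

## Synthetic study generator

The generator emulates the study design the pipeline targets: 5
experiments with schedule (F, R, F, R, F); 175 identified proteins of
which 143 are quantifiable — the remainder emit single-channel
(unpairable) features or sub-60 identification scores; 30 regulated (23
down, 7 up) with |log2 fold| drawn uniformly in [1, 2]; 1–5 peptides per
protein with 1–2 label sites and charge 1–2; ratio noise is one mean-one
log-normal factor per pair with CV `noise_cv` (default 0.15); decoy
features (default 5% of peptides) are unpaired low-S/N peaks. RT pair
separation is uniform within ±15 s; S/N uniform in (11, 100).

The background is a configuration-model-style graph (geometric degree
distribution, mean degree 8, 3000 nodes, self-loops/multi-edges
rejected) whose node set contains the protein universe, so seeds map into
it. Edges are apportioned to articles with exact provenance bookkeeping:
high-throughput articles (20% of 400 base articles) receive 5–12 records
each and are assigned to distinct edges first, low-throughput articles
1–4; extra low-throughput article ids are minted when the edge count
exceeds the base pool's capacity, so exactly the flagged articles cross
the ≥ 5 boundary, and surplus slots add second supporting articles to
random edges (mixed-evidence cases for the filter). `plant_module`
densifies a chosen node set to a target edge density with fresh ≤ 4-record
(filter-surviving) articles; the packaged pipeline plants a 12-node,
0.9-density module around regulated proteins so percolation has a
detectable community.

What the generator does **not** emulate: missed cleavages and shared
peptides, correlated peptide-level noise, chromatographic drift,
protein-abundance-dependent detectability, the globally elevated
triangle density of curated PPI networks (synthetic subnetwork clustering
is therefore typically *not* significant against the degree null), and
orthology/identifier noise in interaction databases. Passing tests
demonstrate algorithmic correctness on known ground truth, not that real
data meet these assumptions.

## Determinism and problem sizes

All randomness flows from one master seed through
`numpy.random.SeedSequence` substreams; two runs with identical config
and seed produce byte-identical artifacts (timestamps appear only in
logs). The test suite exercises: percolation on 300 random graphs of up
to 25 nodes against exhaustive enumeration; pair matching on 100 random
tables of ≤ 100 features against the quadratic oracle; expansion on 50
200-node backgrounds against exhaustive path enumeration; the null test
on 20-seed batches of 210-node planted-clique and 40-node unstructured
graphs; and the full pipeline at reduced size (300-node background).
These sizes were chosen to keep the default suite fast while leaving the
asymptotic behavior to the implementation's documented complexity.
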