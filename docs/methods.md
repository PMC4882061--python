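# Methods

`gcnet` implements a tissue-restricted protein–protein interaction (PPI)
analysis for the kidney glomerulus: it assembles a cytoskeleton-annotated,
glomerulus-enriched gene universe, induces a confidence-filtered interaction
network on it, nominates candidate genes by direction-consistent
differential expression across five proteinuric diseases, reconstructs
bridge-node subnetworks around the candidates, and prioritizes
candidate–phenotype associations by correlating phenotype similarity with
network closeness. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Gene-set assembly

Gene sets are plain sets of uppercase gene symbols, one namespace per set;
numeric identifiers are treated as opaque strings. Mouse-identifier sets are
converted through an ortholog map before any set algebra; an unmapped source
symbol is dropped and tallied. A one-to-many ortholog maps to **all** of its
targets by default (`keep_all_targets=True`); the conservative alternative
(drop ambiguous sources) is a flag, because neither convention is canonical
and the tallies make the difference auditable. Enrichment lists are consumed
as published — their original selection criteria (fold-change cut-offs,
library comparisons) are provenance metadata, not re-applied filters.

The tissue universe is the exact intersection of the annotation union with
the enrichment union. Overlap reports carry the raw counts and display
proportions at two decimals, the convention of the source tables.

## Interaction integration and filtering

Per-edge evidence-channel confidences in [0, 1] are combined with a
noisy-OR product, with each channel first capped at 0.9:

    combined = 1 − Π_i (1 − min(s_i, 0.9))

The cap reproduces the defining property of the source database's
integration: an interaction supported by a single channel can score at most
0.9. An optional prior correction (subtract the random-expectation prior
from each channel, renormalize, recombine, re-add) is available but off by
default (`prior=0`), because the prior used by any given database release is
not published. Scored edges pass the filter iff `combined ≥ 0.9`
(inclusive, so a single maximal-stringency channel qualifies).
Literature-curated edges carry no channel scores and bypass the threshold by
default; a strict mode thresholds them like any other edge. Duplicate
unordered pairs collapse to one edge keeping the maximum combined score.

The tissue network is induced on the **whole** universe: genes without a
surviving interaction remain as isolated nodes, because disconnected nodes
are part of the tissue network's published structure. The network summary
reports `mean_interactions_per_node = n_edges / n_nodes` (the convention
behind the printed "interactions per node" figure — note this is half the
mean degree), largest-component node and edge fractions with the whole
network as denominator, and separate counts of isolated nodes and two-node
components, so no guess is needed about which of those a "disconnected
nodes" figure includes.

Degree and betweenness centrality

    C_B(v) = Σ_{ {s,t} : v ∉ {s,t} } σ_st(v) / σ_st

are computed per node; betweenness sums over unordered pairs within each
component (Brandes' accumulation, exact on unweighted graphs). The test
suite checks it bit-for-bit against an independent exhaustive shortest-path
enumeration on the complete small-graph atlas and on random seeded graphs.

## Cross-disease consistency classification

A gene is differentially expressed (DE) in a disease iff it appears in that
disease's table with p < 0.05. The threshold is applied to raw p-values with
no multiple-testing correction, matching the upstream tables' convention; an
FDR mode exists but is off by default. A gene absent from a table is treated
as not-DE there (the platform may simply not probe it); a strict mode can
require presence in every table. Direction is the sign of the reported
(log) fold change; a zero fold change is rejected at parse time, and
duplicate gene rows keep the minimum-p row deterministically.

Classes are determined by the sign pattern over the DE diseases only:
all-positive → consistently up, all-negative → consistently down, mixed →
inconsistent. A **candidate** must be DE in *all* K diseases with one
consistent direction. The consistency table stratifies the network's node
set by DE-disease count (the strata totals partition the node set), and the
per-disease table reports network-restricted up/down DEG counts with
percentages at one decimal, half-up.

A permutation null for the all-K consistent count shuffles gene labels
within each disease table independently, preserving each table's marginal
DE counts and sign balance while breaking the cross-disease coupling;
empirical p-values use the add-one rule.

## Bridged subnetworks

Candidates are sparsely interconnected, so subnetworks are rebuilt with
bridge nodes under two deterministic policies: `common_neighbors` (default)
adds every non-seed background node adjacent to ≥ 2 seeds — a reproducible
superset of any curated "some common first-order neighbors" selection — and
`steiner_greedy` adds only the internal nodes of greedily chosen shortest
seed-pair paths, a compact Steiner-style alternative. Edges are always the
background-induced edges on the retained nodes; nothing is invented.
Bridging runs against the full integrated (pre-tissue-restriction) filtered
network, since bridges are by definition genes outside the tissue list.
Shortest paths are made unique by taking the lexicographically smallest node
sequence, so outputs are stable across runs and platforms.

## Phenotype-concordance prioritization

For gene g and phenotype p with known gene set G_p, the closeness profile is

    Φ(g, p) = Σ_{g' ∈ G_p} exp(−L(g, g')²)

with L the unweighted shortest-path distance on the integrated network,
L(g, g) = 0 (a known gene scores its own phenotype maximally through the
kernel), and disconnected pairs contributing 0. The association score of
(g, p) is the Pearson correlation, across all phenotypes, of the similarity
row S[p, ·] with Φ(g, ·); a zero-variance profile scores 0. At least three
phenotypes are required — below that the correlation is degenerate. The
whole-profile correlation (including p's own column) is the default, and the
per-phenotype ranking calls the top N genes (N = 1000 by default) as
predicted, with lexicographic tie-breaks. Because Pearson correlation is
scale-invariant, the score measures the *shape* agreement between a gene's
closeness profile and the phenotype's similarity profile, not the absolute
closeness; this is the method's central assumption — phenotype similarity
mirrors the network proximity of the underlying disease genes.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with planted ground truth; its
defaults are the study's conditions wherever those are printed:

| parameter | default | rationale |
|---|---|---|
| `n_annotation` | 2030 | published annotation-union size |
| `enrichment_set_sizes` | 148…1890 (nine sets) | published per-study sizes |
| `mouse_dataset_indices` | the three mouse studies | published species mix |
| `n_overlap` | 426 | published tissue-universe size |
| `n_diseases` | 5 | FSGS, MN, MCD, DN, IgA |
| planted up / down / inconsistent | 3 / 18 / 16 | published all-disease stratum |
| `deg_p_threshold` | 0.05 | published DE criterion |
| `score_threshold`, cap | 0.9 | published confidence threshold |
| `top_n` | 1000 | published prediction cut-off |

Where the study prints no value, a single realistic choice is made and kept:

* **Universe size 4000.** Large enough that the annotation set, enrichment
  fills and background genes do not exhaust each other; small enough that a
  full run takes about a second.
* **Interactome.** A preferential-attachment backbone (m = 2) plus a 10%
  uniform-random edge fraction gives the heavy-tailed degree profile of real
  interactomes. Because genes of a shared cellular machinery interact far
  more densely than the genome background, an extra `core_edge_factor × 426`
  candidate edges are laid down inside the tissue core with rank-skewed
  endpoint weights (exponent 1.3) and a higher-confidence channel
  distribution; with `core_edge_factor = 3` the filtered tissue network
  lands at the published profile (~850 edges, ~2 interactions per node,
  largest component holding ≈80% of nodes and >99% of edges, ~100 isolated
  nodes, a few two-node islets).
* **Background DE rate 0.05 per disease.** Background genes are null genes:
  p-values uniform, so they cross the 0.05 threshold at rate 0.05,
  independently per disease; non-DE p-values are uniform on (0.05, 1] and DE
  p-values on (0, 0.05), since only the thresholded indicator and the sign
  matter downstream. Under independence the expected number of background
  genes DE in all five diseases with one consistent sign is ≈ 400·2·(0.025)⁵
  ≈ 6·10⁻⁵, which is what makes exact planted-candidate recovery a testable
  guarantee.
* **Phenotypes.** Six phenotypes in three clusters. Cluster anchors are
  moderate-degree nodes (degree 6–25) of the largest component kept ≥ 5 hops
  apart; each phenotype gets its own center (the anchor or a distinct
  neighbor), and draws a 10-gene module from a tight BFS pool (1.5× the
  module size) around it, split 60/40 into known and held-out genes. The
  similarity matrix is **derived from the planted modules**: the mean
  closeness kernel between two phenotypes' known sets, cosine-normalized by
  the within-set closeness (unit diagonal by construction), plus small
  non-negative noise. This realizes the prioritization method's premise in
  the generated data; an earlier design with fixed within/between-cluster
  similarity levels was discarded because it asserted similarities the
  module geometry did not support, violating the method's own model.

What the generator does **not** emulate: cross-disease correlation of
background DE (in real data DE fractions per disease are far higher and
strongly correlated across diseases, which is why the real study's strata
are much flatter than the synthetic ones); probe-level duplication and
platform effects; literature bias in curated edges; and any phenotype
similarity derived from clinical text. Passing tests therefore demonstrate
the correctness of the set algebra, integration arithmetic, classification
logic, graph operations and scoring — not that real inputs satisfy the
generator's independence assumptions.

## Numerical conventions and degenerate inputs

* Percentages display at one decimal (half-up), overlap proportions at two
  decimals; all comparisons in code use exact values.
* Empty universe → empty network without error; a single-node network
  reports largest-component fractions of 1.0 by convention (logged); a
  zero-edge network reports an edge fraction of 1.0 vacuously.
* Shortest-path and ranking tie-breaks are lexicographic everywhere.
* All randomness flows through `numpy` generators keyed on
  (seed, stage index); identical configuration and seed give byte-identical
  outputs, and stage seeds stay below 2³¹.

## Problem sizes used in the checks

The acceptance script runs the full pipeline at the default study-scale
conditions (4000-gene universe, 426-gene core) and measures held-out rank
recovery over 10 seeded replicates; the test suite uses the same scale for
recovery checks (20 replicates) and a scaled-down configuration (400 genes,
40-gene core) for fast unit tests. These sizes are the package's own
defaults for a laptop-scale run.

## Known limitations

* The score-integration prior and the exact variant of the prioritization
  algorithm used originally are unpublished; both are exposed as
  configuration rather than guessed, and the direct-correlation variant
  with the exp(−L²) kernel is the default.
* Bridge-node outputs are policy-labeled supersets/compactions, not matched
  to any hand-curated published figure.
* With few phenotypes the correlation score is coarse (scale-invariance
  makes far-field genes competitive); discrimination improves with the
  number and cluster structure of phenotypes.
* The pipeline consumes DEG tables as given; it does not re-derive them
  from raw expression data, apply batch correction, or distinguish probes
  from genes beyond deterministic per-gene deduplication.
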