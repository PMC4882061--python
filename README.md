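# gcnet

Tissue-restricted protein–protein interaction (PPI) network analysis for
glomerular cytoskeleton genes.

Glomerular diseases — FSGS, membranous nephropathy, minimal change disease,
diabetic nephropathy, IgA nephropathy — share a failure mode: the actin- and
microtubule-based cytoskeleton of glomerular cells (above all the podocyte
foot process) loses its organization, and the filtration barrier leaks
protein. `gcnet` is for computational biologists who want to study that
machinery as a network rather than one gene at a time. It builds a
cytoskeleton-annotated, glomerulus-enriched PPI network, nominates candidate
disease genes by cross-disease expression consistency, reconstructs
candidate-centered subnetworks, and prioritizes candidate–phenotype
associations.

## The method

Four computational stages, each available as a library module and a CLI
stage:

1. **Gene-set assembly** (`gcnet.genesets`). Cytoskeleton annotation sets
   and per-study glomerulus-enriched sets are combined by set union (mouse
   sets first routed through an ortholog map); the tissue universe is the
   intersection of the two unions.
2. **Interaction integration** (`gcnet.interactome`). Per-channel
   confidence scores s_i ∈ [0,1] combine by capped noisy-OR,
   `1 − Π(1 − min(s_i, 0.9))`, so a single channel scores at most 0.9;
   scored edges pass at combined ≥ 0.9, literature-curated edges always
   pass. The network is induced on the tissue universe (isolated genes kept)
   and summarized by degree and betweenness centrality
   `C_B(v) = Σ_{s,t} σ_st(v)/σ_st`.
3. **Consistency classification** (`gcnet.consistency`). A gene is DE in a
   disease iff p < 0.05 in that disease's table; genes DE in *all* K
   diseases with one consistent direction are the candidates. Strata counts,
   per-disease network DEG percentages, and a label-permutation null are
   provided.
4. **Subnetworks and prioritization** (`gcnet.subnetworks`,
   `gcnet.cipher`). Candidates are re-connected through common-neighbor (or
   greedy Steiner) bridge nodes and linked to known disease genes; each
   (gene, phenotype) pair is scored by the Pearson correlation between the
   phenotype-similarity row S[p,·] and the gene's network-closeness profile
   Φ(g,p) = Σ_{g'∈G_p} exp(−L(g,g')²), with the top 1000 genes per
   phenotype called as predicted.

A synthetic-data module (`gcnet.synthetic`) generates every input at the
study's published scale with planted ground truth — a 2030-gene annotation
set, nine enrichment studies (sizes 148–1890, three in mouse identifiers), a
426-gene tissue core, five disease tables with 3/18/16 planted
consistent-up/consistent-down/inconsistent genes, and clustered phenotype
modules — so the whole pipeline is testable without any downloads. See
`docs/methods.md` for the model details and generator assumptions.

## Worked example

Run the synthetic study end to end:

```bash
$ gcnet run-all --synthetic --seed 2 --out demo_out
tissue network: 426 nodes, 876 edges (2.1 interactions/node)
candidates: 3 up, 18 down
report: demo_out/report.json
```

The tissue network has 426 nodes (the annotation ∩ enrichment core) and
about two surviving high-confidence interactions per node; the consistency
classifier recovers exactly the planted candidates — 3 consistently
up-regulated and 18 consistently down-regulated across all five disease
tables — while the 16 planted direction-inconsistent genes are correctly
excluded. `demo_out/` contains the intermediate TSVs (filtered edge list,
node metrics with degree/betweenness/component, consistency strata,
candidate list, subnetwork tables, per-phenotype prioritization ranks) and
`report.json` with the machine-readable run summary.

The same run from files: `gcnet synth --seed 2 --out inputs/` writes every
input as TSV plus a `config.yaml`, and
`gcnet run-all --config inputs/config.yaml --out demo_out` reproduces the
identical report through the file-based code path.

Library use mirrors the CLI:

```python
from gcnet import PipelineConfig, SyntheticConfig, run_pipeline

report = run_pipeline(PipelineConfig(synthetic=SyntheticConfig(seed=2)))
print(report.network_summary.n_nodes)      # 426
print(sorted(report.candidates.up.genes))  # the 3 planted up-regulated genes
```

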