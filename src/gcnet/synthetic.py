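"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure of the real inputs: a
sparse, heavy-tailed interactome with per-channel confidence scores; a large
annotation (cytoskeleton) set and nine glomerulus-enriched study sets — three
of them in mouse identifiers routed through an ortholog map — whose
intersection with the annotation set is a planted core of a few hundred
genes; five per-disease differential-expression tables with planted
direction-consistent candidates and direction-inconsistent decoys; and
clustered phenotype modules with a matching phenotype-similarity matrix.

Everything is deterministic under a fixed seed: each stage draws from a
``numpy`` generator keyed on (seed, stage index), so regenerating any stage
with the same config is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .genesets import GeneSet, OrthologMap, HUMAN, MOUSE
from .consistency import DiseaseExpressionTable
from .interactome import ScoredInteraction, InteractionNetwork, CURATED, SCORED
from .cipher import PhenotypeSimilarity
from .subnetworks import DiseaseGeneMap

# Glomerulus-enriched gene counts of the nine published expression studies
# (SAGE, microarray, EST and plasmid-library profiling, 2003-2011); the
# indices of the three mouse-identifier studies follow the same ordering.
STUDY_SET_SIZES = (148, 102, 310, 165, 914, 130, 202, 675, 1890)
MOUSE_STUDY_INDICES = (2, 3, 4)

DISEASE_NAMES = ("FSGS", "MN", "MCD", "DN", "IgA")


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the real study: a 2030-gene annotation set,
    nine enrichment sets with the published sizes (three in mouse
    identifiers), a 426-gene annotation/enrichment core, five diseases with
    3 planted consistently-up, 18 consistently-down and 16 inconsistent
    genes, DE at p < 0.05, and six phenotypes in three clusters.
    """

    seed: int = 0
    n_genes: int = 4000
    n_annotation: int = 2030
    n_enriched_datasets: int = 9
    enrichment_set_sizes: tuple[int, ...] = STUDY_SET_SIZES
    mouse_dataset_indices: tuple[int, ...] = MOUSE_STUDY_INDICES
    n_overlap: int = 426
    ortholog_unmapped_rate: float = 0.05
    # interactome
    attachment_edges: int = 2
    random_edge_fraction: float = 0.1
    n_sources: int = 3
    curated_fraction: float = 0.1
    planted_edge_fraction: float = 0.05
    core_edge_factor: float = 3.0
    # disease tables
    n_diseases: int = 5
    n_planted_consistent_up: int = 3
    n_planted_consistent_down: int = 18
    n_planted_inconsistent: int = 16
    deg_p_threshold: float = 0.05
    background_de_rate: float = 0.05
    # phenotypes
    n_phenotypes: int = 6
    n_phenotype_clusters: int = 3
    module_size: int = 10
    known_gene_fraction: float = 0.6
    module_pool_factor: float = 1.5
    cluster_separation: int = 5
    center_degree_min: int = 6
    center_degree_max: int = 25
    similarity_noise: float = 0.05

    @property
    def n_planted(self) -> int:
        return (self.n_planted_consistent_up + self.n_planted_consistent_down
                + self.n_planted_inconsistent)

    @property
    def effective_overlap(self) -> int:
        return min(self.n_overlap, self.n_annotation, self.n_genes)

    def validate(self) -> None:
        counts = (
            self.n_genes, self.n_annotation, self.n_enriched_datasets,
            self.n_overlap, self.n_sources, self.n_diseases,
            self.n_planted_consistent_up, self.n_planted_consistent_down,
            self.n_planted_inconsistent, self.n_phenotypes, self.module_size,
            self.attachment_edges,
        )
        if any(c < 0 for c in counts):
            raise SyntheticConfigError("all counts must be non-negative")
        if len(self.enrichment_set_sizes) != self.n_enriched_datasets:
            raise SyntheticConfigError(
                f"{self.n_enriched_datasets} datasets but "
                f"{len(self.enrichment_set_sizes)} sizes given"
            )
        if any(i >= self.n_enriched_datasets for i in self.mouse_dataset_indices):
            raise SyntheticConfigError("mouse dataset index out of range")
        if self.n_annotation > self.n_genes:
            raise SyntheticConfigError("annotation set larger than universe")
        if self.n_planted > self.effective_overlap:
            raise SyntheticConfigError(
                f"{self.n_planted} planted genes exceed the achievable "
                f"annotation/enrichment intersection ({self.effective_overlap})"
            )
        if self.n_diseases < 2 and self.n_planted_inconsistent > 0:
            raise SyntheticConfigError(
                "direction inconsistency needs at least 2 diseases"
            )
        for name in ("deg_p_threshold", "background_de_rate", "curated_fraction",
                     "planted_edge_fraction", "random_edge_fraction",
                     "ortholog_unmapped_rate", "known_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{name}={v} outside [0, 1]")
        largest_fill = max(
            (s for s in self.enrichment_set_sizes), default=0
        )
        if largest_fill > self.n_genes - self.n_annotation + self.effective_overlap:
            raise SyntheticConfigError(
                "universe too small for the requested enrichment set sizes"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stage])


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _mouse_name(human: str) -> str:
    return "Mm" + human


@dataclass(frozen=True)
class SyntheticUniverse:
    """Gene-set stage output, including the planted ground truth."""

    universe: GeneSet
    annotation: GeneSet
    enrichment_sets: tuple[GeneSet, ...]
    ortholog_map: OrthologMap
    core: GeneSet                       # the planted annotation∩enrichment set
    planted_up: GeneSet
    planted_down: GeneSet
    planted_inconsistent: GeneSet


def generate_universe(config: SyntheticConfig) -> SyntheticUniverse:
    """Build the gene universe, annotation set, enrichment sets and orthologs.

    The core (annotation ∩ enrichment-union) is constructed exactly: core
    genes sit in the annotation set and in at least one enrichment set, and
    every non-core enrichment gene is drawn from outside the annotation set,
    so the downstream intersection recovers the core gene-for-gene.  Mouse
    study sets carry mouse identifiers; their core genes are guaranteed an
    ortholog pair, while non-core mouse genes drop out of the map at the
    configured unmapped rate.
    """
    config.validate()
    rng = _rng(config, 0)
    names = np.array([_gene_name(i) for i in range(config.n_genes)])
    order = rng.permutation(config.n_genes)
    n_core = config.effective_overlap
    core_genes = names[order[:n_core]]
    annotation_genes = names[order[:config.n_annotation]]
    pool = names[order[config.n_annotation:]]  # genes outside the annotation set

    universe = GeneSet(name="universe", species=HUMAN, genes=frozenset(names),
                       provenance="synthetic gene universe")
    annotation = GeneSet(name="annotation", species=HUMAN,
                         genes=frozenset(annotation_genes),
                         provenance="synthetic cytoskeleton annotation set")

    # distribute core genes across the enrichment sets proportionally to size,
    # guaranteeing every core gene lands in at least one set
    sizes = np.array(config.enrichment_set_sizes, dtype=float)
    memberships: list[list[str]] = [[] for _ in sizes] if len(sizes) else []
    if len(sizes) and n_core:
        probs = sizes / sizes.sum()
        assignment = rng.choice(len(sizes), size=n_core, p=probs)
        for gene, s in zip(core_genes, assignment):
            memberships[s].append(gene)
        # trim any set whose core share exceeds its size (tiny sets)
        for i, size in enumerate(config.enrichment_set_sizes):
            while len(memberships[i]) > size:
                moved = memberships[i].pop()
                target = int(np.argmin([len(m) / s for m, s in
                                        zip(memberships, sizes)]))
                memberships[target].append(moved)

    enrichment_sets = []
    mouse_pairs: set[tuple[str, str]] = set()
    mouse_set = set(config.mouse_dataset_indices)
    for i, size in enumerate(config.enrichment_set_sizes):
        core_share = memberships[i] if memberships else []
        n_fill = size - len(core_share)
        fill = rng.choice(pool, size=n_fill, replace=False) if n_fill else []
        human_genes = sorted(set(core_share) | set(fill))
        if i in mouse_set:
            genes = frozenset(_mouse_name(g) for g in human_genes)
            for g in human_genes:
                is_core = g in set(core_share)
                if is_core or rng.random() >= config.ortholog_unmapped_rate:
                    mouse_pairs.add((_mouse_name(g), g))
            species = MOUSE
        else:
            genes = frozenset(human_genes)
            species = HUMAN
        enrichment_sets.append(GeneSet(
            name=f"study_{i + 1}", species=species, genes=genes,
            provenance=f"synthetic enrichment study {i + 1} (n={size})",
        ))

    planted = rng.choice(core_genes, size=config.n_planted, replace=False) \
        if config.n_planted else np.array([], dtype=object)
    n_up = config.n_planted_consistent_up
    n_down = config.n_planted_consistent_down
    mk = lambda name, genes: GeneSet(name=name, species=HUMAN,
                                     genes=frozenset(genes),
                                     provenance="planted ground truth")
    return SyntheticUniverse(
        universe=universe,
        annotation=annotation,
        enrichment_sets=tuple(enrichment_sets),
        ortholog_map=OrthologMap(pairs=frozenset(mouse_pairs),
                                 source_species=MOUSE, target_species=HUMAN),
        core=mk("planted_core", core_genes),
        planted_up=mk("planted_up", planted[:n_up]),
        planted_down=mk("planted_down", planted[n_up:n_up + n_down]),
        planted_inconsistent=mk("planted_inconsistent", planted[n_up + n_down:]),
    )


def generate_interactome(
    config: SyntheticConfig,
    universe: GeneSet,
    planted: GeneSet | None = None,
    core: GeneSet | None = None,
) -> list[ScoredInteraction]:
    """Scored interactome: preferential attachment plus uniform random edges.

    A preferential-attachment backbone gives the heavy-tailed degree profile
    of real interactomes (hub genes), topped up with a uniform-random edge
    fraction.  Each scored edge carries 1..n_sources channel scores; a
    ``curated_fraction`` of edges are literature-curated (no channel scores).

    Genes of a shared cellular machinery interact far more densely than the
    genome background, so when a ``core`` set is given an extra
    ``core_edge_factor * |core|`` preferentially-attached edges are laid
    down inside it, scored from a higher-confidence channel distribution.
    When a planted gene set is given, ``planted_edge_fraction`` of its pairs
    are forced in as high-confidence edges (combined score >= 0.9) so the
    planted candidates survive confidence filtering.
    """
    if not universe.genes:
        raise SyntheticConfigError("universe must be non-empty")
    rng = _rng(config, 1)
    nodes = sorted(universe.genes)
    n = len(nodes)
    m = min(config.attachment_edges, max(n - 1, 0))
    if m > 0 and n > m:
        ba = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        perm = rng.permutation(n)
        pairs = {tuple(sorted((nodes[perm[a]], nodes[perm[b]])))
                 for a, b in ba.edges}
    else:
        pairs = set()
    n_extra = int(round(config.random_edge_fraction * len(pairs)))
    attempts = 0
    while n_extra > 0 and attempts < 50 * n_extra:
        a, b = rng.integers(0, n, size=2)
        attempts += 1
        if a == b:
            continue
        pair = tuple(sorted((nodes[a], nodes[b])))
        if pair not in pairs:
            pairs.add(pair)
            n_extra -= 1

    core_pairs: set[tuple[str, str]] = set()
    if core is not None and config.core_edge_factor > 0:
        core_nodes = np.array(sorted(core.genes & universe.genes))
        if len(core_nodes) >= 2:
            # preferential weights over a shuffled core order give the
            # heavy-tailed within-core degree profile (hubs + isolated tail)
            w = 1.0 / (np.arange(len(core_nodes)) + 1.0) ** 1.3
            w /= w.sum()
            shuffled = core_nodes[rng.permutation(len(core_nodes))]
            n_want = int(round(config.core_edge_factor * len(core_nodes)))
            tries = 0
            while len(core_pairs) < n_want and tries < 30 * n_want:
                tries += 1
                i, j = rng.choice(len(shuffled), size=2, p=w)
                if i == j:
                    continue
                pair = tuple(sorted((shuffled[i], shuffled[j])))
                if pair not in pairs:
                    core_pairs.add(pair)

    edges: dict[tuple[str, str], ScoredInteraction] = {}
    for pair in sorted(pairs | core_pairs):
        low, high = (0.45, 0.97) if pair in core_pairs else (0.2, 0.95)
        if rng.random() < config.curated_fraction:
            edges[pair] = ScoredInteraction(
                gene_a=pair[0], gene_b=pair[1], database=CURATED)
        else:
            k = int(rng.integers(1, config.n_sources + 1))
            scores = tuple((f"channel_{j + 1}",
                            float(rng.uniform(low, high))) for j in range(k))
            edges[pair] = ScoredInteraction(
                gene_a=pair[0], gene_b=pair[1], source_scores=scores,
                database=SCORED)

    if planted is not None and config.planted_edge_fraction > 0:
        planted_nodes = sorted(planted.genes & universe.genes)
        candidate_pairs = [
            (a, b)
            for i, a in enumerate(planted_nodes)
            for b in planted_nodes[i + 1:]
        ]
        n_force = int(round(config.planted_edge_fraction * len(candidate_pairs)))
        if config.planted_edge_fraction >= 1.0:
            n_force = len(candidate_pairs)
        chosen = rng.choice(len(candidate_pairs), size=n_force, replace=False) \
            if n_force else []
        for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
            a, b = candidate_pairs[idx]
            scores = (("channel_1", float(rng.uniform(0.85, 0.95))),
                      ("channel_2", float(rng.uniform(0.8, 0.95))))
            edges[(a, b)] = ScoredInteraction(
                gene_a=a, gene_b=b, source_scores=scores, database=SCORED)
    return [edges[p] for p in sorted(edges)]


def generate_disease_tables(
    config: SyntheticConfig,
    candidates_up: GeneSet,
    candidates_down: GeneSet,
    decoys: GeneSet,
    universe: GeneSet,
) -> list[DiseaseExpressionTable]:
    """Per-disease expression tables with planted consistency structure.

    Planted consistently-up genes are DE (p below the threshold) with a
    positive fold change in every disease; consistently-down genes likewise
    negative; decoys are DE in every disease with a guaranteed-mixed sign
    pattern.  Every other gene is DE in each disease independently with
    probability ``background_de_rate`` (random sign); non-DE p-values are
    uniform above the threshold — only the thresholded indicator and the
    sign matter downstream.
    """
    up, down, inc = candidates_up.genes, candidates_down.genes, decoys.genes
    if (up & down) or (up & inc) or (down & inc):
        raise SyntheticConfigError("planted gene sets must be disjoint")
    if config.n_diseases < 2 and inc:
        raise SyntheticConfigError(
            "cannot plant inconsistent genes with fewer than 2 diseases"
        )
    rng = _rng(config, 2)
    thr = config.deg_p_threshold
    K = config.n_diseases
    names = (DISEASE_NAMES[:K] if K <= len(DISEASE_NAMES)
             else tuple(f"D{i + 1}" for i in range(K)))

    # mixed sign vector per decoy: 1..K-1 positive diseases
    decoy_signs: dict[str, np.ndarray] = {}
    for gene in sorted(inc):
        n_pos = int(rng.integers(1, K))
        signs = np.full(K, -1, dtype=int)
        signs[rng.choice(K, size=n_pos, replace=False)] = 1
        decoy_signs[gene] = signs

    tables = []
    genes = sorted(universe.genes)
    for d, disease in enumerate(names):
        rows: dict[str, tuple[int, float]] = {}
        for gene in genes:
            if gene in up or gene in down:
                sign = 1 if gene in up else -1
                p = float(rng.uniform(0.0, thr))
            elif gene in inc:
                sign = int(decoy_signs[gene][d])
                p = float(rng.uniform(0.0, thr))
            elif rng.random() < config.background_de_rate:
                sign = 1 if rng.random() < 0.5 else -1
                p = float(rng.uniform(0.0, thr))
            else:
                sign = 1 if rng.random() < 0.5 else -1
                p = float(rng.uniform(thr, 1.0))
            rows[gene] = (sign, p)
        tables.append(DiseaseExpressionTable(disease=disease, rows=rows))
    return tables


@dataclass(frozen=True)
class SyntheticPhenotypes:
    """Phenotype-similarity stage output with planted modules."""

    similarity: PhenotypeSimilarity
    disease_genes: DiseaseGeneMap
    modules: dict[str, frozenset[str]] = field(compare=False)
    held_out: dict[str, frozenset[str]] = field(compare=False)


def generate_phenotype_data(
    config: SyntheticConfig, network: InteractionNetwork
) -> SyntheticPhenotypes:
    """Clustered phenotype modules on the network plus a similarity matrix.

    Cluster anchors are moderate-degree nodes of the largest component kept
    at least ``cluster_separation`` hops apart; each phenotype gets its own
    center (the anchor, or a distinct neighbor of it for the other
    phenotypes of the cluster) and draws its module from a tight
    breadth-first pool around that center, so same-cluster modules overlap
    without coinciding.  Each module splits into known disease genes
    (exposed in the disease-gene map) and held-out genes, the recovery
    targets for prioritization.

    The similarity matrix is derived from the modules themselves: the mean
    closeness kernel between two phenotypes' known gene sets, normalized by
    the within-set closeness (a cosine-style normalization giving a unit
    diagonal), plus non-negative noise, clipped to [0, 1].  This realizes
    the premise of concordance-based prioritization — phenotype similarity
    mirrors the network proximity of the underlying disease genes — so
    phenotypes with identical known genes get similarity exactly 1 and
    unrelated clusters similarity near 0.
    """
    if config.n_phenotypes < 3:
        raise SyntheticConfigError(
            "need at least 3 phenotypes (correlation scoring is degenerate)"
        )
    if network.n_nodes == 0:
        raise SyntheticConfigError("network must be non-empty")
    rng = _rng(config, 3)
    g = network.graph
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    lcc = sorted(components[0])
    if len(lcc) < config.module_size:
        raise SyntheticConfigError(
            f"largest component ({len(lcc)} nodes) smaller than module_size"
        )
    n_clusters = max(1, min(config.n_phenotype_clusters, config.n_phenotypes))

    candidates = [v for v in lcc
                  if config.center_degree_min <= g.degree(v)
                  <= config.center_degree_max]
    if len(candidates) < n_clusters:
        candidates = list(lcc)
    candidates.sort(key=lambda v: (-g.degree(v), v))
    anchors: list[str] = []
    separation = config.cluster_separation
    while len(anchors) < n_clusters and separation >= 0:
        anchors = []
        for v in candidates:
            if all(nx.shortest_path_length(g, v, a) >= separation
                   for a in anchors):
                anchors.append(v)
            if len(anchors) == n_clusters:
                break
        separation -= 1
    if len(anchors) < n_clusters:
        raise SyntheticConfigError("could not place distinct cluster anchors")

    phenotypes = [f"P{i + 1:02d}" for i in range(config.n_phenotypes)]
    used: set[str] = set()
    centers: dict[str, str] = {}
    for i, pheno in enumerate(phenotypes):
        anchor = anchors[i % n_clusters]
        if anchor not in used:
            centers[pheno] = anchor
        else:
            # nearest unused node to the anchor, highest degree first
            for layer in nx.bfs_layers(g, anchor):
                fresh = sorted((v for v in layer if v not in used),
                               key=lambda v: (-g.degree(v), v))
                if fresh:
                    centers[pheno] = fresh[0]
                    break
            else:
                raise SyntheticConfigError("network exhausted placing centers")
        used.add(centers[pheno])

    modules: dict[str, frozenset[str]] = {}
    known: dict[str, frozenset[str]] = {}
    held: dict[str, frozenset[str]] = {}
    pool_size = max(config.module_size,
                    int(config.module_pool_factor * config.module_size))
    for pheno in phenotypes:
        center = centers[pheno]
        pool: list[str] = []
        for layer in nx.bfs_layers(g, center):
            pool.extend(sorted(layer))
            if len(pool) >= pool_size:
                break
        pool = pool[:pool_size]
        if len(pool) < config.module_size:
            raise SyntheticConfigError(
                f"neighborhood of {center} too small for module_size"
            )
        module = {center}
        extra = rng.choice([v for v in pool if v != center],
                           size=config.module_size - 1, replace=False)
        module.update(extra.tolist())
        modules[pheno] = frozenset(module)
        n_known = max(1, int(math.ceil(config.known_gene_fraction
                                       * config.module_size)))
        n_known = min(n_known, config.module_size)
        chosen = rng.choice(sorted(module - {center}), size=n_known - 1,
                            replace=False) if n_known > 1 else np.array([])
        known[pheno] = frozenset({center} | set(chosen.tolist()))
        held[pheno] = modules[pheno] - known[pheno]

    # similarity from the actual cross-closeness of the known gene sets
    k = config.n_phenotypes
    closeness = np.zeros((k, k))
    lengths = {v: nx.single_source_shortest_path_length(g, v)
               for v in sorted(set().union(*known.values()))}
    for i in range(k):
        for j in range(k):
            total = 0.0
            ki, kj = known[phenotypes[i]], known[phenotypes[j]]
            for a in ki:
                for b in kj:
                    d = lengths[a].get(b)
                    if d is not None:
                        total += math.exp(-float(d) ** 2)
            closeness[i, j] = total / (len(ki) * len(kj))
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            denom = math.sqrt(closeness[i, i] * closeness[j, j])
            sim[i, j] = closeness[i, j] / denom if denom > 0 else 0.0
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    noise = rng.uniform(0.0, config.similarity_noise, size=(k, k))
    sim = np.clip(sim + (noise + noise.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)

    return SyntheticPhenotypes(
        similarity=PhenotypeSimilarity(phenotypes=tuple(phenotypes), matrix=sim),
        disease_genes=DiseaseGeneMap(
            genes_by_phenotype={p: known[p] for p in phenotypes},
            names={p: f"synthetic phenotype {p}" for p in phenotypes},
        ),
        modules=modules,
        held_out=held,
    )
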