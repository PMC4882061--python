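"""Scored interaction integration, confidence filtering, and network topology.

Interaction confidences from several evidence channels are combined with a
noisy-OR product (each channel capped, STRING-style, so that an edge supported
by a single source can score at most the cap, 0.9 by default).  Edges at or
above the 0.9 combined-score threshold — plus literature-curated edges, which
carry no channel scores — are kept, and the network is induced on the
tissue-restricted gene universe, retaining isolated genes as disconnected
nodes.  Node importance is measured by degree and betweenness centrality

    C_B(v) = sum over unordered pairs {s,t}, v not in {s,t}, of
             sigma_st(v) / sigma_st

where sigma_st counts shortest s-t paths and sigma_st(v) those through v.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .genesets import GeneSet

logger = logging.getLogger(__name__)

CURATED = "curated"
SCORED = "scored"

DEFAULT_CAP = 0.9
DEFAULT_THRESHOLD = 0.9


class ScoreError(ValueError):
    """Raised on confidence scores outside [0, 1]."""


def combine_scores(
    source_scores,
    per_source_cap: float = DEFAULT_CAP,
    prior: float = 0.0,
) -> float:
    """Noisy-OR combination of per-channel confidence scores.

    Each channel score is capped at ``per_source_cap`` and the capped scores
    are combined as ``1 - prod_i (1 - s_i)``.  With ``prior > 0`` each channel
    is first corrected for the random-expectation prior
    (``(s - p) / (1 - p)``, floored at 0), combined, and the prior re-added —
    the correction used by STRING-style integration.  A single channel at or
    above the cap therefore combines to exactly the cap.

    Parameters
    ----------
    source_scores : iterable of (source name, score) or of bare scores
    per_source_cap : float
        Upper bound applied to every channel before combination.
    prior : float
        Random-expectation prior in [0, 1); 0 disables the correction.
    """
    scores = []
    for item in source_scores:
        s = item[1] if isinstance(item, tuple) else float(item)
        if not 0.0 <= s <= 1.0:
            raise ScoreError(f"confidence score {s} outside [0, 1]")
        scores.append(min(float(s), per_source_cap))
    if not 0.0 <= prior < 1.0:
        raise ScoreError(f"prior {prior} outside [0, 1)")
    if not scores:
        return 0.0
    if prior > 0.0:
        residual = 1.0
        for s in scores:
            residual *= 1.0 - max(s - prior, 0.0) / (1.0 - prior)
        return (1.0 - residual) * (1.0 - prior) + prior
    residual = 1.0
    for s in scores:
        residual *= 1.0 - s
    return 1.0 - residual


@dataclass(frozen=True)
class ScoredInteraction:
    """An undirected gene pair with per-channel scores and a combined score.

    The pair is stored in canonical (sorted) order so duplicates collapse.
    ``database`` distinguishes literature-curated edges (no channel scores,
    retained regardless of threshold) from scored edges.
    """

    gene_a: str
    gene_b: str
    source_scores: tuple[tuple[str, float], ...] = ()
    combined_score: float | None = None
    database: str = SCORED

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ScoreError(f"self-interaction {self.gene_a!r} not allowed")
        if self.database not in (CURATED, SCORED):
            raise ScoreError(f"unknown database tag {self.database!r}")
        a, b = sorted((self.gene_a, self.gene_b))
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        object.__setattr__(self, "source_scores", tuple(self.source_scores))
        for _, s in self.source_scores:
            if not 0.0 <= s <= 1.0:
                raise ScoreError(f"source score {s} outside [0, 1]")
        if self.combined_score is None and self.source_scores:
            object.__setattr__(
                self, "combined_score", combine_scores(self.source_scores)
            )
        if self.combined_score is not None and not 0.0 <= self.combined_score <= 1.0:
            raise ScoreError(f"combined score {self.combined_score} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def filter_interactions(
    edges,
    threshold: float = DEFAULT_THRESHOLD,
    strict: bool = False,
) -> list[ScoredInteraction]:
    """Keep high-confidence edges and deduplicate unordered pairs.

    Scored edges pass iff ``combined_score >= threshold`` (inclusive, so a
    single strong channel at the cap qualifies).  Curated edges bypass the
    threshold unless ``strict`` is set, in which case they are thresholded
    like any other edge (a curated edge with no score then scores 0).
    Duplicate pairs keep the maximum combined score; a curated duplicate
    makes the kept edge curated.
    """
    best: dict[tuple[str, str], ScoredInteraction] = {}
    for e in edges:
        combined = e.combined_score if e.combined_score is not None else 0.0
        if e.database == CURATED and not strict:
            passes = True
        else:
            passes = combined >= threshold
        if not passes:
            continue
        prev = best.get(e.pair)
        if prev is None:
            best[e.pair] = e
        else:
            prev_c = prev.combined_score if prev.combined_score is not None else 0.0
            database = CURATED if CURATED in (prev.database, e.database) else SCORED
            keep = e if combined > prev_c else prev
            best[e.pair] = ScoredInteraction(
                gene_a=keep.gene_a, gene_b=keep.gene_b,
                source_scores=keep.source_scores,
                combined_score=max(prev_c, combined) if (prev.combined_score is not None or e.combined_score is not None) else None,
                database=database,
            )
    return [best[p] for p in sorted(best)]


@dataclass
class InteractionNetwork:
    """An undirected simple graph over gene identifiers.

    Thin wrapper around :class:`networkx.Graph`; node metrics (degree,
    betweenness) are computed on demand and cached on the instance.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes) -> "InteractionNetwork":
        return InteractionNetwork(graph=nx.Graph(self.graph.subgraph(nodes)))

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def induce_network(universe: GeneSet, edges) -> InteractionNetwork:
    """Induce the network on a gene universe from filtered edges.

    The node set is the *whole* universe — genes without a surviving
    interaction stay as isolated nodes — and the edge set is every filtered
    edge with both endpoints in the universe.
    """
    g = nx.Graph()
    g.add_nodes_from(universe.genes)
    for e in edges:
        if e.gene_a in universe.genes and e.gene_b in universe.genes:
            g.add_edge(
                e.gene_a, e.gene_b,
                combined_score=e.combined_score, database=e.database,
            )
    return InteractionNetwork(graph=g)


def build_network(edges) -> InteractionNetwork:
    """Network over exactly the genes that appear in the given edges."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b,
                   combined_score=e.combined_score, database=e.database)
    return InteractionNetwork(graph=g)


def compute_degree(network: InteractionNetwork) -> dict[str, int]:
    """Number of incident edges per gene."""
    return dict(network.graph.degree())


def compute_betweenness(network: InteractionNetwork) -> dict[str, float]:
    """Betweenness centrality C_B(v), summed over unordered node pairs.

    Uses Brandes' accumulation (exact on unweighted graphs); equals the
    exhaustive enumeration of all shortest paths.
    """
    return nx.betweenness_centrality(network.graph, normalized=False)


@dataclass(frozen=True)
class NetworkSummary:
    """Headline topology statistics of an interaction network."""

    n_nodes: int
    n_edges: int
    mean_interactions_per_node: float
    lcc_node_fraction: float
    lcc_edge_fraction: float
    n_isolated_nodes: int
    n_two_node_islets: int
    n_components: int


def mean_interactions_per_node(n_nodes: int, n_edges: int) -> float:
    """Edges per node, the convention used for the printed network mean."""
    return n_edges / n_nodes if n_nodes else 0.0


def summarize_network(network: InteractionNetwork) -> NetworkSummary:
    """Node/edge counts, edges-per-node mean, and component structure.

    ``mean_interactions_per_node`` is ``n_edges / n_nodes`` (not the mean
    degree, which is twice that).  LCC fractions use the whole network as
    denominator; with zero edges the edge fraction is 1.0 by convention.
    """
    n = network.n_nodes
    m = network.n_edges
    if n == 0:
        return NetworkSummary(0, 0, 0.0, 0.0, 0.0, 0, 0, 0)
    components = list(nx.connected_components(network.graph))
    sizes = sorted((len(c) for c in components), reverse=True)
    lcc = max(components, key=len)
    lcc_edges = network.graph.subgraph(lcc).number_of_edges()
    if n == 1:
        logger.info("single-node network: LCC fractions 1.0 by convention")
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        mean_interactions_per_node=mean_interactions_per_node(n, m),
        lcc_node_fraction=len(lcc) / n,
        lcc_edge_fraction=lcc_edges / m if m else 1.0,
        n_isolated_nodes=sum(1 for s in sizes if s == 1),
        n_two_node_islets=sum(1 for s in sizes if s == 2),
        n_components=len(components),
    )


# ---------------------------------------------------------------------------
# TSV / GraphML input-output


def read_interactions_tsv(path) -> list[ScoredInteraction]:
    """Read a scored edge list.

    Columns: gene_a, gene_b, database, combined_score, then any number of
    per-source score columns (header names become source names).  Header
    line is ``#``-prefixed; an empty combined_score field means unscored
    (curated) edges.
    """
    edges: list[ScoredInteraction] = []
    source_names: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().split("\t")
                source_names = header[4:]
                continue
            parts = line.split("\t")
            a, b, database = parts[0], parts[1], parts[2]
            combined = float(parts[3]) if len(parts) > 3 and parts[3] != "" else None
            sources = []
            for name, value in zip(source_names, parts[4:]):
                if value != "":
                    sources.append((name, float(value)))
            edges.append(ScoredInteraction(
                gene_a=a, gene_b=b, source_scores=tuple(sources),
                combined_score=combined, database=database,
            ))
    return edges


def write_interactions_tsv(edges, path) -> None:
    source_names = sorted({name for e in edges for name, _ in e.source_scores})
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\tdatabase\tcombined_score\t"
                 + "\t".join(source_names) + "\n")
        for e in sorted(edges, key=lambda e: e.pair):
            by_name = dict(e.source_scores)
            combined = "" if e.combined_score is None else f"{e.combined_score:.6g}"
            row = [e.gene_a, e.gene_b, e.database, combined]
            row += [f"{by_name[n]:.6g}" if n in by_name else "" for n in source_names]
            fh.write("\t".join(row) + "\n")


def write_network_tables(network: InteractionNetwork, node_path, edge_path) -> None:
    """Export node table (gene, degree, betweenness, component_id) and edges."""
    degree = compute_degree(network)
    betweenness = compute_betweenness(network)
    component_id: dict[str, int] = {}
    for i, comp in enumerate(
        sorted(nx.connected_components(network.graph), key=lambda c: (-len(c), min(c)))
    ):
        for node in comp:
            component_id[node] = i
    with open(node_path, "w") as fh:
        fh.write("#gene\tdegree\tbetweenness\tcomponent_id\n")
        for gene in sorted(network.nodes):
            fh.write(f"{gene}\t{degree[gene]}\t{betweenness[gene]:.6g}\t"
                     f"{component_id[gene]}\n")
    with open(edge_path, "w") as fh:
        fh.write("#gene_a\tgene_b\tcombined_score\tdatabase\n")
        for a, b in sorted(network.edges):
            data = network.graph.edges[a, b]
            combined = data.get("combined_score")
            fh.write(f"{a}\t{b}\t"
                     f"{'' if combined is None else f'{combined:.6g}'}\t"
                     f"{data.get('database', '')}\n")


def write_graphml(network: InteractionNetwork, path) -> None:
    g = network.graph.copy()
    for _, _, data in g.edges(data=True):
        for k in list(data):
            if data[k] is None:
                del data[k]
    nx.write_graphml(g, path)
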