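"""Candidate-centered subnetwork reconstruction with bridge nodes.

Direction-consistent candidates are typically sparsely interconnected in the
integrated interactome, so subnetworks around them are rebuilt by adding
*bridge* nodes: either every non-seed gene adjacent to at least two seeds
(``common_neighbors``, the default) or the internal nodes of greedily chosen
shortest seed-pair paths (``steiner_greedy``, a compact Steiner-style
alternative).  Edges are always the background-induced edges on the retained
node set — no edges are invented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .genesets import GeneSet
from .interactome import InteractionNetwork

logger = logging.getLogger(__name__)

COMMON_NEIGHBORS = "common_neighbors"
STEINER_GREEDY = "steiner_greedy"

ROLE_SEED = "seed"
ROLE_SEED_UP = "seed_up"
ROLE_SEED_DOWN = "seed_down"
ROLE_BRIDGE = "bridge"
ROLE_KNOWN = "known_disease_gene"
ROLE_ISOLATED = "isolated"


class DiseaseGeneMapError(ValueError):
    pass


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Phenotype identifier -> set of known disease genes (plus a name)."""

    genes_by_phenotype: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        clean = {}
        for pheno, genes in self.genes_by_phenotype.items():
            genes = frozenset(genes)
            if not genes:
                raise DiseaseGeneMapError(f"phenotype {pheno!r} has no genes")
            clean[pheno] = genes
        object.__setattr__(self, "genes_by_phenotype", clean)

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.genes_by_phenotype)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.genes_by_phenotype.values():
            out |= genes
        return frozenset(out)

    def __getitem__(self, phenotype: str) -> frozenset[str]:
        return self.genes_by_phenotype[phenotype]

    def __len__(self) -> int:
        return len(self.genes_by_phenotype)

    @classmethod
    def read_tsv(cls, path) -> "DiseaseGeneMap":
        """Read a TSV with columns phenotype_id, phenotype_name, gene."""
        genes: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                pid, pname, gene = line.split("\t")[:3]
                genes.setdefault(pid, set()).add(gene)
                names[pid] = pname
        return cls(genes_by_phenotype={p: frozenset(g) for p, g in genes.items()},
                   names=names)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#phenotype_id\tphenotype_name\tgene\n")
            for pid in self.phenotypes:
                for gene in sorted(self.genes_by_phenotype[pid]):
                    fh.write(f"{pid}\t{self.names.get(pid, pid)}\t{gene}\n")


@dataclass
class BridgedSubnetwork:
    """Seeds plus bridge nodes with background-induced edges and role flags."""

    network: InteractionNetwork
    seeds: frozenset[str]
    bridges: frozenset[str]
    roles: dict[str, set[str]]

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    @property
    def n_edges(self) -> int:
        return self.network.n_edges

    def write_tables(self, node_path, edge_path) -> None:
        with open(node_path, "w") as fh:
            fh.write("#gene\troles\n")
            for gene in sorted(self.network.nodes):
                fh.write(f"{gene}\t{','.join(sorted(self.roles.get(gene, set())))}\n")
        with open(edge_path, "w") as fh:
            fh.write("#gene_a\tgene_b\n")
            for a, b in sorted(self.network.edges):
                fh.write(f"{a}\t{b}\n")


def _lexicographic_shortest_path(graph: nx.Graph, a: str, b: str) -> list[str] | None:
    """Lexicographically smallest shortest path a->b, or None if unreachable.

    Greedy walk from ``a``: among neighbors one step closer to ``b`` (by BFS
    distance from ``b``), always take the smallest label.  Any such walk is a
    shortest path, and the greedy choice makes the node sequence the
    lexicographic minimum among them.
    """
    if a == b:
        return [a] if a in graph else None
    if a not in graph or b not in graph:
        return None
    dist_to_b = nx.single_source_shortest_path_length(graph, b)
    if a not in dist_to_b:
        return None
    path = [a]
    current = a
    remaining = dist_to_b[a]
    while current != b:
        nxt = min(
            n for n in graph.neighbors(current)
            if dist_to_b.get(n, -1) == remaining - 1
        )
        path.append(nxt)
        current = nxt
        remaining -= 1
    return path


def build_bridged_subnetwork(
    seeds: GeneSet | frozenset[str],
    background: InteractionNetwork,
    policy: str = COMMON_NEIGHBORS,
    seed_roles: dict[str, str] | None = None,
) -> BridgedSubnetwork:
    """Reconstruct a subnetwork around seed genes using bridge nodes.

    Seeds absent from the background are logged and dropped.  Under
    ``common_neighbors`` every non-seed background node adjacent to at least
    two retained seeds becomes a bridge.  Under ``steiner_greedy`` seed pairs
    are processed in sorted order and, whenever a pair is not yet connected
    inside the growing subnetwork but is connected in the background, the
    internal nodes of the lexicographically smallest background shortest path
    are added.  Edges are the background edges among retained nodes.
    """
    seed_genes = set(seeds.genes if isinstance(seeds, GeneSet) else seeds)
    missing = seed_genes - background.nodes
    if missing:
        logger.warning("%d seed genes absent from background, dropped: %s",
                       len(missing), sorted(missing)[:10])
    seed_genes -= missing
    g = background.graph

    if not seed_genes:
        return BridgedSubnetwork(network=InteractionNetwork(graph=nx.Graph()),
                                 seeds=frozenset(), bridges=frozenset(), roles={})

    bridges: set[str] = set()
    if policy == COMMON_NEIGHBORS:
        neighbor_count: dict[str, int] = {}
        for s in seed_genes:
            for n in g.neighbors(s):
                if n not in seed_genes:
                    neighbor_count[n] = neighbor_count.get(n, 0) + 1
        bridges = {n for n, c in neighbor_count.items() if c >= 2}
    elif policy == STEINER_GREEDY:
        retained = set(seed_genes)
        ordered = sorted(seed_genes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                sub = g.subgraph(retained)
                if a in sub and b in sub and nx.has_path(sub, a, b):
                    continue
                path = _lexicographic_shortest_path(g, a, b)
                if path is not None:
                    retained.update(path[1:-1])
        bridges = retained - seed_genes
    else:
        raise ValueError(f"unknown bridge policy {policy!r}")

    nodes = seed_genes | bridges
    sub = InteractionNetwork(graph=nx.Graph(g.subgraph(nodes)))
    # isolated seeds must survive induction
    sub.graph.add_nodes_from(seed_genes)

    roles: dict[str, set[str]] = {}
    for s in seed_genes:
        roles.setdefault(s, set()).add(
            seed_roles.get(s, ROLE_SEED) if seed_roles else ROLE_SEED
        )
        if sub.graph.degree(s) == 0:
            roles[s].add(ROLE_ISOLATED)
    for b in bridges:
        roles.setdefault(b, set()).add(ROLE_BRIDGE)
    return BridgedSubnetwork(network=sub, seeds=frozenset(seed_genes),
                             bridges=frozenset(bridges), roles=roles)


def link_to_disease_genes(
    candidates: GeneSet,
    disease_genes: DiseaseGeneMap,
    background: InteractionNetwork,
    policy: str = COMMON_NEIGHBORS,
) -> BridgedSubnetwork:
    """Subnetwork joining candidates to known disease genes.

    Seeds are the candidates plus every known disease gene present in the
    background; bridges are added under the chosen policy.  Node roles
    distinguish candidates from known disease genes; candidates left with no
    connection are flagged isolated.
    """
    known = disease_genes.all_genes()
    seed_roles = {g: ROLE_SEED for g in candidates.genes}
    seed_roles.update({g: ROLE_KNOWN for g in known})
    # a gene that is both candidate and known keeps both flags below
    result = build_bridged_subnetwork(
        frozenset(candidates.genes | known), background, policy=policy,
        seed_roles=seed_roles,
    )
    for g in candidates.genes & result.seeds:
        result.roles.setdefault(g, set()).add(ROLE_SEED)
    for g in known & result.seeds:
        result.roles.setdefault(g, set()).add(ROLE_KNOWN)
    return result


@dataclass(frozen=True)
class PathLink:
    """One shortest path between a gene pair, or a reachability failure."""

    gene_a: str
    gene_b: str
    length: int | None
    nodes: tuple[str, ...]

    @property
    def reachable(self) -> bool:
        return self.length is not None


def shortest_path_links(
    genes: GeneSet | frozenset[str],
    background: InteractionNetwork,
) -> list[PathLink]:
    """One deterministic shortest path per gene pair in the same component.

    Tie-break: the lexicographically smallest node sequence.  Pairs in
    different components (or genes absent from the background) are reported
    unreachable.  The self-pair of each gene is the trivial length-0 path.
    """
    gene_list = sorted(genes.genes if isinstance(genes, GeneSet) else genes)
    g = background.graph
    links: list[PathLink] = []
    for i, a in enumerate(gene_list):
        for b in gene_list[i:]:
            if a == b:
                if a in g:
                    links.append(PathLink(a, a, 0, (a,)))
                else:
                    links.append(PathLink(a, a, None, ()))
                continue
            path = _lexicographic_shortest_path(g, a, b)
            if path is None:
                links.append(PathLink(a, b, None, ()))
            else:
                links.append(PathLink(a, b, len(path) - 1, tuple(path)))
    return links
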