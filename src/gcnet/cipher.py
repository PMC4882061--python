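"""Network-based disease-gene prioritization by phenotype-profile concordance.

For a gene g and phenotype p, a closeness profile

    Phi(g, p) = sum over known genes g' of p of exp(-L(g, g')^2)

is computed from unweighted shortest-path lengths L on the integrated
interactome (L(g, g) = 0, disconnected pairs contribute 0).  The
prioritization score of (g, p) is the Pearson correlation, across all
phenotypes p', between the phenotype-similarity row S[p, .] and the gene's
closeness profile Phi(g, .): genes whose network neighborhood mirrors the
phenotype's similarity structure score high.  The top N genes per phenotype
(N = 1000 in the original application) are called predicted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import InteractionNetwork
from .subnetworks import DiseaseGeneMap

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 1000

MIN_PHENOTYPES = 3


class PhenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeSimilarity:
    """A symmetric phenotype-phenotype similarity matrix with unit diagonal."""

    phenotypes: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.phenotypes)
        if m.shape != (k, k):
            raise PhenotypeError(f"matrix shape {m.shape} != ({k}, {k})")
        if not np.allclose(m, m.T):
            raise PhenotypeError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise PhenotypeError("similarity diagonal must be 1")
        if m.min() < 0.0 or m.max() > 1.0 + 1e-12:
            raise PhenotypeError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "phenotypes", tuple(self.phenotypes))
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.phenotypes)

    def row(self, phenotype: str) -> np.ndarray:
        return self.matrix[self.phenotypes.index(phenotype)]

    @classmethod
    def read_tsv(cls, path) -> "PhenotypeSimilarity":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(phenotypes=tuple(df.index.astype(str)), matrix=df.to_numpy())

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=list(self.phenotypes),
                     columns=list(self.phenotypes)).to_csv(path, sep="\t")


def _gaussian_kernel(distances: np.ndarray) -> np.ndarray:
    return np.exp(-distances.astype(float) ** 2)


def closeness_matrix(
    network: InteractionNetwork,
    disease_gene_map: DiseaseGeneMap,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Closeness profiles Phi for all genes at once (genes x phenotypes).

    One breadth-first search per known disease gene; phenotypes with no
    known gene in the network contribute a zero column (logged).
    """
    if network.n_nodes == 0:
        raise PhenotypeError("cannot compute closeness on an empty network")
    node_list = sorted(network.nodes) if genes is None else list(genes)
    index = {g: i for i, g in enumerate(node_list)}
    phenotypes = disease_gene_map.phenotypes
    phi = np.zeros((len(node_list), len(phenotypes)))
    # cache BFS results: a known gene may serve several phenotypes
    kernel_cache: dict[str, np.ndarray] = {}
    for j, pheno in enumerate(phenotypes):
        in_network = [g for g in disease_gene_map[pheno] if g in network]
        if not in_network:
            logger.info("phenotype %s: no known gene in network; Phi column is 0",
                        pheno)
            continue
        for known in sorted(in_network):
            if known not in kernel_cache:
                col = np.zeros(len(node_list))
                lengths = nx.single_source_shortest_path_length(network.graph, known)
                for node, d in lengths.items():
                    i = index.get(node)
                    if i is not None:
                        col[i] = math.exp(-float(d) ** 2)
                kernel_cache[known] = col
            phi[:, j] += kernel_cache[known]
    return pd.DataFrame(phi, index=node_list, columns=phenotypes)


def closeness_profile(
    gene: str,
    disease_gene_map: DiseaseGeneMap,
    network: InteractionNetwork,
) -> np.ndarray:
    """Phi(gene, .) over the map's phenotypes (sorted phenotype order)."""
    if network.n_nodes == 0:
        raise PhenotypeError("cannot compute closeness on an empty network")
    phenotypes = disease_gene_map.phenotypes
    out = np.zeros(len(phenotypes))
    if gene not in network:
        return out
    lengths = nx.single_source_shortest_path_length(network.graph, gene)
    for j, pheno in enumerate(phenotypes):
        out[j] = sum(
            math.exp(-float(lengths[g]) ** 2)
            for g in disease_gene_map[pheno] if g in lengths
        )
    return out


def _pearson_rows(phi: np.ndarray, sim: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of phi with each row of sim.

    Zero-variance rows (in either matrix) yield score 0.
    """
    phi_c = phi - phi.mean(axis=1, keepdims=True)
    sim_c = sim - sim.mean(axis=1, keepdims=True)
    phi_norm = np.linalg.norm(phi_c, axis=1)
    sim_norm = np.linalg.norm(sim_c, axis=1)
    num = phi_c @ sim_c.T  # genes x phenotypes
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.outer(phi_norm, sim_norm)
        scores = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return scores


def cipher_scores(
    similarity: PhenotypeSimilarity,
    disease_gene_map: DiseaseGeneMap,
    network: InteractionNetwork,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Concordance scores for every (gene, phenotype) pair.

    Returns a genes x phenotypes frame of Pearson correlations between the
    phenotype's similarity row and the gene's closeness profile; pairs with
    a zero-variance profile score 0.  Requires at least three phenotypes,
    below which the correlation is degenerate.
    """
    if len(similarity) < MIN_PHENOTYPES:
        raise PhenotypeError(
            f"need >= {MIN_PHENOTYPES} phenotypes for concordance scoring"
        )
    phenotypes = disease_gene_map.phenotypes
    if sorted(similarity.phenotypes) != phenotypes:
        raise PhenotypeError("similarity matrix and disease-gene map disagree "
                             "on the phenotype set")
    phi = closeness_matrix(network, disease_gene_map, genes=genes)
    sim_rows = np.vstack([similarity.row(p) for p in phenotypes])
    # align similarity columns to the map's sorted phenotype order
    order = [similarity.phenotypes.index(p) for p in phenotypes]
    sim_rows = sim_rows[:, order]
    scores = _pearson_rows(phi.to_numpy(), sim_rows)
    return pd.DataFrame(scores, index=phi.index, columns=phenotypes)


def cipher_score(
    gene: str,
    similarity: PhenotypeSimilarity,
    disease_gene_map: DiseaseGeneMap,
    network: InteractionNetwork,
) -> dict[str, float]:
    """Scores for a single gene across phenotypes (convenience wrapper)."""
    frame = cipher_scores(similarity, disease_gene_map, network, genes=[gene])
    return {p: float(frame.loc[gene, p]) for p in frame.columns}


@dataclass(frozen=True)
class PrioritizationResult:
    """A (gene, phenotype) concordance score with rank and top-N call."""

    gene: str
    phenotype: str
    score: float
    rank: int
    predicted: bool


def rank_and_call(
    scores: pd.DataFrame, top_n: int = DEFAULT_TOP_N
) -> pd.DataFrame:
    """Rank genes per phenotype (descending score, lexicographic ties).

    Returns a long-format frame with columns gene, phenotype, score, rank,
    predicted; ranks are a permutation of 1..n_genes within each phenotype
    and ``predicted`` marks ranks <= top_n.
    """
    records = []
    for pheno in scores.columns:
        col = scores[pheno]
        ordered = sorted(col.index, key=lambda g: (-col[g], g))
        for rank, gene in enumerate(ordered, start=1):
            records.append({
                "gene": gene, "phenotype": pheno, "score": float(col[gene]),
                "rank": rank, "predicted": rank <= top_n,
            })
    return pd.DataFrame.from_records(records)


def prioritization_results(ranked: pd.DataFrame) -> list[PrioritizationResult]:
    return [
        PrioritizationResult(r.gene, r.phenotype, r.score, int(r.rank),
                             bool(r.predicted))
        for r in ranked.itertuples(index=False)
    ]


def write_scores_tsv(ranked: pd.DataFrame, path) -> None:
    ranked.to_csv(path, sep="\t", index=False, float_format="%.6g")
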