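"""Cross-disease differential-expression consistency classification.

Each network gene is checked against K per-disease differential-expression
tables (gene, fold-change direction, p-value).  A gene is differentially
expressed (DE) in a disease iff it appears in that table with p below the
threshold (0.05, uncorrected, by default).  Genes DE in every disease with
the same sign everywhere are the direction-consistent candidates; a single
opposite sign among the DE diseases makes the gene inconsistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSet, HUMAN
from .interactome import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.05

CLASS_NONE = "none"
CLASS_UP = "consistent_up"
CLASS_DOWN = "consistent_down"
CLASS_INCONSISTENT = "inconsistent"


class ExpressionTableError(ValueError):
    pass


@dataclass(frozen=True)
class DiseaseExpressionTable:
    """Per-disease mapping gene -> (direction, p-value).

    ``direction`` is +1 (up-regulated in disease vs healthy) or -1 (down);
    zero fold changes are rejected at construction.
    """

    disease: str
    rows: dict[str, tuple[int, float]]

    def __post_init__(self) -> None:
        for gene, (direction, p) in self.rows.items():
            if direction not in (1, -1):
                raise ExpressionTableError(
                    f"{self.disease}/{gene}: direction must be +1 or -1, got {direction}"
                )
            if not 0.0 <= p <= 1.0:
                raise ExpressionTableError(
                    f"{self.disease}/{gene}: p-value {p} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def is_de(self, gene: str, p_threshold: float = DEFAULT_P_THRESHOLD) -> bool:
        row = self.rows.get(gene)
        return row is not None and row[1] < p_threshold

    def direction(self, gene: str) -> int | None:
        row = self.rows.get(gene)
        return None if row is None else row[0]

    @classmethod
    def from_dataframe(cls, disease: str, df: pd.DataFrame) -> "DiseaseExpressionTable":
        """Build from a frame with columns ``gene``, ``p_value`` and either
        ``log_fold_change`` or ``direction`` (``up``/``down`` or signed int).

        Duplicate genes keep the row with the minimum p-value (deterministic;
        ties keep the first in file order) with a logged warning.
        """
        if "gene" not in df.columns or "p_value" not in df.columns:
            raise ExpressionTableError(
                f"{disease}: table needs 'gene' and 'p_value' columns"
            )
        if "log_fold_change" in df.columns:
            lfc = pd.to_numeric(df["log_fold_change"])
            if (lfc == 0).any():
                bad = df.loc[lfc == 0, "gene"].tolist()
                raise ExpressionTableError(
                    f"{disease}: zero fold change for {bad[:5]} — direction undefined"
                )
            signs = np.sign(lfc).astype(int)
        elif "direction" in df.columns:
            mapping = {"up": 1, "down": -1, "1": 1, "-1": -1, 1: 1, -1: -1}
            try:
                signs = df["direction"].map(mapping).astype(int)
            except (ValueError, TypeError) as exc:
                raise ExpressionTableError(f"{disease}: bad direction column") from exc
        else:
            raise ExpressionTableError(
                f"{disease}: need a 'log_fold_change' or 'direction' column"
            )
        if df["gene"].duplicated().any():
            n_dup = int(df["gene"].duplicated().sum())
            logger.warning("%s: %d duplicate gene rows; keeping min-p row each",
                           disease, n_dup)
        work = pd.DataFrame({
            "gene": df["gene"].astype(str),
            "direction": signs.to_numpy(),
            "p_value": pd.to_numeric(df["p_value"]).to_numpy(),
        })
        work = work.sort_values("p_value", kind="stable").drop_duplicates("gene")
        rows = {
            r.gene: (int(r.direction), float(r.p_value))
            for r in work.itertuples(index=False)
        }
        return cls(disease=disease, rows=rows)

    @classmethod
    def read_tsv(cls, disease: str, path) -> "DiseaseExpressionTable":
        df = pd.read_csv(path, sep="\t", comment=None)
        df.columns = [c.lstrip("#") for c in df.columns]
        return cls.from_dataframe(disease, df)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#gene\tlog_fold_change\tp_value\n")
            for gene in sorted(self.rows):
                d, p = self.rows[gene]
                fh.write(f"{gene}\t{float(d):.4g}\t{p:.6g}\n")


@dataclass(frozen=True)
class ConsistencyProfile:
    """Classification of one gene across the K disease tables."""

    gene: str
    n_diseases_de: int
    directions: dict[str, int] = field(compare=False)  # DE diseases only
    klass: str = CLASS_NONE
    candidate: bool = False


def classify_gene(
    gene: str,
    tables: list[DiseaseExpressionTable],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> ConsistencyProfile:
    """Classify a gene by its DE sign pattern across the disease tables.

    The class is determined from the signs in the diseases where the gene is
    DE: all positive -> consistent_up, all negative -> consistent_down, mixed
    -> inconsistent, none -> none.  ``candidate`` additionally requires DE in
    every table.  A gene absent from a table is simply not DE there.
    """
    if not tables:
        raise ExpressionTableError("need at least one disease table")
    directions: dict[str, int] = {}
    for t in tables:
        if t.is_de(gene, p_threshold):
            directions[t.disease] = t.direction(gene)
    k_de = len(directions)
    signs = set(directions.values())
    if k_de == 0:
        klass = CLASS_NONE
    elif signs == {1}:
        klass = CLASS_UP
    elif signs == {-1}:
        klass = CLASS_DOWN
    else:
        klass = CLASS_INCONSISTENT
    candidate = klass in (CLASS_UP, CLASS_DOWN) and k_de == len(tables)
    return ConsistencyProfile(
        gene=gene, n_diseases_de=k_de, directions=directions,
        klass=klass, candidate=candidate,
    )


def _percent_1dp(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, half-up (display convention)."""
    if denominator == 0:
        return 0.0
    return math.floor(1000.0 * numerator / denominator + 0.5) / 10.0


@dataclass(frozen=True)
class ConsistencyTable:
    """Stratified counts of DE behaviour over the network's node set.

    ``strata`` has one row per number-of-diseases stratum k = 0..K with
    columns consistent_up / consistent_down / inconsistent / total;
    ``per_disease`` has one row per disease with the genome-wide and
    network-restricted up/down DEG counts and the percent of network nodes.
    """

    strata: pd.DataFrame
    per_disease: pd.DataFrame
    n_network_genes: int

    def stratum(self, k) -> tuple[int, int, int, int]:
        row = self.strata.loc[k]
        return (int(row.consistent_up), int(row.consistent_down),
                int(row.inconsistent), int(row.total))


def build_consistency_table(
    network: InteractionNetwork,
    tables: list[DiseaseExpressionTable],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> ConsistencyTable:
    """Stratify every network gene by DE count and direction consistency."""
    K = len(tables)
    genes = sorted(network.nodes)
    counts = {k: {"consistent_up": 0, "consistent_down": 0,
                  "inconsistent": 0, "total": 0} for k in range(K + 1)}
    for gene in genes:
        prof = classify_gene(gene, tables, p_threshold)
        counts[prof.n_diseases_de]["total"] += 1
        if prof.klass == CLASS_UP:
            counts[prof.n_diseases_de]["consistent_up"] += 1
        elif prof.klass == CLASS_DOWN:
            counts[prof.n_diseases_de]["consistent_down"] += 1
        elif prof.klass == CLASS_INCONSISTENT:
            counts[prof.n_diseases_de]["inconsistent"] += 1
    strata = pd.DataFrame.from_dict(counts, orient="index")
    strata.index.name = "n_diseases_de"

    node_set = set(genes)
    rows = []
    for t in tables:
        up_all = sum(1 for g, (d, p) in t.rows.items() if d > 0 and p < p_threshold)
        down_all = sum(1 for g, (d, p) in t.rows.items() if d < 0 and p < p_threshold)
        up_net = sum(1 for g, (d, p) in t.rows.items()
                     if g in node_set and d > 0 and p < p_threshold)
        down_net = sum(1 for g, (d, p) in t.rows.items()
                       if g in node_set and d < 0 and p < p_threshold)
        total_net = up_net + down_net
        rows.append({
            "disease": t.disease,
            "n_up": up_all, "n_up_network": up_net,
            "n_down": down_all, "n_down_network": down_net,
            "n_total_network": total_net,
            "percent_of_network": _percent_1dp(total_net, len(node_set)),
        })
    per_disease = pd.DataFrame(rows).set_index("disease")
    return ConsistencyTable(strata=strata, per_disease=per_disease,
                            n_network_genes=len(node_set))


@dataclass(frozen=True)
class CandidateSet:
    """Direction-consistent all-disease candidates, split by direction."""

    up: GeneSet
    down: GeneSet

    @property
    def all(self) -> GeneSet:
        return GeneSet(name="candidates", species=self.up.species,
                       genes=self.up.genes | self.down.genes)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def select_candidates(
    tables: list[DiseaseExpressionTable],
    network: InteractionNetwork,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> CandidateSet:
    """Network genes DE in all diseases with one consistent direction."""
    up, down = set(), set()
    for gene in network.nodes:
        prof = classify_gene(gene, tables, p_threshold)
        if prof.candidate:
            (up if prof.klass == CLASS_UP else down).add(gene)
    return CandidateSet(
        up=GeneSet(name="candidates_up", species=HUMAN, genes=frozenset(up)),
        down=GeneSet(name="candidates_down", species=HUMAN, genes=frozenset(down)),
    )


@dataclass(frozen=True)
class NullSummary:
    """Permutation null for the all-disease consistent-candidate count."""

    observed: int
    null_counts: np.ndarray
    empirical_p: float
    n_permutations: int


def consistency_null(
    network: InteractionNetwork,
    tables: list[DiseaseExpressionTable],
    n_permutations: int,
    seed: int,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> NullSummary:
    """Permutation null: shuffle gene labels within each disease table.

    Breaking the gene-wise coupling across diseases while preserving each
    table's marginal DE counts and sign balance yields the null distribution
    of the number of all-disease direction-consistent network genes.  The
    empirical p-value uses the add-one rule (>= observed), so it is bounded
    below by 1/(n_permutations+1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    observed = len(select_candidates(tables, network, p_threshold))

    # Vectorized permutation over the network genes only: a permuted table
    # restricted to network genes has hypergeometric DE counts; sampling
    # per-gene (DE, sign) without replacement from each full table's label
    # multiset is equivalent to a full label permutation.
    genes = sorted(network.nodes)
    n = len(genes)
    null_counts = np.zeros(n_permutations, dtype=int)
    # per table: array of labels over all genes in the table, -1/0/+1 (0 = not DE)
    label_pools = []
    for t in tables:
        labels = np.array(
            [d if p < p_threshold else 0 for (d, p) in t.rows.values()], dtype=np.int8
        )
        # genes in the network but absent from the table contribute label 0
        n_absent = sum(1 for g in genes if g not in t.rows)
        pool = np.concatenate([labels, np.zeros(n_absent, dtype=np.int8)])
        label_pools.append(pool)
    for i in range(n_permutations):
        signs = np.empty((len(tables), n), dtype=np.int8)
        for j, pool in enumerate(label_pools):
            take = rng.choice(len(pool), size=n, replace=False)
            signs[j] = pool[take]
        de_all = (signs != 0).all(axis=0)
        consistent = (signs == signs[0]).all(axis=0)
        null_counts[i] = int((de_all & consistent).sum())
    p = (1 + int((null_counts >= observed).sum())) / (n_permutations + 1)
    return NullSummary(observed=observed, null_counts=null_counts,
                       empirical_p=p, n_permutations=n_permutations)
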