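"""Gene-set assembly: annotation sets, enrichment sets, ortholog mapping, overlaps.

A :class:`GeneSet` is the unit of input for the tissue-restricted network:
cytoskeleton annotation sets (GO-term derived) and glomerulus-enriched sets
(one per expression study) are combined by set union, mouse sets are routed
through an ortholog map, and the annotation/enrichment intersection defines
the node universe of the tissue network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

HUMAN = "human"
MOUSE = "mouse"
_SPECIES = (HUMAN, MOUSE)


class GeneSetError(ValueError):
    """Raised on malformed gene sets or species/namespace mismatches."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers in a single namespace.

    Parameters
    ----------
    name : str
        Label for the set (e.g. the study or ontology term it came from).
    species : str
        ``"human"`` or ``"mouse"``; one namespace per set.
    genes : frozenset of str
        Gene identifiers (canonical uppercase symbols by convention here;
        numeric IDs are treated as opaque strings).
    provenance : str
        Free text: method, year, selection criterion.
    gene_sources : dict, optional
        For union results: gene -> frozenset of contributing set names.
    """

    name: str
    species: str
    genes: frozenset[str] = frozenset()
    provenance: str = ""
    gene_sources: dict[str, frozenset[str]] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise GeneSetError(f"unknown species {self.species!r}")
        genes = frozenset(self.genes)
        for g in genes:
            if not isinstance(g, str) or not g:
                raise GeneSetError(f"invalid gene identifier {g!r} in set {self.name!r}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass(frozen=True)
class OrthologMap:
    """Pairs of (source identifier, target identifier) between two species.

    A source gene may map to several targets (e.g. one mouse gene with two
    human co-orthologs); the mapping policy is chosen at call time.
    """

    pairs: frozenset[tuple[str, str]]
    source_species: str = MOUSE
    target_species: str = HUMAN

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def targets_of(self, source: str) -> frozenset[str]:
        return frozenset(t for s, t in self.pairs if s == source)

    def as_dict(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, set()).add(t)
        return out


@dataclass(frozen=True)
class OrthologResult:
    """Output of :func:`map_orthologs`: the mapped set plus an unmapped tally."""

    gene_set: GeneSet
    unmapped: frozenset[str]

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


@dataclass(frozen=True)
class OverlapReport:
    """Intersection counts and proportions between two gene sets."""

    set_a: str
    set_b: str
    n_a: int
    n_b: int
    n_intersection: int
    genes: frozenset[str] = field(default=frozenset(), compare=False)

    @property
    def proportion_of_a(self) -> float:
        return self.n_intersection / self.n_a if self.n_a else 0.0

    @property
    def proportion_of_b(self) -> float:
        return self.n_intersection / self.n_b if self.n_b else 0.0

    def display_of_b(self) -> str:
        """``"299/1890 (15.82%)"``-style string, percentage at 2 decimals."""
        return f"{self.n_intersection}/{self.n_b} ({round(100 * self.proportion_of_b, 2):.2f}%)"


def union_gene_sets(sets: list[GeneSet], name: str = "union") -> GeneSet:
    """Exact set-theoretic union of same-species gene sets.

    Records per-gene provenance (which input sets contributed each gene).
    Mixed-species input raises: map orthologs first.
    """
    if not sets:
        raise GeneSetError("union of zero sets is undefined; pass at least one set")
    species = {s.species for s in sets}
    if len(species) > 1:
        raise GeneSetError(
            "mixed-species union: map mouse sets through map_orthologs() first"
        )
    sources: dict[str, set[str]] = {}
    for s in sets:
        for g in s.genes:
            sources.setdefault(g, set()).add(s.name)
    return GeneSet(
        name=name,
        species=sets[0].species,
        genes=frozenset(sources),
        provenance="union of: " + ", ".join(s.name for s in sets),
        gene_sources={g: frozenset(v) for g, v in sources.items()},
    )


def map_orthologs(
    gene_set: GeneSet, ortholog_map: OrthologMap, keep_all_targets: bool = True
) -> OrthologResult:
    """Convert a gene set to the ortholog map's target species.

    Unmapped inputs are dropped and tallied. With ``keep_all_targets`` (the
    default) a one-to-many source contributes every target; otherwise
    ambiguous sources (more than one target) are dropped as unmapped.
    """
    if gene_set.species != ortholog_map.source_species:
        raise GeneSetError(
            f"species mismatch: set is {gene_set.species}, "
            f"map expects {ortholog_map.source_species}"
        )
    lookup = ortholog_map.as_dict()
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for g in gene_set.genes:
        targets = lookup.get(g, set())
        if not targets or (len(targets) > 1 and not keep_all_targets):
            unmapped.add(g)
        else:
            mapped.update(targets)
    if unmapped:
        logger.info(
            "map_orthologs(%s): %d of %d identifiers unmapped",
            gene_set.name, len(unmapped), len(gene_set),
        )
    out = GeneSet(
        name=gene_set.name,
        species=ortholog_map.target_species,
        genes=frozenset(mapped),
        provenance=gene_set.provenance + f" [mapped {gene_set.species}->"
        f"{ortholog_map.target_species}, {len(unmapped)} unmapped]",
    )
    return OrthologResult(gene_set=out, unmapped=frozenset(unmapped))


def overlap_report(a: GeneSet, b: GeneSet) -> OverlapReport:
    """Exact intersection counts of two same-namespace sets."""
    if a.species != b.species:
        raise GeneSetError("overlap requires same-species sets")
    inter = a.genes & b.genes
    return OverlapReport(
        set_a=a.name, set_b=b.name,
        n_a=len(a), n_b=len(b), n_intersection=len(inter),
        genes=frozenset(inter),
    )


def intersect_universe(
    cytoskeleton: GeneSet, enriched: GeneSet, name: str = "tissue_universe"
) -> GeneSet:
    """Intersection of the annotation set and the enriched union.

    This is the node universe of the tissue-restricted network.
    """
    if cytoskeleton.species != enriched.species:
        raise GeneSetError("intersection requires same-species sets")
    return GeneSet(
        name=name,
        species=cytoskeleton.species,
        genes=cytoskeleton.genes & enriched.genes,
        provenance=f"{cytoskeleton.name} ∩ {enriched.name}",
    )


def read_gene_set_tsv(path, name: str, species: str = HUMAN, provenance: str = "") -> GeneSet:
    """Read a one-column (or first-column) TSV of gene identifiers.

    Lines starting with ``#`` are comments; duplicates collapse silently.
    """
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split("\t")[0].strip())
    return GeneSet(name=name, species=species, genes=frozenset(genes), provenance=provenance)


def write_gene_set_tsv(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gene set: {gene_set.name} ({gene_set.species})\n")
        for g in gene_set:
            fh.write(g + "\n")


def read_ortholog_map_tsv(path, source_species: str = MOUSE, target_species: str = HUMAN) -> OrthologMap:
    """Read a two-column TSV (source id, target id)."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            src, tgt = line.split("\t")[:2]
            pairs.add((src.strip(), tgt.strip()))
    return OrthologMap(pairs=frozenset(pairs), source_species=source_species,
                       target_species=target_species)


def write_ortholog_map_tsv(omap: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ortholog map {omap.source_species} -> {omap.target_species}\n")
        for s, t in sorted(omap.pairs):
            fh.write(f"{s}\t{t}\n")


def rename(gene_set: GeneSet, name: str) -> GeneSet:
    return replace(gene_set, name=name)
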