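"""End-to-end pipeline: gene sets -> network -> candidates -> prioritization.

A single :class:`PipelineConfig` drives either a fully synthetic run (inputs
generated in memory with planted ground truth) or a file-based run on TSV
inputs.  Stages execute in order — set assembly, interaction integration and
filtering, tissue-network induction and topology, cross-disease consistency
classification, bridged subnetwork reconstruction, and phenotype-concordance
prioritization — writing intermediate tables and a machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import genesets, interactome, consistency, subnetworks, cipher, synthetic
from .genesets import GeneSet, HUMAN, MOUSE
from .interactome import InteractionNetwork, NetworkSummary
from .consistency import CandidateSet, ConsistencyTable, DiseaseExpressionTable
from .subnetworks import DiseaseGeneMap
from .cipher import PhenotypeSimilarity

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``synthetic`` is set (everything is generated) or the input paths
    are; thresholds default to the study's published choices (DE at p < 0.05,
    combined interaction score >= 0.9 with a 0.9 per-channel cap, top-1000
    prioritization calls).
    """

    synthetic: synthetic.SyntheticConfig | None = None
    annotation_path: str | None = None
    enrichment_sets: tuple[tuple[str, str, str], ...] = ()  # (name, path, species)
    ortholog_path: str | None = None
    interactions_path: str | None = None
    disease_tables: tuple[tuple[str, str], ...] = ()        # (disease, path)
    disease_genes_path: str | None = None
    similarity_path: str | None = None
    p_threshold: float = 0.05
    score_threshold: float = 0.9
    per_source_cap: float = 0.9
    strict_curated: bool = False
    bridge_policy: str = subnetworks.COMMON_NEIGHBORS
    top_n: int = 1000
    seed: int = 0
    out_dir: str = "gcnet_out"

    def __post_init__(self) -> None:
        for name in ("p_threshold", "score_threshold", "per_source_cap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PipelineError(f"{name}={v} outside [0, 1]")
        if self.top_n < 1:
            raise PipelineError("top_n must be >= 1")

    @property
    def is_synthetic(self) -> bool:
        return self.synthetic is not None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if self.synthetic is not None:
            payload["synthetic"] = self.synthetic.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if isinstance(syn, dict):
                for key in ("enrichment_set_sizes", "mouse_dataset_indices"):
                    if key in syn:
                        syn[key] = tuple(syn[key])
                raw["synthetic"] = synthetic.SyntheticConfig(**syn)
            elif syn is True:
                raw["synthetic"] = synthetic.SyntheticConfig()
        if "enrichment_sets" in raw:
            raw["enrichment_sets"] = tuple(tuple(e) for e in raw["enrichment_sets"])
        if "disease_tables" in raw:
            raw["disease_tables"] = tuple(tuple(d) for d in raw["disease_tables"])
        return cls(**raw)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Schema-check every referenced input file before running.

    Missing mandatory files and out-of-range values are fatal; duplicate
    gene rows and a missing similarity matrix (prioritization skipped) are
    warnings.
    """
    report = ValidationReport()
    if config.is_synthetic:
        try:
            config.synthetic.validate()
        except synthetic.SyntheticConfigError as exc:
            report.errors.append(f"synthetic config: {exc}")
        return report

    def need(path, label):
        if path is None:
            report.errors.append(f"{label}: path not set")
            return False
        if not Path(path).exists():
            report.errors.append(f"{label}: {path} does not exist")
            return False
        return True

    need(config.annotation_path, "annotation set")
    need(config.interactions_path, "interaction edge list")
    if not config.disease_tables:
        report.errors.append("no disease tables configured")
    for name, path, species in config.enrichment_sets:
        if species not in (HUMAN, MOUSE):
            report.errors.append(f"enrichment set {name}: bad species {species!r}")
        need(path, f"enrichment set {name}")
        if species == MOUSE and config.ortholog_path is None:
            report.errors.append(
                f"enrichment set {name} is mouse but no ortholog map given")
    for disease, path in config.disease_tables:
        if not need(path, f"disease table {disease}"):
            continue
        try:
            table = DiseaseExpressionTable.read_tsv(disease, path)
            if len(table) == 0:
                report.warnings.append(f"disease table {disease}: empty")
        except (consistency.ExpressionTableError, ValueError) as exc:
            report.errors.append(f"disease table {disease}: {exc}")
    if config.similarity_path is None or config.disease_genes_path is None:
        report.warnings.append(
            "no similarity matrix / disease-gene map: prioritization stage "
            "will be skipped")
    elif need(config.similarity_path, "similarity matrix") and \
            need(config.disease_genes_path, "disease-gene map"):
        try:
            PhenotypeSimilarity.read_tsv(config.similarity_path)
        except (cipher.PhenotypeError, ValueError) as exc:
            report.errors.append(f"similarity matrix: {exc}")
    return report


@dataclass
class RunReport:
    """Everything a run produced, regenerable from the written intermediates."""

    config_hash: str
    seed: int
    network_summary: NetworkSummary
    consistency: ConsistencyTable
    candidates: CandidateSet
    n_tissue_genes: int
    n_edges_before_filter: int
    n_edges_after_filter: int
    subnetwork_nodes: int
    subnetwork_edges: int
    disease_link_nodes: int | None = None
    disease_link_edges: int | None = None
    predictions_per_phenotype: dict[str, int] | None = None
    prioritization_skipped: bool = False

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "network": dataclasses.asdict(self.network_summary),
            "consistency_strata": {
                str(k): list(self.consistency.stratum(k))
                for k in self.consistency.strata.index
            },
            "per_disease": self.consistency.per_disease.reset_index()
                .to_dict(orient="records"),
            "candidates_up": sorted(self.candidates.up.genes),
            "candidates_down": sorted(self.candidates.down.genes),
            "n_tissue_genes": self.n_tissue_genes,
            "n_edges_before_filter": self.n_edges_before_filter,
            "n_edges_after_filter": self.n_edges_after_filter,
            "subnetwork": {"nodes": self.subnetwork_nodes,
                           "edges": self.subnetwork_edges},
            "disease_link_subnetwork": {
                "nodes": self.disease_link_nodes,
                "edges": self.disease_link_edges,
            },
            "predictions_per_phenotype": self.predictions_per_phenotype,
            "prioritization_skipped": self.prioritization_skipped,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class _Inputs:
    annotation: GeneSet
    enrichment_sets: list[GeneSet]
    ortholog_map: genesets.OrthologMap | None
    edges: list[interactome.ScoredInteraction]
    disease_tables: list[DiseaseExpressionTable]
    disease_genes: DiseaseGeneMap | None
    similarity: PhenotypeSimilarity | None
    held_out: dict[str, frozenset[str]] | None = None


def _load_synthetic(config: PipelineConfig) -> _Inputs:
    syn = config.synthetic
    bundle = synthetic.generate_universe(syn)
    edges = synthetic.generate_interactome(
        syn, bundle.universe,
        planted=GeneSet(name="planted", species=HUMAN,
                        genes=bundle.planted_up.genes
                        | bundle.planted_down.genes),
        core=bundle.core,
    )
    tables = synthetic.generate_disease_tables(
        syn, bundle.planted_up, bundle.planted_down,
        bundle.planted_inconsistent, bundle.universe,
    )
    kept = interactome.filter_interactions(
        edges, threshold=config.score_threshold, strict=config.strict_curated)
    integrated = interactome.build_network(kept)
    phen = synthetic.generate_phenotype_data(syn, integrated)
    return _Inputs(
        annotation=bundle.annotation,
        enrichment_sets=list(bundle.enrichment_sets),
        ortholog_map=bundle.ortholog_map,
        edges=edges,
        disease_tables=tables,
        disease_genes=phen.disease_genes,
        similarity=phen.similarity,
        held_out=phen.held_out,
    )


def _load_files(config: PipelineConfig) -> _Inputs:
    annotation = genesets.read_gene_set_tsv(
        config.annotation_path, name="annotation")
    sets = [genesets.read_gene_set_tsv(path, name=name, species=species)
            for name, path, species in config.enrichment_sets]
    omap = (genesets.read_ortholog_map_tsv(config.ortholog_path)
            if config.ortholog_path else None)
    edges = interactome.read_interactions_tsv(config.interactions_path)
    tables = [DiseaseExpressionTable.read_tsv(disease, path)
              for disease, path in config.disease_tables]
    dgm = (DiseaseGeneMap.read_tsv(config.disease_genes_path)
           if config.disease_genes_path else None)
    sim = (PhenotypeSimilarity.read_tsv(config.similarity_path)
           if config.similarity_path else None)
    return _Inputs(annotation=annotation, enrichment_sets=sets,
                   ortholog_map=omap, edges=edges, disease_tables=tables,
                   disease_genes=dgm, similarity=sim)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> RunReport:
    """Execute every stage and return (and optionally write) the run report."""
    validation = validate_inputs(config)
    if not validation.ok:
        raise PipelineError("input validation failed: "
                            + "; ".join(validation.errors))
    for w in validation.warnings:
        logger.warning("%s", w)

    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    try:
        inputs = (_load_synthetic(config) if config.is_synthetic
                  else _load_files(config))
    except Exception as exc:
        raise PipelineError(f"stage load_inputs: {exc}") from exc

    # --- gene-set assembly ------------------------------------------------
    try:
        human_sets = []
        for s in inputs.enrichment_sets:
            if s.species == MOUSE:
                if inputs.ortholog_map is None:
                    raise genesets.GeneSetError(
                        f"mouse set {s.name} but no ortholog map")
                result = genesets.map_orthologs(s, inputs.ortholog_map)
                logger.info("stage genesets: %s mapped, %d unmapped",
                            s.name, result.n_unmapped)
                human_sets.append(result.gene_set)
            else:
                human_sets.append(s)
        enriched = genesets.union_gene_sets(human_sets, name="enriched_union")
        tissue = genesets.intersect_universe(inputs.annotation, enriched)
        logger.info("stage genesets: %d annotation, %d enriched union, "
                    "%d tissue universe",
                    len(inputs.annotation), len(enriched), len(tissue))
    except Exception as exc:
        raise PipelineError(f"stage genesets: {exc}") from exc

    # --- interactome ------------------------------------------------------
    try:
        kept = interactome.filter_interactions(
            inputs.edges, threshold=config.score_threshold,
            strict=config.strict_curated)
        integrated = interactome.build_network(kept)
        tissue_net = interactome.induce_network(tissue, kept)
        summary = interactome.summarize_network(tissue_net)
        logger.info("stage interactome: %d edges in, %d kept; tissue network "
                    "%d nodes / %d edges",
                    len(inputs.edges), len(kept), summary.n_nodes,
                    summary.n_edges)
    except Exception as exc:
        raise PipelineError(f"stage interactome: {exc}") from exc

    # --- disease consistency ---------------------------------------------
    try:
        ctable = consistency.build_consistency_table(
            tissue_net, inputs.disease_tables, config.p_threshold)
        candidates = consistency.select_candidates(
            inputs.disease_tables, tissue_net, config.p_threshold)
        logger.info("stage consistency: %d candidates (%d up, %d down)",
                    len(candidates), len(candidates.up), len(candidates.down))
    except Exception as exc:
        raise PipelineError(f"stage consistency: {exc}") from exc

    # --- subnetworks ------------------------------------------------------
    try:
        seed_roles = {g: subnetworks.ROLE_SEED_UP for g in candidates.up.genes}
        seed_roles.update(
            {g: subnetworks.ROLE_SEED_DOWN for g in candidates.down.genes})
        bridged = subnetworks.build_bridged_subnetwork(
            candidates.all, integrated, policy=config.bridge_policy,
            seed_roles=seed_roles)
        linked = None
        if inputs.disease_genes is not None:
            linked = subnetworks.link_to_disease_genes(
                candidates.all, inputs.disease_genes, integrated,
                policy=config.bridge_policy)
    except Exception as exc:
        raise PipelineError(f"stage subnetworks: {exc}") from exc

    # --- prioritization ---------------------------------------------------
    ranked = None
    predictions = None
    skipped = inputs.similarity is None or inputs.disease_genes is None
    if not skipped:
        try:
            scores = cipher.cipher_scores(
                inputs.similarity, inputs.disease_genes, integrated)
            ranked = cipher.rank_and_call(scores, top_n=config.top_n)
            predictions = {
                p: int(ranked.loc[(ranked.phenotype == p)
                                  & ranked.predicted].shape[0])
                for p in scores.columns
            }
        except Exception as exc:
            raise PipelineError(f"stage prioritization: {exc}") from exc
    else:
        logger.info("stage prioritization: skipped (no similarity matrix or "
                    "disease-gene map)")

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        network_summary=summary,
        consistency=ctable,
        candidates=candidates,
        n_tissue_genes=len(tissue),
        n_edges_before_filter=len(inputs.edges),
        n_edges_after_filter=len(kept),
        subnetwork_nodes=bridged.n_nodes,
        subnetwork_edges=bridged.n_edges,
        disease_link_nodes=None if linked is None else linked.n_nodes,
        disease_link_edges=None if linked is None else linked.n_edges,
        predictions_per_phenotype=predictions,
        prioritization_skipped=skipped,
    )

    if write_outputs:
        genesets.write_gene_set_tsv(tissue, out / "tissue_universe.tsv")
        interactome.write_interactions_tsv(kept, out / "interactions_filtered.tsv")
        interactome.write_network_tables(
            tissue_net, out / "network_nodes.tsv", out / "network_edges.tsv")
        ctable.strata.to_csv(out / "consistency_strata.tsv", sep="\t")
        ctable.per_disease.to_csv(out / "consistency_per_disease.tsv", sep="\t")
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("#gene\tdirection\n")
            for g in sorted(candidates.up.genes):
                fh.write(f"{g}\tup\n")
            for g in sorted(candidates.down.genes):
                fh.write(f"{g}\tdown\n")
        bridged.write_tables(out / "subnetwork_nodes.tsv",
                             out / "subnetwork_edges.tsv")
        if linked is not None:
            linked.write_tables(out / "disease_link_nodes.tsv",
                                out / "disease_link_edges.tsv")
        if ranked is not None:
            cipher.write_scores_tsv(ranked, out / "prioritization.tsv")
        report.write_json(out / "report.json")
    return report


def write_synthetic_inputs(syn: synthetic.SyntheticConfig, out_dir) -> PipelineConfig:
    """Materialize a synthetic study as TSV files plus a file-mode config.

    Used by the command-line ``synth`` subcommand and to exercise the
    file-based code path end-to-end without external downloads.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = synthetic.generate_universe(syn)
    edges = synthetic.generate_interactome(
        syn, bundle.universe,
        planted=GeneSet(name="planted", species=HUMAN,
                        genes=bundle.planted_up.genes
                        | bundle.planted_down.genes),
        core=bundle.core,
    )
    tables = synthetic.generate_disease_tables(
        syn, bundle.planted_up, bundle.planted_down,
        bundle.planted_inconsistent, bundle.universe,
    )
    kept = interactome.filter_interactions(edges)
    integrated = interactome.build_network(kept)
    phen = synthetic.generate_phenotype_data(syn, integrated)

    genesets.write_gene_set_tsv(bundle.annotation, out / "annotation.tsv")
    enrichment_entries = []
    for s in bundle.enrichment_sets:
        path = out / f"{s.name}.tsv"
        genesets.write_gene_set_tsv(s, path)
        enrichment_entries.append((s.name, str(path), s.species))
    genesets.write_ortholog_map_tsv(bundle.ortholog_map, out / "orthologs.tsv")
    interactome.write_interactions_tsv(edges, out / "interactions.tsv")
    table_entries = []
    for t in tables:
        path = out / f"disease_{t.disease}.tsv"
        t.write_tsv(path)
        table_entries.append((t.disease, str(path)))
    phen.disease_genes.write_tsv(out / "disease_genes.tsv")
    phen.similarity.write_tsv(out / "similarity.tsv")

    config = PipelineConfig(
        annotation_path=str(out / "annotation.tsv"),
        enrichment_sets=tuple(enrichment_entries),
        ortholog_path=str(out / "orthologs.tsv"),
        interactions_path=str(out / "interactions.tsv"),
        disease_tables=tuple(table_entries),
        disease_genes_path=str(out / "disease_genes.tsv"),
        similarity_path=str(out / "similarity.tsv"),
        seed=syn.seed,
        out_dir=str(out / "results"),
    )
    with open(out / "config.yaml", "w") as fh:
        payload = dataclasses.asdict(config)
        payload["enrichment_sets"] = [list(e) for e in config.enrichment_sets]
        payload["disease_tables"] = [list(d) for d in config.disease_tables]
        del payload["synthetic"]
        yaml.safe_dump(payload, fh, sort_keys=True)
    return config
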