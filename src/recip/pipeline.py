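"""End-to-end orchestration of the forward and reverse integrations.

A :class:`RunConfig` names every input file and threshold; ``run_forward``
and ``run_reverse`` chain the module operations and fill a :class:`Report`
(pydantic model, so the JSON report validates against a shipped schema).
Stage boundaries are logged with record counts, making the records surviving
each stated filter auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import genome_model, metabolome_model, reciprocal_map
from .metabolome_model import ChemTaxonomy, MergedAnnotations, MolecularNetwork

logger = logging.getLogger(__name__)


class Thresholds(BaseModel):
    min_identity: float = 70.0
    cosine_min: float = 0.7
    min_matched: int = 6
    top_k: int = 10
    frag_tol: float = 0.02
    ppm_tol: float = 20.0
    rt_min_diff: float = 1.0


class RunConfig(BaseModel):
    genome: Optional[Path] = None
    genome_fasta: Optional[Path] = None
    protein_fasta: Optional[Path] = None
    regions: Optional[Path] = None
    ref_cluster: Optional[Path] = None
    query_cluster: Optional[Path] = None
    spectra: Optional[Path] = None
    quant: Optional[Path] = None
    edges: Optional[Path] = None
    tier1: Optional[Path] = None
    tier2: Optional[Path] = None
    tier3: Optional[Path] = None
    taxonomy: Optional[Path] = None
    pathway_db: Optional[Path] = None
    predicted_compounds: Optional[Path] = None
    scaffold_flags: Optional[Path] = None
    out_dir: Path = Path("out")
    seed: int = 0
    thresholds: Thresholds = Field(default_factory=Thresholds)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        cfg = cls.model_validate(data)
        return cfg

    def validate_paths(self) -> None:
        for name, value in self.model_dump().items():
            if name in ("out_dir", "seed", "thresholds") or value is None:
                continue
            if not Path(value).exists():
                raise FileNotFoundError(f"config input {name}: {value} does not exist")

    @classmethod
    def for_scenario_dir(cls, scenario_dir: str | Path, **overrides) -> "RunConfig":
        """Point every input at the files a synthetic scenario emits."""
        d = Path(scenario_dir)
        defaults = dict(
            genome=d / "genome.gff3",
            genome_fasta=d / "genome.fna",
            protein_fasta=d / "proteins.faa",
            regions=d / "regions.tsv",
            ref_cluster=d / "ref_cluster.gbk",
            query_cluster=d / "query_cluster.gbk",
            spectra=d / "spectra.mgf",
            quant=d / "quant.tsv",
            edges=d / "edges.tsv",
            tier1=d / "tier1_spectral_library.tsv",
            tier2=d / "tier2_network_propagation.tsv",
            tier3=d / "tier3_in_silico.tsv",
            taxonomy=d / "taxonomy.tsv",
            pathway_db=d / "pathways.json",
            predicted_compounds=d / "predicted_compounds.tsv",
            scaffold_flags=d / "scaffold_flags.tsv",
            out_dir=d / "out",
        )
        defaults.update(overrides)
        return cls(**defaults)


# --- report sections -------------------------------------------------------


class CensusSection(BaseModel):
    illumina: int
    minion: int
    total_rows: int


class ComparisonSection(BaseModel):
    cluster_similarity_pct: int
    orientation: str
    rank_corr: float
    n_hits: int
    unmatched_ref: list[str]


class AnnotationSection(BaseModel):
    n_nodes: int
    n_components: int
    tier_counts: dict[str, int]
    n_unannotated: int
    composition: list[tuple[str, int, float]]


class ForwardSection(BaseModel):
    presences: dict[str, list[int]]
    classes: dict[str, list[str]]
    n_distinct_classes: int
    class_search: dict[str, tuple[int, list[int]]]


class PathwayHit(BaseModel):
    feature_id: int
    pathway_ids: list[str]


class ReverseSection(BaseModel):
    pathway_hits: list[PathwayHit]
    n_pathway_enzymes: int
    n_enzyme_matches: int
    matched_by: dict[str, int]
    region_overlap: dict[str, int]
    region_ranking: list[str]
    top_region: Optional[str]
    neighborhood: Optional[dict] = None


class IsomerSection(BaseModel):
    pairs: list[tuple[int, int]]


class Report(BaseModel):
    census: Optional[CensusSection] = None
    comparison: Optional[ComparisonSection] = None
    annotation: Optional[AnnotationSection] = None
    forward: Optional[ForwardSection] = None
    reverse: Optional[ReverseSection] = None
    isomers: Optional[IsomerSection] = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


# --- shared loading --------------------------------------------------------


class RunContext:
    """Inputs loaded once and shared by the forward and reverse runs."""

    def __init__(self, config: RunConfig):
        config.validate_paths()
        self.config = config
        t = config.thresholds
        self.genome = genome_model.parse_cds_annotation(
            config.genome, config.genome_fasta, config.protein_fasta
        )
        logger.info("parse: %d CDS on %d contigs", len(self.genome.cds),
                    len(self.genome.contigs))
        self.regions = genome_model.parse_region_table(config.regions)
        logger.info("parse: %d BGC regions", len(self.regions))
        if config.quant and config.edges:
            quant = metabolome_model.read_quant_table(config.quant)
            edges = metabolome_model.read_edge_table(config.edges)
            self.network: MolecularNetwork = metabolome_model.network_from_tables(
                quant, edges
            )
        elif config.spectra:
            spectra = metabolome_model.read_mgf(config.spectra)
            self.network = metabolome_model.build_network(
                spectra,
                cosine_min=t.cosine_min,
                min_matched=t.min_matched,
                top_k=t.top_k,
                frag_tol=t.frag_tol,
            )
        else:
            raise FileNotFoundError("need either quant+edges or spectra")
        logger.info(
            "network: %d nodes, %d edges, %d components",
            len(self.network.nodes), len(self.network.edges),
            self.network.n_components,
        )
        tiers = []
        for tier, path in ((1, config.tier1), (2, config.tier2), (3, config.tier3)):
            tiers.append(_read_annotation_table(path, tier) if path else [])
        self.merged: MergedAnnotations = metabolome_model.merge_annotations(
            self.network, *tiers
        )
        logger.info(
            "annotate: tiers %s, %d unannotated",
            self.merged.tier_counts, self.merged.n_unannotated,
        )
        self.taxonomy = (
            ChemTaxonomy.from_tsv(config.taxonomy)
            if config.taxonomy
            else ChemTaxonomy(table={})
        )
        self.pathway_db = (
            reciprocal_map.PathwayDb.from_json(config.pathway_db)
            if config.pathway_db
            else reciprocal_map.PathwayDb({}, {})
        )
        self.predicted = (
            reciprocal_map.load_predicted_compounds(config.predicted_compounds)
            if config.predicted_compounds
            else []
        )
        self.scaffold_flags = (
            reciprocal_map.load_scaffold_flags(config.scaffold_flags)
            if config.scaffold_flags
            else {}
        )


def _read_annotation_table(path, tier):
    import pandas as pd

    df = pd.read_csv(path, sep="\t").fillna("")
    records = []
    for row in df.to_dict("records"):
        records.append(
            metabolome_model.AnnotationRecord(
                feature_id=int(row["feature_id"]),
                name=str(row["name"]),
                structure_key=str(row["structure_key"]) or None,
                tier=int(row.get("tier", tier)),
                score=float(row["score"]),
                mz_error_ppm=float(row["mz_error_ppm"])
                if str(row.get("mz_error_ppm", "")).strip()
                else None,
            )
        )
    return records


# --- runs ------------------------------------------------------------------


def run_forward(ctx: RunContext) -> ForwardSection:
    """Predicted compounds -> direct presence -> class grouping -> class-mates."""
    presences = {
        c.name: reciprocal_map.compound_presence(c, ctx.merged)
        for c in ctx.predicted
    }
    groups, n_classes = reciprocal_map.classify_predicted(ctx.predicted, ctx.taxonomy)
    class_search = reciprocal_map.forward_class_search(
        sorted(groups), ctx.merged, ctx.taxonomy
    )
    logger.info(
        "forward: %d predicted compounds, %d direct presences, %d classes",
        len(ctx.predicted), sum(len(v) for v in presences.values()), n_classes,
    )
    return ForwardSection(
        presences=presences,
        classes={label: [c.name for c in cs] for label, cs in groups.items()},
        n_distinct_classes=n_classes,
        class_search=class_search,
    )


def run_reverse(ctx: RunContext) -> ReverseSection:
    """Annotated metabolome -> pathways -> enzymes -> genome -> BGC overlap."""
    hits = reciprocal_map.reverse_pathway_map(ctx.merged, ctx.pathway_db)
    logger.info("reverse: %d metabolites with pathway hits", len(hits))
    if not hits:
        if not ctx.pathway_db.compound_to_pathways:
            logger.warning("pathway database is empty; reverse section empty")
        return ReverseSection(
            pathway_hits=[], n_pathway_enzymes=0, n_enzyme_matches=0,
            matched_by={}, region_overlap={}, region_ranking=[], top_region=None,
        )
    feature_id, pathway_ids = hits[0]
    pathway_id = pathway_ids[0]
    matches = reciprocal_map.match_pathway_enzymes(
        pathway_id, ctx.pathway_db, ctx.genome
    )
    logger.info("reverse: %d enzyme matches for %s", len(matches), pathway_id)
    counts, ranking = reciprocal_map.overlap_with_bgcs(matches, ctx.regions)
    neighborhood = reciprocal_map.neighborhood_report(
        ctx.network, feature_id, ctx.merged, ctx.scaffold_flags
    )
    by = {}
    for m in matches:
        by[m.matched_by] = by.get(m.matched_by, 0) + 1
    return ReverseSection(
        pathway_hits=[PathwayHit(feature_id=f, pathway_ids=p) for f, p in hits],
        n_pathway_enzymes=len(ctx.pathway_db.pathway_to_enzymes[pathway_id]),
        n_enzyme_matches=len(matches),
        matched_by=by,
        region_overlap=counts,
        region_ranking=ranking,
        top_region=ranking[0] if ranking else None,
        neighborhood=neighborhood.to_dict(),
    )


def run_all(config: RunConfig) -> Report:
    """Forward plus reverse plus the shared census/annotation summaries."""
    ctx = RunContext(config)
    t = config.thresholds
    census = CensusSection(
        illumina=genome_model.region_census(ctx.regions, "Illumina"),
        minion=genome_model.region_census(ctx.regions, "MinION"),
        total_rows=len(ctx.regions),
    )
    comparison = None
    if config.ref_cluster and config.query_cluster:
        from . import bgc_compare

        ref = genome_model.parse_cds_annotation(config.ref_cluster).cds
        qry = genome_model.parse_cds_annotation(config.query_cluster).cds
        comp = bgc_compare.compare_clusters(qry, ref, min_identity=t.min_identity)
        comparison = ComparisonSection(
            cluster_similarity_pct=comp.cluster_similarity_pct,
            orientation=comp.orientation,
            rank_corr=comp.rank_corr,
            n_hits=len(comp.hits),
            unmatched_ref=comp.unmatched_ref,
        )
    composition = (
        metabolome_model.composition_summary(ctx.merged, ctx.taxonomy, "superclass")
        if not ctx.merged.table.empty
        else []
    )
    annotation = AnnotationSection(
        n_nodes=len(ctx.network.nodes),
        n_components=ctx.network.n_components,
        tier_counts={str(k): v for k, v in ctx.merged.tier_counts.items()},
        n_unannotated=ctx.merged.n_unannotated,
        composition=composition,
    )
    isomers = IsomerSection(
        pairs=metabolome_model.find_isomer_candidates(
            ctx.network, ppm_tol=t.ppm_tol, rt_min_diff=t.rt_min_diff
        )
    )
    report = Report(
        census=census,
        comparison=comparison,
        annotation=annotation,
        forward=run_forward(ctx),
        reverse=run_reverse(ctx),
        isomers=isomers,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.write(out / "report.json")
    return report
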