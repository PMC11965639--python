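"""Two-way integration of genome mining and metabolome annotation.

Forward direction: compounds predicted from BGC content are searched in the
annotated metabolome — first directly (name / InChIKey skeleton), then by
chemical class, so that class-mates of a predicted compound surface even
when the compound itself was never detected.

Reverse direction: annotated metabolites are looked up in a pathway database
(KEGG-style compound -> pathway -> enzyme EC/COG sets), the pathway's enzymes
are matched against the genome's CDS annotations by EC number (with '-'
wildcard fields) or COG identifier, and the matched CDS are intersected with
the predicted BGC regions — ranking the regions by how many pathway enzymes
they contain.  A network-neighborhood report around the anchoring metabolite
completes the picture.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .genome_model import BgcRegion, CdsRecord, GenomeAnnotation, is_valid_ec
from .metabolome_model import (
    ChemTaxonomy,
    MergedAnnotations,
    MolecularNetwork,
    normalize_structure_key,
)

logger = logging.getLogger(__name__)

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_name(name: str) -> str:
    """Casefold, strip accents and all non-alphanumerics."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return _NON_ALNUM.sub("", stripped.casefold())


@dataclass
class PredictedCompound:
    """A compound a BGC is predicted to produce, with its chemical class."""

    name: str
    structure_key: Optional[str] = None
    chem_class: str = ""
    source_region: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("predicted compound needs a name")
        if self.structure_key is not None:
            self.structure_key = normalize_structure_key(self.structure_key)


def load_predicted_compounds(path: str | Path) -> list[PredictedCompound]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t").fillna("")
    return [
        PredictedCompound(
            name=str(row["name"]),
            structure_key=str(row["structure_key"]) or None
            if "structure_key" in row
            else None,
            chem_class=str(row.get("chem_class", "")),
            source_region=str(row.get("source_region", "")),
        )
        for row in df.to_dict("records")
    ]


@dataclass
class PathwayEnzyme:
    ec: str
    cog: Optional[str]
    name: str

    def __post_init__(self) -> None:
        if not is_valid_ec(self.ec):
            raise ValueError(f"enzyme {self.name}: malformed EC {self.ec!r}")


@dataclass
class PathwayDb:
    """Compound -> pathways and pathway -> enzymes maps (KEGG-style)."""

    compound_to_pathways: dict[str, list[str]]
    pathway_to_enzymes: dict[str, list[PathwayEnzyme]]

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayDb":
        data = json.loads(Path(path).read_text())
        return cls(
            compound_to_pathways={
                k: list(v) for k, v in data["compound_to_pathways"].items()
            },
            pathway_to_enzymes={
                pid: [PathwayEnzyme(e["ec"], e.get("cog"), e["name"]) for e in enzymes]
                for pid, enzymes in data["pathway_to_enzymes"].items()
            },
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "compound_to_pathways": self.compound_to_pathways,
            "pathway_to_enzymes": {
                pid: [{"ec": e.ec, "cog": e.cog, "name": e.name} for e in enzymes]
                for pid, enzymes in self.pathway_to_enzymes.items()
            },
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    def pathways_for(self, key: str) -> list[str]:
        """Look up by structure key first, normalized name second."""
        hit = self.compound_to_pathways.get(normalize_structure_key(key))
        if hit is not None:
            return list(hit)
        wanted = normalize_name(key)
        for cand, pathways in self.compound_to_pathways.items():
            if normalize_name(cand) == wanted:
                return list(pathways)
        return []


@dataclass
class EnzymeMatch:
    pathway_id: str
    enzyme_name: str
    matched_by: str  # "EC", "COG" or "both"
    cds: CdsRecord

    def __post_init__(self) -> None:
        if self.matched_by not in ("EC", "COG", "both"):
            raise ValueError(f"matched_by {self.matched_by!r}")


@dataclass
class PathwayMappingResult:
    feature_id: int
    pathway_id: str
    n_pathway_enzymes: int
    matches: list[EnzymeMatch]
    region_overlap: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "pathway_id": self.pathway_id,
            "n_pathway_enzymes": self.n_pathway_enzymes,
            "n_matches": len(self.matches),
            "matches": [
                {
                    "enzyme_name": m.enzyme_name,
                    "matched_by": m.matched_by,
                    "locus_tag": m.cds.locus_tag,
                    "contig_id": m.cds.contig_id,
                    "start": m.cds.start,
                    "end": m.cds.end,
                }
                for m in self.matches
            ],
            "region_overlap": self.region_overlap,
        }


# ---------------------------------------------------------------------------
# Forward direction


def compound_presence(
    predicted: PredictedCompound, merged: MergedAnnotations
) -> list[int]:
    """Feature ids whose annotation matches the predicted compound.

    Matches on normalized name equality, or on equal InChIKey skeleton
    (first 14-character block) when both sides carry a key.
    """
    wanted_name = normalize_name(predicted.name)
    wanted_block = (
        predicted.structure_key.split("-")[0]
        if predicted.structure_key and "-" in predicted.structure_key
        else None
    )
    out = []
    for row in merged.table.to_dict("records"):
        if normalize_name(str(row["name"])) == wanted_name:
            out.append(int(row["feature_id"]))
            continue
        key = row.get("structure_key")
        if wanted_block and isinstance(key, str) and "-" in key:
            if key.split("-")[0] == wanted_block:
                out.append(int(row["feature_id"]))
    return sorted(set(out))


def classify_predicted(
    compounds: Sequence[PredictedCompound],
    taxonomy: Optional[ChemTaxonomy] = None,
) -> tuple[dict[str, list[PredictedCompound]], int]:
    """Group predicted compounds by chemical class.

    The explicit ``chem_class`` wins; otherwise the taxonomy is consulted via
    the structure key.  Compounds with neither are grouped under "None".
    Returns the grouping and the number of distinct named classes
    ("None" not counted as a class).
    """
    groups: dict[str, list[PredictedCompound]] = {}
    for c in compounds:
        label = c.chem_class
        if not label and taxonomy is not None and c.structure_key:
            label = taxonomy.lookup(c.structure_key, "class")
        if not label:
            label = "None"
        groups.setdefault(label, []).append(c)
    n_classes = len([k for k in groups if k != "None"])
    return groups, n_classes


def forward_class_search(
    classes: Iterable[str],
    merged: MergedAnnotations,
    taxonomy: ChemTaxonomy,
) -> dict[str, tuple[int, list[int]]]:
    """For each query class, the annotated nodes of that taxonomy class."""
    by_class: dict[str, list[int]] = {}
    for row in merged.table.to_dict("records"):
        key = row.get("structure_key")
        label = taxonomy.lookup(
            key if isinstance(key, str) and key else None, "class"
        )
        if label != "None":
            by_class.setdefault(label, []).append(int(row["feature_id"]))
    return {
        cls: (len(by_class.get(cls, [])), sorted(by_class.get(cls, [])))
        for cls in classes
    }


# ---------------------------------------------------------------------------
# Reverse direction


def reverse_pathway_map(
    merged: MergedAnnotations, db: PathwayDb
) -> list[tuple[int, list[str]]]:
    """Annotated metabolites found in the pathway database, with pathway ids."""
    if not db.compound_to_pathways:
        return []
    out = []
    for row in merged.table.to_dict("records"):
        key = row.get("structure_key")
        pathways: list[str] = []
        if isinstance(key, str) and key:
            pathways = db.pathways_for(key)
        if not pathways:
            pathways = db.pathways_for(str(row["name"]))
        if pathways:
            out.append((int(row["feature_id"]), sorted(set(pathways))))
    return out


def ec_matches(pattern: str, candidate: str) -> bool:
    """Field-wise EC comparison; '-' on either side matches any value."""
    for name, ec in (("pattern", pattern), ("candidate", candidate)):
        if not is_valid_ec(ec):
            raise ValueError(f"malformed EC {name}: {ec!r}")
    for f1, f2 in zip(pattern.split("."), candidate.split(".")):
        if f1 != "-" and f2 != "-" and f1 != f2:
            return False
    return True


def match_pathway_enzymes(
    pathway_id: str, db: PathwayDb, genome: GenomeAnnotation
) -> list[EnzymeMatch]:
    """Genome CDS matching the pathway's enzymes by EC and/or COG."""
    if pathway_id not in db.pathway_to_enzymes:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    enzymes = db.pathway_to_enzymes[pathway_id]
    if not any(c.ec_numbers or c.cog_id for c in genome.cds):
        logger.warning("genome carries no EC or COG qualifiers; nothing to match")
        return []
    matches = []
    for enzyme in enzymes:
        for cds in genome.cds:
            by_ec = any(ec_matches(enzyme.ec, ec) for ec in cds.ec_numbers)
            by_cog = enzyme.cog is not None and cds.cog_id == enzyme.cog
            if by_ec or by_cog:
                matched_by = "both" if (by_ec and by_cog) else ("EC" if by_ec else "COG")
                matches.append(
                    EnzymeMatch(
                        pathway_id=pathway_id,
                        enzyme_name=enzyme.name,
                        matched_by=matched_by,
                        cds=cds,
                    )
                )
    return matches


def overlap_with_bgcs(
    matches: Sequence[EnzymeMatch], regions: Sequence[BgcRegion]
) -> tuple[dict[str, int], list[str]]:
    """Per-region count of matched CDS overlapping it, plus a ranking.

    Overlap is half-open interval intersection on the same contig:
    max(starts) < min(ends).  A CDS matched by several enzymes counts once
    per region.  Regions are ranked by count descending, ties by region id.
    """
    counts: dict[str, int] = {}
    for region in regions:
        seen: set[str] = set()
        for m in matches:
            cds = m.cds
            if cds.contig_id != region.contig_id or cds.locus_tag in seen:
                continue
            if max(cds.start, region.start) < min(cds.end, region.end):
                seen.add(cds.locus_tag)
        counts[region.region_id] = len(seen)
    ranking = sorted(counts, key=lambda rid: (-counts[rid], rid))
    return counts, ranking


# ---------------------------------------------------------------------------
# Network neighborhood


@dataclass
class NeighborInfo:
    feature_id: int
    name: str
    tier: str
    shares_scaffold: bool


@dataclass
class NeighborhoodReport:
    feature_id: int
    neighbors: list[NeighborInfo]

    @property
    def n_neighbors(self) -> int:
        return len(self.neighbors)

    @property
    def n_scaffold_sharing(self) -> int:
        return sum(1 for n in self.neighbors if n.shares_scaffold)

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "n_neighbors": self.n_neighbors,
            "n_scaffold_sharing": self.n_scaffold_sharing,
            "neighbors": [
                {
                    "feature_id": n.feature_id,
                    "name": n.name,
                    "tier": n.tier,
                    "shares_scaffold": n.shares_scaffold,
                }
                for n in self.neighbors
            ],
        }


def neighborhood_report(
    network: MolecularNetwork,
    feature_id: int,
    merged: MergedAnnotations,
    scaffold_flags: Mapping[str, bool] = (),
) -> NeighborhoodReport:
    """Direct neighbors of a node with their annotations and scaffold flags.

    ``scaffold_flags`` maps structure keys to whether the caller judges the
    structure to share the query compound's core scaffold (e.g. an
    indole-like nucleus); the report counts flagged neighbors.
    """
    if feature_id not in network.nodes:
        raise KeyError(f"feature {feature_id} not in network")
    flags = dict(scaffold_flags) if scaffold_flags else {}
    flags = {normalize_structure_key(k): v for k, v in flags.items()}
    neighbors = []
    from .metabolome_model import TIER_NAMES

    for nid in network.neighbors(feature_id):
        ann = merged.annotation_for(nid)
        if ann is None:
            neighbors.append(NeighborInfo(nid, "", "unannotated", False))
        else:
            shares = bool(ann.structure_key and flags.get(ann.structure_key, False))
            neighbors.append(
                NeighborInfo(nid, ann.name, TIER_NAMES[ann.tier], shares)
            )
    return NeighborhoodReport(feature_id=feature_id, neighbors=neighbors)


def load_scaffold_flags(path: str | Path) -> dict[str, bool]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {
        normalize_structure_key(str(r["structure_key"])): bool(r["shares_scaffold"])
        for r in df.to_dict("records")
    }
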