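"""Genome annotation and biosynthetic gene cluster (BGC) region handling.

Coding sequences and cluster regions are the genomic half of the reciprocal
metabologenomics analysis.  Internally every interval is 0-based half-open on
the forward strand; printed coordinates (GenBank, antiSMASH region tables) are
1-based inclusive and are converted on input and output.

The module also packages the region census of the *Micromonospora* sp. BRA006
isolate — the predicted BGC regions of the two sequencing techniques
(short-read Illumina and long-read MinION) with their most-similar known
clusters — as a data fixture, together with the census operation over it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

TECHNIQUES = ("Illumina", "MinION", "Both")

_EC_FIELD = r"(?:\d+|-)"
EC_PATTERN = re.compile(rf"^{_EC_FIELD}\.{_EC_FIELD}\.{_EC_FIELD}\.(?:n?\d+|-)$")


class ParseError(ValueError):
    """Raised when an input file does not conform to its named standard."""


def is_valid_ec(ec: str) -> bool:
    """True if ``ec`` is a four-field EC number, '-' allowed per field."""
    return bool(EC_PATTERN.match(ec))


@dataclass
class CdsRecord:
    """A coding sequence with functional identifiers.

    Coordinates are 0-based half-open.  ``ec_numbers`` may contain partial EC
    codes such as ``6.3.2.-``; ``cog_id`` is a Cluster of Orthologous Groups
    identifier such as ``COG1020`` when annotated.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    cog_id: Optional[str] = None
    protein_seq: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"CDS {self.locus_tag}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.locus_tag}: strand must be '+' or '-'")
        for ec in self.ec_numbers:
            if not is_valid_ec(ec):
                raise ValueError(f"CDS {self.locus_tag}: malformed EC number {ec!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Contig lengths plus the coding sequences annotated on them."""

    contigs: dict[str, int]
    cds: list[CdsRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.cds:
            if rec.locus_tag in seen:
                raise ValueError(f"duplicate locus_tag {rec.locus_tag}")
            seen.add(rec.locus_tag)
            length = self.contigs.get(rec.contig_id)
            if length is not None and rec.end > length:
                raise ValueError(
                    f"CDS {rec.locus_tag} extends past contig "
                    f"{rec.contig_id} (len {length})"
                )

    def by_locus_tag(self) -> dict[str, CdsRecord]:
        return {rec.locus_tag: rec for rec in self.cds}


@dataclass
class BgcRegion:
    """A predicted biosynthetic gene cluster interval.

    ``similarity`` maps a sequencing technique to the percent of the
    most-similar known cluster's genes with significant hits, as reported by
    cluster-prediction tools.  Rows printed with a dual cell like ``92%/88%``
    carry one value per technique (Illumina first, MinION second).
    ``editorial`` flags rows whose printed cells required a cleaned numeric
    interpretation; ``verbatim`` keeps the original cell text for those rows.
    """

    region_id: str
    contig_id: str
    start: int
    end: int
    bgc_type: str
    known_cluster: str = ""
    known_cluster_type: str = ""
    similarity: dict[str, float] = field(default_factory=dict)
    technique: str = "Both"
    editorial: bool = False
    verbatim: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )
        if self.technique not in TECHNIQUES:
            raise ValueError(
                f"region {self.region_id}: unknown technique {self.technique!r}"
            )
        for tech, pct in self.similarity.items():
            if tech not in TECHNIQUES[:2]:
                raise ValueError(f"region {self.region_id}: similarity key {tech!r}")
            if not 0 <= pct <= 100:
                raise ValueError(
                    f"region {self.region_id}: similarity {pct} outside [0, 100]"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def similarity_pct(self, technique: str) -> Optional[float]:
        return self.similarity.get(technique)


# ---------------------------------------------------------------------------
# Genome annotation I/O


def _cds_from_seqfeature(contig_id: str, feature, seq) -> Optional[CdsRecord]:
    if feature.location is None:
        return None
    quals = feature.qualifiers
    locus_tag = quals.get("locus_tag", quals.get("ID", [""]))[0]
    ecs = [e for e in quals.get("EC_number", []) + quals.get("eC_number", [])]
    cog = None
    for xref in quals.get("db_xref", []):
        if xref.startswith("COG:"):
            cog = xref.split(":", 1)[1]
    if cog is None and "COG" in quals:
        cog = quals["COG"][0]
    translation = quals.get("translation", [""])[0]
    if not translation and seq is not None:
        translation = str(feature.extract(seq).translate(to_stop=True))
    return CdsRecord(
        contig_id=contig_id,
        start=int(feature.location.start),
        end=int(feature.location.end),
        strand="-" if feature.location.strand == -1 else "+",
        locus_tag=locus_tag,
        product=quals.get("product", [""])[0],
        ec_numbers=ecs,
        cog_id=cog,
        protein_seq=translation,
    )


def _parse_genbank(path: Path) -> GenomeAnnotation:
    contigs: dict[str, int] = {}
    cds: list[CdsRecord] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:  # Biopython names the offending record/line
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no GenBank records found")
    for record in records:
        contigs[record.id] = len(record.seq)
        for feature in record.features:
            if feature.type != "CDS":
                continue
            rec = _cds_from_seqfeature(record.id, feature, record.seq)
            if rec is None:
                logger.warning("%s: CDS without coordinates skipped", record.id)
                continue
            cds.append(rec)
    return GenomeAnnotation(contigs=contigs, cds=cds)


def _parse_gff3(
    path: Path,
    fasta: Optional[Path] = None,
    protein_fasta: Optional[Path] = None,
) -> GenomeAnnotation:
    from gffutils.iterators import DataIterator

    contigs: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                contigs[parts[1]] = int(parts[3])
        elif line.startswith("##FASTA"):
            break

    genome_seqs = {}
    if fasta is not None:
        genome_seqs = {r.id: r.seq for r in SeqIO.parse(str(fasta), "fasta")}
        for cid, seq in genome_seqs.items():
            contigs.setdefault(cid, len(seq))
    proteins = {}
    if protein_fasta is not None:
        proteins = {
            r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")
        }

    cds: list[CdsRecord] = []
    try:
        features = list(DataIterator(str(path)))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for feat in features:
        if feat.featuretype != "CDS":
            continue
        attrs = feat.attributes
        locus_tag = (attrs.get("locus_tag") or attrs.get("ID") or [""])[0]
        if feat.start is None or feat.end is None:
            logger.warning("CDS %s without coordinates skipped", locus_tag)
            continue
        ecs = list(attrs.get("eC_number") or attrs.get("EC_number") or [])
        cog = None
        for xref in attrs.get("Dbxref") or attrs.get("db_xref") or []:
            if xref.startswith("COG:"):
                cog = xref.split(":", 1)[1]
        protein = proteins.get(locus_tag, "")
        if not protein and feat.seqid in genome_seqs:
            sub = genome_seqs[feat.seqid][feat.start - 1 : feat.end]
            if feat.strand == "-":
                sub = sub.reverse_complement()
            protein = str(sub.translate(to_stop=True))
        cds.append(
            CdsRecord(
                contig_id=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand="-" if feat.strand == "-" else "+",
                locus_tag=locus_tag,
                product=(attrs.get("product") or [""])[0],
                ec_numbers=ecs,
                cog_id=cog,
                protein_seq=protein,
            )
        )
    return GenomeAnnotation(contigs=contigs, cds=cds)


def parse_cds_annotation(
    path: str | Path,
    fasta: Optional[str | Path] = None,
    protein_fasta: Optional[str | Path] = None,
) -> GenomeAnnotation:
    """Read a genome annotation from GenBank or GFF3.

    Format is chosen by extension (``.gb``/``.gbk``/``.gbff`` vs
    ``.gff``/``.gff3``).  For GFF3, ``fasta`` supplies contig nucleotide
    sequence and ``protein_fasta`` supplies translations keyed by locus tag;
    CDS lacking a translation are translated from the nucleotide sequence
    when it is available, else left with an empty protein.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return _parse_genbank(path)
    if suffix in (".gff", ".gff3"):
        return _parse_gff3(
            path,
            Path(fasta) if fasta else None,
            Path(protein_fasta) if protein_fasta else None,
        )
    raise ParseError(f"{path}: unrecognized annotation format {suffix!r}")


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3 (CDS features only, Prokka-style tags)."""
    lines = ["##gff-version 3"]
    for contig_id, length in annotation.contigs.items():
        lines.append(f"##sequence-region {contig_id} 1 {length}")
    for rec in annotation.cds:
        attrs = [f"ID={rec.locus_tag}", f"locus_tag={rec.locus_tag}"]
        if rec.product:
            attrs.append(f"product={rec.product}")
        for ec in rec.ec_numbers:
            attrs.append(f"eC_number={ec}")
        if rec.cog_id:
            attrs.append(f"Dbxref=COG:{rec.cog_id}")
        lines.append(
            "\t".join(
                [
                    rec.contig_id,
                    "recip",
                    "CDS",
                    str(rec.start + 1),
                    str(rec.end),
                    ".",
                    rec.strand,
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Region tables

_REGION_COLUMNS = {
    "region": "region",
    "type": "type",
    "from": "from",
    "to": "to",
    "known_cluster": "known_cluster",
    "most similar known cluster": "known_cluster",
    "known_cluster_type": "known_cluster_type",
    "type from most similar known cluster": "known_cluster_type",
    "similarity": "similarity",
    "technique": "technique",
}

_NUM_RE = re.compile(r"[\d.]+")


def _clean_coordinate(cell: str) -> int:
    return int(str(cell).replace(",", "").strip())


def _clean_pct(cell: str) -> float:
    m = _NUM_RE.search(str(cell).replace(",", ""))
    if m is None:
        raise ParseError(f"cannot parse similarity cell {cell!r}")
    value = float(m.group())
    return value


def _parse_similarity_cell(cell: str, technique: str) -> dict[str, float]:
    cell = str(cell).strip()
    if not cell or cell.lower() in ("nan", "na", "-"):
        return {}
    parts = cell.split("/")
    if len(parts) == 2:
        # dual cells are ordered Illumina then MinION
        return {"Illumina": _clean_pct(parts[0]), "MinION": _clean_pct(parts[1])}
    value = _clean_pct(cell)
    if technique == "Both":
        return {"Illumina": value, "MinION": value}
    return {technique: value}


def parse_region_table(path: str | Path) -> list[BgcRegion]:
    """Read a TSV of predicted BGC regions (antiSMASH-region dialect).

    Coordinates are 1-based inclusive in the file and converted to 0-based
    half-open; dual similarity cells like ``92%/88%`` are split into
    per-technique values (Illumina first).  The contig id is the prefix of
    the dotted region id (region ``1.9`` lies on contig ``1``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [
        _REGION_COLUMNS.get(c.strip().lower(), c.strip().lower()) for c in df.columns
    ]
    required = {"region", "type", "from", "to", "technique"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    regions = []
    for row in df.to_dict("records"):
        region_id = str(row["region"]).strip()
        technique = str(row["technique"]).strip()
        if technique not in TECHNIQUES:
            raise ParseError(
                f"{path}: region {region_id}: unknown technique {technique!r}"
            )
        start1 = _clean_coordinate(row["from"])
        end1 = _clean_coordinate(row["to"])
        if start1 >= end1:
            raise ParseError(
                f"{path}: region {region_id}: From {start1} >= To {end1}"
            )
        regions.append(
            BgcRegion(
                region_id=region_id,
                contig_id=region_id.split(".")[0],
                start=start1 - 1,
                end=end1,
                bgc_type=str(row["type"]).strip(),
                known_cluster=str(row.get("known_cluster", "")).strip(),
                known_cluster_type=str(row.get("known_cluster_type", "")).strip(),
                similarity=_parse_similarity_cell(
                    row.get("similarity", ""), technique
                ),
                technique=technique,
            )
        )
    return regions


def write_region_table(regions: Iterable[BgcRegion], path: str | Path) -> None:
    rows = []
    for r in regions:
        if r.similarity.get("Illumina") is not None and r.similarity.get(
            "MinION"
        ) is not None and r.similarity["Illumina"] != r.similarity["MinION"]:
            sim = f"{r.similarity['Illumina']:g}%/{r.similarity['MinION']:g}%"
        elif r.similarity:
            sim = f"{next(iter(r.similarity.values())):g}%"
        else:
            sim = ""
        rows.append(
            {
                "region": r.region_id,
                "type": r.bgc_type,
                "from": r.start + 1,
                "to": r.end,
                "known_cluster": r.known_cluster,
                "known_cluster_type": r.known_cluster_type,
                "similarity": sim,
                "technique": r.technique,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# Printed cells in the packaged BRA006 table with an obvious typographic slip;
# the loader substitutes a cleaned numeric reading and flags the row.
_FIXTURE_EDITORIAL: dict[str, dict[str, object]] = {
    "6.1": {"to": 37_770, "similarity": {"Illumina": 28.0, "MinION": 67.0}},
}


def load_paper_region_fixture() -> list[BgcRegion]:
    """The packaged BRA006 BGC region table, one :class:`BgcRegion` per row.

    Rows needing a cleaned numeric interpretation (e.g. a truncated ``To``
    coordinate) keep their verbatim cells and are flagged ``editorial``.
    """
    ref = resources.files("recip.data").joinpath("bra006_regions.tsv")
    df = pd.read_csv(ref.open("r"), sep="\t", dtype=str).fillna("")
    regions = []
    for row in df.to_dict("records"):
        region_id = str(row["region"]).strip()
        fixes = _FIXTURE_EDITORIAL.get(region_id, {})
        start1 = _clean_coordinate(row["from"])
        end1 = int(fixes.get("to", 0)) or _clean_coordinate(row["to"])
        similarity = fixes.get("similarity") or _parse_similarity_cell(
            row["similarity"], row["technique"]
        )
        regions.append(
            BgcRegion(
                region_id=region_id,
                contig_id=region_id.split(".")[0],
                start=start1 - 1,
                end=end1,
                bgc_type=row["type"],
                known_cluster=row["known_cluster"],
                known_cluster_type=row["known_cluster_type"],
                similarity=dict(similarity),
                technique=row["technique"],
                editorial=bool(fixes),
                verbatim={"from": row["from"], "to": row["to"],
                          "similarity": row["similarity"]} if fixes else {},
            )
        )
    return regions


def region_census(regions: Iterable[BgcRegion], technique: str) -> int:
    """Count regions detected by ``technique`` (its own rows plus 'Both')."""
    if technique not in ("Illumina", "MinION"):
        raise ValueError(f"technique must be Illumina or MinION, got {technique!r}")
    return sum(1 for r in regions if r.technique in (technique, "Both"))
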