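"""Deterministic synthetic datasets with planted ground truth.

Every stage of the reciprocal analysis is testable without external
downloads: the generator emits a complete toy study — annotated genome
(GFF3 + FASTA), BGC region table, reference/mutated cluster GenBank pair,
MS/MS spectra (MGF) with quantification and edge tables, tiered annotation
tables, chemical taxonomy, pathway database and predicted-compound table —
together with a :class:`GroundTruth` record of every planted fact.

Planted facts mirror the counts of the study design the package models: a
pathway of 16 enzymes whose coding sequences are scattered through the
genome with 11 of them inside one predicted BGC region; a molecular-network
hub with seven neighbors, six of which share the query compound's scaffold;
sequential annotation tiers of fixed sizes; isomer pairs (same precursor
m/z, distant retention times, adjacent nodes).

Determinism: one pseudo-random stream per artifact type, sub-seeded from the
scenario seed and the artifact tag, so adding an artifact never perturbs the
others and a fixed seed reproduces byte-identical files.

Network construction guarantee: each planted component is realized as a set
of spectra sharing one component-specific fragment-peak set (pairwise
modified cosine well above threshold), and fragment windows of different
components are disjoint.  Component sizes never exceed top_k + 1 under the
default network parameters, so the top-K edge filter cannot split a
component.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio import SeqIO

from .genome_model import BgcRegion, CdsRecord, GenomeAnnotation, write_gff3, write_region_table
from .metabolome_model import AnnotationRecord, Spectrum, build_network, write_mgf
from .reciprocal_map import PathwayDb, PathwayEnzyme

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one codon per amino acid (standard table); enough to make translations valid
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

DEFAULT_CLASS_COUNTS = (
    ("Phenols", 10),
    ("Organooxygen compounds", 34),
    ("Steroids and steroid derivatives", 34),
    ("Peptidomimetics", 2),
)

CLASS_TO_SUPERCLASS = {
    "Phenols": "Benzenoids",
    "Organooxygen compounds": "Organic oxygen compounds",
    "Steroids and steroid derivatives": "Lipids and lipid-like molecules",
    "Peptidomimetics": "Organic acids and derivatives",
}

PREDICTED_COMPOUNDS = (
    ("loseolamycin A1", "Phenols", "1.2"),
    ("cinerubin B", "Anthracyclines", "1.4"),
    ("brasilicardin A", "Steroids and steroid derivatives", "1.1"),
    ("pradimicin A", "Naphthacenes", "1.5"),
    ("bleomycin A2", "Peptidomimetics", "1.2"),
    ("quinolidomycin A", "Organooxygen compounds", "1.1"),
    ("kedarcidin", "Organooxygen compounds", "1.3"),
)


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), zlib.crc32(tag.encode())])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _protein_to_nt(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _inchikey(rng: np.random.Generator) -> str:
    letters = rng.choice(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), size=24)
    return "".join(letters[:14]) + "-" + "".join(letters[14:24]) + "-N"


@dataclass
class ScenarioParams:
    """Tunable conditions of a synthetic study, with planted defaults."""

    seed: int = 1
    n_contigs: int = 2
    n_cds: int = 60
    n_regions: int = 5
    planted_pathway_size: int = 16
    planted_in_region: int = 11
    cluster_identity_target: float = 80.0
    invert_cluster: bool = True
    n_cluster_genes: int = 8
    n_indels: int = 2
    n_network_nodes: int = 90
    n_components: int = 9
    tier_counts: tuple[int, int, int] = (20, 50, 10)
    n_isomer_pairs: int = 2
    hub_degree: int = 7
    hub_scaffold_sharers: int = 6
    class_counts: Optional[tuple[tuple[str, int], ...]] = None

    def validate(self) -> None:
        if self.planted_in_region > self.planted_pathway_size:
            raise ValueError("planted_in_region exceeds planted_pathway_size")
        if sum(self.tier_counts) > self.n_network_nodes:
            raise ValueError("tier counts exceed the number of network nodes")
        if self.hub_scaffold_sharers > self.hub_degree:
            raise ValueError("hub_scaffold_sharers exceeds hub_degree")
        if self.tier_counts[0] < 1:
            raise ValueError("need at least one spectral-library annotation (hub)")
        if self.tier_counts[1] < self.hub_degree:
            raise ValueError("hub neighbors are tier-2; tier_counts[1] too small")
        if not 0 < self.cluster_identity_target <= 100:
            raise ValueError("cluster_identity_target must be in (0, 100]")
        if self.n_cds < 50:
            raise ValueError("n_cds must be >= 50 to host the planted layout")
        if not 2 <= self.n_regions <= 6:
            raise ValueError("n_regions must be between 2 and 6")
        if self.n_components < 2:
            raise ValueError("need at least two components")
        hub_size = self.hub_degree + 1
        rest = self.n_network_nodes - hub_size
        if rest < 2 * (self.n_components - 1):
            raise ValueError(
                "too few nodes for the requested components (each needs >= 2)"
            )
        if self.n_isomer_pairs > self.n_components - 1:
            raise ValueError("at most one isomer pair per non-hub component")
        if int(np.ceil(rest / (self.n_components - 1))) > 11:
            raise ValueError(
                "component sizes above 11 are not representable under the "
                "default top-K network filter; raise n_components"
            )

    def resolved_class_counts(self, n_annotated: int) -> list[tuple[str, int]]:
        base = list(self.class_counts or DEFAULT_CLASS_COUNTS)
        total = sum(c for _, c in base)
        if total == n_annotated:
            return base
        # proportional reallocation (largest remainder) for scaled scenarios
        raw = [(label, c * n_annotated / total) for label, c in base]
        counts = [(label, int(x)) for label, x in raw]
        short = n_annotated - sum(c for _, c in counts)
        order = sorted(
            range(len(raw)), key=lambda i: raw[i][1] - int(raw[i][1]), reverse=True
        )
        counts = [list(t) for t in counts]
        for i in order[:short]:
            counts[i][1] += 1
        return [(label, c) for label, c in counts if c > 0]


@dataclass
class GroundTruth:
    """Every planted fact, recoverable by the corresponding pipeline stage."""

    pathway_id: str
    pathway_cds: list[str]
    in_region_cds: list[str]
    target_region_id: str
    expected_matched_by: dict[str, str]
    cluster_identities: dict[str, float]
    cluster_orientation: str
    tier_assignment: dict[int, int]
    tier_counts: tuple[int, int, int]
    n_unannotated: int
    class_counts: dict[str, int]
    isomer_pairs: list[tuple[int, int]]
    hub_id: int
    hub_neighbors: list[int]
    hub_scaffold_sharers: int
    pathway_metabolite_node: int
    pathway_metabolite_name: str
    n_network_nodes: int
    n_components: int
    predicted_compound_names: list[str]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["tier_assignment"] = {str(k): v for k, v in data["tier_assignment"].items()}
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["tier_assignment"] = {
            int(k): v for k, v in data["tier_assignment"].items()
        }
        data["tier_counts"] = tuple(data["tier_counts"])
        data["isomer_pairs"] = [tuple(p) for p in data["isomer_pairs"]]
        return cls(**data)


@dataclass
class ScenarioFiles:
    """Paths of everything a scenario writes."""

    out_dir: Path
    genome_gff3: Path
    genome_fasta: Path
    protein_fasta: Path
    region_table: Path
    ref_cluster: Path
    query_cluster: Path
    spectra_mgf: Path
    quant_table: Path
    edge_table: Path
    tier1_table: Path
    tier2_table: Path
    tier3_table: Path
    taxonomy_table: Path
    pathway_db: Path
    predicted_compounds: Path
    scaffold_flags: Path
    ground_truth: Path


# ---------------------------------------------------------------------------
# Genome with planted pathway


def _build_genome(params: ScenarioParams):
    rng = _rng(params.seed, "genome")
    n1 = 40
    n2 = params.n_cds - n1
    block_start, block_len = 10, params.planted_in_region
    block = list(range(block_start, block_start + block_len))
    n_out = params.planted_pathway_size - block_len
    out1 = [block[-1] + 4 + 2 * k for k in range(min(3, n_out))]
    out2 = list(range(2, 2 + 3 * (n_out - len(out1)), 3))

    pathway_slots = {("1", i) for i in block + out1} | {("2", i) for i in out2}
    enzyme_of_slot: dict[tuple[str, int], int] = {}
    ordered_slots = [("1", i) for i in block + out1] + [("2", i) for i in out2]
    for enz_idx, slot in enumerate(ordered_slots):
        enzyme_of_slot[slot] = enz_idx

    # enzyme i: unique EC third field; a mix of EC-only, COG-only and
    # EC+COG matching conventions so matched_by can be audited
    enzymes: list[PathwayEnzyme] = []
    cds_keys: list[tuple[list[str], Optional[str]]] = []  # per enzyme: CDS ec/cog
    expected_matched_by: dict[str, str] = {}
    for i in range(params.planted_pathway_size):
        name = f"pathway enzyme {i + 1}"
        cog = f"COG10{i:02d}"
        if i == 0:
            ec, cds_ec = "6.3.99.-", ["6.3.99.26"]  # wildcard in the database
        else:
            ec, cds_ec = f"6.3.{i + 1}.{i + 1}", [f"6.3.{i + 1}.{i + 1}"]
        if 10 <= i <= 12:  # COG-only: the CDS carries no EC number
            enzymes.append(PathwayEnzyme(ec=ec, cog=cog, name=name))
            cds_keys.append(([], cog))
            expected_matched_by[name] = "COG"
        elif i >= 13:  # both keys present on the CDS
            enzymes.append(PathwayEnzyme(ec=ec, cog=cog, name=name))
            cds_keys.append((cds_ec, cog))
            expected_matched_by[name] = "both"
        else:  # EC-only: the CDS carries a foreign COG or none
            enzymes.append(PathwayEnzyme(ec=ec, cog=cog, name=name))
            cds_keys.append((cds_ec, None))
            expected_matched_by[name] = "EC"

    contigs: dict[str, int] = {}
    cds: list[CdsRecord] = []
    contig_seqs: dict[str, str] = {}
    pathway_cds: list[str] = []
    in_region_cds: list[str] = []
    cds_index: dict[tuple[str, int], CdsRecord] = {}
    counter = 0
    for contig_id, n_genes in (("1", n1), ("2", n2)):
        cursor = 200
        seq_parts = [_random_nt(rng, 200)]
        for i in range(n_genes):
            counter += 1
            aa_len = int(rng.integers(120, 300))
            protein = _random_protein(rng, aa_len)
            nt = _protein_to_nt(protein)
            strand = "+" if rng.random() < 0.7 else "-"
            locus = f"SYN_{counter:05d}"
            slot = (contig_id, i)
            if slot in pathway_slots:
                ecs, cog = cds_keys[enzyme_of_slot[slot]]
                product = enzymes[enzyme_of_slot[slot]].name
                pathway_cds.append(locus)
                if contig_id == "1" and i in block:
                    in_region_cds.append(locus)
            else:
                ecs = (
                    [f"{rng.choice([2, 3])}.{rng.integers(1, 9)}."
                     f"{rng.integers(1, 9)}.{rng.integers(1, 99)}"]
                    if rng.random() < 0.4
                    else []
                )
                cog = f"COG9{rng.integers(100, 999)}" if rng.random() < 0.3 else None
                product = "hypothetical protein"
            start = cursor
            end = cursor + len(nt)
            seq_parts.append(
                nt if strand == "+" else str(Seq(nt).reverse_complement())
            )
            gap = int(rng.integers(60, 200))
            seq_parts.append(_random_nt(rng, gap))
            rec = CdsRecord(
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                locus_tag=locus,
                product=product,
                ec_numbers=list(ecs),
                cog_id=cog,
                protein_seq=protein,
            )
            cds.append(rec)
            cds_index[slot] = rec
            cursor = end + gap
        contigs[contig_id] = cursor + 200
        contig_seqs[contig_id] = "".join(seq_parts) + _random_nt(rng, 200)

    genome = GenomeAnnotation(contigs=contigs, cds=cds)

    # regions: the target region covers the planted block; one decoy region
    # catches a single out-of-block pathway CDS; the rest are background
    def span(idx_lo: int, idx_hi: int) -> tuple[int, int]:
        return (
            max(cds_index[("1", idx_lo)].start - 50, 0),
            cds_index[("1", idx_hi)].end + 50,
        )

    target_id = "1.3"
    region_specs = [
        ("1.1", 0, 3, "terpene", "isorenieratene-like", {"Illumina": 25.0, "MinION": 25.0}, "Both"),
        ("1.2", 5, 8, "T3PKS", "loseolamycin-like", {"MinION": 88.0}, "MinION"),
        (target_id, block[0], block[-1], "NRPS", "kedarcidin-like", {"Illumina": 13.0}, "Illumina"),
        ("1.4", out1[0] - 1, out1[0] + 1, "T2PKS", "cinerubin-like", {"Illumina": 80.0, "MinION": 74.0}, "Both"),
        ("1.5", 36, 38, "T1PKS", "quinolidomicin-like", {"Illumina": 45.0}, "Illumina"),
    ]
    regions = []
    for rid, lo, hi, btype, known, sim, tech in region_specs[: params.n_regions]:
        start, end = span(lo, hi)
        regions.append(
            BgcRegion(
                region_id=rid,
                contig_id="1",
                start=start,
                end=end,
                bgc_type=btype,
                known_cluster=known,
                known_cluster_type=btype,
                similarity=sim,
                technique=tech,
            )
        )

    return (
        genome,
        contig_seqs,
        regions,
        enzymes,
        pathway_cds,
        in_region_cds,
        target_id,
        expected_matched_by,
    )


# ---------------------------------------------------------------------------
# Reference / query cluster pair


def _layout_cluster(
    proteins: Sequence[tuple[str, str, str]], contig_id: str
) -> list[CdsRecord]:
    """(locus, protein, strand) triples -> CdsRecords on a fresh contig."""
    out = []
    cursor = 100
    for locus, protein, strand in proteins:
        nt_len = 3 * len(protein) + 3
        out.append(
            CdsRecord(
                contig_id=contig_id,
                start=cursor,
                end=cursor + nt_len,
                strand=strand,
                locus_tag=locus,
                product="cluster protein",
                protein_seq=protein,
            )
        )
        cursor += nt_len + 50
    return out


def make_reference_cluster(
    n_genes: int, seed: int, contig_id: str = "refclus"
) -> list[CdsRecord]:
    rng = _rng(seed, "cluster-ref")
    triples = [
        (f"REF_{i + 1:03d}", _random_protein(rng, int(rng.integers(200, 320))), "+")
        for i in range(n_genes)
    ]
    return _layout_cluster(triples, contig_id)


def _mutate_protein(
    protein: str, rate: float, rng: np.random.Generator
) -> tuple[str, float]:
    length = len(protein)
    k = int(rng.binomial(length, rate))
    positions = rng.choice(length, size=k, replace=False) if k else []
    chars = list(protein)
    for pos in positions:
        choices = [a for a in AA20 if a != chars[pos]]
        chars[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars), 100.0 * (length - k) / length


def mutate_cluster(
    ref_cds: Sequence[CdsRecord],
    identity_target: float,
    invert: bool,
    n_indels: int,
    seed: int,
) -> tuple[list[CdsRecord], dict[str, float]]:
    """Derive a query cluster from a reference at a planted identity level.

    Each gene receives point substitutions at rate (100 - target)/100 at
    uniform positions (always to a different residue, so every substitution
    is non-synonymous at the protein level).  ``invert`` reverses gene order
    and flips strands — a complete cluster inversion.  ``n_indels``
    alternates random gene deletions and insertions of unrelated genes.
    Returns the query CDS list and the realized per-gene identity, keyed by
    query locus tag (inserted genes are absent from the map).
    """
    if not 0 < identity_target <= 100:
        raise ValueError("identity_target must be in (0, 100]")
    rng = _rng(seed, "cluster-mut")
    rate = (100.0 - identity_target) / 100.0
    genes: list[tuple[str, str, Optional[float]]] = []  # ref locus, protein, identity
    for rec in ref_cds:
        mutated, identity = _mutate_protein(rec.protein_seq, rate, rng)
        genes.append((rec.locus_tag, mutated, identity))
    for op in range(n_indels):
        if op % 2 == 0 and len(genes) > 3:  # deletion
            del genes[int(rng.integers(0, len(genes)))]
        else:  # insertion of an unrelated gene
            pos = int(rng.integers(0, len(genes) + 1))
            genes.insert(
                pos, (None, _random_protein(rng, int(rng.integers(150, 250))), None)
            )
    if invert:
        genes = genes[::-1]
    strand = "-" if invert else "+"
    triples = []
    identities: dict[str, float] = {}
    for i, (_ref_locus, protein, identity) in enumerate(genes):
        locus = f"QRY_{i + 1:03d}"
        triples.append((locus, protein, strand))
        if identity is not None:
            identities[locus] = identity
    return _layout_cluster(triples, "qryclus"), identities


def write_cluster_genbank(cds: Sequence[CdsRecord], path: str | Path) -> None:
    """Write a cluster as a single-record GenBank file with translations."""
    contig_id = cds[0].contig_id if cds else "cluster"
    length = (max(c.end for c in cds) + 100) if cds else 100
    seq_chars = ["A"] * length
    for rec in cds:
        nt = _protein_to_nt(rec.protein_seq)
        if rec.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        seq_chars[rec.start : rec.end] = list(nt)
    record = SeqRecord(
        Seq("".join(seq_chars)),
        id=contig_id,
        name=contig_id[:16],
        description="synthetic biosynthetic gene cluster",
        annotations={"molecule_type": "DNA", "date": "01-JAN-2000"},
    )
    for rec in cds:
        record.features.append(
            SeqFeature(
                SimpleLocation(rec.start, rec.end, 1 if rec.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [rec.locus_tag],
                    "product": [rec.product],
                    "translation": [rec.protein_seq],
                },
            )
        )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# Molecular network, annotations, taxonomy, pathway database


def _component_sizes(params: ScenarioParams) -> list[int]:
    hub_size = params.hub_degree + 1
    rest = params.n_network_nodes - hub_size
    k = params.n_components - 1
    base = rest // k
    sizes = [base + (1 if i < rest % k else 0) for i in range(k)]
    return [hub_size] + sizes


def _build_spectra(params: ScenarioParams):
    rng = _rng(params.seed, "network")
    sizes = _component_sizes(params)
    spectra: list[Spectrum] = []
    component_of: dict[int, int] = {}
    next_id = 1
    precursor_slots = iter(
        250.0 + 3.1 * np.arange(params.n_network_nodes) + rng.uniform(0, 1, params.n_network_nodes)
    )
    members_by_comp: list[list[int]] = []
    for comp, size in enumerate(sizes):
        base_mz = 150.0 + 95.0 * comp
        offsets = np.sort(base_mz + np.arange(10) * 7.3 + rng.uniform(0, 1, 10))
        members = []
        for _ in range(size):
            fid = next_id
            next_id += 1
            pre = float(next(precursor_slots))
            rt = float(rng.uniform(2.0, 28.0))
            # intensities within a 2x band: sqrt-weighted vectors of any two
            # members then have cosine >= 2*sqrt(2)/3 ~ 0.94, safely above
            # the default edge threshold
            intensities = rng.uniform(50.0, 100.0, size=10)
            spectra.append(
                Spectrum(fid, pre, rt, np.column_stack([offsets, intensities]))
            )
            component_of[fid] = comp
            members.append(fid)
        members_by_comp.append(members)

    by_id = {s.feature_id: s for s in spectra}
    # isomer pairs: adjacent members of non-hub components, same precursor
    # m/z within a few ppm, retention times well apart
    isomer_pairs: list[tuple[int, int]] = []
    for k in range(params.n_isomer_pairs):
        members = members_by_comp[1 + k]  # one pair per non-hub component
        a, b = members[0], members[1]
        by_id[b].precursor_mz = by_id[a].precursor_mz + float(rng.uniform(-2e-3, 2e-3))
        by_id[b].rt = by_id[a].rt + float(rng.uniform(1.5, 3.0))
        isomer_pairs.append((min(a, b), max(a, b)))
    hub_id = members_by_comp[0][0]
    hub_neighbors = members_by_comp[0][1:]
    return spectra, component_of, isomer_pairs, hub_id, hub_neighbors


def _build_annotations(params: ScenarioParams, node_ids: list[int], hub_id: int,
                       hub_neighbors: list[int]):
    rng = _rng(params.seed, "annotations")
    n1, n2, n3 = params.tier_counts
    pool = [n for n in node_ids if n != hub_id and n not in hub_neighbors]
    tier1_nodes = [hub_id] + pool[: n1 - 1]
    rest = pool[n1 - 1 :]
    tier2_nodes = list(hub_neighbors) + rest[: n2 - len(hub_neighbors)]
    rest = rest[n2 - len(hub_neighbors) :]
    tier3_nodes = rest[:n3]
    unannotated = rest[n3:]

    keys = {}
    for fid in tier1_nodes + tier2_nodes + tier3_nodes:
        keys[fid] = _inchikey(rng)

    def records(nodes, tier, lo, hi):
        out = []
        for fid in nodes:
            out.append(
                AnnotationRecord(
                    feature_id=fid,
                    name=f"compound {fid:03d}",
                    structure_key=keys[fid],
                    tier=tier,
                    score=round(float(rng.uniform(lo, hi)), 4),
                    mz_error_ppm=round(float(rng.uniform(0.5, 15.0)), 2)
                    if tier == 1
                    else None,
                )
            )
        return out

    tier1 = records(tier1_nodes, 1, 0.75, 0.99)
    tier2 = records(tier2_nodes, 2, 0.3, 0.9)
    tier3 = records(tier3_nodes, 3, 0.2, 0.8)
    # the hub is the pathway-anchoring metabolite: a high-confidence
    # spectral-library match (score 0.97, 2.47 ppm mirror the study design)
    tier1[0].name = "brevianamide F"
    tier1[0].score = 0.97
    tier1[0].mz_error_ppm = 2.47

    # decoy lower-tier candidates for already-annotated nodes: these must
    # lose to the sequential precedence rule
    decoys2 = [
        AnnotationRecord(fid, f"decoy {fid:03d}", keys[fid], 2, 0.99)
        for fid in tier1_nodes[: min(5, len(tier1_nodes))]
    ]
    decoys3 = [
        AnnotationRecord(fid, f"decoy {fid:03d}", keys[fid], 3, 0.99)
        for fid in (tier1_nodes[:2] + tier2_nodes[:3])
    ]
    # duplicate within-tier candidates with lower scores: must lose on score
    dup1 = [
        AnnotationRecord(fid, f"altname {fid:03d}", keys[fid], 1,
                         max(0.0, r.score - 0.2))
        for fid, r in [(n, rec) for n, rec in zip(tier1_nodes[:3], tier1[:3])]
    ]
    tier_assignment = {fid: 1 for fid in tier1_nodes}
    tier_assignment.update({fid: 2 for fid in tier2_nodes})
    tier_assignment.update({fid: 3 for fid in tier3_nodes})
    return (
        tier1 + dup1,
        tier2 + decoys2,
        tier3 + decoys3,
        tier_assignment,
        keys,
        len(unannotated),
    )


# ---------------------------------------------------------------------------
# Scenario assembly


def generate_scenario(
    params: ScenarioParams, out_dir: str | Path
) -> tuple[ScenarioFiles, GroundTruth]:
    """Emit a complete synthetic study into ``out_dir``.

    Identical parameters (including seed) produce byte-identical files.
    Raises on inconsistent parameters before anything is written.
    """
    params.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (
        genome,
        contig_seqs,
        regions,
        enzymes,
        pathway_cds,
        in_region_cds,
        target_region_id,
        expected_matched_by,
    ) = _build_genome(params)

    ref_cds = make_reference_cluster(params.n_cluster_genes, params.seed)
    query_cds, identities = mutate_cluster(
        ref_cds,
        params.cluster_identity_target,
        params.invert_cluster,
        params.n_indels,
        params.seed,
    )

    spectra, component_of, isomer_pairs, hub_id, hub_neighbors = _build_spectra(params)
    network = build_network(spectra)
    node_ids = sorted(network.nodes)
    if len(node_ids) != params.n_network_nodes or network.n_components != params.n_components:
        raise RuntimeError(
            "generator internal error: realized network does not match the "
            "planted topology"
        )
    (
        tier1,
        tier2,
        tier3,
        tier_assignment,
        keys,
        n_unannotated,
    ) = _build_annotations(params, node_ids, hub_id, hub_neighbors)

    annotated = sorted(tier_assignment)
    class_counts = params.resolved_class_counts(len(annotated))
    class_of: dict[int, str] = {}
    cursor = 0
    for label, count in class_counts:
        for fid in annotated[cursor : cursor + count]:
            class_of[fid] = label
        cursor += count

    files = ScenarioFiles(
        out_dir=out,
        genome_gff3=out / "genome.gff3",
        genome_fasta=out / "genome.fna",
        protein_fasta=out / "proteins.faa",
        region_table=out / "regions.tsv",
        ref_cluster=out / "ref_cluster.gbk",
        query_cluster=out / "query_cluster.gbk",
        spectra_mgf=out / "spectra.mgf",
        quant_table=out / "quant.tsv",
        edge_table=out / "edges.tsv",
        tier1_table=out / "tier1_spectral_library.tsv",
        tier2_table=out / "tier2_network_propagation.tsv",
        tier3_table=out / "tier3_in_silico.tsv",
        taxonomy_table=out / "taxonomy.tsv",
        pathway_db=out / "pathways.json",
        predicted_compounds=out / "predicted_compounds.tsv",
        scaffold_flags=out / "scaffold_flags.tsv",
        ground_truth=out / "ground_truth.json",
    )

    # --- genome + regions
    write_gff3(genome, files.genome_gff3)
    with open(files.genome_fasta, "w") as fh:
        for contig_id, seq in contig_seqs.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(files.protein_fasta, "w") as fh:
        for rec in genome.cds:
            fh.write(f">{rec.locus_tag} {rec.product}\n{rec.protein_seq}\n")
    write_region_table(regions, files.region_table)

    # --- cluster pair
    write_cluster_genbank(ref_cds, files.ref_cluster)
    write_cluster_genbank(query_cds, files.query_cluster)

    # --- network
    write_mgf(spectra, files.spectra_mgf)
    import pandas as pd

    pd.DataFrame(
        [
            {"feature_id": s.feature_id, "mz": round(s.precursor_mz, 6),
             "rt": round(s.rt, 4)}
            for s in spectra
        ]
    ).to_csv(files.quant_table, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "node_a": e.node_a,
                "node_b": e.node_b,
                "cosine": round(e.cosine, 6),
                "mass_diff": round(e.mass_diff, 6),
            }
            for e in network.edges
        ]
    ).to_csv(files.edge_table, sep="\t", index=False)

    # --- annotations
    def dump(records, path):
        pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "name": r.name,
                    "structure_key": r.structure_key,
                    "tier": r.tier,
                    "score": r.score,
                    "mz_error_ppm": "" if r.mz_error_ppm is None else r.mz_error_ppm,
                }
                for r in records
            ]
        ).to_csv(path, sep="\t", index=False)

    dump(tier1, files.tier1_table)
    dump(tier2, files.tier2_table)
    dump(tier3, files.tier3_table)

    pd.DataFrame(
        [
            {
                "structure_key": keys[fid],
                "kingdom": "Organic compounds",
                "superclass": CLASS_TO_SUPERCLASS.get(class_of[fid], "Organic compounds"),
                "class": class_of[fid],
            }
            for fid in annotated
        ]
    ).to_csv(files.taxonomy_table, sep="\t", index=False)

    # --- pathway database: the hub metabolite anchors the planted pathway
    pathway_id = "KO00404"
    db = PathwayDb(
        compound_to_pathways={
            keys[hub_id]: [pathway_id],
            "decoy compound": ["KO99999"],
        },
        pathway_to_enzymes={
            pathway_id: enzymes,
            "KO99999": [
                PathwayEnzyme(ec=f"4.2.1.{i}", cog=None, name=f"decoy enzyme {i}")
                for i in (1, 2, 3)
            ],
        },
    )
    db.to_json(files.pathway_db)

    pd.DataFrame(
        [
            {"name": name, "chem_class": cls, "source_region": region}
            for name, cls, region in PREDICTED_COMPOUNDS
        ]
    ).to_csv(files.predicted_compounds, sep="\t", index=False)

    # --- scaffold flags: the first hub_scaffold_sharers neighbors share the
    # hub compound's scaffold
    sharers = set(hub_neighbors[: params.hub_scaffold_sharers])
    pd.DataFrame(
        [
            {"structure_key": keys[fid], "shares_scaffold": fid in sharers}
            for fid in hub_neighbors
        ]
    ).to_csv(files.scaffold_flags, sep="\t", index=False)

    truth = GroundTruth(
        pathway_id=pathway_id,
        pathway_cds=pathway_cds,
        in_region_cds=in_region_cds,
        target_region_id=target_region_id,
        expected_matched_by=expected_matched_by,
        cluster_identities=identities,
        cluster_orientation="inverted" if params.invert_cluster else "colinear",
        tier_assignment=tier_assignment,
        tier_counts=params.tier_counts,
        n_unannotated=n_unannotated,
        class_counts={label: c for label, c in class_counts},
        isomer_pairs=isomer_pairs,
        hub_id=hub_id,
        hub_neighbors=list(hub_neighbors),
        hub_scaffold_sharers=params.hub_scaffold_sharers,
        pathway_metabolite_node=hub_id,
        pathway_metabolite_name="brevianamide F",
        n_network_nodes=params.n_network_nodes,
        n_components=params.n_components,
        predicted_compound_names=[name for name, _, _ in PREDICTED_COMPOUNDS],
    )
    truth.to_json(files.ground_truth)
    return files, truth
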