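"""Molecular network construction and tiered metabolite annotation.

MS/MS features become nodes of a molecular network whose edges connect
spectrally similar features (modified cosine, i.e. cosine similarity that
also pairs fragment peaks shifted by the precursor mass difference).  Node
annotations arrive from three sources applied sequentially: spectral-library
matches first, network-propagated candidates second, single-spectrum in
silico candidates third — a later tier only annotates nodes the earlier
tiers left empty.  Annotated nodes are summarized by chemical-taxonomy level
(kingdom / superclass / class), and candidate isomer pairs are flagged as
network neighbors sharing a precursor m/z but eluting at very different
retention times.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as pymgf

logger = logging.getLogger(__name__)

TIER_NAMES = {1: "spectral_library", 2: "network_propagation", 3: "in_silico"}

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass
class Spectrum:
    """An MS/MS feature: precursor m/z, retention time, fragment peak list."""

    feature_id: int
    precursor_mz: float
    rt: float
    peaks: np.ndarray  # shape (n, 2): m/z, intensity; sorted by m/z

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.precursor_mz <= 0:
            raise ValueError(f"feature {self.feature_id}: precursor_mz <= 0")
        if np.any(self.peaks[:, 1] < 0):
            raise ValueError(f"feature {self.feature_id}: negative intensity")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class NetworkEdge:
    node_a: int
    node_b: int
    cosine: float
    mass_diff: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("self-loop edge")
        if not 0 <= self.cosine <= 1:
            raise ValueError(f"cosine {self.cosine} outside [0, 1]")


@dataclass
class MolecularNetwork:
    """Connected MS/MS features: nodes carry (m/z, rt), edges carry cosine."""

    nodes: dict[int, tuple[float, float]]  # feature_id -> (mz, rt)
    edges: list[NetworkEdge]
    component_index: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.component_index:
            self.component_index = _components(self.nodes, self.edges)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.node_a, e.node_b, {"cosine": e.cosine, "mass_diff": e.mass_diff})
            for e in self.edges
        )
        return g

    def neighbors(self, feature_id: int) -> list[int]:
        if feature_id not in self.nodes:
            raise KeyError(f"feature {feature_id} not in network")
        out = set()
        for e in self.edges:
            if e.node_a == feature_id:
                out.add(e.node_b)
            elif e.node_b == feature_id:
                out.add(e.node_a)
        return sorted(out)

    @property
    def n_components(self) -> int:
        return len(set(self.component_index.values()))


def _components(nodes, edges) -> dict[int, int]:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((e.node_a, e.node_b) for e in edges)
    index = {}
    for i, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for node in comp:
            index[node] = i
    return index


@dataclass
class AnnotationRecord:
    """A candidate structure for one network node from one annotation tier."""

    feature_id: int
    name: str
    structure_key: Optional[str] = None
    tier: int = 1
    score: float = 0.0
    mz_error_ppm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tier not in TIER_NAMES:
            raise ValueError(f"tier must be 1, 2 or 3, got {self.tier}")
        if self.structure_key is not None:
            self.structure_key = normalize_structure_key(self.structure_key)


def normalize_structure_key(key: str) -> str:
    """Uppercase InChIKey when key-shaped (27 chars, two dashes), else raw."""
    key = key.strip()
    if _INCHIKEY_RE.match(key.upper()):
        return key.upper()
    return key


# ---------------------------------------------------------------------------
# Spectral I/O


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    with pymgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            fid = int(params.get("scans", params.get("feature_id", 0)))
            pep = params["pepmass"]
            mz = pep[0] if isinstance(pep, (tuple, list)) else float(pep)
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(Spectrum(fid, float(mz), rt, peaks))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = [
        {
            "m/z array": s.peaks[:, 0],
            "intensity array": s.peaks[:, 1],
            "params": {
                "title": f"feature_{s.feature_id}",
                "scans": s.feature_id,
                "pepmass": s.precursor_mz,
                "rtinseconds": round(s.rt * 60.0, 3),
                "charge": "1+",
            },
        }
        for s in spectra
    ]
    pymgf.write(entries, str(path), file_mode="w")


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Feature table with columns feature_id, mz, rt (MZmine dialect accepted)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    renames = {
        "row ID": "feature_id",
        "row m/z": "mz",
        "row retention time": "rt",
    }
    df = df.rename(columns=renames)
    missing = {"feature_id", "mz", "rt"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: quant table missing columns {sorted(missing)}")
    df["feature_id"] = df["feature_id"].astype(int)
    return df


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Edge list; GNPS-style CLUSTERID1/CLUSTERID2/Cosine/DeltaMZ accepted."""
    df = pd.read_csv(path, sep="\t")
    renames = {
        "CLUSTERID1": "node_a",
        "CLUSTERID2": "node_b",
        "Cosine": "cosine",
        "DeltaMZ": "mass_diff",
    }
    df = df.rename(columns=renames)
    missing = {"node_a", "node_b", "cosine"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: edge table missing columns {sorted(missing)}")
    if "mass_diff" not in df.columns:
        df["mass_diff"] = 0.0
    return df


def network_from_tables(
    quant: pd.DataFrame, edges: pd.DataFrame
) -> MolecularNetwork:
    """Assemble a network from a feature table and a precomputed edge list.

    Only features appearing in at least one edge become nodes.
    """
    meta = {
        int(r.feature_id): (float(r.mz), float(r.rt))
        for r in quant.itertuples(index=False)
    }
    edge_objs = []
    connected: set[int] = set()
    for r in edges.itertuples(index=False):
        a, b = int(r.node_a), int(r.node_b)
        if a not in meta or b not in meta:
            logger.warning("edge (%d, %d) references unknown feature; dropped", a, b)
            continue
        edge_objs.append(NetworkEdge(a, b, float(r.cosine), float(r.mass_diff)))
        connected.update((a, b))
    nodes = {fid: meta[fid] for fid in sorted(connected)}
    return MolecularNetwork(nodes=nodes, edges=edge_objs)


# ---------------------------------------------------------------------------
# Modified cosine


def modified_cosine(
    s1: Spectrum, s2: Spectrum, frag_tol: float = 0.02
) -> tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Intensities are square-root weighted.  A peak pair is a candidate when
    the fragment m/z values agree within ``frag_tol`` directly, or after
    shifting one spectrum by the precursor mass difference.  Candidate pairs
    are accepted greedily by descending weight product, each peak used at
    most once; the score is the accepted product sum over the norm product.
    """
    if s1.n_peaks == 0 or s2.n_peaks == 0:
        raise ValueError("modified_cosine requires non-empty peak lists")
    w1 = np.sqrt(s1.peaks[:, 1])
    w2 = np.sqrt(s2.peaks[:, 1])
    norm = float(np.linalg.norm(w1) * np.linalg.norm(w2))
    if norm == 0:
        return 0.0, 0
    shift = s1.precursor_mz - s2.precursor_mz
    mz1 = s1.peaks[:, 0]
    mz2 = s2.peaks[:, 0]
    candidates = []
    for i in range(len(mz1)):
        for j in range(len(mz2)):
            d = mz1[i] - mz2[j]
            if abs(d) <= frag_tol or abs(d - shift) <= frag_tol:
                candidates.append((float(w1[i] * w2[j]), i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    total = 0.0
    n_matched = 0
    for product, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        total += product
        n_matched += 1
    return min(total / norm, 1.0), n_matched


def build_network(
    spectra: Sequence[Spectrum],
    cosine_min: float = 0.7,
    min_matched: int = 6,
    top_k: int = 10,
    frag_tol: float = 0.02,
) -> MolecularNetwork:
    """All-pairs modified-cosine network with the usual FBMN-style filters.

    An edge survives when cosine >= ``cosine_min``, at least ``min_matched``
    peak pairs matched, and the edge ranks within the strongest ``top_k``
    edges of both endpoints.  Features left without any edge are excluded
    (the network counts only nodes with at least one connection).
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    raw: list[NetworkEdge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            s1, s2 = spectra[i], spectra[j]
            cosine, n_matched = modified_cosine(s1, s2, frag_tol)
            if cosine >= cosine_min and n_matched >= min_matched:
                raw.append(
                    NetworkEdge(
                        s1.feature_id,
                        s2.feature_id,
                        cosine,
                        s1.precursor_mz - s2.precursor_mz,
                    )
                )
    per_node: dict[int, list[NetworkEdge]] = {}
    for e in raw:
        per_node.setdefault(e.node_a, []).append(e)
        per_node.setdefault(e.node_b, []).append(e)
    top: dict[int, set[tuple[int, int]]] = {}
    for node, node_edges in per_node.items():
        node_edges.sort(key=lambda e: -e.cosine)
        top[node] = {(e.node_a, e.node_b) for e in node_edges[:top_k]}
    kept = [
        e
        for e in raw
        if (e.node_a, e.node_b) in top[e.node_a]
        and (e.node_a, e.node_b) in top[e.node_b]
    ]
    connected = {n for e in kept for n in (e.node_a, e.node_b)}
    nodes = {
        s.feature_id: (s.precursor_mz, s.rt)
        for s in spectra
        if s.feature_id in connected
    }
    return MolecularNetwork(nodes=nodes, edges=kept)


# ---------------------------------------------------------------------------
# Sequential annotation


@dataclass
class MergedAnnotations:
    """One winning annotation per node after sequential tier precedence."""

    table: pd.DataFrame  # feature_id, name, structure_key, tier, score, mz_error_ppm
    tier_counts: dict[int, int]
    n_unannotated: int

    def annotation_for(self, feature_id: int) -> Optional[AnnotationRecord]:
        rows = self.table[self.table.feature_id == feature_id]
        if rows.empty:
            return None
        r = rows.iloc[0]
        return AnnotationRecord(
            feature_id=int(r.feature_id),
            name=r["name"],
            structure_key=None if pd.isna(r.structure_key) else r.structure_key,
            tier=int(r.tier),
            score=float(r.score),
            mz_error_ppm=None if pd.isna(r.mz_error_ppm) else float(r.mz_error_ppm),
        )


def merge_annotations(
    network: MolecularNetwork,
    tier1: Sequence[AnnotationRecord],
    tier2: Sequence[AnnotationRecord] = (),
    tier3: Sequence[AnnotationRecord] = (),
) -> MergedAnnotations:
    """Assign each node its annotation, tiers applied sequentially.

    Spectral-library matches first; network-propagated candidates only fill
    nodes still unannotated; in-silico candidates fill the remainder.  Within
    a tier the highest score wins, ties broken by lexicographic name.
    Records referencing nodes outside the network are logged and dropped.
    """
    assigned: dict[int, AnnotationRecord] = {}
    for tier_records in (tier1, tier2, tier3):
        stage: dict[int, AnnotationRecord] = {}
        for rec in tier_records:
            if rec.feature_id not in network.nodes:
                logger.warning(
                    "annotation for unknown node %d dropped", rec.feature_id
                )
                continue
            if rec.feature_id in assigned:
                continue
            cur = stage.get(rec.feature_id)
            if (
                cur is None
                or rec.score > cur.score
                or (rec.score == cur.score and rec.name < cur.name)
            ):
                stage[rec.feature_id] = rec
        assigned.update(stage)
    rows = [
        {
            "feature_id": fid,
            "name": rec.name,
            "structure_key": rec.structure_key,
            "tier": rec.tier,
            "score": rec.score,
            "mz_error_ppm": rec.mz_error_ppm,
        }
        for fid, rec in sorted(assigned.items())
    ]
    table = pd.DataFrame(
        rows,
        columns=["feature_id", "name", "structure_key", "tier", "score", "mz_error_ppm"],
    )
    tier_counts = {t: int((table.tier == t).sum()) if len(table) else 0 for t in (1, 2, 3)}
    return MergedAnnotations(
        table=table,
        tier_counts=tier_counts,
        n_unannotated=len(network.nodes) - len(table),
    )


# ---------------------------------------------------------------------------
# Chemical taxonomy


@dataclass
class ChemTaxonomy:
    """Structure key -> (kingdom, superclass, class) lookup; missing -> None."""

    table: dict[str, tuple[str, str, str]]

    LEVELS = ("kingdom", "superclass", "class")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemTaxonomy":
        df = pd.read_csv(path, sep="\t").fillna("None")
        required = {"structure_key", "kingdom", "superclass", "class"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: taxonomy missing columns {sorted(missing)}")
        table = {}
        for row in df.to_dict("records"):
            table[normalize_structure_key(str(row["structure_key"]))] = (
                str(row["kingdom"]),
                str(row["superclass"]),
                str(row["class"]),
            )
        return cls(table=table)

    def lookup(self, structure_key: Optional[str], level: str) -> str:
        if level not in self.LEVELS:
            raise ValueError(f"level must be one of {self.LEVELS}")
        if structure_key is None:
            return "None"
        row = self.table.get(normalize_structure_key(structure_key))
        if row is None:
            return "None"
        return row[self.LEVELS.index(level)]


def composition_summary(
    merged: MergedAnnotations, taxonomy: ChemTaxonomy, level: str = "superclass"
) -> list[tuple[str, int, float]]:
    """Counts and percentages of annotated nodes per taxonomy label.

    Percentages are over annotated nodes, rounded to one decimal, sorted
    descending (ties alphabetically).  Keys absent from the taxonomy are
    pooled under "None".
    """
    if merged.table.empty:
        raise ValueError("no annotated nodes to summarize")
    labels = [
        taxonomy.lookup(None if pd.isna(k) else k, level)
        for k in merged.table.structure_key
    ]
    counts = pd.Series(labels).value_counts()
    n = int(counts.sum())
    out = [
        (str(label), int(c), round(100.0 * c / n, 1))
        for label, c in counts.items()
    ]
    out.sort(key=lambda t: (-t[2], t[0]))
    return out


def load_paper_superclass_composition() -> list[tuple[str, float]]:
    """The packaged BRA006 superclass composition of the annotated metabolome.

    Returns (superclass label, percent of annotated compounds) pairs;
    unclassifiable compounds appear under the label "None".
    """
    from importlib import resources

    ref = resources.files("recip.data").joinpath("bra006_superclass_composition.tsv")
    df = pd.read_csv(ref.open("r"), sep="\t", keep_default_na=False)
    return [(str(r.superclass), float(r.pct)) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Isomer candidates


def find_isomer_candidates(
    network: MolecularNetwork,
    ppm_tol: float = 20.0,
    rt_min_diff: float = 1.0,
    require_adjacent: bool = True,
) -> list[tuple[int, int]]:
    """Node pairs with matching precursor m/z but well-separated elution.

    A pair qualifies when |dmz| / mean(mz) <= ppm_tol * 1e-6, |drt| >=
    ``rt_min_diff`` minutes, and (by default) the nodes share an edge —
    putative isomers sit next to each other in the network because their
    fragmentation is similar.
    """
    if require_adjacent:
        pairs = [(e.node_a, e.node_b) for e in network.edges]
    else:
        ids = sorted(network.nodes)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    out = []
    for a, b in pairs:
        mza, rta = network.nodes[a]
        mzb, rtb = network.nodes[b]
        mean_mz = 0.5 * (mza + mzb)
        if abs(mza - mzb) / mean_mz <= ppm_tol * 1e-6 and abs(rta - rtb) >= rt_min_diff:
            out.append((min(a, b), max(a, b)))
    return sorted(set(out))
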