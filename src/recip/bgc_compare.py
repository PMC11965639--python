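"""Protein-level comparison of a predicted BGC against a reference cluster.

A query cluster's coding sequences are aligned pairwise (Smith–Waterman local
alignment, BLOSUM62 with affine gaps) against a reference cluster's, each
query keeps its single best-scoring hit, weak hits are filtered at a percent
identity threshold, and the retained matches yield a cluster-level similarity
(fraction of reference genes hit) and an orientation call.  A complete
inversion of the cluster — reference gene order reversed in the query — shows
up as a Kendall rank correlation of −1 between query and reference gene
ordinals.

Best-hit selection ranks by raw alignment score.  This replaces the e-value
ranking of a database search: with a single reference cluster there is no
database-size statistic to correct for, and for a fixed scoring system the
highest-scoring pair is the lowest-e-value pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import kendalltau

from .genome_model import CdsRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring: substitution matrix and affine gap penalties.

    Gap of length k costs ``gap_open + k * gap_extend`` (BLASTp convention).
    ``score_floor`` suppresses hits whose alignment score falls below it,
    avoiding spurious short-segment matches between unrelated proteins.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    score_floor: float = 40.0


@dataclass
class ProteinHit:
    query_id: str
    ref_id: str
    identity_pct: float
    aln_len: int
    score: float
    query_index: int = -1
    ref_index: int = -1

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


@dataclass
class ClusterComparison:
    hits: list[ProteinHit]
    cluster_similarity_pct: int
    orientation: str
    rank_corr: float
    unmatched_ref: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def align_protein_pair(
    a: str,
    b: str,
    scoring: ScoringParams = ScoringParams(),
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Optional[ProteinHit]:
    """Local-align two protein sequences; identity is matches over columns.

    Among co-optimal alignments the traceback of the lexicographically
    ordered pair is used, so score, identity and length are symmetric in the
    argument order.  Returns a :class:`ProteinHit` with empty ids (callers
    fill in locus tags), or ``None`` when no local alignment scores above
    zero (completely dissimilar sequences).
    """
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name} has non-amino-acid symbols {bad}")
    if aligner is None:
        aligner = _make_aligner(scoring)
    a, b = a.upper(), b.upper()
    alignments = aligner.align(*((a, b) if a <= b else (b, a)))
    if alignments.score <= 0:
        return None
    best = alignments[0]
    counts = best.counts()
    aln_len = best.length
    identity = 100.0 * counts.identities / aln_len if aln_len else 0.0
    return ProteinHit(
        query_id="",
        ref_id="",
        identity_pct=identity,
        aln_len=aln_len,
        score=float(best.score),
    )


def best_hits(
    query_cds: Sequence[CdsRecord],
    ref_cds: Sequence[CdsRecord],
    scoring: ScoringParams = ScoringParams(),
) -> list[ProteinHit]:
    """One best hit per query CDS, ranked by alignment score.

    Hits scoring below ``scoring.score_floor`` are suppressed.  Ties are
    broken by higher identity, then by lexicographically smaller reference
    locus tag.  CDS with empty protein sequence are skipped with a warning.
    """
    aligner = _make_aligner(scoring)
    refs = [(i, r) for i, r in enumerate(ref_cds) if r.protein_seq]
    hits: list[ProteinHit] = []
    n_skipped = 0
    for qi, q in enumerate(query_cds):
        if not q.protein_seq:
            n_skipped += 1
            continue
        best: Optional[ProteinHit] = None
        for ri, r in refs:
            hit = align_protein_pair(q.protein_seq, r.protein_seq, scoring, aligner)
            if hit is None or hit.score < scoring.score_floor:
                continue
            hit.query_id = q.locus_tag
            hit.ref_id = r.locus_tag
            hit.query_index = qi
            hit.ref_index = ri
            if best is None or _beats(hit, best):
                best = hit
        if best is not None:
            hits.append(best)
    if n_skipped:
        logger.warning("%d query CDS without protein sequence skipped", n_skipped)
    return hits


def _beats(hit: ProteinHit, best: ProteinHit) -> bool:
    a = (hit.score, hit.identity_pct)
    b = (best.score, best.identity_pct)
    return a > b or (a == b and hit.ref_id < best.ref_id)


def filter_hits(
    hits: Iterable[ProteinHit], min_identity: float = 70.0
) -> list[ProteinHit]:
    """Keep hits with identity strictly greater than ``min_identity``."""
    return [h for h in hits if h.identity_pct > min_identity]


def cluster_similarity(
    hits: Iterable[ProteinHit],
    ref_cds: Sequence[CdsRecord],
    min_identity: float = 70.0,
) -> int:
    """Percent of reference genes with a retained hit, rounded to integer."""
    if not ref_cds:
        raise ValueError("reference cluster has no CDS")
    kept = filter_hits(hits, min_identity)
    matched_refs = {h.ref_id for h in kept}
    return round(100.0 * len(matched_refs) / len(ref_cds))


def orientation_analysis(hits: Sequence[ProteinHit]) -> tuple[str, float]:
    """Classify gene-order conservation from matched ordinal positions.

    Kendall's tau between query and reference ordinals over matched pairs:
    colinear (tau >= 0.5), inverted (tau <= -0.5), else rearranged.  Fewer
    than three matched pairs is reported as rearranged with tau 0.
    """
    pairs = [(h.query_index, h.ref_index) for h in hits]
    if len(pairs) < 3:
        return "rearranged", 0.0
    qi, ri = zip(*pairs)
    tau = kendalltau(qi, ri).statistic
    if tau != tau:  # constant ranks give NaN
        return "rearranged", 0.0
    if tau >= 0.5:
        return "colinear", float(tau)
    if tau <= -0.5:
        return "inverted", float(tau)
    return "rearranged", float(tau)


def compare_clusters(
    query_cds: Sequence[CdsRecord],
    ref_cds: Sequence[CdsRecord],
    min_identity: float = 70.0,
    scoring: ScoringParams = ScoringParams(),
) -> ClusterComparison:
    """Full comparison: best hits, identity filter, similarity, orientation."""
    hits = best_hits(query_cds, ref_cds, scoring)
    kept = filter_hits(hits, min_identity)
    matched_refs = {h.ref_id for h in kept}
    orientation, tau = orientation_analysis(kept)
    return ClusterComparison(
        hits=kept,
        cluster_similarity_pct=cluster_similarity(hits, ref_cds, min_identity),
        orientation=orientation,
        rank_corr=tau,
        unmatched_ref=[r.locus_tag for r in ref_cds if r.locus_tag not in matched_refs],
    )


def hits_to_tsv(hits: Iterable[ProteinHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "ref_id": h.ref_id,
                "identity_pct": round(h.identity_pct, 2),
                "aln_len": h.aln_len,
                "score": h.score,
                "query_index": h.query_index,
                "ref_index": h.ref_index,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)
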