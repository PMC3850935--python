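"""Duplication-mode classification: tandem, segmental, both, or dispersed.

Tandem clusters are runs of family genes on one chromosome separated by
at most ``max_intervening`` (default 10) non-family genes.  Segmental
block pairs are detected by counting "anchors": flanking protein-coding
genes within a window (default +/-100 kb of the gene midpoint) whose
best non-self protein match lies within the window of the candidate
paralog.  A family gene in neither structure is classed dispersed
(consistent with a retrotransposition origin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices


# ---------------------------------------------------------------------------
# gene records
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One protein-coding gene with its position and sequences.

    ``ordinal`` is the 0-based rank of the gene among all protein-coding
    genes on its chromosome, ordered by start coordinate; coordinates
    are 1-based inclusive base pairs.
    """
    id: str
    chromosome: str
    ordinal: int
    start: int
    end: int
    strand: str = "+"
    cds: str = ""
    protein: str = ""
    exon_count: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.id}: start > end")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]
    max_gap_observed: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs >= 2 members")


@dataclass
class AnchorBlockPair:
    focal: str
    paralog: str
    anchors: list[tuple[str, str]]
    window_kb: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# alignment scoring (shared with the similarity prescreen)
# ---------------------------------------------------------------------------

_BLAST_LAMBDA = 0.267   # gapped BLOSUM62 Karlin-Altschul parameters
_BLAST_K = 0.041


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_bit_score(seq1: str, seq2: str,
                    aligner: Optional[PairwiseAligner] = None) -> float:
    """Smith-Waterman bit score (BLOSUM62, gap open 11 / extend 1)."""
    import math
    aligner = aligner or _local_aligner()
    raw = aligner.score(_sanitize(seq1), _sanitize(seq2))
    return (_BLAST_LAMBDA * raw - math.log(_BLAST_K)) / math.log(2.0)


def _sanitize(seq: str) -> str:
    allowed = set("ACDEFGHIKLMNPQRSTVWYBZX")
    return "".join(c if c in allowed else "X" for c in seq.upper())


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------

def find_tandem(genes: Sequence[GeneModel], family_ids,
                max_intervening: int = 10) -> list[TandemCluster]:
    """Maximal runs of family genes with <= max_intervening genes between.

    Every family gene lands in at most one cluster; singletons are not
    reported.  Family ids absent from ``genes`` raise ``ValueError``.
    """
    by_id = {g.id: g for g in genes}
    family_ids = list(family_ids)
    missing = [f for f in family_ids if f not in by_id]
    if missing:
        raise ValueError(f"family ids not in gene list: {missing}")
    clusters: list[TandemCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for f in family_ids:
        by_chrom.setdefault(by_id[f].chromosome, []).append(by_id[f])
    for chrom, members in sorted(by_chrom.items()):
        members.sort(key=lambda g: g.ordinal)
        run, max_gap = [members[0]], 0
        for prev, cur in zip(members, members[1:]):
            gap = cur.ordinal - prev.ordinal - 1
            if gap <= max_intervening:
                run.append(cur)
                max_gap = max(max_gap, gap)
            else:
                if len(run) >= 2:
                    clusters.append(TandemCluster(chrom, [g.id for g in run],
                                                  max_gap))
                run, max_gap = [cur], 0
        if len(run) >= 2:
            clusters.append(TandemCluster(chrom, [g.id for g in run], max_gap))
    return clusters


# ---------------------------------------------------------------------------
# best non-self protein matches
# ---------------------------------------------------------------------------

def best_nonself_matches(proteins: dict[str, str],
                         bits_cutoff: float = 50.0) -> dict[str, str]:
    """Directional best non-self match per protein under local-alignment bits.

    Genes whose best score falls below ``bits_cutoff`` are omitted from
    the returned map.  Ties break toward the lexicographically smaller
    partner id, keeping the map deterministic.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    ids = sorted(proteins)
    aligner = _local_aligner()
    best: dict[str, tuple[float, str]] = {}
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1:]:
            bits = local_bit_score(proteins[a], proteins[b], aligner)
            for x, y in ((a, b), (b, a)):
                cur = best.get(x)
                if cur is None or bits > cur[0] + 1e-9:
                    best[x] = (bits, y)
    return {g: m for g, (score, m) in best.items() if score >= bits_cutoff}


# ---------------------------------------------------------------------------
# segmental blocks
# ---------------------------------------------------------------------------

def _window_ids(genes_by_chrom, gene: GeneModel, window_bp: float,
                exclude=()) -> set[str]:
    out = set()
    for other in genes_by_chrom[gene.chromosome]:
        if other.id in exclude:
            continue
        if abs(other.midpoint - gene.midpoint) <= window_bp:
            out.add(other.id)
    return out


def find_segmental(focal: GeneModel, candidate: GeneModel,
                   genes: Sequence[GeneModel], best_match: dict[str, str],
                   window_kb: float = 100.0,
                   min_anchors: int = 3) -> Optional[AnchorBlockPair]:
    """Test one (focal, paralog) pair for a shared duplicated block.

    An anchor is a gene within ``window_kb`` of the focal gene midpoint
    whose best non-self match lies within the window of the candidate.
    Returns the pair when at least ``min_anchors`` anchors exist.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    window_bp = window_kb * 1000.0
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    exclude = {focal.id, candidate.id}
    near_focal = _window_ids(by_chrom, focal, window_bp, exclude)
    near_cand = _window_ids(by_chrom, candidate, window_bp, exclude)
    anchors = [(g, best_match[g]) for g in sorted(near_focal)
               if best_match.get(g) in near_cand]
    if len(anchors) < min_anchors:
        return None
    return AnchorBlockPair(focal.id, candidate.id, anchors, window_kb)


def segmental_blocks(genes: Sequence[GeneModel], family_ids,
                     best_match: Optional[dict[str, str]] = None,
                     window_kb: float = 100.0, min_anchors: int = 3,
                     bits_cutoff: float = 50.0) -> list[AnchorBlockPair]:
    """All family-gene block pairs with enough anchors (each pair once)."""
    by_id = {g.id: g for g in genes}
    family_ids = [f for f in family_ids if f in by_id]
    if best_match is None:
        best_match = best_nonself_matches({g.id: g.protein for g in genes},
                                          bits_cutoff=bits_cutoff)
    blocks = []
    for i, a in enumerate(sorted(family_ids)):
        for b in sorted(family_ids)[i + 1:]:
            pair = find_segmental(by_id[a], by_id[b], genes, best_match,
                                  window_kb, min_anchors)
            if pair is not None:
                blocks.append(pair)
    return blocks


# ---------------------------------------------------------------------------
# final classification
# ---------------------------------------------------------------------------

def classify_origin(gene_id: str, clusters: Sequence[TandemCluster],
                    blocks: Sequence[AnchorBlockPair]) -> str:
    """tandem / segmental / both / dispersed for one family gene."""
    in_tandem = any(gene_id in c.members for c in clusters)
    in_block = any(gene_id in (b.focal, b.paralog) for b in blocks)
    if in_tandem and in_block:
        return "both"
    if in_tandem:
        return "tandem"
    if in_block:
        return "segmental"
    return "dispersed"
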