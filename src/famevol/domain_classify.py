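"""WRKY domain detection and group I / II(a-e) / III classification.

A WRKY domain is recognized by its conserved heptapeptide (WRKYGQK by
default) followed, within a bounded gap, by a zinc-finger motif of one
of two spacings: C2H2 (C-X4/5-C-X22/23-H-X-H) or C2HC
(C-X7-C-X23-H-X-C).  Group assignment follows the classical scheme —
two domains: group I; one domain with a C2H2 finger: group II; one
domain with a C2HC finger: group III — and group II proteins are
placed into subgroups IIa-IIe by nearest labeled reference domain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from ._io import read_fasta
from .duplication_map import local_bit_score, _local_aligner
from .trees import Tree

SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe")


# ---------------------------------------------------------------------------
# patterns and hits
# ---------------------------------------------------------------------------

@dataclass
class DomainPattern:
    """Sequence signature of a WRKY domain.

    ``heptapeptides`` is the accepted literal set; the canonical
    WRKYGQK alone by default (variants such as WRKYGKK may be added).
    Finger spacings are inclusive residue-count ranges between the
    zinc-coordinating positions; ``max_gap`` bounds the residues
    between the heptapeptide end and the first finger cysteine.
    """
    heptapeptides: frozenset = frozenset({"WRKYGQK"})
    c2h2_x1: tuple[int, int] = (4, 5)
    c2h2_x2: tuple[int, int] = (22, 23)
    c2hc_x1: tuple[int, int] = (7, 7)
    c2hc_x2: tuple[int, int] = (23, 23)
    max_gap: int = 30

    def __post_init__(self):
        for lo, hi in (self.c2h2_x1, self.c2h2_x2,
                       self.c2hc_x1, self.c2hc_x2):
            if hi < lo:
                raise ValueError("empty spacing range")
        if any(len(h) != 7 for h in self.heptapeptides):
            raise ValueError("heptapeptide literals must have length 7")


@dataclass
class DomainHit:
    protein_id: str
    heptapeptide_start: int       # 0-based
    finger_type: str              # C2H2 | C2HC
    finger_start: int
    finger_end: int               # exclusive

    @property
    def span(self) -> tuple[int, int]:
        return (self.heptapeptide_start, self.finger_end)


@dataclass
class FamilyAssignment:
    protein_id: str
    n_domains: int
    group: str                    # I | II | III | unassigned
    subgroup: str = "none"
    domain_labels: tuple = ()     # ('N', 'C') for group I
    flagged: bool = False
    hits: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# similarity prescreen
# ---------------------------------------------------------------------------

def prescreen_similarity(query: str, references: Sequence[str],
                         bits_cutoff: float = 50.0) -> tuple[bool, float]:
    """Local-alignment screen standing in for a BLASTP E-value filter.

    Scores the query against every reference with Smith-Waterman
    (BLOSUM62, gap open 11 / extend 1) and converts the best raw score
    to bits; passes iff the best bit score reaches ``bits_cutoff``.
    """
    references = list(references)
    if not query or not references:
        raise ValueError("query and reference set must be non-empty")
    aligner = _local_aligner()
    best = max(local_bit_score(query, ref, aligner) for ref in references)
    return best >= bits_cutoff, best


# ---------------------------------------------------------------------------
# domain scanning
# ---------------------------------------------------------------------------

def _finger_candidates(seq: str, pattern: DomainPattern):
    """All (start, end, type) finger matches, leftmost/shortest per start."""
    out = {}
    specs = [("C2H2", pattern.c2h2_x1, pattern.c2h2_x2, "H"),
             ("C2HC", pattern.c2hc_x1, pattern.c2hc_x2, "C")]
    for ftype, (a1, b1), (a2, b2), last in specs:
        regex = re.compile(
            rf"(?=(C.{{{a1},{b1}}}?C.{{{a2},{b2}}}?H.{last}))")
        for m in regex.finditer(seq):
            start, end = m.start(1), m.end(1)
            key = (start, ftype)
            if key not in out or end < out[key][1]:
                out[key] = (start, end, ftype)
    return sorted(out.values())


def scan_wrky_domains(protein: str, protein_id: str = "query",
                      pattern: Optional[DomainPattern] = None
                      ) -> list[DomainHit]:
    """Detect WRKY domains: heptapeptide plus downstream zinc finger.

    Each heptapeptide occurrence (left to right) is paired with the
    nearest unused downstream finger whose first cysteine starts within
    ``pattern.max_gap`` residues of the heptapeptide end; at equal
    distance C2H2 wins.  ``X`` residues match only gap positions, never
    the conserved letters.  Returns hits sorted by position.
    """
    pattern = pattern or DomainPattern()
    seq = protein.upper()
    hept_starts = sorted(
        m.start() for h in pattern.heptapeptides
        for m in re.finditer(rf"(?={re.escape(h)})", seq))
    fingers = _finger_candidates(seq, pattern)
    used = [False] * len(fingers)
    hits = []
    for hs in hept_starts:
        hept_end = hs + 7
        best_k = None
        for k, (fs, fe, ftype) in enumerate(fingers):
            if used[k] or fs <= hs or fs < hept_end \
                    or fs - hept_end > pattern.max_gap:
                continue
            if best_k is None or fs < fingers[best_k][0] or (
                    fs == fingers[best_k][0] and ftype == "C2H2"
                    and fingers[best_k][2] != "C2H2"):
                best_k = k
        if best_k is not None:
            used[best_k] = True
            fs, fe, ftype = fingers[best_k]
            hits.append(DomainHit(protein_id, hs, ftype, fs, fe))
    return sorted(hits, key=lambda h: h.heptapeptide_start)


# ---------------------------------------------------------------------------
# group classification
# ---------------------------------------------------------------------------

def classify_group(hits: Sequence[DomainHit],
                   protein_id: Optional[str] = None) -> FamilyAssignment:
    """Assign a family group from the detected domains of one protein.

    Two domains -> group I (upstream labeled N, downstream C); one
    C2HC domain -> group III; one C2H2 domain -> group II; none ->
    unassigned.  Mixed two-domain proteins keep group I (domain count
    dominates) but are flagged; >2 domains are likewise group I and
    flagged, with the two strongest-positioned (first) domains labeled.
    """
    hits = sorted(hits, key=lambda h: h.heptapeptide_start)
    pid = protein_id or (hits[0].protein_id if hits else "query")
    n = len(hits)
    if n == 0:
        return FamilyAssignment(pid, 0, "unassigned")
    if n == 1:
        hit = hits[0]
        group = "III" if hit.finger_type == "C2HC" else "II"
        return FamilyAssignment(pid, 1, group, hits=list(hits))
    mixed = len({h.finger_type for h in hits}) > 1
    return FamilyAssignment(pid, n, "I", domain_labels=("N", "C"),
                            flagged=mixed or n > 2, hits=list(hits))


# ---------------------------------------------------------------------------
# subgroup assignment by nearest labeled reference
# ---------------------------------------------------------------------------

def _norm_distance(a: str, b: str, aligner: PairwiseAligner) -> float:
    """1 - identity over aligned columns of a global alignment."""
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return 1.0 - matches / max(len(s1), 1)


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def assign_subgroup(assignment: FamilyAssignment, domain_seq: str,
                    references: Sequence[tuple[str, str]]) -> str:
    """Nearest-reference subgroup for a group II domain sequence.

    ``references`` is a list of (subgroup label, domain sequence); all
    five subgroups must be represented.  Distance is one minus global
    alignment identity; ties break to the alphabetically smallest
    subgroup label.
    """
    if assignment.group != "II":
        raise ValueError("subgroups are defined for group II only")
    present = {label for label, _ in references}
    missing = [s for s in SUBGROUPS if s not in present]
    if missing:
        raise ValueError(f"reference set lacks subgroups: {missing}")
    aligner = _global_aligner()
    best_label, best_d = None, None
    for label, ref_seq in sorted(references):
        d = _norm_distance(domain_seq.upper(), ref_seq.upper(), aligner)
        if best_d is None or d < best_d - 1e-12:
            best_label, best_d = label, d
    assignment.subgroup = best_label
    return best_label


def load_reference_domains() -> list[tuple[str, str]]:
    """The synthetic labeled reference domain fixture shipped in-package."""
    pkg = resources.files("famevol") / "data"
    seqs = read_fasta((pkg / "reference_domains_synthetic.fasta").read_text())
    labels = {}
    for line in (pkg / "reference_domains_synthetic.tsv").read_text() \
            .strip().splitlines()[1:]:
        name, label = line.split("\t")
        labels[name] = label
    return [(labels[name], seq) for name, seq in seqs.items()]


# ---------------------------------------------------------------------------
# neighbor-joining convenience builder
# ---------------------------------------------------------------------------

def build_nj_tree(aligned_seqs: dict[str, str]) -> Tree:
    """Neighbor-joining tree on p-distances of an aligned sequence set."""
    import numpy as np
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = list(aligned_seqs)
    if len(names) < 3:
        raise ValueError("need at least three sequences")
    lengths = {len(s) for s in aligned_seqs.values()}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal aligned length")
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aligned_seqs[names[i]], aligned_seqs[names[j]]
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            diff = sum(x != y for x, y in pairs)
            dm[i, j] = dm[j, i] = diff / max(len(pairs), 1)
    skb = nj(DistanceMatrix(dm, names))
    return Tree.from_newick(str(skb).strip())
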