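"""Ka/Ks estimation and Ks-based molecular-clock dating of duplications.

The estimator is Nei–Gojobori (1986): per-codon synonymous site
fractions averaged over the two sequences, equal-weight averaging over
all substitution pathways for codons differing at 2–3 positions
(pathways through stop codons are excluded), and Jukes–Cantor
correction of the raw proportions.  Block ages follow the standard
clock conversion T = Ks / (2 * lambda) with saturated anchors
(Ks above a cutoff, default 1.0) discarded before averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import log
from typing import Optional, Sequence

import numpy as np

from ._codon import (
    CODON_AA,
    CODON_INDEX,
    N_CODONS,
    SENSE_CODONS,
    synonymous_site_fractions,
)
from .errors import BacktranslationError, SaturationError

#: synonymous substitutions / site / year (soybean and Arabidopsis clocks)
LAMBDA_SOYBEAN = 6.1e-9
LAMBDA_ARABIDOPSIS = 1.5e-8


# ---------------------------------------------------------------------------
# NG86 pathway-count tables
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _pair_count_matrices():
    """(61, 61) expected synonymous / nonsynonymous difference counts.

    Entry [i, j] is the NG86 pathway-averaged number of synonymous
    (resp. nonsynonymous) one-step changes on a path from codon i to
    codon j; paths passing through a stop codon are dropped and the
    remaining paths weighted equally.
    """
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            paths = []
            for order in itertools.permutations(diff):
                cur, s, n, ok = ci, 0, 0, True
                for pos in order:
                    nxt = cur[:pos] + cj[pos] + cur[pos + 1:]
                    if nxt not in CODON_INDEX:
                        ok = False
                        break
                    if CODON_AA[CODON_INDEX[cur]] == CODON_AA[CODON_INDEX[nxt]]:
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                if ok:
                    paths.append((s, n))
            if paths:
                sd[i, j] = sum(p[0] for p in paths) / len(paths)
                nd[i, j] = sum(p[1] for p in paths) / len(paths)
            else:  # no stop-free path; count every change nonsynonymous
                nd[i, j] = len(diff)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a raw proportion of differences."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4; distance undefined")
    if p <= 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsEstimate:
    """NG86 estimate for one aligned CDS pair."""
    ka: float
    ks: float
    n_sites: float    # nonsynonymous sites N
    s_sites: float    # synonymous sites S
    nd: float         # nonsynonymous differences
    sd: float         # synonymous differences
    n_codons: int     # comparable (gap-free) codons

    @property
    def omega(self) -> Optional[float]:
        return None if self.ks == 0 else self.ka / self.ks


def ng86_ka_ks(seq1: str, seq2: str) -> KaKsEstimate:
    """NG86 Ka/Ks for two aligned, in-frame CDS rows.

    Codons containing a gap or any non-ACGT character in either row
    are excluded pairwise.  Raises ``SaturationError`` when either raw
    proportion reaches 3/4 and ``ValueError`` when no codon is
    comparable.
    """
    seq1 = seq1.upper().replace("U", "T")
    seq2 = seq2.upper().replace("U", "T")
    if len(seq1) != len(seq2):
        raise ValueError("aligned rows differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    sd_mat, nd_mat = _pair_count_matrices()
    s_frac = synonymous_site_fractions()
    S = Sd = Nd = 0.0
    n_codons = 0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k:k + 3], seq2[k:k + 3]
        if c1 not in CODON_INDEX or c2 not in CODON_INDEX:
            continue
        i, j = CODON_INDEX[c1], CODON_INDEX[c2]
        S += 0.5 * (s_frac[i] + s_frac[j])
        Sd += sd_mat[i, j]
        Nd += nd_mat[i, j]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons in the pair")
    N = 3.0 * n_codons - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KaKsEstimate(ka=jukes_cantor(pn), ks=jukes_cantor(ps),
                        n_sites=N, s_sites=S, nd=Nd, sd=Sd,
                        n_codons=n_codons)


def expected_ng86_proportions(codon_indices: np.ndarray,
                              P: np.ndarray) -> tuple[float, float]:
    """Expected (ps, pn) when each codon of a fixed sequence is replaced
    by a draw from transition matrix row ``P[codon]``.

    Used to calibrate simulated divergence against the NG86 estimator.
    """
    sd_mat, nd_mat = _pair_count_matrices()
    s_frac = synonymous_site_fractions()
    rows = P[codon_indices]                       # (L, 61)
    S = float((0.5 * (s_frac[codon_indices][:, None] + s_frac[None, :])
               * rows).sum())
    Sd = float((sd_mat[codon_indices] * rows).sum())
    Nd = float((nd_mat[codon_indices] * rows).sum())
    N = 3.0 * len(codon_indices) - S
    return Sd / S, Nd / N


# ---------------------------------------------------------------------------
# protein-guided codon alignment
# ---------------------------------------------------------------------------

def codon_align(protein_alignment, cds_sequences) -> dict[str, str]:
    """Back-translate a gapped protein alignment onto CDS sequences.

    Every amino-acid column expands to one codon column; protein gaps
    become triplet gaps.  Each ungapped CDS must translate exactly to
    its ungapped protein row (trailing stop codons are tolerated and
    trimmed); a mismatch raises ``BacktranslationError`` naming the
    sequence and codon position.
    """
    from Bio.Seq import Seq

    if isinstance(protein_alignment, dict):
        items = list(protein_alignment.items())
    else:
        items = list(protein_alignment)
    out: dict[str, str] = {}
    for name, prot_row in items:
        if name not in cds_sequences:
            raise KeyError(f"no CDS provided for {name!r}")
        cds = cds_sequences[name].upper().replace("U", "T")
        if len(cds) % 3:
            raise BacktranslationError(name, len(cds) // 3,
                                       f"CDS of {name!r} is out of frame")
        codons = [cds[k:k + 3] for k in range(0, len(cds), 3)]
        if codons and str(Seq(codons[-1]).translate()) == "*":
            codons = codons[:-1]
        translated = str(Seq("".join(codons)).translate())
        if "*" in translated:
            raise BacktranslationError(name, translated.index("*"),
                                       f"internal stop codon in {name!r} at "
                                       f"codon {translated.index('*')}")
        ungapped = prot_row.replace("-", "")
        if translated != ungapped:
            pos = next((k for k, (a, b) in
                        enumerate(zip(translated, ungapped)) if a != b),
                       min(len(translated), len(ungapped)))
            raise BacktranslationError(name, pos)
        it = iter(codons)
        out[name] = "".join("---" if aa == "-" else next(it)
                            for aa in prot_row)
    return out


# ---------------------------------------------------------------------------
# block-level summaries and dating
# ---------------------------------------------------------------------------

@dataclass
class ClockConfig:
    """Molecular-clock settings: synonymous rate and saturation cutoff."""
    lambda_rate: float = LAMBDA_SOYBEAN
    saturation_cutoff: float = 1.0

    def __post_init__(self):
        if self.lambda_rate <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class BlockKs:
    mean_ks: Optional[float]
    sd_ks: Optional[float]
    retained: int
    discarded: int

    @property
    def empty(self) -> bool:
        return self.retained == 0


def block_ks(ks_values: Sequence[float],
             config: Optional[ClockConfig] = None) -> BlockKs:
    """Mean/sd of anchor Ks after discarding saturated anchors."""
    config = config or ClockConfig()
    vals = [float(v) for v in ks_values]
    if not vals:
        raise ValueError("at least one anchor Ks is required")
    kept = [v for v in vals if v <= config.saturation_cutoff]
    if not kept:
        return BlockKs(None, None, 0, len(vals))
    sd = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
    return BlockKs(float(np.mean(kept)), sd, len(kept), len(vals) - len(kept))


def date_duplication(mean_ks: float,
                     config: Optional[ClockConfig] = None) -> float:
    """Age of a duplication event in Myr: T = Ks / (2 * lambda)."""
    config = config or ClockConfig()
    if mean_ks < 0:
        raise ValueError("mean Ks must be non-negative")
    return mean_ks / (2.0 * config.lambda_rate) / 1e6


def round_age(age_myr: float) -> int:
    """Round an age to integer Myr, half away from zero (table convention)."""
    return int(np.floor(age_myr + 0.5))


@dataclass
class DuplicationDate:
    block_id: str
    anchor_ks: list
    mean_ks: Optional[float]
    sd_ks: Optional[float]
    age_myr: Optional[float]

    @property
    def age_myr_int(self) -> Optional[int]:
        return None if self.age_myr is None else round_age(self.age_myr)


def date_block(block_id: str, anchor_ks: Sequence[float],
               config: Optional[ClockConfig] = None) -> DuplicationDate:
    """Filter, summarize and date one duplicated block's anchor Ks list."""
    config = config or ClockConfig()
    summary = block_ks(anchor_ks, config)
    age = (None if summary.empty
           else date_duplication(summary.mean_ks, config))
    return DuplicationDate(block_id, list(anchor_ks), summary.mean_ks,
                           summary.sd_ks, age)
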