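"""Codon-level lookup tables for the universal genetic code.

Everything downstream (NG86 counting, GY94 rate matrices, codon
simulation) works on the 61 sense codons of the standard code, indexed
alphabetically (AAA=0 ... TTT=60 minus the three stops).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCS = "ACGT"
_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

#: the 61 sense codons in alphabetical order
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCS, repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

#: amino acid encoded by each sense codon
CODON_AA = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return a != b and (a in _PURINES) == (b in _PURINES)


@lru_cache(maxsize=1)
def neighbor_arrays():
    """Arrays describing all single-nucleotide sense-codon changes.

    Returns (i, j, transition, synonymous): parallel int arrays of codon
    indices plus boolean flags, one entry per ordered neighbor pair.
    """
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for n in NUCS:
                if n == ci[pos]:
                    continue
                cj = ci[:pos] + n + ci[pos + 1:]
                j = CODON_INDEX.get(cj)
                if j is None:  # stop codon
                    continue
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(ci[pos], n))
                syn.append(CODON_AA[i] == CODON_AA[j])
    return (np.array(ii), np.array(jj),
            np.array(ts, dtype=bool), np.array(syn, dtype=bool))


@lru_cache(maxsize=1)
def synonymous_site_fractions() -> np.ndarray:
    """Per-codon count of synonymous sites, NG86 style.

    For each codon position the fraction of the three possible changes
    that are synonymous is summed over positions; changes to stop codons
    count as nonsynonymous opportunities removed from the denominator is
    NOT applied here — the classical convention treats each position as
    contributing ``(# synonymous changes)/3`` sites, with stop-codon
    changes counted as nonsynonymous.
    """
    s = np.zeros(N_CODONS)
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            n_syn = 0
            for n in NUCS:
                if n == ci[pos]:
                    continue
                cj = ci[:pos] + n + ci[pos + 1:]
                if cj in CODON_INDEX and CODON_AA[CODON_INDEX[cj]] == CODON_AA[i]:
                    n_syn += 1
            s[i] += n_syn / 3.0
    return s


def codons_of(cds: str):
    """Split an in-frame CDS into codons, validating frame and alphabet."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[k:k + 3] for k in range(0, len(cds), 3)]


def encode_cds(cds: str) -> np.ndarray:
    """Map an in-frame CDS to sense-codon indices; stops are rejected."""
    out = []
    for k, c in enumerate(codons_of(cds)):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {k}")
        if c not in CODON_INDEX:
            raise ValueError(f"unrecognized codon {c!r} at codon {k}")
        out.append(CODON_INDEX[c])
    return np.array(out, dtype=np.int64)


def decode_cds(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def translate_codon_indices(idx: np.ndarray) -> str:
    return "".join(CODON_AA[i] for i in idx)


def f3x4_frequencies(seqs) -> np.ndarray:
    """F3x4 codon frequencies from observed per-position nucleotide counts.

    ``seqs`` is an iterable of in-frame CDS strings (gaps ignored).
    Stop-codon cells are zeroed and the vector renormalized, following
    the usual empirical-frequency convention.
    """
    counts = np.full((3, 4), 1e-9)
    for s in seqs:
        s = s.upper().replace("U", "T")
        for k in range(0, len(s) - len(s) % 3, 3):
            cod = s[k:k + 3]
            if "-" in cod:
                continue
            for pos, n in enumerate(cod):
                if n in NUCS:
                    counts[pos, NUCS.index(n)] += 1
    counts /= counts.sum(axis=1, keepdims=True)
    freqs = np.array([
        counts[0, NUCS.index(c[0])]
        * counts[1, NUCS.index(c[1])]
        * counts[2, NUCS.index(c[2])]
        for c in SENSE_CODONS
    ])
    return freqs / freqs.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)
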