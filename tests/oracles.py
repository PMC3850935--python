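"""Independent brute-force oracles used to check the main implementations.

Each oracle favours directness over speed: explicit enumeration of
substitution pathways, of internal-node state assignments, of
(heptapeptide, finger) index pairs, and position-by-position IUPAC
matching.  They share no code path with the package implementations
they validate.
"""

from __future__ import annotations

import itertools
from math import log

import numpy as np
from scipy.linalg import expm

from Bio.Data.CodonTable import unambiguous_dna_by_id

_CODE = unambiguous_dna_by_id[1].forward_table
_STOPS = set(unambiguous_dna_by_id[1].stop_codons)
_NUCS = "ACGT"


# ---------------------------------------------------------------------------
# NG86 by direct pathway enumeration
# ---------------------------------------------------------------------------

def _syn_sites_of_codon(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        for n in _NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1:]
            if alt not in _STOPS and _CODE.get(alt) == _CODE[codon]:
                s += 1.0 / 3.0
    return s


def _path_counts(c1: str, c2: str):
    """All stop-free pathway (syn, nonsyn) step counts from c1 to c2."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    results = []
    for order in itertools.permutations(diff):
        cur, s, n = c1, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _CODE[cur] == _CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            results.append((s, n))
    return results, len(diff)


def ng86_brute(seq1: str, seq2: str):
    """Brute-force NG86 (Ka, Ks) on two aligned gap-free-codon CDS rows."""
    S = Sd = Nd = 0.0
    n_codons = 0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k:k + 3], seq2[k:k + 3]
        if any(ch not in _NUCS for ch in c1 + c2) or \
                c1 in _STOPS or c2 in _STOPS:
            continue
        n_codons += 1
        S += 0.5 * (_syn_sites_of_codon(c1) + _syn_sites_of_codon(c2))
        paths, n_diff = _path_counts(c1, c2)
        if paths:
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
        else:
            Nd += n_diff
    N = 3.0 * n_codons - S
    ps, pn = Sd / S, Nd / N
    ks = -0.75 * log(1.0 - 4.0 * ps / 3.0) if ps > 0 else 0.0
    ka = -0.75 * log(1.0 - 4.0 * pn / 3.0) if pn > 0 else 0.0
    return ka, ks


# ---------------------------------------------------------------------------
# exhaustive codon-model likelihood (sum over internal-node states)
# ---------------------------------------------------------------------------

def exhaustive_lnl(alignment: dict[str, str], tree, model: str,
                   params: dict, freqs: np.ndarray) -> float:
    """Log-likelihood by explicit summation over every assignment of
    codon states to internal nodes, holding the full joint tensor in
    memory.  Transition matrices come from ``scipy.linalg.expm`` —
    a different matrix-exponential route than the implementation.
    """
    from famevol._codon import CODON_INDEX, N_CODONS
    from famevol.codeml_lite import codon_rate_matrix, mixture_scale, \
        site_classes

    classes = site_classes(model, params)
    c = mixture_scale(params["kappa"], classes, freqs)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    axis = {id(n): k for k, n in enumerate(internal)}
    n_int = len(internal)
    n_sites = len(next(iter(alignment.values()))) // 3
    obs = {n.label: [CODON_INDEX[alignment[n.label][3 * k:3 * k + 3]]
                     for k in range(n_sites)] for n in nodes if n.is_leaf}

    def shaped(vec_or_mat, axes):
        """Broadcast an array onto the joint internal-state tensor."""
        shape = [1] * n_int
        for ax, size in axes:
            shape[ax] = size
        return vec_or_mat.reshape(shape)

    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for w, w_bg, w_fg in classes:
            P = {}
            for nd in nodes:
                if nd.parent is None:
                    continue
                om = w_fg if nd.foreground else w_bg
                Q = codon_rate_matrix(params["kappa"], om, freqs,
                                      scale=False) / c
                P[id(nd)] = expm(Q * nd.length)
            T = np.ones([N_CODONS] * n_int)
            root_ax = axis[id(tree.root)]
            T = T * shaped(freqs, [(root_ax, N_CODONS)])
            for nd in nodes:
                if nd.parent is None:
                    continue
                pa = axis[id(nd.parent)]
                if nd.is_leaf:
                    T = T * shaped(P[id(nd)][:, obs[nd.label][site]],
                                   [(pa, N_CODONS)])
                else:
                    ca = axis[id(nd)]
                    mat = P[id(nd)]
                    if pa < ca:
                        T = T * shaped(mat, [(pa, N_CODONS),
                                             (ca, N_CODONS)])
                    else:
                        T = T * shaped(mat.T, [(ca, N_CODONS),
                                               (pa, N_CODONS)])
            site_lik += w * float(T.sum())
        total += log(site_lik)
    return total


def random_model_params(model: str, rng: np.random.Generator) -> dict:
    """Random valid parameter draws for oracle comparisons."""
    kappa = float(rng.uniform(0.8, 4.0))
    if model == "M0":
        return {"kappa": kappa, "omega": float(rng.uniform(0.05, 2.0))}
    if model == "M3":
        p = rng.dirichlet([2.0, 2.0, 2.0])
        return {"kappa": kappa, "proportions": p.tolist(),
                "omegas": sorted(rng.uniform(0.02, 3.0, 3).tolist())}
    if model == "M8":
        return {"kappa": kappa, "p0": float(rng.uniform(0.5, 0.95)),
                "p": float(rng.uniform(0.2, 2.0)),
                "q": float(rng.uniform(0.2, 2.0)),
                "omega_s": float(rng.uniform(1.0, 6.0))}
    if model == "bsA":
        return {"kappa": kappa, "p0": float(rng.uniform(0.3, 0.5)),
                "p1": float(rng.uniform(0.2, 0.4)),
                "omega0": float(rng.uniform(0.05, 0.8)),
                "omega2": float(rng.uniform(1.0, 8.0))}
    raise ValueError(model)


# ---------------------------------------------------------------------------
# brute-force WRKY domain scan
# ---------------------------------------------------------------------------

def scan_domains_brute(seq: str, max_gap: int = 30):
    """All (heptapeptide, finger) pairings by explicit index enumeration,
    greedily resolved left-most-first with each finger used once."""
    hepts = [i for i in range(len(seq) - 6) if seq[i:i + 7] == "WRKYGQK"]

    def finger_at(start):
        """Shortest finger match starting exactly at ``start`` per type."""
        found = []
        for ftype, x1s, x2s, last in (("C2H2", (4, 5), (22, 23), "H"),
                                      ("C2HC", (7,), (23,), "C")):
            best = None
            for x1 in x1s:
                for x2 in x2s:
                    end = start + 1 + x1 + 1 + x2 + 1 + 1 + 1
                    if end > len(seq):
                        continue
                    w = seq[start:end]
                    if (w[0] == "C" and w[1 + x1] == "C"
                            and w[2 + x1 + x2] == "H"
                            and w[4 + x1 + x2] == last):
                        if best is None or end < best:
                            best = end
            if best is not None:
                found.append((start, best, ftype))
        return found

    fingers = sorted(f for start in range(len(seq))
                     if seq[start:start + 1] == "C"
                     for f in finger_at(start))
    used = set()
    hits = []
    for h in hepts:
        candidates = [(fs, fe, ft) for (fs, fe, ft) in fingers
                      if (fs, ft) not in used and fs >= h + 7
                      and fs - (h + 7) <= max_gap]
        if not candidates:
            continue
        fs = min(c[0] for c in candidates)
        at_fs = [c for c in candidates if c[0] == fs]
        chosen = next((c for c in at_fs if c[2] == "C2H2"), at_fs[0])
        used.add((chosen[0], chosen[2]))
        hits.append((h, chosen[2], chosen[0], chosen[1]))
    return hits


# ---------------------------------------------------------------------------
# brute-force IUPAC scanning
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def count_iupac_brute(seq: str, pattern: str, both_strands: bool = True):
    """Position-by-position overlapping IUPAC match count (site-merged)."""
    def matches(window: str, pat: str) -> bool:
        return len(window) == len(pat) and all(
            c in _IUPAC[p] for c, p in zip(window, pat))

    # map a degenerate complement set back to an IUPAC letter
    rev = {tuple(sorted(v)): k for k, v in _IUPAC.items()}
    rc_pattern = "".join(rev[tuple(sorted(set(
        _COMP[c] for c in _IUPAC[p])))] for p in reversed(pattern))
    n = 0
    for i in range(len(seq) - len(pattern) + 1):
        win = seq[i:i + len(pattern)]
        hit = matches(win, pattern)
        if both_strands and not hit:
            hit = matches(win, rc_pattern)
        n += hit
    return n


# ---------------------------------------------------------------------------
# brute-force minimum-change (Fitch) counts
# ---------------------------------------------------------------------------

def min_changes_brute(sub, alignment: dict[str, str], site: int) -> int:
    """Minimum substitutions over all internal-state assignments of a
    nested-tuple subtree (leaves are sequence names)."""
    states = sorted({alignment[name][site]
                     for name in _leaves_of(sub)
                     if alignment[name][site] not in "-.Xx?"})
    if not states:
        return 0

    def internals(node):
        if isinstance(node, str):
            return []
        out = [node]
        for child in node:
            out.extend(internals(child))
        return out

    nodes = internals(sub)
    best = None
    for assign in itertools.product(states, repeat=len(nodes)):
        amap = dict(zip(map(id, nodes), assign))

        def cost(node, parent_state):
            if isinstance(node, str):
                aa = alignment[node][site]
                if aa in "-.Xx?":
                    return 0
                return int(aa != parent_state)
            own = amap[id(node)]
            c = int(own != parent_state) if parent_state is not None else 0
            return c + sum(cost(child, own) for child in node)

        total = cost(sub, None)
        if best is None or total < best:
            best = total
    return best


def _leaves_of(sub):
    if isinstance(sub, str):
        return [sub]
    out = []
    for child in sub:
        out.extend(_leaves_of(child))
    return out
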