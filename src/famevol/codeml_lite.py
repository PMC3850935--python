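"""Maximum-likelihood codon substitution models (GY94 family).

Implements the standard site models M0 (one ratio), M3 (discrete),
M7 (beta), M8 (beta & omega) and branch-site model A, with likelihood
ratio tests and naive / Bayes empirical Bayes identification of sites
in the positively selected class.

The rate structure is Goldman–Yang: only single-nucleotide codon
changes have nonzero rate, transitions are scaled by kappa,
nonsynonymous changes by omega, and target-codon frequencies multiply
every rate.  Branch lengths are expected substitutions per codon under
the fitted site-class mixture.  The state space is the 61 sense codons
of the universal code; stop codons are never reachable.

The per-site likelihood is computed by Felsenstein pruning with
per-node rescaling; site-class mixtures combine per-class site
log-likelihoods by logsumexp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc, logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from ._codon import (
    N_CODONS,
    SENSE_CODONS,
    encode_cds,
    f3x4_frequencies,
    neighbor_arrays,
    uniform_frequencies,
)
from .trees import Tree

__all__ = [
    "CodonModelParams", "SiteModelFit", "BranchSiteFit", "LRTResult",
    "SitePosterior", "codon_rate_matrix", "log_likelihood", "fit_model",
    "lrt", "site_posteriors", "OMEGA_MAX",
]

#: upper bound for any estimated omega; boundary hits are flagged
OMEGA_MAX = 999.0

_NESTED_PAIRS = {("M0", "M3"): None, ("M7", "M8"): 2, ("bsA_null", "bsA"): 1}


# ---------------------------------------------------------------------------
# rate matrices
# ---------------------------------------------------------------------------

def codon_rate_matrix(kappa: float, omega: float,
                      freqs: Optional[np.ndarray] = None,
                      scale: bool = True) -> np.ndarray:
    """61x61 GY94 generator for one (kappa, omega) pair.

    Off-diagonal rate i->j is ``freqs[j] * kappa^[transition] *
    omega^[nonsynonymous]`` for single-nucleotide neighbours and zero
    otherwise; rows sum to zero.  With ``scale=True`` the matrix is
    normalized so the expected substitution rate at stationarity is 1.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if freqs is None:
        freqs = uniform_frequencies()
    ii, jj, ts, syn = neighbor_arrays()
    Q = np.zeros((N_CODONS, N_CODONS))
    rate = freqs[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    Q[ii, jj] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -freqs @ np.diag(Q)
        if mu > 0:
            Q /= mu
    return Q


def mixture_scale(kappa: float, classes, freqs: np.ndarray) -> float:
    """Mean substitution rate of the site-class mixture at stationarity.

    Uses the background omega of every class; dividing the unscaled
    generators by this constant makes branch lengths mean expected
    substitutions per codon under the mixture (shared by the simulator
    so simulated and fitted branch lengths live on the same scale).
    """
    ii, jj, ts, syn = neighbor_arrays()
    base = freqs[ii] * freqs[jj] * np.where(ts, kappa, 1.0)
    syn_rate = base[syn].sum()
    nonsyn_rate = base[~syn].sum()
    c = sum(w * (syn_rate + omega_bg * nonsyn_rate)
            for w, omega_bg, _ in classes)
    return max(c, 1e-12)


class _Spectral:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        sqrt_pi = np.sqrt(np.maximum(freqs, 1e-300))
        # A = D^{-1/2} Q D^{1/2} is symmetric for a pi-reversible Q
        A = (Q * sqrt_pi[np.newaxis, :]) / sqrt_pi[:, np.newaxis]
        w, V = np.linalg.eigh((A + A.T) / 2.0)
        self._w = w
        # P(t) = D^{1/2} V exp(wt) V' D^{-1/2}
        self._left = V * sqrt_pi[:, np.newaxis]
        self._right = (V / sqrt_pi[:, np.newaxis]).T

    def probs(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# model specifications: site classes as (weight, omega_background, omega_fg)
# ---------------------------------------------------------------------------

def beta_category_means(p: float, q: float, ncat: int) -> np.ndarray:
    """Means of ``ncat`` equal-probability categories of Beta(p, q)."""
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, ncat + 1), p, q)
    upper = betainc(p + 1.0, q, edges[1:])
    lower = betainc(p + 1.0, q, edges[:-1])
    means = (p / (p + q)) * (upper - lower) * ncat
    return np.clip(means, 1e-8, 1.0)


def site_classes(model: str, params: dict, ncat: int = 10):
    """Expand a model tag + parameter dict into site-class triples."""
    if model == "M0":
        return [(1.0, params["omega"], params["omega"])]
    if model == "M3":
        return [(p, w, w) for p, w in
                zip(params["proportions"], params["omegas"])]
    if model == "M7":
        means = beta_category_means(params["p"], params["q"], ncat)
        return [(1.0 / ncat, w, w) for w in means]
    if model == "M8":
        p0 = params["p0"]
        means = beta_category_means(params["p"], params["q"], ncat)
        cls = [(p0 / ncat, w, w) for w in means]
        cls.append((1.0 - p0, params["omega_s"], params["omega_s"]))
        return cls
    if model in ("bsA", "bsA_null"):
        p0, p1 = params["p0"], params["p1"]
        p2 = max(1.0 - p0 - p1, 0.0)
        tot = max(p0 + p1, 1e-12)
        p2a, p2b = p2 * p0 / tot, p2 * p1 / tot
        w0 = params["omega0"]
        w2 = 1.0 if model == "bsA_null" else params["omega2"]
        return [(p0, w0, w0), (p1, 1.0, 1.0), (p2a, w0, w2), (p2b, 1.0, w2)]
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# alignment handling
# ---------------------------------------------------------------------------

def _aln_to_matrix(alignment) -> tuple[list[str], np.ndarray]:
    """Codon-index matrix (taxa x sites); gap/ambiguous codons become -1."""
    if isinstance(alignment, dict):
        items = list(alignment.items())
    else:
        items = list(alignment)
    names, rows = [], []
    length = None
    for name, seq in items:
        seq = seq.upper().replace("U", "T")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError("alignment rows differ in length")
        if length % 3:
            raise ValueError("alignment length is not a multiple of 3")
        row = np.empty(length // 3, dtype=np.int64)
        for k in range(0, length, 3):
            cod = seq[k:k + 3]
            if "-" in cod or any(c not in "ACGT" for c in cod):
                row[k // 3] = -1
            else:
                row[k // 3] = encode_cds(cod)[0]
        names.append(name)
        rows.append(row)
    return names, np.vstack(rows)


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------

class _Engine:
    """Pruning likelihood for one (alignment, tree, frequency) triple."""

    def __init__(self, alignment, tree: Tree, freqs: Optional[np.ndarray],
                 ncat: int = 10):
        names, mat = _aln_to_matrix(alignment)
        leaf_labels = tree.leaf_labels()
        if set(names) != set(leaf_labels):
            missing = set(leaf_labels) ^ set(names)
            raise ValueError(f"tree/alignment name mismatch: {sorted(missing)}")
        self.tree = tree
        self.row_of = {n: mat[i] for i, n in enumerate(names)}
        self.n_sites = mat.shape[1]
        self.ncat = ncat
        if freqs is None:
            seqs = ("".join(SENSE_CODONS[c] for c in row if c >= 0)
                    for row in mat)
            freqs = f3x4_frequencies(seqs)
        self.freqs = freqs
        self._spec_cache: dict[float, _Spectral] = {}
        self._post = list(tree.postorder())

    def _spectral(self, kappa: float, omega: float, scale_c: float) -> _Spectral:
        key = (round(kappa, 14), round(omega, 14), round(scale_c, 14))
        sp = self._spec_cache.get(key)
        if sp is None:
            Q = codon_rate_matrix(kappa, omega, self.freqs, scale=False)
            sp = _Spectral(Q / scale_c, self.freqs)
            if len(self._spec_cache) > 64:
                self._spec_cache.clear()
            self._spec_cache[key] = sp
        return sp

    def _mixture_scale(self, kappa: float, classes) -> float:
        return mixture_scale(kappa, classes, self.freqs)

    def class_site_loglik(self, kappa: float, omega_bg: float,
                          omega_fg: float, scale_c: float,
                          lengths: Optional[dict] = None) -> np.ndarray:
        """Per-site log-likelihood for one site class."""
        sp_bg = self._spectral(kappa, omega_bg, scale_c)
        sp_fg = self._spectral(kappa, omega_fg, scale_c)
        logscale = np.zeros(self.n_sites)
        partial: dict[int, np.ndarray] = {}
        for node in self._post:
            if node.is_leaf:
                continue
            L = np.ones((N_CODONS, self.n_sites))
            for child in node.children:
                t = child.length if lengths is None else lengths[id(child)]
                P = (sp_fg if child.foreground else sp_bg).probs(t)
                if child.is_leaf:
                    idx = self.row_of[child.label]
                    Lc = P[:, np.where(idx < 0, 0, idx)]
                    if (idx < 0).any():
                        Lc[:, idx < 0] = 1.0
                else:
                    Lc = P @ partial.pop(id(child))
                L *= Lc
            m = L.max(axis=0)
            m[m <= 0] = 1.0
            L /= m
            logscale += np.log(m)
            partial[id(node)] = L
        root = partial[id(self.tree.root)]
        site_lik = self.freqs @ root
        return np.log(np.maximum(site_lik, 1e-300)) + logscale

    def loglik(self, model: str, params: dict,
               lengths: Optional[dict] = None,
               return_site_matrix: bool = False):
        classes = site_classes(model, params, self.ncat)
        weights = np.array([c[0] for c in classes])
        if abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("class proportions must sum to 1")
        kappa = params["kappa"]
        c = self._mixture_scale(kappa, classes)
        per_class = np.empty((len(classes), self.n_sites))
        done: dict[tuple, int] = {}
        for k, (_, w_bg, w_fg) in enumerate(classes):
            key = (round(w_bg, 14), round(w_fg, 14))
            if key in done:
                per_class[k] = per_class[done[key]]
            else:
                per_class[k] = self.class_site_loglik(kappa, w_bg, w_fg, c,
                                                      lengths)
                done[key] = k
        logw = np.log(np.maximum(weights, 1e-300))
        site_ll = logsumexp(per_class + logw[:, np.newaxis], axis=0)
        if return_site_matrix:
            return float(site_ll.sum()), per_class, weights, site_ll
        return float(site_ll.sum())


def log_likelihood(alignment, tree: Tree, model: str, params: dict,
                   freqs: Optional[np.ndarray] = None,
                   ncat: int = 10) -> float:
    """Log-likelihood of a codon alignment under one model.

    ``params`` holds the model's free parameters (see ``site_classes``);
    branch lengths come from the tree.  F3x4 frequencies are estimated
    from the alignment unless ``freqs`` is given.
    """
    return _Engine(alignment, tree, freqs, ncat).loglik(model, params)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class SiteModelFit:
    model: str
    lnL: float
    kappa: float
    params: dict
    converged: bool
    boundary_hit: bool = False
    site_class_posteriors: Optional[np.ndarray] = None  # (classes, sites)
    class_weights: Optional[np.ndarray] = None
    _engine: Optional[_Engine] = field(default=None, repr=False)

    @property
    def positive_class_omega(self) -> Optional[float]:
        if self.model == "M0":
            return self.params["omega"]
        if self.model == "M3":
            return max(self.params["omegas"])
        if self.model == "M8":
            return self.params["omega_s"]
        return None


@dataclass
class BranchSiteFit:
    model: str  # bsA or bsA_null
    lnL: float
    kappa: float
    params: dict
    converged: bool
    foreground: list
    boundary_hit: bool = False
    site_class_posteriors: Optional[np.ndarray] = None
    class_weights: Optional[np.ndarray] = None
    _engine: Optional[_Engine] = field(default=None, repr=False)

    @property
    def proportions(self) -> tuple[float, float, float, float]:
        cls = site_classes(self.model, self.params)
        return tuple(c[0] for c in cls)


@dataclass
class LRTResult:
    lnL_null: float
    lnL_alt: float
    two_delta_lnl: float
    df: int
    pvalue: float


@dataclass
class SitePosterior:
    site: int
    probability: float
    method: str

    @property
    def stars(self) -> str:
        if self.probability > 0.99:
            return "**"
        if self.probability > 0.95:
            return "*"
        return ""


# ---------------------------------------------------------------------------
# parameter transforms for unconstrained optimization
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class _Transform:
    """Map between an unconstrained vector and a model parameter dict."""

    def __init__(self, model: str, k_classes: int = 3):
        self.model = model
        self.k = k_classes

    def names(self):
        m = self.model
        if m == "M0":
            return ["log_kappa", "log_omega"]
        if m == "M3":
            return (["log_kappa"] + [f"z_p{i}" for i in range(self.k - 1)]
                    + [f"log_w{i}" for i in range(self.k)])
        if m == "M7":
            return ["log_kappa", "log_p", "log_q"]
        if m == "M8":
            return ["log_kappa", "z_p0", "log_p", "log_q", "z_ws"]
        if m == "bsA":
            return ["log_kappa", "z_a", "z_b", "z_w0", "z_w2"]
        if m == "bsA_null":
            return ["log_kappa", "z_a", "z_b", "z_w0"]
        raise ValueError(m)

    def bounds(self):
        b = []
        for n in self.names():
            if n == "log_kappa":
                b.append((np.log(0.02), np.log(50.0)))
            elif n.startswith("log_w") or n == "log_omega":
                b.append((np.log(1e-4), np.log(OMEGA_MAX)))
            elif n in ("log_p", "log_q"):
                b.append((np.log(0.005), np.log(100.0)))
            elif n in ("z_ws", "z_w2"):
                b.append((np.log(1e-6), np.log(OMEGA_MAX - 1.0)))
            else:
                b.append((-12.0, 12.0))
        return b

    def to_params(self, x: np.ndarray) -> dict:
        m, x = self.model, np.asarray(x, dtype=float)
        out = {"kappa": float(np.exp(x[0]))}
        if m == "M0":
            out["omega"] = float(np.exp(x[1]))
        elif m == "M3":
            z = np.concatenate([x[1:self.k], [0.0]])
            e = np.exp(z - z.max())
            out["proportions"] = (e / e.sum()).tolist()
            out["omegas"] = np.exp(x[self.k:2 * self.k]).tolist()
        elif m == "M7":
            out["p"], out["q"] = float(np.exp(x[1])), float(np.exp(x[2]))
        elif m == "M8":
            out["p0"] = float(_sigmoid(x[1]))
            out["p"], out["q"] = float(np.exp(x[2])), float(np.exp(x[3]))
            out["omega_s"] = float(1.0 + np.exp(x[4]))
        elif m in ("bsA", "bsA_null"):
            a, bb = _sigmoid(x[1]), _sigmoid(x[2])
            out["p0"], out["p1"] = float(a * bb), float(a * (1.0 - bb))
            out["omega0"] = float(_sigmoid(x[3]))
            if m == "bsA":
                out["omega2"] = float(1.0 + np.exp(x[4]))
        return out

    def initial(self, rng: np.random.Generator, start: int) -> np.ndarray:
        base = {
            "M0": [np.log(2.0), np.log(0.3)],
            "M3": [np.log(2.0)] + [0.0] * (self.k - 1)
                   + list(np.log(np.linspace(0.05, 1.0, self.k))),
            "M7": [np.log(2.0), np.log(0.5), np.log(1.5)],
            "M8": [np.log(2.0), 2.0, np.log(0.5), np.log(1.5), np.log(0.5)],
            "bsA": [np.log(2.0), 2.0, 1.5, 0.0, np.log(1.0)],
            "bsA_null": [np.log(2.0), 2.0, 1.5, 0.0],
        }[self.model]
        x = np.array(base, dtype=float)
        if start > 0:
            x = x + rng.normal(0.0, 0.75, size=x.size)
        lo, hi = zip(*self.bounds())
        return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_model(alignment, tree: Tree, model: str, *,
              freqs: Optional[np.ndarray] = None,
              k_classes: int = 3, ncat: int = 10,
              n_starts: int = 3, seed: int = 0,
              optimize_branch_lengths: bool = False,
              tol: float = 1e-8, maxiter: int = 500):
    """Fit a codon site or branch-site model by bounded quasi-Newton search.

    Branch lengths are taken from the tree by default (they may come
    from a pairwise or NJ estimate); set ``optimize_branch_lengths`` to
    estimate them jointly.  Multi-start initialization is controlled by
    ``n_starts`` and ``seed``; the best of all starts is returned with
    its convergence flag — a non-converged fit is flagged, never
    silently dropped.
    """
    if model in ("bsA", "bsA_null"):
        fg = [n for n in tree.postorder() if n.foreground]
        if not fg:
            raise ValueError("branch-site model requires foreground branches")
    eng = _Engine(alignment, tree, freqs, ncat)
    tf = _Transform(model, k_classes)
    rng = np.random.default_rng(seed)
    bounds = tf.bounds()

    edge_nodes = [n for n in eng._post if n.parent is not None]
    n_bl = len(edge_nodes) if optimize_branch_lengths else 0
    if n_bl:
        bounds = bounds + [(np.log(1e-5), np.log(20.0))] * n_bl

    def unpack(x):
        params = tf.to_params(x[:len(tf.names())])
        lengths = None
        if n_bl:
            bl = np.exp(x[len(tf.names()):])
            lengths = {id(n): bl[i] for i, n in enumerate(edge_nodes)}
        return params, lengths

    def neg_loglik(x):
        params, lengths = unpack(x)
        try:
            return -eng.loglik(model, params, lengths=lengths)
        except (ValueError, FloatingPointError):
            return 1e12

    best = None
    for start in range(max(1, n_starts)):
        x0 = tf.initial(rng, start)
        if n_bl:
            bl0 = np.log(np.clip([n.length for n in edge_nodes], 1e-4, 20.0))
            x0 = np.concatenate([x0, bl0 + (rng.normal(0, 0.3, n_bl)
                                            if start else 0.0)])
        res = minimize(neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": tol,
                                "gtol": 1e-5, "eps": 1e-6})
        if best is None or res.fun < best.fun:
            best = res

    params, lengths = unpack(best.x)
    lnL = -float(best.fun)
    _, per_class, weights, site_ll = eng.loglik(model, params, lengths=lengths,
                                                return_site_matrix=True)
    post = np.exp(per_class + np.log(np.maximum(weights, 1e-300))[:, None]
                  - site_ll[np.newaxis, :])
    boundary = _boundary_hit(model, params)
    common = dict(model=model, lnL=lnL, kappa=params["kappa"], params=params,
                  converged=bool(best.success), boundary_hit=boundary,
                  site_class_posteriors=post, class_weights=weights,
                  _engine=eng)
    if model in ("bsA", "bsA_null"):
        return BranchSiteFit(foreground=tree.foreground_labels(), **common)
    return SiteModelFit(**common)


def _boundary_hit(model: str, params: dict) -> bool:
    vals = []
    if model == "M0":
        vals = [params["omega"]]
    elif model == "M3":
        vals = params["omegas"]
    elif model == "M8":
        vals = [params["omega_s"]]
    elif model == "bsA":
        vals = [params["omega2"]]
    return any(v > 0.995 * OMEGA_MAX for v in vals)


def lrt(fit_null, fit_alt, df: Optional[int] = None) -> LRTResult:
    """Likelihood ratio test between two nested fits.

    Supported pairs: M0 vs M3 (df = 2K-2 for K classes), M7 vs M8
    (df=2), branch-site null vs alternative (df=1, the conservative
    chi2(1) variant of the 50:50 mixture null).  2*dlnL is floored at
    zero to absorb optimizer noise.
    """
    pair = (fit_null.model, fit_alt.model)
    if pair not in _NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    if df is None:
        df = _NESTED_PAIRS[pair]
        if df is None:  # M0 vs M3
            df = 2 * len(fit_alt.params["omegas"]) - 2
    two_delta = max(2.0 * (fit_alt.lnL - fit_null.lnL), 0.0)
    return LRTResult(lnL_null=fit_null.lnL, lnL_alt=fit_alt.lnL,
                     two_delta_lnl=two_delta, df=df,
                     pvalue=float(chi2.sf(two_delta, df)))


# ---------------------------------------------------------------------------
# empirical Bayes site identification
# ---------------------------------------------------------------------------

def _positive_class_indices(model: str, params: dict) -> list[int]:
    cls = site_classes(model, params)
    if model == "M0":
        return [0] if params["omega"] > 1.0 else []
    if model == "M3":
        return [k for k, (_, w, _) in enumerate(cls) if w > 1.0]
    if model == "M8":
        return [len(cls) - 1]
    if model == "bsA":
        return [2, 3]
    return []


def site_posteriors(fit, method: str = "NEB",
                    beb_grid: int = 10) -> list[SitePosterior]:
    """Per-site posterior probability of the positively selected class.

    NEB plugs the MLEs into Bayes' rule.  BEB (M8 and branch-site A
    only) integrates over a uniform grid on the mixture parameters
    (proportion axes and the positive omega), holding the remaining
    MLEs fixed, weighting grid points by their data likelihood.
    """
    model, params = fit.model, fit.params
    pos = _positive_class_indices(model, params)
    if not pos:
        raise ValueError(
            f"model {model} has no positively selected class at the MLE")
    if method == "NEB":
        prob = fit.site_class_posteriors[pos].sum(axis=0)
        return [SitePosterior(i, float(p), "NEB") for i, p in enumerate(prob)]
    if method != "BEB":
        raise ValueError("method must be NEB or BEB")
    if model not in ("M8", "bsA"):
        raise ValueError("BEB is implemented for M8 and branch-site A")
    eng = fit._engine
    grids = []
    if model == "M8":
        for p0 in np.linspace(0.05, 0.99, beb_grid):
            for ws in np.linspace(1.0, max(params["omega_s"] * 2.0, 11.0),
                                  beb_grid):
                g = dict(params)
                g["p0"], g["omega_s"] = float(p0), float(ws)
                grids.append(g)
    else:
        ticks = np.linspace(0.05, 0.95, beb_grid)
        w2s = np.linspace(1.0, max(params["omega2"] * 2.0, 11.0), beb_grid)
        for a in ticks:
            for b in ticks:
                g = dict(params)
                g["p0"], g["p1"] = float(a * b), float(a * (1 - b))
                g["omega2"] = float(w2s[len(grids) % beb_grid])
                grids.append(g)
    log_weights = np.empty(len(grids))
    post_acc = np.zeros(eng.n_sites)
    per_grid_post = []
    for gi, g in enumerate(grids):
        total, per_class, weights, site_ll = eng.loglik(
            model, g, return_site_matrix=True)
        log_weights[gi] = total
        pos_g = _positive_class_indices(model, g) or pos
        p = np.exp(per_class[pos_g]
                   + np.log(np.maximum(weights[pos_g], 1e-300))[:, None]
                   - site_ll[np.newaxis, :]).sum(axis=0)
        per_grid_post.append(p)
    w = np.exp(log_weights - logsumexp(log_weights))
    for gi, p in enumerate(per_grid_post):
        post_acc += w[gi] * p
    return [SitePosterior(i, float(p), "BEB") for i, p in enumerate(post_acc)]
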