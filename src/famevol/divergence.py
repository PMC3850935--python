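"""Type-I and Type-II functional divergence between paralogous clusters.

Type I (shifted evolutionary rate): per-site minimum-change
substitution counts are inferred in each cluster by Fitch parsimony;
a two-state mixture model then says that with probability 1-theta a
site draws one rate from a gamma prior shared by both clusters, and
with probability theta the two clusters draw independent rates.
Counts are Poisson given the rate times a cluster-specific intensity.
theta and the gamma shape alpha are estimated by maximum likelihood
(discretized gamma, 8 equal-probability categories), with a
likelihood-ratio test of theta = 0 on one degree of freedom
(conservative at the boundary).

Type II (radical shift of physicochemical property) uses a
count-category simplification: sites where both clusters are
internally conserved are trinomial over {same residue, conservative
difference, radical difference}; theta-II is the excess mass of the
cluster-fixed radical category over its null expectation.  This is a
deliberate approximation of the full Gu formulation — see the package
methods note.

Per-site posteriors Qk of belonging to the divergent state flag
candidate critical residues at Qk > 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln
from scipy.stats import chi2, gamma as gamma_dist

from .trees import Tree

#: default physicochemical classes (charge / polarity); a substitution
#: across classes is "radical", within a class "conservative"
AA_PROPERTY_CLASSES = {
    "nonpolar": set("AVLIPMFWG"),
    "polar": set("STCYNQ"),
    "positive": set("KRH"),
    "negative": set("DE"),
}


# ---------------------------------------------------------------------------
# per-site substitution counts (Fitch parsimony)
# ---------------------------------------------------------------------------

def site_substitution_counts(alignment: dict[str, str], tree: Tree,
                             cluster_leaves: Sequence[str]) -> np.ndarray:
    """Minimum-change count per alignment column within one subtree.

    The cluster's induced subtree is traversed bottom-up with the
    classical Fitch set rule; gaps are treated as missing (they join
    any state).  Requires at least 3 cluster sequences.
    """
    leaves = list(cluster_leaves)
    if len(leaves) < 3:
        raise ValueError("a cluster needs at least 3 sequences")
    missing = [l for l in leaves if l not in alignment]
    if missing:
        raise ValueError(f"cluster leaves not in alignment: {missing}")
    sub = _induced_subtree(tree, set(leaves))
    n_sites = len(next(iter(alignment.values())))
    counts = np.zeros(n_sites, dtype=int)
    for site in range(n_sites):
        counts[site] = _fitch_count(sub, alignment, site)
    return counts


def _induced_subtree(tree: Tree, keep: set[str]):
    """Nested-tuple topology of the subtree spanning ``keep`` leaves."""
    def prune(node):
        if node.is_leaf:
            return node.label if node.label in keep else None
        kids = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return tuple(kids)

    out = prune(tree.root)
    if out is None or isinstance(out, str):
        raise ValueError("cluster does not span an internal subtree")
    return out


def _fitch_count(sub, alignment, site: int) -> int:
    changes = 0

    def sets(node):
        nonlocal changes
        if isinstance(node, str):
            aa = alignment[node][site]
            return None if aa in "-.Xx?" else frozenset({aa})
        child_sets = [s for s in (sets(c) for c in node) if s is not None]
        if not child_sets:
            return None
        cur = child_sets[0]
        for s in child_sets[1:]:
            inter = cur & s
            if inter:
                cur = inter
            else:
                cur = cur | s
                changes += 1
        return cur

    sets(sub)
    return changes


# ---------------------------------------------------------------------------
# cluster pair container
# ---------------------------------------------------------------------------

@dataclass
class ClusterPair:
    alignment: dict[str, str]
    cluster1: list[str]
    cluster2: list[str]
    counts1: np.ndarray = field(default=None)
    counts2: np.ndarray = field(default=None)

    @classmethod
    def from_tree(cls, alignment: dict[str, str], tree: Tree,
                  cluster1: Sequence[str], cluster2: Sequence[str]):
        c1, c2 = set(cluster1), set(cluster2)
        if c1 & c2:
            raise ValueError("clusters must be disjoint")
        return cls(alignment, sorted(c1), sorted(c2),
                   site_substitution_counts(alignment, tree, cluster1),
                   site_substitution_counts(alignment, tree, cluster2))

    @property
    def n_sites(self) -> int:
        return len(self.counts1)


@dataclass
class ThetaEstimate:
    type: str                  # "I" or "II"
    theta: float
    se: Optional[float]
    lnL_alt: float
    lnL_null: float
    pvalue: float
    alpha: Optional[float] = None     # gamma shape (Type I)
    params: dict = field(default_factory=dict)
    flagged: bool = False

    @property
    def two_delta_lnl(self) -> float:
        return max(2.0 * (self.lnL_alt - self.lnL_null), 0.0)


@dataclass
class SiteQk:
    site: int
    qk: float
    flagged: bool


# ---------------------------------------------------------------------------
# Type I: shared vs independent gamma rates
# ---------------------------------------------------------------------------

def _gamma_category_rates(alpha: float, k: int = 8) -> np.ndarray:
    """Means of k equal-probability categories of Gamma(alpha, mean 1)."""
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), alpha,
                           scale=1.0 / alpha)
    edges[-1] = np.inf
    upper = gammainc(alpha + 1.0, np.where(np.isinf(edges[1:]), 1e12,
                                           edges[1:]) * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    return np.clip((upper - lower) * k, 1e-8, None)


def _log_poisson(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log Poisson pmf table: sites x rate categories."""
    c = counts[:, None]
    return c * np.log(lam[None, :]) - lam[None, :] - gammaln(c + 1.0)


def _theta1_site_loglik(counts1, counts2, theta, alpha, d1, d2, k=8):
    rates = _gamma_category_rates(alpha, k)
    lp1 = _log_poisson(counts1, d1 * rates)   # (S, k)
    lp2 = _log_poisson(counts2, d2 * rates)
    m = np.maximum(lp1.max(axis=1, keepdims=True),
                   lp2.max(axis=1, keepdims=True))
    e1 = np.exp(lp1 - m)
    e2 = np.exp(lp2 - m)
    f_shared = (e1 * e2).mean(axis=1) * np.exp(2 * m[:, 0])
    f_ind = e1.mean(axis=1) * e2.mean(axis=1) * np.exp(2 * m[:, 0])
    f = (1.0 - theta) * f_shared + theta * f_ind
    return np.log(np.maximum(f, 1e-300)), f_shared, f_ind


def estimate_theta1(pair: ClusterPair, n_rate_cats: int = 8,
                    seed: int = 0) -> ThetaEstimate:
    """ML estimate of the Type-I functional-divergence coefficient.

    Fits (theta, alpha, d1, d2) where d_c is the cluster intensity
    (expected substitutions per site at relative rate 1), then tests
    theta = 0 by a one-degree LRT.  Degenerate all-zero counts return
    a flagged theta = 0 estimate.
    """
    x1, x2 = pair.counts1.astype(float), pair.counts2.astype(float)
    if x1.max() == 0 and x2.max() == 0:
        return ThetaEstimate("I", 0.0, None, 0.0, 0.0, 1.0, alpha=None,
                             flagged=True)
    d1_0, d2_0 = max(x1.mean(), 0.05), max(x2.mean(), 0.05)

    def nll(z, fix_theta_zero=False):
        theta = 0.0 if fix_theta_zero else 1.0 / (1.0 + np.exp(-z[0]))
        off = 0 if fix_theta_zero else 1
        alpha = np.exp(z[off])
        d1, d2 = np.exp(z[off + 1]), np.exp(z[off + 2])
        ll, _, _ = _theta1_site_loglik(x1, x2, theta, alpha, d1, d2,
                                       n_rate_cats)
        return -ll.sum()

    bounds_full = [(-9.0, 9.0), (np.log(0.05), np.log(50.0)),
                   (np.log(1e-3), np.log(50.0)), (np.log(1e-3), np.log(50.0))]
    z0 = np.array([-1.0, 0.0, np.log(d1_0), np.log(d2_0)])
    best = None
    rng = np.random.default_rng(seed)
    for start in range(3):
        z = z0 if start == 0 else z0 + rng.normal(0, 1.0, size=4)
        z = np.clip(z, [b[0] for b in bounds_full], [b[1] for b in bounds_full])
        res = minimize(nll, z, method="L-BFGS-B", bounds=bounds_full)
        if best is None or res.fun < best.fun:
            best = res
    res0 = minimize(lambda z: nll(z, True), z0[1:], method="L-BFGS-B",
                    bounds=bounds_full[1:])
    theta = float(1.0 / (1.0 + np.exp(-best.x[0])))
    alpha = float(np.exp(best.x[1]))
    d1, d2 = float(np.exp(best.x[2])), float(np.exp(best.x[3]))
    lnl_alt, lnl_null = -float(best.fun), -float(res0.fun)
    two_delta = max(2.0 * (lnl_alt - lnl_null), 0.0)
    pval = float(chi2.sf(two_delta, 1))
    se = _theta_se(lambda th: -_theta1_site_loglik(
        x1, x2, th, alpha, d1, d2, n_rate_cats)[0].sum(), theta)
    return ThetaEstimate("I", theta, se, lnl_alt, lnl_null, pval,
                         alpha=alpha,
                         params={"d1": d1, "d2": d2,
                                 "converged": bool(best.success)})


def _theta_se(profile_nll, theta: float, h: float = 1e-4) -> Optional[float]:
    """Standard error from the curvature of the profile log-likelihood."""
    t = min(max(theta, 2 * h), 1.0 - 2 * h)
    d2 = (profile_nll(t + h) - 2 * profile_nll(t) + profile_nll(t - h)) / h**2
    if d2 <= 0:
        return None
    return float(1.0 / np.sqrt(d2))


def simulate_site_counts(n_sites: int, theta: float, alpha: float,
                         d1: float, d2: float, seed: int = 0):
    """Draw per-site count pairs from the Type-I generative model."""
    rng = np.random.default_rng(seed)
    divergent = rng.random(n_sites) < theta
    r_shared = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    r1 = np.where(divergent, rng.gamma(alpha, 1.0 / alpha, size=n_sites),
                  r_shared)
    r2 = np.where(divergent, rng.gamma(alpha, 1.0 / alpha, size=n_sites),
                  r_shared)
    return (rng.poisson(d1 * r1), rng.poisson(d2 * r2), divergent)


# ---------------------------------------------------------------------------
# Type II: cluster-fixed radical differences
# ---------------------------------------------------------------------------

def _property_class_of(aa: str, partition) -> Optional[str]:
    for name, members in partition.items():
        if aa in members:
            return name
    return None


def _consensus(column: Sequence[str]) -> Optional[str]:
    """The single residue if the column is internally conserved."""
    residues = {c for c in column if c not in "-.Xx?"}
    return residues.pop() if len(residues) == 1 else None


def type2_site_categories(pair: ClusterPair, partition=None) -> np.ndarray:
    """Per-site category: 0 same, 1 conservative diff, 2 radical diff,
    3 variable-in-either (excluded from the Type-II likelihood)."""
    partition = partition or AA_PROPERTY_CLASSES
    cats = np.full(pair.n_sites, 3, dtype=int)
    for s in range(pair.n_sites):
        col1 = [pair.alignment[l][s] for l in pair.cluster1]
        col2 = [pair.alignment[l][s] for l in pair.cluster2]
        a, b = _consensus(col1), _consensus(col2)
        if a is None or b is None:
            continue
        if a == b:
            cats[s] = 0
        else:
            ca = _property_class_of(a, partition)
            cb = _property_class_of(b, partition)
            cats[s] = 2 if (ca is not None and cb is not None and ca != cb) \
                else 1
    return cats


def _radical_fraction(partition) -> float:
    """P(radical | substitution) for residue pairs drawn uniformly."""
    aas = [a for cls in partition.values() for a in cls]
    if len(partition) <= 1 or len(aas) < 2:
        return 0.0
    n_pairs = n_rad = 0
    for i, a in enumerate(aas):
        for b in aas[i + 1:]:
            n_pairs += 1
            if _property_class_of(a, partition) != \
                    _property_class_of(b, partition):
                n_rad += 1
    return n_rad / n_pairs


def estimate_theta2(pair: ClusterPair, partition=None) -> ThetaEstimate:
    """Type-II coefficient from conserved-site category counts.

    Model (trinomial over conserved-in-both sites): with probability
    theta a site is Type-II divergent and shows a radical fixed
    difference; otherwise it differs with probability delta, and a
    difference is radical with the background probability rho computed
    from the property partition.  LRT against theta = 0 with df = 1.
    """
    partition = partition or AA_PROPERTY_CLASSES
    rho = _radical_fraction(partition)
    cats = type2_site_categories(pair, partition)
    n_s = int((cats == 0).sum())
    n_c = int((cats == 1).sum())
    n_r = int((cats == 2).sum())
    n_tot = n_s + n_c + n_r
    if n_tot == 0 or rho == 0.0:
        return ThetaEstimate("II", 0.0, None, 0.0, 0.0, 1.0,
                             params={"rho": rho}, flagged=True)

    def nll(z):
        theta = 1.0 / (1.0 + np.exp(-z[0]))
        delta = 1.0 / (1.0 + np.exp(-z[1]))
        p_same = (1 - theta) * (1 - delta)
        p_cons = (1 - theta) * delta * (1 - rho)
        p_rad = (1 - theta) * delta * rho + theta
        ll = (n_s * np.log(max(p_same, 1e-300))
              + n_c * np.log(max(p_cons, 1e-300))
              + n_r * np.log(max(p_rad, 1e-300)))
        return -ll

    res = minimize(nll, np.array([-2.0, -2.0]), method="L-BFGS-B",
                   bounds=[(-12.0, 12.0)] * 2)
    theta = float(1.0 / (1.0 + np.exp(-res.x[0])))
    delta_mle = float(1.0 / (1.0 + np.exp(-res.x[1])))
    # null: theta = 0, delta has closed-form MLE
    delta0 = (n_c + n_r) / n_tot
    lnl_null = (n_s * np.log(max(1 - delta0, 1e-300))
                + n_c * np.log(max(delta0 * (1 - rho), 1e-300))
                + n_r * np.log(max(delta0 * rho, 1e-300)))
    lnl_alt = -float(res.fun)
    two_delta = max(2.0 * (lnl_alt - lnl_null), 0.0)
    se = _theta_se(lambda th: -_t2_loglik(n_s, n_c, n_r, th, delta_mle, rho),
                   theta)
    return ThetaEstimate("II", theta, se, lnl_alt, float(lnl_null),
                         float(chi2.sf(two_delta, 1)),
                         params={"delta": delta_mle, "rho": rho,
                                 "n_same": n_s, "n_conservative": n_c,
                                 "n_radical": n_r})


def _t2_loglik(n_s, n_c, n_r, theta, delta, rho):
    p_same = (1 - theta) * (1 - delta)
    p_cons = (1 - theta) * delta * (1 - rho)
    p_rad = (1 - theta) * delta * rho + theta
    return (n_s * np.log(max(p_same, 1e-300))
            + n_c * np.log(max(p_cons, 1e-300))
            + n_r * np.log(max(p_rad, 1e-300)))


# ---------------------------------------------------------------------------
# per-site posteriors
# ---------------------------------------------------------------------------

def site_qk(estimate: ThetaEstimate, pair: ClusterPair,
            cutoff: float = 0.8, partition=None) -> list[SiteQk]:
    """Empirical-Bayes posterior that each site is in the divergent state."""
    theta = estimate.theta
    if estimate.type == "I":
        if theta == 0.0 or estimate.alpha is None:
            return [SiteQk(s, 0.0, False) for s in range(pair.n_sites)]
        _, f_sh, f_ind = _theta1_site_loglik(
            pair.counts1.astype(float), pair.counts2.astype(float),
            theta, estimate.alpha, estimate.params["d1"],
            estimate.params["d2"])
        qk = theta * f_ind / np.maximum(theta * f_ind + (1 - theta) * f_sh,
                                        1e-300)
    else:
        cats = type2_site_categories(pair, partition)
        delta = estimate.params.get("delta", 0.0)
        rho = estimate.params.get("rho", 0.0)
        q_rad = (theta / max(theta + (1 - theta) * delta * rho, 1e-300)
                 if theta > 0 else 0.0)
        qk = np.where(cats == 2, q_rad, 0.0)
    return [SiteQk(s, float(q), bool(q > cutoff)) for s, q in enumerate(qk)]
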