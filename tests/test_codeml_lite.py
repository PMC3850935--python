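"""Codon-model engine: rate matrices, pruning likelihood, fits, LRTs."""

import numpy as np
import pytest

from famevol._codon import N_CODONS, neighbor_arrays, uniform_frequencies
from famevol.codeml_lite import (
    codon_rate_matrix,
    fit_model,
    log_likelihood,
    lrt,
    site_classes,
    site_posteriors,
)
from famevol.synthetic_data import (
    BranchSiteRegime,
    M0Regime,
    SimConfig,
    simulate_codon_alignment,
    simulate_tree,
)
from famevol.trees import Tree
from tests.oracles import exhaustive_lnl, random_model_params as _random_params


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous(self):
        Q = codon_rate_matrix(2.0, 0.0)
        ii, jj, _, syn = neighbor_arrays()
        assert np.all(Q[ii[~syn], jj[~syn]] == 0.0)
        assert Q[ii[syn], jj[syn]].sum() > 0

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            freqs = rng.dirichlet(np.ones(N_CODONS))
            Q = codon_rate_matrix(float(rng.uniform(0.5, 5)),
                                  float(rng.uniform(0, 3)), freqs)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_uniform_neutral_detailed_balance(self):
        Q = codon_rate_matrix(1.0, 1.0)
        assert np.allclose(Q, Q.T)
        pi = uniform_frequencies()
        assert np.allclose(pi @ Q, 0.0, atol=1e-14)

    def test_unit_mean_rate_at_stationarity(self):
        freqs = np.random.default_rng(1).dirichlet(np.ones(N_CODONS))
        Q = codon_rate_matrix(3.0, 0.7, freqs)
        assert -(freqs @ np.diag(Q)) == pytest.approx(1.0)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            codon_rate_matrix(0.0, 1.0)
        with pytest.raises(ValueError):
            codon_rate_matrix(1.0, -0.5)


class TestLikelihood:
    def test_zero_branch_shared_codon(self):
        tree = Tree.from_newick("(t1:0.0,t2:0.0);")
        freqs = uniform_frequencies()
        lnl = log_likelihood({"t1": "ATG", "t2": "ATG"}, tree, "M0",
                             {"kappa": 2.0, "omega": 0.5}, freqs=freqs)
        assert lnl == pytest.approx(np.log(1.0 / 61.0), abs=1e-9)

    def test_zero_branch_conflicting_codons_impossible(self):
        tree = Tree.from_newick("(t1:0.0,t2:0.0);")
        lnl = log_likelihood({"t1": "ATG", "t2": "TTG"}, tree, "M0",
                             {"kappa": 2.0, "omega": 0.5},
                             freqs=uniform_frequencies())
        assert lnl < -30  # numerically floored -inf

    def test_m3_single_class_reduces_to_m0(self):
        tree = simulate_tree(5, "balanced", seed=2)
        sim = simulate_codon_alignment(tree, SimConfig(seed=1, n_codons=40))
        l0 = log_likelihood(sim.sequences, tree, "M0",
                            {"kappa": 2.0, "omega": 0.3}, freqs=sim.freqs)
        l3 = log_likelihood(sim.sequences, tree, "M3",
                            {"kappa": 2.0, "proportions": [1.0],
                             "omegas": [0.3]}, freqs=sim.freqs)
        assert l0 == pytest.approx(l3, abs=1e-10)

    def test_name_mismatch_rejected(self):
        tree = Tree.from_newick("(t1:0.1,t2:0.1);")
        with pytest.raises(ValueError):
            log_likelihood({"t1": "ATG", "x": "ATG"}, tree, "M0",
                           {"kappa": 2.0, "omega": 1.0})

    @pytest.mark.parametrize("model,draw", [
        ("M0", 0), ("M0", 1), ("M3", 2), ("bsA", 3), ("M8", 4),
    ])
    def test_matches_exhaustive_state_summation(self, model, draw):
        """Pruning equals brute-force summation over all internal-node
        codon assignments on small random instances."""
        rng = np.random.default_rng(draw)
        n_taxa = int(rng.integers(3, 5))
        tree = simulate_tree(n_taxa, "balanced", seed=draw)
        if model == "bsA":
            tree.set_foreground(["t1"])
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=draw, n_codons=int(rng.integers(1, 4))))
        params = _random_params(model, rng)
        freqs = sim.freqs
        mine = log_likelihood(sim.sequences, tree, model, params,
                              freqs=freqs)
        oracle = exhaustive_lnl(sim.sequences, tree, model, params, freqs)
        assert mine == pytest.approx(oracle, abs=1e-8)


@pytest.fixture(scope="module")
def m0_sim():
    tree = simulate_tree(8, "birth_death", seed=1)
    sim = simulate_codon_alignment(
        tree, SimConfig(seed=11, n_codons=300, kappa=2.0,
                        omega_regime=M0Regime(0.2)))
    return tree, sim


class TestFitsAndLRT:
    def test_m0_parameter_recovery(self, m0_sim):
        tree, sim = m0_sim
        fit = fit_model(sim.sequences, tree, "M0", freqs=sim.freqs,
                        n_starts=2, seed=0)
        assert 0.1 <= fit.params["omega"] <= 0.3
        assert 1.4 <= fit.kappa <= 2.8

    def test_nesting_m3_at_least_m0(self, m0_sim):
        tree, sim = m0_sim
        f0 = fit_model(sim.sequences, tree, "M0", freqs=sim.freqs,
                       n_starts=1, seed=0)
        f3 = fit_model(sim.sequences, tree, "M3", freqs=sim.freqs,
                       n_starts=1, seed=0)
        assert f3.lnL >= f0.lnL - 1e-6
        r = lrt(f0, f3)
        assert r.df == 4 and r.two_delta_lnl >= 0.0

    def test_lrt_identical_fits(self, m0_sim):
        tree, sim = m0_sim
        f0 = fit_model(sim.sequences, tree, "M0", freqs=sim.freqs,
                       n_starts=1, seed=0)
        r = lrt(f0, _as_model(f0, "M3"), df=4)
        assert r.two_delta_lnl == 0.0 and r.pvalue == pytest.approx(1.0)

    def test_large_2dlnl_is_significant(self):
        """A 2*dlnL of 335.95 on 4 df is overwhelming evidence of
        among-site omega heterogeneity (p << 0.01)."""
        from scipy.stats import chi2
        assert chi2.sf(335.95, 4) < 0.01
        assert chi2.sf(1944.18, 2) < 0.01

    def test_non_nested_pair_rejected(self, m0_sim):
        tree, sim = m0_sim
        f0 = fit_model(sim.sequences, tree, "M0", freqs=sim.freqs,
                       n_starts=1, seed=0)
        with pytest.raises(ValueError):
            lrt(f0, f0)

    def test_branch_site_detects_planted_selection(self):
        tree = simulate_tree(6, "birth_death", seed=3)
        reg = BranchSiteRegime(p0=0.5, p1=0.3, p2a=0.125, p2b=0.075,
                               omega0=0.1, omega2=5.0,
                               foreground=["t1", "t2"])
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=5, n_codons=200, omega_regime=reg))
        alt = fit_model(sim.sequences, tree, "bsA", freqs=sim.freqs,
                        n_starts=1, seed=0)
        null = fit_model(sim.sequences, tree, "bsA_null", freqs=sim.freqs,
                         n_starts=1, seed=0)
        r = lrt(null, alt)
        assert r.df == 1 and r.pvalue < 0.01
        assert alt.params["omega2"] > 1.5

    def test_branch_site_needs_foreground(self):
        tree = simulate_tree(4, "balanced", seed=1)
        sim = simulate_codon_alignment(tree, SimConfig(seed=2, n_codons=30))
        with pytest.raises(ValueError):
            fit_model(sim.sequences, tree, "bsA", n_starts=1)


def _as_model(fit, model):
    import copy
    alt = copy.copy(fit)
    alt.model = model
    return alt


class TestSitePosteriors:
    def test_m7_has_no_positive_class(self):
        tree = simulate_tree(4, "balanced", seed=1)
        sim = simulate_codon_alignment(tree, SimConfig(seed=2, n_codons=30))
        fit = fit_model(sim.sequences, tree, "M7", freqs=sim.freqs,
                        n_starts=1, seed=0)
        with pytest.raises(ValueError):
            site_posteriors(fit, "NEB")

    def test_degenerate_single_class_posterior_one(self):
        tree = simulate_tree(4, "balanced", seed=1)
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=2, n_codons=30,
                            omega_regime=M0Regime(2.0)))
        fit = fit_model(sim.sequences, tree, "M3", freqs=sim.freqs,
                        k_classes=1, n_starts=1, seed=0)
        if fit.params["omegas"][0] > 1.0:
            post = site_posteriors(fit, "NEB")
            assert all(p.probability == pytest.approx(1.0) for p in post)

    def test_selected_sites_rank_above_neutral(self):
        """Planted positively selected sites get higher NEB posteriors
        than background sites under branch-site A."""
        tree = simulate_tree(8, "birth_death", seed=4)
        reg = BranchSiteRegime(p0=0.48, p1=0.32, p2a=0.12, p2b=0.08,
                               omega0=0.1, omega2=5.0, foreground=["t1"])
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=6, n_codons=300, omega_regime=reg))
        fit = fit_model(sim.sequences, tree, "bsA", freqs=sim.freqs,
                        n_starts=1, seed=0)
        post = np.array([p.probability
                         for p in site_posteriors(fit, "NEB")])
        selected = np.isin(sim.site_classes, [2, 3])
        assert post[selected].mean() > post[~selected].mean()

    def test_stars_thresholds(self):
        from famevol.codeml_lite import SitePosterior
        assert SitePosterior(0, 0.996, "NEB").stars == "**"
        assert SitePosterior(0, 0.96, "NEB").stars == "*"
        assert SitePosterior(0, 0.5, "NEB").stars == ""
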