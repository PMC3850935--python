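"""Generators: determinism, planted truth, and regime semantics."""

import numpy as np
import pytest
from Bio.Seq import Seq

from famevol.errors import SaturationError
from famevol.ks_clock import ng86_ka_ks
from famevol.synthetic_data import (
    BranchSiteRegime,
    DiscreteRegime,
    GenomeLayoutSpec,
    M0Regime,
    SegmentalSpec,
    SimConfig,
    TandemSpec,
    evolve_pair_to_ks,
    simulate_codon_alignment,
    simulate_expression,
    simulate_genome_layout,
    simulate_promoters,
    simulate_tree,
)


class TestTrees:
    def test_two_leaf_tree(self):
        tree = simulate_tree(2, "balanced", seed=0)
        assert tree.n_leaves == 2
        assert all(n.length > 0 for n in tree.postorder()
                   if n.parent is not None)

    def test_determinism(self):
        a = simulate_tree(8, "birth_death", seed=1).to_newick()
        b = simulate_tree(8, "birth_death", seed=1).to_newick()
        assert a == b
        c = simulate_tree(8, "birth_death", seed=2).to_newick()
        assert a != c

    def test_caterpillar_depth(self):
        tree = simulate_tree(64, "caterpillar", seed=7)
        internal = sum(1 for n in tree.postorder() if not n.is_leaf)
        assert internal == 63
        # ladder: walking internal children reaches depth 63
        depth, node = 0, tree.root
        while not node.is_leaf:
            depth += 1
            kids = [c for c in node.children if not c.is_leaf]
            node = kids[0] if kids else node.children[0]
        assert depth == 63

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, "balanced", seed=0)

    @pytest.mark.parametrize("shape", ["balanced", "caterpillar",
                                       "birth_death"])
    def test_binary_and_serializable(self, shape):
        tree = simulate_tree(6, shape, seed=3)
        from famevol.trees import Tree
        rt = Tree.from_newick(tree.to_newick())
        assert sorted(rt.leaf_labels()) == sorted(tree.leaf_labels())
        for n in tree.postorder():
            assert n.is_leaf or len(n.children) == 2


class TestCodonAlignment:
    def test_omega_zero_freezes_protein(self):
        tree = simulate_tree(5, "balanced", seed=2)
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=3, n_codons=60,
                            omega_regime=M0Regime(0.0)))
        prots = {str(Seq(s).translate()) for s in sim.sequences.values()}
        assert len(prots) == 1

    def test_no_stop_codons_and_length(self):
        tree = simulate_tree(4, "balanced", seed=1)
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=9, n_codons=120,
                            omega_regime=DiscreteRegime(
                                [(0.5, 0.1), (0.5, 1.5)])))
        for s in sim.sequences.values():
            assert len(s) == 360
            assert "*" not in str(Seq(s).translate())

    def test_branch_site_zero_positive_classes(self):
        tree = simulate_tree(4, "balanced", seed=1)
        reg = BranchSiteRegime(p0=0.7, p1=0.3, p2a=0.0, p2b=0.0,
                               omega0=0.1, omega2=5.0, foreground=["t1"])
        sim = simulate_codon_alignment(tree, SimConfig(seed=4, n_codons=200,
                                                       omega_regime=reg))
        assert set(np.unique(sim.site_classes)) <= {0, 1}

    def test_branch_site_requires_foreground(self):
        tree = simulate_tree(4, "balanced", seed=1)
        reg = BranchSiteRegime(p0=0.7, p1=0.3, p2a=0.0, p2b=0.0,
                               omega0=0.1, omega2=5.0, foreground=[])
        with pytest.raises(ValueError):
            simulate_codon_alignment(tree, SimConfig(omega_regime=reg))

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(omega_regime=DiscreteRegime([(0.5, 0.1), (0.4, 1.0)]))

    def test_purifying_regime_pairwise_kaks_below_one(self):
        """M0 at omega 0.2 is purifying: mean pairwise NG86 Ka/Ks < 1."""
        tree = simulate_tree(8, "birth_death", seed=1)
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=11, n_codons=500, kappa=2.0,
                            omega_regime=M0Regime(0.2)))
        names = sorted(sim.sequences)
        ratios = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                try:
                    e = ng86_ka_ks(sim.sequences[a], sim.sequences[b])
                except SaturationError:
                    continue      # synonymous-saturated deep pair
                if e.ks > 0:
                    ratios.append(e.ka / e.ks)
        assert ratios and np.mean(ratios) < 1.0

    def test_determinism(self):
        tree = simulate_tree(4, "balanced", seed=1)
        cfg = SimConfig(seed=5, n_codons=50)
        assert simulate_codon_alignment(tree, cfg).sequences == \
            simulate_codon_alignment(tree, cfg).sequences


class TestEvolvePairToKs:
    def test_zero_target_identity(self):
        cds = "ATGGCTGAA" * 30
        assert evolve_pair_to_ks(cds, 0.0, seed=1) == cds

    def test_calibration_unbiased(self):
        """Mean estimated Ks over replicate copies stays within +/-0.05
        of the 0.3 target for a 300-codon input."""
        cds = "".join(np.random.default_rng(8).choice(
            ["ATG", "GCT", "GAA", "TGC", "CCA", "TTT"], size=300))
        est = [ng86_ka_ks(cds, evolve_pair_to_ks(cds, 0.3, seed=s)).ks
               for s in range(50)]
        assert abs(np.mean(est) - 0.3) < 0.05

    def test_saturating_target_raises(self):
        with pytest.raises(SaturationError):
            evolve_pair_to_ks("ATGGCTGAA" * 30, 5.0, seed=0)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            evolve_pair_to_ks("ATG", -0.1)


class TestGenomeLayout:
    def test_single_tandem_truth(self):
        spec = GenomeLayoutSpec(1, 20, planted_tandem=[TandemSpec(0, 3, 2)])
        sim = simulate_genome_layout(spec, seed=1)
        assert (sim.truth["type"] == "tandem").sum() == 1
        assert len(sim.truth) == 1

    def test_empty_spec(self):
        sim = simulate_genome_layout(GenomeLayoutSpec(1, 5), seed=0)
        assert sim.truth.empty
        assert sim.gff3.startswith("##gff-version 3")
        assert sim.family_ids == []

    def test_capacity_violation(self):
        with pytest.raises(ValueError):
            simulate_genome_layout(
                GenomeLayoutSpec(1, 5,
                                 planted_tandem=[TandemSpec(0, 3, 4)]),
                seed=0)

    def test_collision_rejected(self):
        spec = GenomeLayoutSpec(1, 30,
                                planted_tandem=[TandemSpec(0, 2, 2),
                                                TandemSpec(0, 3, 2)])
        with pytest.raises(ValueError):
            simulate_genome_layout(spec, seed=0)

    def test_coordinates_sorted_nonoverlapping(self, planted_genome):
        by_chrom = {}
        for g in planted_genome.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.ordinal)
            for a, b in zip(genes, genes[1:]):
                assert a.end < b.start

    def test_determinism(self):
        spec = GenomeLayoutSpec(1, 10,
                                planted_segmental=[
                                    SegmentalSpec(0, 1, 0, 6, 2, 0.1)])
        a = simulate_genome_layout(spec, seed=3)
        b = simulate_genome_layout(spec, seed=3)
        assert a.gff3 == b.gff3 and a.cds_fasta == b.cds_fasta


class TestExpression:
    TISSUES = ["root", "stem", "leaf", "flower", "pod", "seed", "nodule"]

    def test_zero_effect_no_planted_peak(self):
        mat, truth = simulate_expression({"g1": "A", "g2": None},
                                         self.TISSUES, 0.0, seed=1)
        assert truth.isna().all()
        assert (mat.to_numpy() >= 0).all()

    def test_strong_effect_recovers_peaks(self):
        labels = {f"g{i}": "A" for i in range(100)}
        mat, truth = simulate_expression(labels, self.TISSUES, 5.0, seed=2)
        recovered = (mat.idxmax(axis=1) == truth).sum()
        assert recovered >= 95

    def test_constant_rows(self):
        mat, _ = simulate_expression({"g1": None}, self.TISSUES, 0.0,
                                     seed=0, noise_sd=0.0)
        row = mat.iloc[0].to_numpy()
        assert np.allclose(row, row[0])

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            simulate_expression({"g1": None}, ["root"], 1.0)


class TestPromoters:
    def test_planted_copies_verbatim(self):
        sim = simulate_promoters(3, 200, [("CACGTG", 2)], seed=1)
        for name, seq in sim.sequences.items():
            for pattern, off in sim.offsets[name]:
                assert seq[off:off + 6] == "CACGTG" or \
                    set("CACGTG") >= set(seq[off:off + 6])
            assert seq.count("CACGTG") >= 2

    def test_pattern_free_background(self):
        sim = simulate_promoters(5, 300, [], seed=2,
                                 background_alphabet="AC")
        for seq in sim.sequences.values():
            assert "G" not in seq and "T" not in seq

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            simulate_promoters(1, 10, [("CACGTG", 3)], seed=0)

    def test_truth_counts(self):
        sim = simulate_promoters(4, 500, [("TTGACC", 3)], seed=3)
        assert (sim.truth_counts["TTGACC"] == 3).all()
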