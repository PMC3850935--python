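"""Domain scanning, group/subgroup assignment, prescreen, NJ builder."""

import numpy as np
import pytest

from famevol.domain_classify import (
    DomainPattern,
    FamilyAssignment,
    assign_subgroup,
    build_nj_tree,
    classify_group,
    load_reference_domains,
    prescreen_similarity,
    scan_wrky_domains,
)
from famevol.synthetic_data import wrky_like_protein
from tests.oracles import scan_domains_brute

PAD = "A" * 10


def c2h2(x1=4, x2=22):
    return "C" + "S" * x1 + "C" + "T" * x2 + "HAH"


def c2hc(x1=7, x2=23):
    return "C" + "S" * x1 + "C" + "T" * x2 + "HAC"


class TestScan:
    def test_exact_c2h2_spacing_single_hit(self):
        seq = PAD + "WRKYGQK" + "G" * 5 + c2h2() + PAD
        hits = scan_wrky_domains(seq)
        assert len(hits) == 1
        assert hits[0].finger_type == "C2H2"
        assert hits[0].heptapeptide_start == 10

    def test_wrong_spacing_no_c2h2(self):
        seq = PAD + "WRKYGQK" + "G" * 5 + "C" + "S" * 6 + "C" + "T" * 22 \
            + "HAH" + PAD
        assert scan_wrky_domains(seq) == []

    def test_wrong_c2h2_but_valid_c2hc_downstream(self):
        seq = PAD + "WRKYGQK" + "G" * 3 + c2hc() + PAD
        hits = scan_wrky_domains(seq)
        assert len(hits) == 1 and hits[0].finger_type == "C2HC"

    def test_two_units_two_hits_increasing(self):
        unit = "WRKYGQK" + "G" * 5 + c2h2()
        hits = scan_wrky_domains(PAD + unit + PAD + unit + PAD)
        assert len(hits) == 2
        assert hits[0].heptapeptide_start < hits[1].heptapeptide_start

    def test_gap_limit_enforced(self):
        seq = PAD + "WRKYGQK" + "G" * 31 + c2h2() + PAD
        assert scan_wrky_domains(seq) == []
        assert len(scan_wrky_domains(
            seq, pattern=DomainPattern(max_gap=40))) == 1

    def test_x_never_matches_conserved_letters(self):
        seq = PAD + "WRKYGQK" + "G" * 5 + "X" + "S" * 4 + "C" + "T" * 22 \
            + "HAH" + PAD
        assert scan_wrky_domains(seq) == []

    def test_variant_heptapeptide_off_by_default(self):
        seq = PAD + "WRKYGKK" + "G" * 5 + c2h2() + PAD
        assert scan_wrky_domains(seq) == []
        pat = DomainPattern(heptapeptides=frozenset({"WRKYGQK", "WRKYGKK"}))
        assert len(scan_wrky_domains(seq, pattern=pat)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_bruteforce_enumeration(self, seed):
        """Random 200-aa sequences seeded with motif fragments: the
        scanner equals exhaustive (heptapeptide, finger) enumeration."""
        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(alphabet, size=200))
        # splice in motif pieces to make hits likely
        for frag in ("WRKYGQK", c2h2(), c2hc(), "WRKYGQK"):
            pos = int(rng.integers(0, 160))
            seq = seq[:pos] + frag + seq[pos + len(frag):]
        hits = scan_wrky_domains(seq)
        brute = scan_domains_brute(seq)
        assert [(h.heptapeptide_start, h.finger_type, h.finger_start,
                 h.finger_end) for h in hits] == brute


class TestClassifyGroup:
    def test_two_c2h2_group_one_with_nc_labels(self):
        unit = "WRKYGQK" + "G" * 5 + c2h2()
        hits = scan_wrky_domains(PAD + unit + PAD + unit, "p")
        asg = classify_group(hits)
        assert asg.group == "I"
        assert asg.domain_labels == ("N", "C")
        assert not asg.flagged

    def test_single_c2hc_group_three(self):
        hits = scan_wrky_domains(PAD + "WRKYGQK" + "G" * 3 + c2hc(), "p")
        assert classify_group(hits).group == "III"

    def test_single_c2h2_group_two(self):
        hits = scan_wrky_domains(PAD + "WRKYGQK" + "G" * 5 + c2h2(), "p")
        assert classify_group(hits).group == "II"

    def test_empty_unassigned(self):
        assert classify_group([], "p").group == "unassigned"

    def test_mixed_two_domain_group_one_flagged(self):
        seq = PAD + "WRKYGQK" + "G" * 5 + c2h2() + PAD \
            + "WRKYGQK" + "G" * 3 + c2hc()
        asg = classify_group(scan_wrky_domains(seq, "p"))
        assert asg.group == "I" and asg.flagged

    def test_partition_of_simulated_family(self, rng):
        """Every simulated family protein lands in exactly one group."""
        for grp in ("I", "II", "III"):
            for _ in range(5):
                asg = classify_group(
                    scan_wrky_domains(wrky_like_protein(rng, grp), "p"))
                assert asg.group == grp


class TestSubgroup:
    def test_identical_reference_zero_distance(self):
        refs = load_reference_domains()
        query = [s for label, s in refs if label == "IIa"][0]
        asg = FamilyAssignment("q", 1, "II")
        assert assign_subgroup(asg, query, refs) == "IIa"

    def test_tie_breaks_to_smallest_label(self):
        refs = [(lab, "WRKYGQK" + "A" * 20) for lab in
                ("IIe", "IId", "IIc", "IIb", "IIa")]
        asg = FamilyAssignment("q", 1, "II")
        assert assign_subgroup(asg, "WRKYGQK" + "A" * 20, refs) == "IIa"

    def test_missing_subgroup_rejected(self):
        refs = [("IIa", "A" * 30), ("IIb", "C" * 30)]
        with pytest.raises(ValueError):
            assign_subgroup(FamilyAssignment("q", 1, "II"), "A" * 30, refs)

    def test_non_group2_rejected(self):
        with pytest.raises(ValueError):
            assign_subgroup(FamilyAssignment("q", 1, "III"), "A",
                            load_reference_domains())

    def test_mutated_queries_return_home(self):
        """Queries derived from IIc references by 10% point mutation are
        assigned IIc in at least 90% of 100 replicates."""
        refs = load_reference_domains()
        iic = [s for label, s in refs if label == "IIc"]
        rng = np.random.default_rng(5)
        alphabet = list("ADEFGIKLMNPQRSTVWY")
        ok = 0
        for rep in range(100):
            base = list(iic[rep % len(iic)])
            n_mut = max(1, len(base) // 10)
            for pos in rng.choice(len(base), size=n_mut, replace=False):
                base[pos] = rng.choice(alphabet)
            asg = FamilyAssignment("q", 1, "II")
            ok += assign_subgroup(asg, "".join(base), refs) == "IIc"
        assert ok >= 90


class TestPrescreen:
    def test_self_match_passes(self):
        ref = wrky_like_protein(np.random.default_rng(1))
        passed, score = prescreen_similarity(ref, [ref])
        assert passed and score > 50

    def test_unrelated_polya_fails(self):
        ref = wrky_like_protein(np.random.default_rng(1))
        passed, _ = prescreen_similarity("A" * 200, [ref])
        assert not passed

    def test_embedded_domain_scores_as_self(self):
        """A reference embedded verbatim in a decoy scores the same as
        the reference against itself (local alignment finds it)."""
        rng = np.random.default_rng(2)
        ref = wrky_like_protein(rng)
        alphabet = list("DEFGIKLMNPQRSTVW")
        decoy = "".join(rng.choice(alphabet, size=250)) + ref + \
            "".join(rng.choice(alphabet, size=250))
        _, self_score = prescreen_similarity(ref, [ref])
        passed, score = prescreen_similarity(decoy, [ref])
        assert passed and score >= self_score - 1e-9

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            prescreen_similarity("AAA", [])


class TestNJ:
    def test_additive_distances_recover_topology(self):
        seqs = {"a": "AAAAAAAA", "b": "AAAAAATT",
                "c": "TTTTTTAA", "d": "TTTTTTTT"}
        tree = build_nj_tree(seqs)
        nwk = tree.to_newick()
        # (a,b) vs (c,d) split present
        leaves = {frozenset(clade) for clade in _splits(tree)}
        assert frozenset({"a", "b"}) in leaves or \
            frozenset({"c", "d"}) in leaves

    def test_identical_sequences_star(self):
        tree = build_nj_tree({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
        assert all(abs(n.length) < 1e-12 for n in tree.postorder()
                   if n.parent is not None)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            build_nj_tree({"a": "AA", "b": "AA"})

    def test_low_divergence_simulation_recovers_tree(self):
        from famevol.synthetic_data import (M0Regime, SimConfig,
                                            simulate_codon_alignment)
        from famevol.trees import Tree
        nwk = ("(((t1:0.06,t2:0.06):0.06,(t3:0.06,t4:0.06):0.06):0.06,"
               "((t5:0.06,t6:0.06):0.06,(t7:0.06,t8:0.06):0.06):0.06);")
        tree = Tree.from_newick(nwk)
        sim = simulate_codon_alignment(
            tree, SimConfig(seed=3, n_codons=400,
                            omega_regime=M0Regime(0.2)))
        est = build_nj_tree(sim.sequences)
        assert _splits(est) == _splits(tree)


def _splits(tree):
    """Unrooted bipartitions (smaller side) as frozensets of leaf names."""
    all_leaves = frozenset(tree.leaf_labels())
    out = set()
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(l.label for l in _subtree_leaves(node))
        other = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def _subtree_leaves(node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out
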