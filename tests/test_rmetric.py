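import numpy as np
import pytest

import caap
from caap.rmetric import (
    BranchPair,
    BranchResolutionError,
    SkipGene,
    expected_E_from_joints,
    pair_convergence_matrix,
    resolve_pair_on_gene_tree,
)
from helpers import enumerate_E_site


@pytest.fixture(scope="module")
def hexa():
    """Six-taxon fixture whose focal branches are the leaves A and C.

    At site 5 the background forces ancestral R at both focal parents while
    A carries D and C carries E: an acidic-shared, different-residue event.
    """
    tree = caap.PhyloTree.from_newick(
        "(((A:0.05,B:0.05)ab:0.05,(C:0.05,D:0.05)cd:0.05)in:0.05,(E:0.05,F:0.05)ef:0.1);"
    )
    rows = {
        "A": "AWLNKD",
        "B": "AWLNKR",
        "C": "AWLNKE",
        "D": "AWLNKR",
        "E": "AWLNKR",
        "F": "AWLNKR",
    }
    aln = caap.ProteinAlignment(
        "hexa", list(rows), np.array([list(s) for s in rows.values()])
    )
    model = caap.build_model("LG", "gene", aln)
    rates = caap.discrete_gamma(2.0, 4)
    asr = caap.marginal_asr(aln, tree, model, rates)
    pair = (tree.find("A"), tree.find("C"))
    return tree, aln, model, rates, asr, pair


class TestBranchPair:
    def test_nested_branches_rejected(self):
        tree = caap.PhyloTree.from_newick("(((A:1,B:1)ab:1,C:1)abc:1,D:1);")
        with pytest.raises(BranchResolutionError):
            BranchPair("ab", "abc").resolve(tree)

    def test_identical_branches_rejected(self):
        tree = caap.PhyloTree.from_newick("((A:1,B:1)ab:1,C:1);")
        with pytest.raises(BranchResolutionError):
            BranchPair("ab", "ab").resolve(tree)

    def test_mrca_spec_resolution(self):
        tree = caap.PhyloTree.from_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        a, b = BranchPair("mrca:A+B", "mrca:D+E").resolve(tree)
        assert sorted(tree.clade_taxa(a)) == ["A", "B"]
        assert sorted(tree.clade_taxa(b)) == ["D", "E"]

    def test_transfer_to_pruned_gene_tree(self):
        sp = caap.PhyloTree.from_newick("(((A:1,B:1)ab:1,C:1):1,(D:1,E:1)de:1);")
        gene = sp.prune_to(["A", "C", "D", "E"])
        pair = BranchPair("ab", "de")
        a, b = resolve_pair_on_gene_tree(pair, sp, gene)
        assert sorted(gene.clade_taxa(a)) == ["A"]
        assert sorted(gene.clade_taxa(b)) == ["D", "E"]

    def test_transfer_missing_clade_skips(self):
        sp = caap.PhyloTree.from_newick("(((A:1,B:1)ab:1,C:1):1,(D:1,E:1)de:1);")
        gene = sp.prune_to(["C", "D", "E"])
        with pytest.raises(SkipGene):
            resolve_pair_on_gene_tree(BranchPair("ab", "de"), sp, gene)


class TestBranchStates:
    def test_terminal_branch_reports_leaf_residue(self, hexa):
        tree, aln, model, rates, asr, pair = hexa
        anc, der, post = caap.branch_states(asr, tree, tree.find("A"), aln)
        assert caap.AMINO_ACIDS[der[5]] == "D"
        assert caap.AMINO_ACIDS[anc[5]] == "R"
        assert post.shape == (6, 20)

    def test_internal_branch_uses_ml_states(self, hexa):
        tree, aln, model, rates, asr, pair = hexa
        ab = tree.find("ab")
        anc, der, _ = caap.branch_states(asr, tree, ab, aln)
        assert (der == asr.ml_states[ab.id]).all()

    def test_root_is_not_a_branch(self, hexa):
        tree, aln, model, rates, asr, pair = hexa
        with pytest.raises(BranchResolutionError):
            caap.branch_states(asr, tree, tree.root, aln)


class TestObservedO:
    def test_acidic_shared_event_counted_under_gs1(self, hexa):
        tree, aln, model, rates, asr, pair = hexa
        gs1 = caap.load_scheme("GS1")
        O, events = caap.observed_O(asr, tree, pair, gs1, aln)
        assert O == 1
        ev = events[0]
        assert ev.site == 6
        assert (ev.anc_a, ev.der_a, ev.anc_b, ev.der_b) == ("R", "D", "R", "E")
        assert ev.event_class is caap.EventClass.EXCLUSIVE_PROPERTY

    def test_same_event_not_counted_under_us(self, hexa):
        tree, aln, model, rates, asr, pair = hexa
        O, _ = caap.observed_O(asr, tree, pair, caap.ungrouped_scheme(), aln)
        assert O == 0

    def test_constant_alignment_has_no_events(self):
        tree = caap.PhyloTree.from_newick("((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1);")
        aln = caap.ProteinAlignment(
            "const", ["A", "B", "C", "D"], np.array([list("AAAA")] * 4)
        )
        model = caap.build_model("LG", "gene", aln)
        asr = caap.marginal_asr(aln, tree, model)
        rates = caap.RateModel(np.inf, 1, (1.0,))
        for scheme in (caap.ungrouped_scheme(), caap.load_scheme("GS1")):
            O, _ = caap.observed_O(asr, tree, (tree.find("A"), tree.find("C")),
                                   scheme, aln)
            assert O == 0


class TestExpectedE:
    def test_zero_branch_length_gives_zero(self, lg, all_schemes):
        rates = caap.discrete_gamma(2.0, 4)
        for scheme in all_schemes:
            e = caap.expected_E_site("A", "R", 0.0, 0.3, rates,
                                     np.full(4, 0.25), lg, scheme)
            assert e == 0.0

    def test_one_class_scheme_gives_zero(self, lg):
        one = caap.GroupingScheme("one", (("all", frozenset(caap.AMINO_ACIDS)),))
        rates = caap.RateModel(np.inf, 1, (1.0,))
        assert caap.expected_E_site("A", "R", 0.1, 0.1, rates, [1.0], lg, one) == 0.0

    def test_point_ancestors_match_enumeration(self, lg):
        gs1 = caap.load_scheme("GS1")
        rates = caap.RateModel(np.inf, 1, (1.0,))
        e = caap.expected_E_site("A", "A", 0.1, 0.1, rates, [1.0], lg, gs1)
        Pa = lg.transition_matrix(0.1)
        qa = np.zeros(20)
        qa[0] = 1.0
        oracle = enumerate_E_site(qa, qa, Pa, Pa, gs1)
        assert e == pytest.approx(oracle, abs=1e-12)

    def test_random_draws_match_enumeration(self, lg, all_schemes):
        rng = np.random.default_rng(11)
        rates = caap.discrete_gamma(2.0, 2)
        for _ in range(25):
            scheme = all_schemes[rng.integers(len(all_schemes))]
            qa = rng.dirichlet(np.ones(20))
            qb = rng.dirichlet(np.ones(20))
            ta, tb = rng.uniform(0.01, 0.8, 2)
            w = rng.dirichlet(np.ones(2))
            e = caap.expected_E_site(qa, qb, ta, tb, rates, w, lg, scheme)
            oracle = sum(
                w[m] * enumerate_E_site(
                    qa, qb,
                    lg.transition_matrix(ta * r), lg.transition_matrix(tb * r),
                    scheme,
                )
                for m, r in enumerate(rates.rates)
            )
            assert e == pytest.approx(oracle, abs=1e-10)

    def test_monotone_in_branch_length(self, lg):
        gs1 = caap.load_scheme("GS1")
        rates = caap.RateModel(np.inf, 1, (1.0,))
        values = [
            caap.expected_E_site("A", "R", t, 0.2, rates, [1.0], lg, gs1)
            for t in np.linspace(0.0, 1.0, 11)
        ]
        assert all(b >= a - 1e-15 for a, b in zip(values, values[1:]))

    def test_gene_E_additive_over_identical_sites(self):
        tree = caap.PhyloTree.from_newick("((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1);")
        n = 7
        aln = caap.ProteinAlignment(
            "rep", ["A", "B", "C", "D"], np.array([["A"] * n, ["R"] * n,
                                                   ["A"] * n, ["K"] * n])
        )
        model = caap.build_model("LG", "gene", aln)
        rates = caap.discrete_gamma(2.0, 4)
        asr = caap.marginal_asr(aln, tree, model, rates)
        pair = (tree.find("ab"), tree.find("cd"))
        for mode in ("joint", "posterior", "conditional"):
            E, e_sites = caap.expected_E_gene(
                asr, tree, pair, model, rates, caap.load_scheme("GS1"),
                mode=mode, aln=aln,
            )
            assert E == pytest.approx(n * e_sites[0], rel=1e-9)

    def test_joint_mode_consistency_with_helper(self, hexa):
        tree, aln, model, rates, asr, pair = hexa
        from caap.model import edge_joint_posteriors

        joints = edge_joint_posteriors(aln, tree, model, rates, list(pair))
        gs1 = caap.load_scheme("GS1")
        e1, _ = caap.expected_E_gene(asr, tree, pair, model, rates, gs1,
                                     mode="joint", aln=aln)
        e2, _ = expected_E_from_joints(joints[pair[0].id], joints[pair[1].id], gs1)
        assert e1 == e2


class TestPoissonTest:
    def test_zero_observed(self):
        assert caap.poisson_test(0, 5.0) == 1.0
        assert caap.poisson_test(0, 0.0) == 1.0

    def test_closed_forms(self):
        assert caap.poisson_test(3, 1.0) == pytest.approx(1 - 2.5 * np.exp(-1), abs=1e-12)
        assert caap.poisson_test(1, 1.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_zero_expectation_with_observation(self):
        assert caap.poisson_test(2, 0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            caap.poisson_test(-1, 1.0)
        with pytest.raises(ValueError):
            caap.poisson_test(1, -0.5)


@pytest.fixture(scope="module")
def batch():
    tree = caap.random_topology(10, seed=21, branch_length=0.1)
    model = caap.build_model("LG")
    alns = [
        caap.simulate_alignment(tree, model, 60, 2.0, seed=500 + i,
                                gene_id=f"g{i:02d}")
        for i in range(6)
    ]
    a, b = caap.choose_calibration_pair(tree, 0)
    pair = BranchPair(a.id, b.id, "BP1")
    return tree, alns, pair


class TestScanGenes:
    def test_result_cardinality(self, batch):
        tree, alns, pair = batch
        schemes = [caap.ungrouped_scheme(), caap.load_scheme("GS1")]
        results, events, sets_ = caap.scan_genes(
            alns, tree, [pair], schemes, alpha=2.0
        )
        assert len(results) == len(alns) * len(schemes)
        assert set(results["status"]) == {"ok"}

    def test_gene_set_membership(self, batch):
        tree, alns, pair = batch
        schemes = [caap.ungrouped_scheme(), caap.load_scheme("GS1")]
        results, _, sets_ = caap.scan_genes(alns, tree, [pair], schemes, alpha=2.0)
        key = ("BP1", "GS1")
        grp = results[results["scheme"] == "GS1"].set_index("gene_id")
        us = results[results["scheme"] == "US"].set_index("gene_id")
        for gene in grp.index:
            assert (gene in sets_[key]["O_gt_0"]) == (grp.loc[gene, "O"] > 0)
            assert (gene in sets_[key]["O_gs_gt_us"]) == (
                grp.loc[gene, "O"] > us.loc[gene, "O"]
            )

    def test_missing_clade_marks_status(self, batch):
        tree, alns, pair = batch
        # drop the taxa under one focal branch from every alignment
        gone = set(tree.clade_taxa(tree.node(pair.branch_a)))
        pruned = [
            aln.subset_taxa([t for t in aln.taxa if t not in gone])
            for aln in alns[:2]
        ]
        results, _, _ = caap.scan_genes(
            pruned, tree, [pair], [caap.ungrouped_scheme()], alpha=2.0
        )
        assert results["status"].str.startswith("skipped").all()

    def test_discarded_gene_logged_not_fatal(self, batch):
        tree, alns, pair = batch
        bad = caap.ProteinAlignment(
            "allgap", alns[0].taxa,
            np.array([["-"] * 5] * len(alns[0].taxa)),
        )
        results, _, _ = caap.scan_genes(
            [bad, alns[0]], tree, [pair], [caap.ungrouped_scheme()], alpha=2.0
        )
        assert set(results[results["gene_id"] == "allgap"]["status"]) == {"discarded"}
        assert set(results[results["gene_id"] == "g00"]["status"]) == {"ok"}
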