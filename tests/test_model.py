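import subprocess

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

import caap
from caap.model import ModelError, RateModel, edge_joint_posteriors


class TestSubstitutionModel:
    def test_rate_matrix_contract(self, lg):
        Q, pi = lg.Q, lg.frequencies
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0, abs=1e-12)
        # detailed balance of Q
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    @pytest.mark.parametrize("name", ["LG", "JTT", "WAG"])
    def test_builtin_matrices_load(self, name):
        m = caap.build_model(name)
        assert m.frequencies.sum() == pytest.approx(1.0)
        assert (m.frequencies > 0).all()

    def test_unknown_matrix(self):
        with pytest.raises(ModelError):
            caap.build_model("DAYHOFF")

    def test_gene_frequencies_match_hand_count(self):
        aln = caap.ProteinAlignment(
            "g", ["a", "b"], np.array([list("AAR"), list("ARR")])
        )
        freqs = caap.gene_frequencies(aln)
        # 3 A, 3 R out of 6 cells; all others floored at 1e-6
        expect_a = 0.5
        assert freqs[caap.AMINO_ACIDS.index("A")] == pytest.approx(expect_a, rel=1e-4)
        assert freqs[caap.AMINO_ACIDS.index("C")] == pytest.approx(1e-6, rel=1e-2)

    def test_all_same_residue_floor(self):
        aln = caap.ProteinAlignment("g", ["a", "b"], np.array([list("AA"), list("AA")]))
        freqs = caap.gene_frequencies(aln)
        assert freqs[0] == pytest.approx(1.0 - 19e-6, rel=1e-5)

    def test_transition_matrix_properties(self, lg):
        P0 = lg.transition_matrix(0.0)
        assert np.abs(P0 - np.eye(20)).max() < 1e-12
        Pinf = lg.transition_matrix(1e4)
        assert np.abs(Pinf - lg.frequencies[None, :]).max() < 1e-6
        P1, P2 = lg.transition_matrix(0.05), lg.transition_matrix(0.07)
        assert np.abs(lg.transition_matrix(0.12) - P1 @ P2).max() < 1e-8

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_detailed_balance_of_P(self, lg, t):
        P = lg.transition_matrix(t)
        pi = lg.frequencies
        flux = pi[:, None] * P
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_negative_time_rejected(self, lg):
        with pytest.raises(ModelError):
            lg.transition_matrix(-0.1)


class TestDiscreteGamma:
    def test_single_category(self):
        assert caap.discrete_gamma(0.7, 1).rates == (1.0,)

    def test_mean_one_and_increasing(self):
        r = caap.discrete_gamma(2.0, 4)
        rates = np.array(r.rates)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(rates) > 0).all()

    def test_matches_quadrature_oracle(self):
        alpha, k = 2.0, 4
        r = caap.discrete_gamma(alpha, k)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
        for i in range(k):
            num, _ = integrate.quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                edges[i],
                edges[i + 1],
            )
            assert r.rates[i] == pytest.approx(num * k, abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ModelError):
            caap.discrete_gamma(-1, 4)
        with pytest.raises(ModelError):
            caap.discrete_gamma(2.0, 0)


def brute_force_quartet(aln, tree, model, rates):
    """Enumerate all internal-state assignments and rate categories."""
    enc = aln.encoded()
    nodes = {n.name: n for n in tree.postorder()}
    pi = model.frequencies

    def P(name, r):
        return model.transition_matrix(nodes[name].length * r)

    site_likes = []
    root_posts = []
    for s in range(aln.n_sites):
        xa, xb, xc, xd = (enc[aln.taxa.index(t), s] for t in ["A", "B", "C", "D"])
        like = 0.0
        post_ab = np.zeros(20)
        for r in rates.rates:
            Pa, Pb, Pc, Pd = P("A", r), P("B", r), P("C", r), P("D", r)
            Pab, Pcd = P("ab", r), P("cd", r)
            for ab in range(20):
                term_ab = Pa[ab, xa] * Pb[ab, xb]
                for cd in range(20):
                    term_cd = Pc[cd, xc] * Pd[cd, xd]
                    for root in range(20):
                        v = (
                            pi[root] * Pab[root, ab] * Pcd[root, cd]
                            * term_ab * term_cd / rates.k
                        )
                        like += v
                        post_ab[ab] += v
        site_likes.append(np.log(like))
        root_posts.append(post_ab / post_ab.sum())
    return np.array(site_likes), np.array(root_posts)


class TestPruningLikelihood:
    def test_single_leaf_tree(self, lg):
        tree = caap.PhyloTree.from_newick("(A:0.3,B:0.4);")
        aln = caap.ProteinAlignment("g", ["A", "B"], np.array([["A"], ["A"]] ))
        # collapse to a 2-leaf tree: the site likelihood is
        # sum_x pi_x P(x->A|0.3) P(x->A|0.4)
        sl, _ = caap.prune_loglik(aln, tree, lg)
        P3, P4 = lg.transition_matrix(0.3), lg.transition_matrix(0.4)
        ia = caap.AMINO_ACIDS.index("A")
        expect = np.log((lg.frequencies * P3[:, ia] * P4[:, ia]).sum())
        assert sl[0] == pytest.approx(expect, abs=1e-12)

    def test_zero_branch_lengths_degenerate(self, lg):
        tree = caap.PhyloTree.from_newick("(A:0.0,B:0.0);")
        concordant = caap.ProteinAlignment("g", ["A", "B"], np.array([["A"], ["A"]]))
        sl, _ = caap.prune_loglik(concordant, tree, lg)
        assert sl[0] == pytest.approx(np.log(lg.frequencies[0]), abs=1e-12)
        discordant = caap.ProteinAlignment("g", ["A", "B"], np.array([["A"], ["R"]]))
        sl, tot = caap.prune_loglik(discordant, tree, lg)
        assert np.isneginf(sl[0]) and np.isneginf(tot)

    def test_quartet_matches_enumeration(self, quartet_tree, quartet_alignment):
        model = caap.build_model("LG", "gene", quartet_alignment)
        rates = caap.discrete_gamma(1.5, 2)
        sl, _ = caap.prune_loglik(quartet_alignment, quartet_tree, model, rates)
        bf, _ = brute_force_quartet(quartet_alignment, quartet_tree, model, rates)
        assert np.abs(sl - bf).max() < 1e-10

    def test_reroot_invariance(self, lg):
        # the same unrooted tree rooted on two different edges
        t1 = caap.PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
        t2 = caap.PhyloTree.from_newick("(A:0.05,(B:0.2,(C:0.3,D:0.1):0.12):0.05);")
        aln = caap.ProteinAlignment(
            "g", ["A", "B", "C", "D"],
            np.array([list("ARN"), list("ARD"), list("AKN"), list("ARN")]),
        )
        rates = caap.discrete_gamma(2.0, 4)
        _, l1 = caap.prune_loglik(aln, t1, lg, rates)
        _, l2 = caap.prune_loglik(aln, t2, lg, rates)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_missing_leaf_sequence(self, lg, quartet_tree):
        aln = caap.ProteinAlignment("g", ["A", "B", "C"],
                                    np.array([["A"], ["A"], ["A"]]))
        with pytest.raises(ModelError):
            caap.prune_loglik(aln, quartet_tree, lg)

    def test_agrees_with_phangorn(self, quartet_tree):
        """Independent cross-check against the R phylogenetics stack."""
        rows = {"A": "ARNDC", "B": "ARDDC", "C": "AKNDW", "D": "ARNEW"}
        aln = caap.ProteinAlignment(
            "ph", list(rows), np.array([list(s) for s in rows.values()])
        )
        m = caap.build_model("LG", "empirical")
        _, ll1 = caap.prune_loglik(aln, quartet_tree, m)
        _, ll4 = caap.prune_loglik(aln, quartet_tree, m, caap.discrete_gamma(2.0, 4))
        rscript = """
suppressMessages(library(phangorn))
tree <- read.tree(text="((A:0.12,B:0.07):0.05,(C:0.3,D:0.02):0.11);")
m <- matrix(c("A","R","N","D","C","A","R","D","D","C","A","K","N","D","W","A","R","N","E","W"),
            nrow=4, byrow=TRUE, dimnames=list(c("A","B","C","D"), NULL))
dat <- phyDat(m, type="AA")
f1 <- pml(tree, dat, model="LG", k=1)
f4 <- pml(tree, dat, model="LG", k=4, shape=2)
cat(sprintf("%.12f %.12f", f1$logLik, f4$logLik))
"""
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r1, r4 = map(float, out.stdout.split())
        assert ll1 == pytest.approx(r1, abs=1e-8)
        assert ll4 == pytest.approx(r4, abs=1e-8)


class TestMarginalASR:
    def test_symmetric_two_leaf_root(self):
        # uniform-frequency model: both leaves 'A' force root ML 'A'
        S = np.ones((20, 20)) - np.eye(20)
        model = caap.SubstitutionModel("flat", S, np.full(20, 0.05))
        tree = caap.PhyloTree.from_newick("(A:0.1,B:0.1);")
        aln = caap.ProteinAlignment("g", ["A", "B"], np.array([["A"], ["A"]]))
        asr = caap.marginal_asr(aln, tree, model)
        assert asr.ml_residues(tree.root.id)[0] == "A"

    def test_quartet_posteriors_match_enumeration(self, quartet_tree, quartet_alignment):
        model = caap.build_model("LG", "gene", quartet_alignment)
        rates = caap.discrete_gamma(1.5, 2)
        asr = caap.marginal_asr(quartet_alignment, quartet_tree, model, rates)
        _, bf_post = brute_force_quartet(quartet_alignment, quartet_tree, model, rates)
        ab = quartet_tree.find("ab").id
        assert np.abs(asr.posteriors[ab] - bf_post).max() < 1e-10

    def test_posterior_rows_normalised(self, quartet_tree, quartet_alignment, lg):
        asr = caap.marginal_asr(
            quartet_alignment, quartet_tree, lg, caap.discrete_gamma(2.0, 4)
        )
        for node_id in asr.node_ids:
            assert np.abs(asr.posteriors[node_id].sum(axis=1) - 1).max() < 1e-9
        assert np.abs(asr.rate_weights.sum(axis=1) - 1).max() < 1e-9

    def test_accuracy_improves_with_shorter_branches(self, lg):
        accs = []
        for t in [0.5, 0.1, 0.02]:
            tree = caap.random_topology(12, seed=3, branch_length=t)
            aln, truth, _ = caap.simulate_alignment(
                tree, lg, 400, None, seed=8, return_ancestral=True
            )
            asr = caap.marginal_asr(aln, tree, lg)
            correct = total = 0
            for nid, true_states in truth.items():
                if nid == tree.root.id:
                    continue
                correct += (asr.ml_states[nid] == true_states).sum()
                total += len(true_states)
            accs.append(correct / total)
        assert accs[0] < accs[1] < accs[2]

    def test_joint_endpoint_posterior_consistency(self, quartet_tree, quartet_alignment):
        model = caap.build_model("LG", "gene", quartet_alignment)
        rates = caap.discrete_gamma(1.5, 2)
        asr = caap.marginal_asr(quartet_alignment, quartet_tree, model, rates)
        ab = quartet_tree.find("ab")
        J = edge_joint_posteriors(quartet_alignment, quartet_tree, model, rates, [ab])
        # marginalising the joint over the child gives the parent posterior
        assert np.abs(J[ab.id].sum(axis=2) - asr.posteriors[quartet_tree.root.id]).max() < 1e-9
        assert np.abs(J[ab.id].sum(axis=1) - asr.posteriors[ab.id]).max() < 1e-9


class TestEstimateAlpha:
    def test_recovers_generating_shape(self, lg):
        tree = caap.random_topology(8, seed=2, branch_length=0.15)
        grid = [0.5, 1.0, 2.0, 4.0]
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            aln = caap.simulate_alignment(tree, lg, 500, 2.0, seed=1000 + rep)
            if caap.estimate_alpha(aln, tree, lg, grid) == 2.0:
                hits += 1
        assert hits >= int(0.9 * n_rep)

    def test_constant_rate_data_prefers_largest_alpha(self, lg):
        tree = caap.random_topology(8, seed=2, branch_length=0.15)
        aln = caap.simulate_alignment(tree, lg, 500, None, seed=77)
        grid = [0.5, 1.0, 2.0, 8.0]
        assert caap.estimate_alpha(aln, tree, lg, grid) == 8.0

    def test_singleton_grid(self, lg, quartet_tree, quartet_alignment):
        assert caap.estimate_alpha(quartet_alignment, quartet_tree, lg, [1.7]) == 1.7

    def test_empty_grid(self, lg, quartet_tree, quartet_alignment):
        with pytest.raises(ModelError):
            caap.estimate_alpha(quartet_alignment, quartet_tree, lg, [])
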