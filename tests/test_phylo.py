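"""Distances, NJ/BioNJ, GTR likelihood and the ML search."""

import math

import dendropy
import numpy as np
import pytest

from ctmarker.phylo import (
    DistanceMatrix,
    GTRParams,
    bionj_tree,
    distance_matrix,
    filter_columns,
    gtr_loglik,
    ml_search,
    nj_tree,
    optimize_branch_lengths,
    p_distance,
    parse_newick,
    rf_distance,
    simulate_gtr_alignment,
    tn93_distance,
    to_newick,
    transition_matrix,
    write_phylip,
)
from ctmarker.seq_io import Alignment, NucSequence
from ctmarker.simulate import simulate_yule_tree


def _random_tree_with_matrix(n_taxa, seed, min_bl=0.05, max_bl=0.4):
    """A random topology with random branch lengths and its additive matrix."""
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_taxa, 1.0, seed=rng.integers(2**31))
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(min_bl, max_bl))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    d = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return tree, DistanceMatrix(labels, d)


class TestDistances:
    def test_identical_zero(self):
        assert p_distance("ACGT", "ACGT") == 0.0
        assert tn93_distance("ACGT", "ACGT") == 0.0

    def test_p_distance_direct_count(self):
        assert p_distance("AAAA", "AAAT") == 0.25

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        assert p_distance("A-RT", "AACT") == 0.0
        with pytest.raises(ValueError, match="no valid"):
            p_distance("--", "AA")

    def test_tn93_unbiased_on_simulated_pairs(self):
        t = 0.15
        tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
        params = GTRParams((1.0, 3.0, 1.0, 1.0, 3.0, 1.0), (0.3, 0.2, 0.2, 0.3))
        estimates = []
        for seed in range(8):
            aln = simulate_gtr_alignment(tree, 5000, params, rng=seed)
            estimates.append(tn93_distance(*[s for s in aln.sequences]))
        assert abs(np.mean(estimates) - t) < 0.01

    def test_saturation_flagged(self):
        with pytest.warns(UserWarning, match="saturated"):
            d = tn93_distance("ACGT" * 5, "CATG" * 5)
        assert d >= 10.0

    def test_phylip_output(self, tmp_path):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.1, 0.0]]))
        path = tmp_path / "m.phy"
        write_phylip(dm, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].startswith("a")


class TestFilterColumns:
    def test_gapless_unchanged(self):
        aln = Alignment([NucSequence("a", "ACGT"), NucSequence("b", "ACGA")])
        assert filter_columns(aln).column_count == 4

    def test_ninety_percent_column_removed(self):
        seqs = [NucSequence(f"s{i}", "ACGT") for i in range(9)]
        seqs.append(NucSequence("s9", "A-GT"))
        filtered = filter_columns(Alignment(seqs), 0.95)
        assert filtered.column_count == 3
        assert filtered.sequences[0].residues == "AGT"

    def test_ambiguity_counts_as_missing(self):
        seqs = [NucSequence(f"s{i}", "ACGT") for i in range(9)]
        seqs.append(NucSequence("s9", "ARGT"))
        assert filter_columns(Alignment(seqs), 0.95).column_count == 3

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(2)
        rows = [
            "".join(rng.choice(list("ACGT-"), p=[0.23] * 4 + [0.08], size=60))
            for _ in range(12)
        ]
        aln = Alignment([NucSequence(f"s{i}", r) for i, r in enumerate(rows)])
        expected_cols = [
            c
            for c in range(60)
            if sum(r[c] in "ACGT" for r in rows) / 12 >= 0.75
        ]
        filtered = filter_columns(aln, 0.75)
        assert filtered.column_count == len(expected_cols)
        assert filtered.sequences[0].residues == "".join(
            rows[0][c] for c in expected_cols
        )

    def test_all_removed_rejected(self):
        aln = Alignment([NucSequence("a", "-"), NucSequence("b", "A")])
        with pytest.raises(ValueError, match="no columns"):
            filter_columns(aln, 0.95)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    @pytest.mark.parametrize("builder", [nj_tree, bionj_tree])
    @pytest.mark.parametrize("n_taxa", [4, 6, 8])
    def test_additive_matrix_recovery(self, builder, n_taxa):
        truth, dm = _random_tree_with_matrix(n_taxa, seed=n_taxa * 7)
        tree = builder(dm)
        assert rf_distance(tree, truth) == 0
        # additivity: implied path lengths reproduce the input matrix
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        dm.d[i, j], abs=1e-9
                    )

    def test_agreement_with_skbio_oracle(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        truth, dm = _random_tree_with_matrix(7, seed=99)
        ours = nj_tree(dm)
        theirs = skbio_nj(SkbioDM(dm.d, ids=dm.labels))
        theirs_dendropy = parse_newick(str(theirs))
        assert rf_distance(ours, theirs_dendropy) == 0

    def test_deterministic_output(self):
        _, dm = _random_tree_with_matrix(6, seed=5)
        assert to_newick(nj_tree(dm)) == to_newick(nj_tree(dm))


class TestGTR:
    def test_rate_matrix_invariants(self):
        params = GTRParams((1.2, 3.0, 0.7, 1.1, 4.0, 1.0), (0.28, 0.22, 0.24, 0.26))
        q = params.rate_matrix()
        pi = np.array(params.base_freqs)
        assert np.allclose(q.sum(axis=1), 0)
        assert np.allclose(pi @ q, 0, atol=1e-12)  # stationarity
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T)  # reversibility
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)  # mean rate 1

    def test_transition_matrix_rows_are_distributions(self):
        params = GTRParams()
        for t in (0.0, 0.01, 0.5, 3.0):
            p = transition_matrix(params, t)
            assert np.allclose(p.sum(axis=1), 1)
            assert np.all(p >= 0)
        assert np.allclose(transition_matrix(params, 0.0), np.eye(4))

    def test_single_site_zero_branch_loglik(self):
        params = GTRParams(base_freqs=(0.1, 0.2, 0.3, 0.4))
        tree = parse_newick("(A:0.0,B:0.0);")
        aln = Alignment([NucSequence("A", "G"), NucSequence("B", "G")])
        assert gtr_loglik(tree, aln, params) == pytest.approx(math.log(0.3))

    def test_jc69_closed_form(self):
        tree = parse_newick("(A:0.05,B:0.05);")
        aln = Alignment([NucSequence("A", "AAAA"), NucSequence("B", "AAAT")])
        lnl = gtr_loglik(tree, aln, GTRParams())
        t = 0.1
        same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        diff = 0.25 - 0.25 * math.exp(-4 * t / 3)
        expected = 3 * math.log(0.25 * same) + math.log(0.25 * diff)
        assert abs(lnl - expected) < 1e-12

    def test_matches_exhaustive_state_sum(self):
        params = GTRParams((1.2, 3.0, 0.7, 1.1, 4.0, 1.0), (0.28, 0.22, 0.24, 0.26))
        tree = parse_newick("((A:0.1,B:0.23):0.07,(C:0.15,D:0.31):0.0831);")
        aln = Alignment(
            [
                NucSequence("A", "AC"),
                NucSequence("B", "AT"),
                NucSequence("C", "GC"),
                NucSequence("D", "RC"),
            ]
        )
        lnl = gtr_loglik(tree, aln, params)
        assert abs(lnl - _exhaustive_loglik(tree, aln, params)) < 1e-10

    def test_rerooting_invariance(self):
        params = GTRParams((1.2, 3.0, 0.7, 1.1, 4.0, 1.0), (0.28, 0.22, 0.24, 0.26))
        tree = simulate_yule_tree(6, 1.0, seed=31)
        aln = simulate_gtr_alignment(tree, 300, params, rng=3)
        lnl = gtr_loglik(tree, aln, params)
        reroot = tree.clone(depth=1)
        internal = [
            n for n in reroot.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ][0]
        reroot.reroot_at_node(internal, update_bipartitions=False)
        assert abs(gtr_loglik(reroot, aln, params) - lnl) < 1e-8


def _exhaustive_loglik(tree, alignment, params):
    """Brute-force sum over all internal-state combinations."""
    from ctmarker.seq_io import expand_iupac

    pi = np.array(params.base_freqs)
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    by_id = {s.id: s.residues for s in alignment.sequences}
    total = 0.0
    for site in range(alignment.column_count):
        site_lik = 0.0
        for states in np.ndindex(*(4,) * len(internal)):
            assign = dict(zip((id(n) for n in internal), states))
            term = pi[assign[id(tree.seed_node)]]
            for node in nodes:
                if node.parent_node is None:
                    continue
                p = transition_matrix(params, node.edge.length or 0.0)
                parent_state = assign[id(node.parent_node)]
                if node.is_leaf():
                    char = by_id[node.taxon.label][site]
                    allowed = [
                        "ACGT".index(b) for b in expand_iupac(char)
                    ] if char != "-" else range(4)
                    term *= sum(p[parent_state, b] for b in allowed)
                else:
                    term *= p[parent_state, assign[id(node)]]
            site_lik += term
        total += math.log(site_lik)
    return total


class TestMLSearch:
    PARAMS = GTRParams((1.5, 4.0, 0.9, 1.2, 5.0, 1.0), (0.3, 0.2, 0.2, 0.3))

    def _simulated(self, n_taxa=5, n_sites=600, seed=17):
        tree = simulate_yule_tree(n_taxa, 1.0, seed=seed)
        height = 0.0
        node = next(tree.leaf_node_iter())
        while node.parent_node is not None:
            height += node.edge.length
            node = node.parent_node
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = max(nd.edge.length * 0.3 / height, 0.03)
        aln = simulate_gtr_alignment(tree, n_sites, self.PARAMS, rng=seed)
        return tree, aln

    def test_final_loglik_not_below_starts(self):
        _, aln = self._simulated()
        dm = distance_matrix(aln, "tn93")
        result = ml_search(aln, params=self.PARAMS)
        for start in (nj_tree(dm), bionj_tree(dm)):
            start_lnl = optimize_branch_lengths(start, aln, self.PARAMS)
            assert result.ln_likelihood >= start_lnl - 1e-6

    def test_search_scores_at_least_the_generating_tree(self):
        """The local search never returns a tree worse than the (branch-
        length-optimized) generating topology."""
        truth, aln = self._simulated(n_taxa=5, n_sites=800, seed=23)
        result = ml_search(aln, params=self.PARAMS)
        truth_opt = truth.clone(depth=1)
        truth_lnl = optimize_branch_lengths(truth_opt, aln, self.PARAMS)
        assert result.ln_likelihood >= truth_lnl - 1e-6

    def test_duplicate_sequences_get_zero_length_terminals(self):
        truth, aln = self._simulated(n_taxa=4, n_sites=400, seed=29)
        seqs = list(aln.sequences)
        dup = NucSequence("dup", seqs[0].residues)
        result = ml_search(Alignment(seqs + [dup]), params=self.PARAMS)
        twins = {
            leaf.taxon.label: leaf
            for leaf in result.leaf_node_iter()
            if leaf.taxon.label in (seqs[0].id, "dup")
        }
        for leaf in twins.values():
            assert leaf.edge.length < 1e-6

    def test_fewer_than_four_taxa_degenerate(self):
        _, aln = self._simulated(n_taxa=4, n_sites=200, seed=3)
        three = Alignment(aln.sequences[:3])
        result = ml_search(three, params=self.PARAMS)
        assert {l.taxon.label for l in result.leaf_node_iter()} == {
            s.id for s in three.sequences
        }

    def test_filter_is_identity_on_gapless_input(self):
        _, aln = self._simulated(n_taxa=4, n_sites=200, seed=9)
        filtered = filter_columns(aln, 0.95)
        assert [s.residues for s in filtered.sequences] == [
            s.residues for s in aln.sequences
        ]
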