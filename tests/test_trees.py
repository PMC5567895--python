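import numpy as np
import pytest

from barcodeval import DistanceMatrix, distance_matrix
from barcodeval.seqio import LabelledAlignment
from barcodeval.synthetic import Locus, SimSpec, simulate
from barcodeval.trees import (
    bootstrap_consensus,
    fitch_length,
    majority_rule_consensus,
    mp_search,
    nj_tree,
    resolution_score,
    tree_bipartitions,
    _tuple_to_dendropy,
)

from oracles import (
    all_unrooted_topologies,
    fitch_exhaustive,
    graph_bipartitions,
    random_additive_tree,
)


def full_dm(ids, values, species=None):
    n = len(ids)
    return DistanceMatrix(
        ids, species or [f"G_{i}" for i in ids], values,
        np.ones((n, n), bool),
    )


def branch_lengths(tree):
    return {
        frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.edge.length
        for nd in tree.preorder_node_iter() if nd.parent_node is not None
    }


class TestNJ:
    def test_three_taxa_three_point_formulas(self):
        # d(ab)=0.3, d(ac)=0.4, d(bc)=0.5 -> la=0.1, lb=0.2, lc=0.3
        v = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = nj_tree(full_dm(list("abc"), v))
        lengths = {nd.taxon.label: nd.edge.length
                   for nd in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.3)

    def test_four_taxon_additive_recovery(self):
        # unrooted tree: A:1, B:2 joined, internal edge 1, C:3, D:4
        ids = list("ABCD")
        v = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(full_dm(ids, v))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        bl = branch_lengths(tree)
        leaf = {next(iter(k)): l for k, l in bl.items() if len(k) == 1}
        assert leaf == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        internal = bl.get(frozenset({"C", "D"}), bl.get(frozenset({"A", "B"})))
        assert internal == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [5, 6, 8])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_recovery_of_random_additive_matrices(self, n, seed):
        rng = np.random.default_rng(10 * n + seed)
        adj, D = random_additive_tree(rng, n)
        ids = [str(i) for i in range(n)]
        tree = nj_tree(full_dm(ids, D))
        got = {frozenset(int(x) for x in side)
               for side in tree_bipartitions(tree)}
        assert got == graph_bipartitions(adj, n)
        # pairwise path distances reproduced exactly
        for i in range(n):
            for j in range(i + 1, n):
                pd = path_distance_on_tree(tree, ids[i], ids[j])
                assert pd == pytest.approx(D[i, j], abs=1e-9)

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        n = 7
        base = rng.uniform(0.1, 1.0, size=(n, n))
        v = np.triu(base, 1)
        v = v + v.T
        ids = [f"t{i}" for i in range(n)]
        ours = nj_tree(full_dm(ids, v))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(v, ids))
        their_bps = set()
        all_ids = frozenset(ids)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if "t0" in side:
                side = all_ids - side
            if 1 < len(side) < n - 1:
                their_bps.add(side)
        assert tree_bipartitions(ours) == their_bps

    def test_undefined_pair_is_an_error(self):
        v = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        defined = np.ones((3, 3), bool)
        defined[1, 2] = defined[2, 1] = False
        dm = DistanceMatrix(list("abc"), ["G_a", "G_b", "G_c"], v, defined)
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm)

    def test_too_few_leaves(self):
        v = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(full_dm(list("ab"), v))

    def test_negative_branch_lengths_clamped(self):
        # strongly non-additive matrix provokes negative NJ estimates
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = 6
            base = rng.uniform(0.0, 1.0, size=(n, n))
            v = np.triu(base, 1)
            v = v + v.T
            tree = nj_tree(full_dm([f"t{i}" for i in range(n)], v))
            for nd in tree.preorder_node_iter():
                if nd.edge.length is not None:
                    assert nd.edge.length >= 0.0


def path_distance_on_tree(tree, a, b):
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.distance(ta, tb)


class TestBootstrapConsensus:
    def two_species_aln(self, per=3, seed=0):
        spec = SimSpec(n_species=2, individuals_per_species=per,
                       loci=(Locus("l", 400),), inter_scale=0.2,
                       intra_scale=0.004, seed=seed)
        return simulate(spec)[0]

    def test_separated_species_reach_full_support(self):
        aln = self.two_species_aln()
        cons = bootstrap_consensus(aln, replicates=100, seed=5)
        res = resolution_score(cons, dict(zip(aln.ids, aln.species)), cutoff=60)
        for sp, (ok, sup) in res.resolved.items():
            assert ok
            assert sup == pytest.approx(100.0)

    def test_single_replicate_equals_that_tree_at_full_support(self):
        aln = self.two_species_aln(seed=3)
        cons = bootstrap_consensus(aln, replicates=1, seed=9)
        for nd in cons.preorder_internal_node_iter():
            if nd.parent_node is not None:
                assert nd.support_pct == pytest.approx(100.0)

    def test_same_seed_same_consensus(self):
        aln = self.two_species_aln(seed=4)
        c1 = bootstrap_consensus(aln, replicates=30, seed=21)
        c2 = bootstrap_consensus(aln, replicates=30, seed=21)
        assert c1.as_string(schema="newick") == c2.as_string(schema="newick")

    def test_consensus_bipartitions_mutually_compatible(self):
        aln = self.two_species_aln(seed=8)
        cons = bootstrap_consensus(aln, replicates=50, seed=2)
        bps = tree_bipartitions(cons)
        for x in bps:
            for y in bps:
                assert x <= y or y <= x or not (x & y)

    def test_supports_within_0_100(self):
        aln = self.two_species_aln(seed=6)
        cons = bootstrap_consensus(aln, replicates=40, seed=4)
        for nd in cons.preorder_internal_node_iter():
            sup = getattr(nd, "support_pct", None)
            if sup is not None:
                assert 0.0 <= sup <= 100.0


class TestResolution:
    def test_perfect_two_species_tree(self, fixture_aln):
        cons = bootstrap_consensus(fixture_aln, replicates=100, seed=17)
        res = resolution_score(cons, dict(zip(fixture_aln.ids,
                                              fixture_aln.species)))
        assert res.n_species_scored == 4
        assert res.n_resolved == 4

    def test_support_below_cutoff_not_resolved(self):
        import dendropy

        # 20 trees grouping (a1,a2), only 11 grouping (b1,b2): 55% support
        tns_trees = []
        for k in range(20):
            if k < 11:
                nwk = "((a1,a2),(b1,b2),c1);"
            else:
                nwk = "((a1,a2),(b1,c1),b2);"
            tns_trees.append(nwk)
        trees = []
        tns = dendropy.TaxonNamespace(["a1", "a2", "b1", "b2", "c1"])
        for nwk in tns_trees:
            t = dendropy.Tree.get(data=nwk, schema="newick",
                                  taxon_namespace=tns)
            t.is_rooted = False
            trees.append(t)
        cons = majority_rule_consensus(trees)
        species_of = {"a1": "G_a", "a2": "G_a", "b1": "G_b", "b2": "G_b",
                      "c1": "G_c"}
        res = resolution_score(cons, species_of, cutoff=60)
        assert res.resolved["G_a"] == (True, pytest.approx(100.0))
        ok_b, sup_b = res.resolved["G_b"]
        assert not ok_b
        assert sup_b == pytest.approx(55.0)
        assert res.excluded_species == ["G_c"]

    def test_equals_bruteforce_bipartition_check(self):
        spec = SimSpec(n_species=5, individuals_per_species=3,
                       loci=(Locus("l", 500),), inter_scale=0.1,
                       intra_scale=0.004, seed=13)
        aln = simulate(spec)[0]
        cons = bootstrap_consensus(aln, replicates=50, seed=3)
        species_of = dict(zip(aln.ids, aln.species))
        res = resolution_score(cons, species_of, cutoff=60)
        # brute force: walk every internal node, gather its leaf set
        from barcodeval.trees import _leaf_clusters

        clusters = _leaf_clusters(cons)
        all_leaves = clusters[cons.seed_node]
        for sp in set(aln.species):
            members = frozenset(i for i, s in species_of.items() if s == sp)
            hit = None
            for nd, cl in clusters.items():
                if nd.is_leaf() or nd is cons.seed_node:
                    continue
                if cl == members or (all_leaves - cl) == members:
                    hit = getattr(nd, "support_pct", None)
            expected = hit is not None and hit > 60
            assert res.resolved[sp][0] == expected

    def test_missing_specimen_is_an_error(self, fixture_aln):
        cons = bootstrap_consensus(fixture_aln, replicates=5, seed=1)
        species_of = dict(zip(fixture_aln.ids, fixture_aln.species))
        species_of["ghost"] = "G_x"
        with pytest.raises(ValueError, match="absent"):
            resolution_score(cons, species_of)


class TestFitch:
    def aln_from_columns(self, columns, n):
        seqs = ["".join(col[i] for col in columns) for i in range(n)]
        return LabelledAlignment(
            "x", [f"t{i}" for i in range(n)],
            [f"G_s{i}" for i in range(n)], seqs,
        )

    def test_invariant_alignment_scores_zero(self):
        aln = self.aln_from_columns(["AAAA", "CCCC", "GGGG"], 4)
        tree = _tuple_to_dendropy((0, ((1, 2), 3)), aln.ids)
        score = fitch_length(tree, aln)
        assert score.tree_length == 0
        assert score.ci is None

    def test_single_informative_column(self):
        aln = self.aln_from_columns(["AAGG"] + ["AAAA"] * 5, 4)
        tree = _tuple_to_dendropy(((0, 1), (2, 3)), aln.ids)
        score = fitch_length(tree, aln)
        assert score.tree_length == 1
        assert score.ci == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed + 200)
        n = 6
        columns = ["".join(rng.choice(list("ACGT-"), size=n))
                   for _ in range(8)]
        aln = self.aln_from_columns(columns, n)
        topo = all_unrooted_topologies(n)[int(rng.integers(105))]
        tree = _tuple_to_dendropy(topo, aln.ids)
        assert fitch_length(tree, aln).tree_length == \
            fitch_exhaustive(topo, columns)

    def test_invariant_to_leaf_permutation_and_rerooting(self):
        rng = np.random.default_rng(77)
        n = 6
        columns = ["".join(rng.choice(list("ACGT"), size=n))
                   for _ in range(12)]
        aln = self.aln_from_columns(columns, n)
        topo = all_unrooted_topologies(n)[7]
        tree = _tuple_to_dendropy(topo, aln.ids)
        base = fitch_length(tree, aln).tree_length
        # reroot on every internal edge
        import dendropy

        for edge in list(tree.preorder_edge_iter()):
            if edge.head_node.parent_node is None or edge.head_node.is_leaf():
                continue
            t2 = tree.clone(depth=1)
            e2 = [e for e in t2.preorder_edge_iter()
                  if e.head_node.parent_node is not None
                  and not e.head_node.is_leaf()][0]
            t2.reroot_at_edge(e2)
            assert fitch_length(t2, aln).tree_length == base

    def test_leaf_mismatch_is_an_error(self, fixture_aln):
        tree = _tuple_to_dendropy((0, (1, 2)), ["x", "y", "z"])
        with pytest.raises(ValueError, match="match"):
            fitch_length(tree, fixture_aln)


class TestMPSearch:
    def test_five_taxa_equals_exhaustive(self):
        rng = np.random.default_rng(31)
        n = 5
        columns = ["".join(rng.choice(list("ACGT"), size=n))
                   for _ in range(10)]
        seqs = ["".join(col[i] for col in columns) for i in range(n)]
        aln = LabelledAlignment("x", [f"t{i}" for i in range(n)],
                                [f"G_s{i}" for i in range(n)], seqs)
        best_exhaustive = min(
            fitch_exhaustive(t, columns) for t in all_unrooted_topologies(n)
        )
        _, score = mp_search(aln, n_starts=5, seed=2)
        assert score.tree_length == best_exhaustive

    def test_single_informative_column_attains_one_step(self):
        seqs = ["A" * 10, "A" * 10, "G" * 1 + "A" * 9, "G" + "A" * 9,
                "A" * 10]
        aln = LabelledAlignment("x", [f"t{i}" for i in range(5)],
                                [f"G_s{i}" for i in range(5)], seqs)
        _, score = mp_search(aln, n_starts=3, seed=0)
        assert score.tree_length == 1

    def test_same_seed_same_length(self, fixture_aln):
        _, s1 = mp_search(fixture_aln, n_starts=2, seed=7)
        _, s2 = mp_search(fixture_aln, n_starts=2, seed=7)
        assert s1.tree_length == s2.tree_length

    def test_rc_is_product_of_ci_and_ri(self, fixture_aln):
        _, score = mp_search(fixture_aln, n_starts=2, seed=7)
        if score.ci is not None and score.ri is not None:
            assert score.rc == pytest.approx(score.ci * score.ri, abs=1e-12)

    def test_too_few_taxa(self):
        aln = LabelledAlignment("x", ["a", "b"], ["G_a", "G_b"],
                                ["ACGT", "ACGT"])
        with pytest.raises(ValueError, match="at least 4"):
            mp_search(aln, n_starts=1, seed=0)
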