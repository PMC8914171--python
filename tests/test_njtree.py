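import numpy as np
import pytest

from superbarcode.distmat import DistanceMatrix
from superbarcode.errors import (
    IdentityError,
    IncompleteMatrixError,
    ParameterError,
    RootingError,
)
from superbarcode.njtree import (
    is_monophyletic,
    neighbor_joining,
    root_with_outgroup,
    tree_method,
)
from superbarcode.seqio import SpeciesMap, read_newick

from _oracles import bf_monophyly, random_additive_tree, rf_distance
from conftest import make_alignment


def dm_from(ids, D, n_sites=100):
    D = np.asarray(D, dtype=float)
    return DistanceMatrix(list(ids), D, np.full_like(D, n_sites, dtype=np.int64))


class TestNeighborJoining:
    def test_four_taxon_additive(self):
        # AB|CD split with internal edge 1: d(AB)=2, d(CD)=2, cross = 3
        dm = dm_from("ABCD", [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]])
        tree = neighbor_joining(dm)
        assert rf_distance(tree.newick(), "((A:1,B:1):1,(C:1,D:1):0);") == 0
        np.testing.assert_allclose(tree.path_lengths(list("ABCD")), dm.values, atol=1e-12)

    def test_three_taxon_closed_form(self):
        dm = dm_from("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = neighbor_joining(dm)
        # limb lengths: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        assert tree.newick() == "(A:1.000000,B:2.000000,C:3.000000);"

    def test_random_additive_recovery(self):
        """NJ is consistent on additive matrices: exact topology and path lengths."""
        rng = np.random.default_rng(42)
        for rep in range(10):
            n = int(rng.integers(5, 13))
            true_tree, ids, D = random_additive_tree(n, rng)
            nj = neighbor_joining(dm_from(ids, D))
            assert rf_distance(nj.newick(), true_tree.newick(precision=8)) == 0
            np.testing.assert_allclose(nj.path_lengths(ids), D, atol=1e-9)

    def test_agrees_with_skbio_on_generic_matrices(self):
        """Independent cross-check against scikit-bio's NJ on perturbed
        additive matrices (no ties, so tie-breaking cannot differ)."""
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        for _ in range(5):
            n = 8
            _, ids, D = random_additive_tree(n, rng)
            noise = rng.uniform(0, 0.05, size=(n, n))
            D = D + (noise + noise.T)  # keep exact float symmetry
            np.fill_diagonal(D, 0.0)
            mine = neighbor_joining(dm_from(ids, D))
            theirs = skbio_nj(SkbioDM(D, ids))
            buf = io.StringIO()
            theirs.write(buf)
            assert rf_distance(mine.newick(), buf.getvalue()) == 0

    def test_input_order_invariance(self):
        rng = np.random.default_rng(13)
        _, ids, D = random_additive_tree(9, rng)
        t1 = neighbor_joining(dm_from(ids, D))
        perm = list(rng.permutation(len(ids)))
        t2 = neighbor_joining(dm_from([ids[i] for i in perm], D[np.ix_(perm, perm)]))
        assert t1.newick() == t2.newick()

    def test_tie_break_is_deterministic(self):
        # fully symmetric matrix: every Q is tied; lexicographic pairs decide
        n = 5
        ids = ["e", "d", "c", "b", "a"]
        D = np.ones((n, n)) - np.eye(n)
        t1 = neighbor_joining(dm_from(ids, D))
        t2 = neighbor_joining(dm_from(sorted(ids), D))
        assert t1.newick() == t2.newick()

    def test_undefined_cell_names_pair(self):
        D = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(IncompleteMatrixError, match="t1.*t3"):
            neighbor_joining(DistanceMatrix(["t1", "t2", "t3"], D, np.ones((3, 3), int)))

    def test_too_few_taxa(self):
        with pytest.raises(ParameterError):
            neighbor_joining(dm_from("AB", [[0, 1], [1, 0]]))

    def test_negative_limb_clamped(self):
        # strongly non-additive matrix that produces a negative limb estimate
        D = np.array(
            [[0, 0.1, 0.4, 0.45], [0.1, 0, 0.05, 0.5], [0.4, 0.05, 0, 0.3], [0.45, 0.5, 0.3, 0]]
        )
        tree = neighbor_joining(dm_from("ABCD", D))
        lengths = []
        for node in tree.preorder():
            if node is not tree.root:
                lengths.append(node.length)
        assert all(l >= 0 for l in lengths)


class TestRooting:
    def test_single_leaf_outgroup(self):
        tree = read_newick_str("((a:1,b:1):1,(c:1,o:1):1,e:1);")
        rooted = root_with_outgroup(tree, ["o"])
        assert rooted.rooted
        # o's lineage is one child of the root
        sides = [sorted(s) for _, s in rooted.clades() if _.parent is rooted.root]
        assert ["o"] in sides

    def test_cherry_outgroup(self):
        tree = read_newick_str("((a:1,b:1):1,c:1,(o1:0.5,o2:0.5):2);")
        rooted = root_with_outgroup(tree, ["o1", "o2"])
        top = [s for n, s in rooted.clades() if n.parent is rooted.root]
        assert frozenset({"o1", "o2"}) in top
        # the rooting edge's length 2 is split equally
        og_node = next(n for n, s in rooted.clades() if s == {"o1", "o2"} and n.parent is rooted.root)
        assert og_node.length == pytest.approx(1.0)

    def test_non_clade_outgroup_raises(self):
        tree = read_newick_str("((a:1,o:1):1,(b:1,c:1):1,d:1);")
        with pytest.raises(RootingError):
            root_with_outgroup(tree, ["o", "b"])

    def test_root_unroot_roundtrip_topology(self):
        rng = np.random.default_rng(77)
        tree, ids, _ = random_additive_tree(8, rng)
        rooted = root_with_outgroup(tree, [ids[0]])
        assert rf_distance(rooted.newick(), tree.newick()) == 0


def read_newick_str(s):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / "t.nwk"
        p.write_text(s + "\n")
        return read_newick(p)


class TestMonophyly:
    def test_simple_cases(self):
        t = read_newick_str("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        assert is_monophyletic(t, {"a1", "a2"}) is True
        t2 = read_newick_str("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        assert is_monophyletic(t2, {"a1", "a2"}) is False

    def test_unknown_leaf(self):
        t = read_newick_str("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        with pytest.raises(IdentityError):
            is_monophyletic(t, {"a1", "zz"})

    def test_agrees_with_clade_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        tree, ids, _ = random_additive_tree(10, rng)
        rooted = root_with_outgroup(tree, [ids[-1]])
        nwk = rooted.newick()
        for _ in range(20):
            k = int(rng.integers(1, 6))
            subset = set(rng.choice(ids, size=k, replace=False))
            assert is_monophyletic(rooted, subset) == bf_monophyly(nwk, subset)


class TestTreeMethod:
    def test_clean_community_fully_monophyletic(self, small_community):
        aln, truth = small_community
        res = tree_method(aln, truth.species_map())
        assert res.n_success == res.n_scored == 6
        assert res.rate == 1.0

    def test_engineered_paraphyly_fails_exactly_one(self):
        from superbarcode.synthdata import SimulationParams, simulate_community

        params = SimulationParams(
            seed=11,
            n_species=6,
            individuals_per_species=4,
            alignment_length=6000,
            interspecific_scale=0.02,
            intraspecific_scale=0.002,
            indel_rate=0.0,
            min_species_stem=0.004,
            paraphyly_species=2,
        )
        aln, truth = simulate_community(params)
        res = tree_method(aln, truth.species_map())
        failures = [e.species for e in res.entries if e.monophyletic is False]
        assert failures == [truth.split_species]

    def test_requires_outgroup(self, small_community):
        aln, truth = small_community
        sm = SpeciesMap(dict(truth.species_of), frozenset())
        ing = aln.subset([a for a in aln.ids if a not in truth.outgroup_ids])
        with pytest.raises(ParameterError):
            tree_method(ing, sm)

    def test_singleton_policy(self):
        # a singleton species nested inside another species' clade is flagged
        aln = make_alignment(
            ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "CCCCCCCCCC", "GGGGGGGGGG"],
            species=["x", "x", "solo", "y", "og"],
            ids=["x1", "x2", "s1", "y1", "o1"],
        )
        sm = SpeciesMap.from_alignment(aln, {"o1"})
        res = tree_method(aln, sm)
        by_sp = {e.species: e for e in res.entries}
        assert by_sp["solo"].singleton
        assert res.n_scored == 1  # only x has >= 2 individuals and a defined score
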