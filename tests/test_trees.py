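"""Tree inference: NJ exactness on additive distances (and skbio agreement),
Fitch vs exhaustive enumeration, likelihood closed forms and invariances,
search behaviour and bootstrap contracts."""

import itertools

import numpy as np
import pytest

from vitephylo import synthetic_data as sd
from vitephylo import trees as tr
from vitephylo._tree import Tree, bipartitions, rf_distance


def _patristic(tree):
    names = sorted(tree.leaf_names())
    paths = {}

    def walk(n, acc):
        if n.is_leaf:
            paths[n.name] = acc
        for c in n.children:
            walk(c, acc + [(id(c), c.length)])

    walk(tree.root, [])
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            sa = {k for k, _ in paths[a]}
            sb = {k for k, _ in paths[b]}
            D[i, j] = sum(l for k, l in paths[a] if k not in sb) + \
                sum(l for k, l in paths[b] if k not in sa)
    return names, D


class TestNeighborJoining:
    def test_additive_matrix_recovers_tree_exactly(self):
        t = Tree.from_newick(
            "((A:1,B:2):1.5,((C:0.5,D:1):0.7,E:3):0.4,F:2);")
        names, D = _patristic(t)
        nj = tr.nj_tree(D, names)
        assert rf_distance(nj, t) == 0
        _, D2 = _patristic(nj)
        assert np.allclose(D2, D, atol=1e-9)

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        t = tr.nj_tree(D, ["a", "b", "c"])
        assert len(t.root.children) == 3
        assert all(c.is_leaf for c in t.root.children)

    def test_taxon_order_invariance(self, rng):
        t = sd.simulate_species_tree(7, seed=5)
        names, D = _patristic(t)
        perm = rng.permutation(len(names))
        t1 = tr.nj_tree(D, names)
        t2 = tr.nj_tree(D[np.ix_(perm, perm)], [names[i] for i in perm])
        assert rf_distance(t1, t2) == 0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            tr.nj_tree(D, list("abc"))

    def test_agrees_with_skbio_on_noisy_distances(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        t = sd.simulate_species_tree(8, seed=9)
        names, D = _patristic(t)
        D += rng.uniform(0, 0.01, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        ours = tr.nj_tree(D, names)
        theirs = skbio_nj(DistanceMatrix(D, ids=names))
        theirs_t = Tree.from_newick(str(theirs))
        assert bipartitions(theirs_t) == bipartitions(ours)


from _oracles import brute_force_fitch


class TestFitch:
    def test_invariant_site_has_zero_changes(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert tr.fitch_score(t, {k: "AAA" for k in "ABCD"}) == 0

    def test_aabb_split_costs_one(self):
        t = Tree.from_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        aln = {"A1": "A", "A2": "A", "B1": "C", "B2": "C"}
        assert tr.fitch_score(t, aln) == 1

    def test_matches_exhaustive_oracle_on_random_cases(self, rng):
        """Random (<=6-taxon tree, site) cases vs brute force (the full
        200-case suite runs in the acceptance tests)."""
        nucs = "ACGT-"
        for _ in range(10):
            n = int(rng.integers(4, 7))
            t = sd.simulate_species_tree(n, seed=int(rng.integers(1 << 30)))
            names = t.leaf_names()
            sites = ["".join(rng.choice(list(nucs), n)) for _ in range(5)]
            aln = {nm: "".join(s[i] for s in sites)
                   for i, nm in enumerate(names)}
            ours = tr.fitch_score(t, aln)
            expected = 0
            for s in sites:
                site = {nm: (None if s[i] == "-" else "ACGT".index(s[i]))
                        for i, nm in enumerate(names)}
                expected += brute_force_fitch(t, site)
            assert ours == expected

    def test_leaf_mismatch_lists_difference(self):
        t = Tree.from_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(ValueError, match="D"):
            tr.fitch_score(t, {"A": "A", "B": "A", "C": "A", "E": "A"})


class TestMpSearch:
    def test_perfect_compatible_characters_recover_tree(self):
        t = Tree.from_newick("((A:1,B:1):1,((C:1,D:1):1,E:1):1,F:1);")
        # one binary character per internal split
        splits = bipartitions(t)
        names = sorted(t.leaf_names())
        aln = {nm: "" for nm in names}
        for side in splits:
            for nm in names:
                aln[nm] += "A" if nm in side else "C"
        aln = {nm: s * 5 for nm, s in aln.items()}
        trees, score = tr.mp_search(aln, n_random_additions=5, seed=0)
        assert any(rf_distance(x, t) == 0 for x in trees)
        assert score == len(splits) * 5

    def test_seeded_determinism_and_score_consistency(self, rng):
        t = sd.simulate_species_tree(6, seed=3)
        aln = sd.simulate_nucleotide_sites(t, 200, rate=0.5, seed=4)
        r1 = tr.mp_search(aln, n_random_additions=4, seed=7)
        r2 = tr.mp_search(aln, n_random_additions=4, seed=7)
        assert r1[1] == r2[1]
        assert [x.to_newick(lengths=False) for x in r1[0]] == \
            [x.to_newick(lengths=False) for x in r2[0]]
        for x in r1[0]:
            assert tr.fitch_score(x, aln) == r1[1]


class TestLikelihood:
    def test_two_taxon_jc_matches_closed_form(self):
        """L = prod over sites of pi * p_same/diff(d) under Jukes-Cantor."""
        aln = {"A": "ACGTACGTAC", "B": "ACGTACTTAG"}  # 8 same, 2 diff
        d = 0.37
        t = Tree.from_newick(f"(A:{d / 2},B:{d / 2});")
        ll = tr.gtr_loglik(t, aln, tr.SubstitutionModel())
        p_same = 0.25 + 0.75 * np.exp(-4 * d / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * d / 3)
        expected = 8 * np.log(0.25 * p_same) + 2 * np.log(0.25 * p_diff)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_rerooting_leaves_loglik_unchanged(self):
        t = sd.simulate_species_tree(7, seed=21)
        aln = sd.simulate_nucleotide_sites(t, 300, rate=0.4, seed=22)
        model = tr.SubstitutionModel(exchangeabilities=(1, 2, 1, 1, 2, 1),
                                     freqs=(0.4, 0.1, 0.2, 0.3), alpha=0.6)
        base = tr.gtr_loglik(t, aln, model)
        for leaf in ("T01", "T04", "T07"):
            rr = t.reroot_on_edge(t.find_leaf(leaf), 0.3)
            assert tr.gtr_loglik(rr, aln, model) == \
                pytest.approx(base, rel=1e-8)

    def test_duplicating_sites_doubles_loglik(self):
        t = sd.simulate_species_tree(5, seed=31)
        aln = sd.simulate_nucleotide_sites(t, 100, rate=0.4, seed=32)
        ll = tr.gtr_loglik(t, aln, tr.SubstitutionModel())
        ll2 = tr.gtr_loglik(t, {k: v + v for k, v in aln.items()},
                            tr.SubstitutionModel())
        assert ll2 == pytest.approx(2 * ll, rel=1e-10)

    def test_gaps_enter_as_missing(self):
        t = Tree.from_newick("(A:0.1,B:0.1);")
        ll_gap = tr.gtr_loglik(t, {"A": "A-", "B": "AC"},
                               tr.SubstitutionModel())
        ll_one = tr.gtr_loglik(t, {"A": "A", "B": "A"},
                               tr.SubstitutionModel())
        # the gapped column contributes the marginal likelihood of "C" = 1/4
        assert ll_gap == pytest.approx(ll_one + np.log(0.25), abs=1e-9)


class TestMlSearch:
    def test_recovers_simulated_topology(self):
        t = sd.simulate_species_tree(8, seed=41)
        aln = sd.simulate_nucleotide_sites(t, 2000, rate=0.4, seed=42)
        best, ll = tr.ml_search(aln, model=tr.SubstitutionModel(), seed=1)
        assert rf_distance(best, t.unroot()) == 0

    def test_start_at_true_tree_never_decreases_loglik(self):
        t = sd.simulate_species_tree(6, seed=51)
        aln = sd.simulate_nucleotide_sites(t, 500, rate=0.4, seed=52)
        model = tr.SubstitutionModel()
        start = t.unroot()
        for n in start.postorder():
            if n.parent is not None:
                n.length = max(n.length * 0.4, 1e-6)  # perturbed lengths
        ll_start = tr.gtr_loglik(start, aln, model)
        _, ll = tr.ml_search(aln, model=model, start=start, seed=1)
        assert ll >= ll_start - 1e-9

    def test_seeded_determinism(self):
        t = sd.simulate_species_tree(6, seed=61)
        aln = sd.simulate_nucleotide_sites(t, 300, rate=0.4, seed=62)
        t1, ll1 = tr.ml_search(aln, seed=5)
        t2, ll2 = tr.ml_search(aln, seed=5)
        assert ll1 == ll2 and t1.to_newick() == t2.to_newick()


class TestBootstrap:
    def test_strong_signal_gives_full_support(self):
        t = sd.simulate_species_tree(6, seed=71)
        aln = sd.simulate_nucleotide_sites(t, 3000, rate=0.4, seed=72)
        best, support = tr.bootstrap_support(aln, n_replicates=30, seed=7,
                                             model=tr.SubstitutionModel())
        assert support and all(v == 100.0 for v in support.values())
        for n in best.internal_nodes():
            if n.parent is not None and n.support is not None:
                assert n.support == 100.0

    def test_supports_bounded_and_deterministic(self):
        t = sd.simulate_species_tree(5, seed=81)
        aln = sd.simulate_nucleotide_sites(t, 120, rate=0.6, seed=82)
        _, s1 = tr.bootstrap_support(aln, n_replicates=20, seed=9)
        _, s2 = tr.bootstrap_support(aln, n_replicates=20, seed=9)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())

    def test_mp_builder_runs(self):
        t = sd.simulate_species_tree(5, seed=91)
        aln = sd.simulate_nucleotide_sites(t, 500, rate=0.4, seed=92)
        _, support = tr.bootstrap_support(aln, builder="mp",
                                          n_replicates=10, seed=3)
        assert all(0.0 <= v <= 100.0 for v in support.values())


class TestRooting:
    def test_root_unroot_roundtrip(self):
        t = sd.simulate_species_tree(6, seed=95).unroot()
        rooted = tr.root_with_outgroup(t, "T03")
        assert len(rooted.root.children) == 2
        assert rf_distance(rooted.unroot(), t) == 0

    def test_missing_outgroup_raises(self):
        t = sd.simulate_species_tree(5, seed=96)
        with pytest.raises(KeyError):
            tr.root_with_outgroup(t, "nope")
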