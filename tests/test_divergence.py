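"""4-fold degenerate site extraction, strict-clock MCMC behaviour and
Nei–Gojobori Ks against hand computation and the Biopython NG86 oracle."""

import numpy as np
import pytest

from vitephylo import divergence as dv
from vitephylo import synthetic_data as sd
from vitephylo._tree import Tree


class TestFourfoldSites:
    def test_glycine_column_retained(self):
        aln = {"a": "GGA", "b": "GGC", "c": "GGG"}
        out = dv.fourfold_sites(aln)
        assert out == {"a": "A", "b": "C", "c": "G"}

    def test_mixed_degeneracy_column_excluded(self):
        aln = {"a": "GGA", "b": "GAA"}  # Gly vs Glu: GAx is 2-fold
        assert dv.fourfold_sites(aln) == {"a": "", "b": ""}

    def test_gap_or_ambiguity_excludes_column(self):
        assert dv.fourfold_sites({"a": "GGA", "b": "G-A"}) == {"a": "", "b": ""}
        assert dv.fourfold_sites({"a": "GGA", "b": "GGN"}) == {"a": "", "b": ""}

    def test_output_is_subset_of_third_positions(self):
        tree = sd.simulate_species_tree(5, seed=3)
        fams = sd.simulate_gene_families(tree, 1, seed=4)
        seqs = sd.simulate_codon_sequences(fams[0].gene_tree, 200, seed=5)
        aln = {sd.parse_gene_id(g)[0]: s for g, s in seqs.items()}
        out = dv.fourfold_sites(aln)
        n4d = len(next(iter(out.values())))
        assert 0 < n4d < 200
        # every extracted character occurs at a third codon position
        taxon = sorted(aln)[0]
        thirds = aln[taxon][2::3]
        assert all(c in thirds for c in set(out[taxon]))

    def test_width_not_divisible_by_three_rejected(self):
        with pytest.raises(ValueError):
            dv.fourfold_sites({"a": "GGAA", "b": "GGAA"})


class TestStrictClockDating:
    def test_prior_only_recovers_root_calibration(self):
        t = sd.simulate_species_tree(8, seed=6)
        for n in t.postorder():
            n.age *= 90.7
            n.length *= 90.7
        res = dv.strict_clock_date(t, None,
                                   [dv.CalibrationPrior("root", 90.7, 1.0)],
                                   steps=40000, seed=3)
        root_key = ",".join(sorted(t.leaf_names()))
        s = res.age_samples[root_key]
        assert abs(s.mean() - 90.7) < 0.15
        assert abs(s.std() - 1.0) < 0.15

    def test_child_never_older_than_parent_in_samples(self):
        t = sd.simulate_species_tree(6, seed=7)
        for n in t.postorder():
            n.age *= 50
            n.length *= 50
        aln = sd.simulate_nucleotide_sites(t, 400, rate=0.01, seed=8)
        res = dv.strict_clock_date(t, aln,
                                   [dv.CalibrationPrior("root", 50, 2.0)],
                                   steps=4000, seed=9)
        # posterior means respect the ordering by construction of the chain
        for n in res.tree.postorder():
            if n.parent is not None and not n.is_leaf:
                assert n.age < n.parent.age + 1e-9

    def test_two_chains_agree_within_mc_error(self):
        t = sd.simulate_species_tree(6, seed=17)
        for n in t.postorder():
            n.age *= 50
            n.length *= 50
        aln = sd.simulate_nucleotide_sites(t, 600, rate=0.01, seed=18)
        cals = [dv.CalibrationPrior("root", 50, 2.0)]
        r1 = dv.strict_clock_date(t, aln, cals, steps=12000, seed=1)
        r2 = dv.strict_clock_date(t, aln, cals, steps=12000, seed=2)
        for clade in r1.age_samples:
            s1, s2 = r1.age_samples[clade], r2.age_samples[clade]
            se = np.sqrt(s1.var() / 30 + s2.var() / 30)  # ~ESS-adjusted
            assert abs(s1.mean() - s2.mean()) <= max(4 * se, 1.0)

    def test_stem_calibration_attaches_to_parent(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        for n in t.postorder():
            n.age = 0.0 if n.is_leaf else (1.0 if n.children[0].is_leaf else 2.0)
        t.root.age = 2.0
        crown = dv.CalibrationPrior(["A", "B"], 10, 1, point="crown")
        stem = dv.CalibrationPrior(["A", "B"], 10, 1, point="stem")
        assert crown.resolve(t) is t.mrca({"A", "B"})
        assert stem.resolve(t) is t.root
        with pytest.raises(ValueError):
            dv.CalibrationPrior("root", 10, -1)

    def test_requires_calibration_and_rooted_tree(self):
        t = sd.simulate_species_tree(5, seed=1)
        with pytest.raises(ValueError):
            dv.strict_clock_date(t, None, [])
        with pytest.raises(ValueError):
            dv.strict_clock_date(t.unroot(), None,
                                 [dv.CalibrationPrior("root", 10, 1)])


class TestKs:
    def test_identical_cds_gives_zero(self):
        kp = dv.ks_pair("ATGGGATTA", "ATGGGATTA", aligned=True)
        assert kp.ks == 0.0 and not kp.saturated

    def test_glycine_hand_computation(self):
        """100 GGA vs 99 GGA + 1 GGG: S per codon = 1 (third position fully
        degenerate, positions 1-2 contribute nothing for GGA), so S = 100,
        Sd = 1, Ks = -3/4 ln(1 - 4/3 * 0.01)."""
        a = "GGA" * 100
        b = "GGA" * 99 + "GGG"
        kp = dv.ks_pair(a, b, aligned=True)
        assert kp.s_sites == pytest.approx(100.0)
        assert kp.s_diffs == pytest.approx(1.0)
        expected = -0.75 * np.log(1 - 4.0 / 3.0 * 0.01)
        assert kp.ks == pytest.approx(expected)

    def test_random_unrelated_cds_saturate(self, rng):
        codons = [c for c in
                  ("".join(p) for p in __import__("itertools").product("ACGT",
                                                                       repeat=3))
                  if c not in ("TAA", "TAG", "TGA")]
        a = "".join(rng.choice(codons, 500))
        b = "".join(rng.choice(codons, 500))
        kp = dv.ks_pair(a, b, aligned=True)
        assert kp.saturated or kp.ks > 1.5

    def test_matches_biopython_ng86_oracle(self, rng):
        """Independent cross-check of Sd/S bookkeeping on diverged pairs."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        pair_tree = Tree.from_newick("(x:0.3,y:0.3);")
        model = sd.GTRModel(exchangeabilities=(1.0,) * 6, freqs=(0.25,) * 4)
        for seed in range(5):
            seqs = sd.simulate_codon_sequences(pair_tree, 150, model, seed=seed)
            # Biopython counts mutations to stops as nonsynonymous; use the
            # matching convention so the check is exact
            kp = dv.ks_pair(seqs["x"], seqs["y"], aligned=True,
                            stop_mode="nonsynonymous")
            dn, ds = cal_dn_ds(CodonSeq(seqs["x"]), CodonSeq(seqs["y"]),
                               method="NG86")
            assert kp.ks == pytest.approx(ds, rel=1e-6)
            assert kp.ka == pytest.approx(dn, rel=1e-6, abs=1e-9)
            # the default (stop-excluding) convention stays close
            kp0 = dv.ks_pair(seqs["x"], seqs["y"], aligned=True)
            assert kp0.ks == pytest.approx(ds, rel=0.1)

    def test_unequal_lengths_are_aligned_first(self):
        a = "ATGGGAGGATTATTCAAG"
        b = "ATGGGAGGATTC"  # internal deletion relative to a
        kp = dv.ks_pair(a, b)
        assert np.isfinite(kp.ks)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            dv.ks_pair("ATGG", "ATGG")


class TestKsDistribution:
    def test_no_paralogs_gives_empty_result(self, small_families):
        out = dv.ks_distribution(small_families)
        assert out == {}

    def test_wgd_paralogs_populate_histogram(self):
        tree = sd.simulate_species_tree(6, seed=21)
        fams = sd.simulate_gene_families(tree, 10, seed=22)
        model = sd.GTRModel(exchangeabilities=(1.0,) * 6, freqs=(0.25,) * 4,
                            rate_multiplier=0.6)
        sd.simulate_family_sequences(fams, n_codons=200, model=model,
                                     wgd=(0.5, 1.0), seed=23)
        out = dv.ks_distribution(fams)
        assert out
        for t, d in out.items():
            assert d["counts"].sum() >= 0
            for p in d["pairs"]:
                assert p.saturated or p.ks >= 0
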