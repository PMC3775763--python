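"""Generator truth: ultrametricity, duplication/loss bookkeeping, codon-model
stationarity, degradation artifacts and truth-map completeness."""

import numpy as np
import pytest

from vitephylo import supermatrix as sm
from vitephylo import synthetic_data as sd
from vitephylo._codons import NUC_INDEX, SENSE_CODONS


def _leaf_depths(tree):
    out = []

    def walk(n, d):
        if n.is_leaf:
            out.append(d)
        for c in n.children:
            walk(c, d + c.length)

    walk(tree.root, 0.0)
    return out


def test_species_tree_is_ultrametric_with_requested_root_age():
    t = sd.simulate_species_tree(15, root_age=2.5, seed=0)
    assert t.n_leaves == 15
    depths = _leaf_depths(t)
    assert np.allclose(depths, 2.5)
    assert t.root.age == pytest.approx(2.5)


def test_species_tree_seeded_determinism_and_validation():
    a = sd.simulate_species_tree(10, seed=42)
    b = sd.simulate_species_tree(10, seed=42)
    assert a.to_newick() == b.to_newick()
    with pytest.raises(ValueError):
        sd.simulate_species_tree(2)


def test_internal_ages_below_root_in_every_replicate():
    for seed in range(300):
        t = sd.simulate_species_tree(6, seed=seed)
        for n in t.postorder():
            if n.parent is not None and not n.is_leaf:
                assert 0 < n.age < t.root.age


def test_no_duplication_no_loss_gives_congruent_single_copy_families(
        species_tree):
    from vitephylo._tree import rf_distance
    fams = sd.simulate_gene_families(species_tree, 10, dup_rate=0.0,
                                     loss_rate=0.0, seed=5)
    assert all(f.single_copy for f in fams)
    for f in fams:
        relabelled = f.gene_tree.copy()
        for leaf in relabelled.leaves():
            leaf.name = sd.parse_gene_id(leaf.name)[0]
        assert rf_distance(relabelled.unroot(), species_tree.unroot()) == 0


def test_duplications_make_multicopy_families(species_tree):
    fams = sd.simulate_gene_families(species_tree, 500, dup_rate=0.1,
                                     loss_rate=0.0, seed=6)
    assert any(max(f.counts.values()) >= 2 for f in fams)
    # duplication nodes are labelled
    multi = [f for f in fams if not f.single_copy]
    assert any(n.name == "dup" for f in multi
               for n in f.gene_tree.postorder() if not n.is_leaf)


def test_single_copy_fraction_nonincreasing_in_dup_rate(species_tree):
    fracs = []
    for dup in (0.0, 0.1, 0.4):
        vals = []
        for seed in range(3):
            fams = sd.simulate_gene_families(species_tree, 100, dup_rate=dup,
                                             loss_rate=0.0, seed=seed)
            vals.append(np.mean([f.single_copy for f in fams]))
        fracs.append(np.mean(vals))
    assert fracs[0] >= fracs[1] >= fracs[2]
    assert fracs[0] == 1.0


def test_zero_branch_lengths_copy_root_sequence():
    from vitephylo._tree import Tree
    t = Tree.from_newick("(A:0,B:0,C:0);")
    seqs = sd.simulate_codon_sequences(t, 50, seed=1)
    vals = list(seqs.values())
    assert vals[0] == vals[1] == vals[2]
    assert len(vals[0]) == 150


def test_codon_sequences_seeded_determinism(species_tree):
    fams = sd.simulate_gene_families(species_tree, 1, seed=2)
    a = sd.simulate_codon_sequences(fams[0].gene_tree, 40, seed=9)
    b = sd.simulate_codon_sequences(fams[0].gene_tree, 40, seed=9)
    assert a == b


def test_long_branch_base_frequencies_approach_stationarity():
    """Law of large numbers: after a long branch the empirical base
    composition matches the stationary distribution of the sense-codon
    chain (product measure restricted to sense codons)."""
    from vitephylo._tree import Tree
    model = sd.GTRModel()
    t = Tree.from_newick("(A:30,B:30);")
    seqs = sd.simulate_codon_sequences(t, 100000, model, seed=3)
    sampler = sd._CodonSampler(model)
    stat_base = np.zeros(4)
    for codon, w in zip(SENSE_CODONS, sampler.stationary):
        for b in codon:
            stat_base[NUC_INDEX[b]] += w / 3.0
    seq = seqs["A"]
    emp = np.array([seq.count(b) for b in "ACGT"]) / len(seq)
    assert np.abs(emp - stat_base).max() < 0.01


def test_invalid_frequencies_rejected():
    with pytest.raises(ValueError):
        sd.GTRModel(freqs=(0.5, 0.5, 0.5, 0.5))


def test_wgd_inserts_retained_duplicates(species_tree):
    fams = sd.simulate_gene_families(species_tree, 20, seed=4)
    sd.simulate_family_sequences(fams, n_codons=30, wgd=(0.5, 1.0), seed=5)
    # with full retention every family duplicates at the WGD age
    assert all(max(f.counts.values()) >= 2 for f in fams)
    assert all(not f.single_copy for f in fams)


def test_degrade_identity_when_no_masking(small_families):
    res = sd.degrade_and_emit(small_families, missing_fraction=0.0, seed=1)
    for fam in small_families:
        for g, s in fam.sequences.items():
            assert res.transcripts[g] == s


def test_reads_have_requested_length_and_truth_map_complete(small_families,
                                                            tmp_path):
    res = sd.degrade_and_emit(small_families, outdir=tmp_path,
                              read_pairs=200, read_length=90, seed=2)
    assert res.fastq_paths is not None
    for _, (m1, m2) in res.reads:
        assert len(m1[0]) == 90 and len(m2[0]) == 90
        assert len(m1[1]) == 90 and len(m2[1]) == 90
    # every emitted sequence is traceable to (taxon, family, copy)
    emitted = set(res.transcripts)
    mapped = {row[2] for row in res.truth_rows}
    assert emitted == mapped
    assert (tmp_path / "truth_map.tsv").exists()
    assert (tmp_path / "reads_1.fastq").exists()


def test_masking_sixty_percent_fails_downstream_missing_filter(small_families):
    """A gene masked to 60% in one taxon must fail the 50%-missing rule."""
    fam = small_families[0]
    gid = sorted(fam.sequences)[0]
    taxon = sd.parse_gene_id(gid)[0]
    res = sd.degrade_and_emit([fam], mask_overrides={(taxon, gid): 0.6}, seed=3)
    taxa = sorted({sd.parse_gene_id(g)[0] for g in fam.sequences})
    width = len(next(iter(fam.sequences.values())))
    rows = {}
    for g, s in res.transcripts.items():
        tx = sd.parse_gene_id(g)[0]
        rows[tx] = s + "-" * (width - len(s))
    ga = sm.GeneAlignment(fam.family_id, rows)
    retained, log = sm.filter_genes_by_missing([ga], taxa)
    assert retained == []
    assert log[0][1] == [taxon]


def test_degrade_rejects_bad_fraction(small_families):
    with pytest.raises(ValueError):
        sd.degrade_and_emit(small_families, missing_fraction=1.0)
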