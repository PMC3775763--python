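"""Read filtering boundaries, contig filtering, redundancy collapse and CDS
extraction against known synthetic coding regions."""

import numpy as np
import pytest

from vitephylo import preprocess as pp
from vitephylo import synthetic_data as sd


def _read(id, bases, quals):
    return pp.ReadRecord(id, bases, quals)


class TestFilterReads:
    def test_low_quality_boundary_is_strict(self):
        # exactly 40 bases at/below threshold: kept; 41: discarded
        keep = _read("k", "A" * 90, [7] * 40 + [30] * 50)
        drop = _read("d", "A" * 90, [7] * 41 + [30] * 49)
        kept, log = pp.filter_reads([keep, drop])
        assert [r.id for r in kept] == ["k"]
        assert log[0][0] == "d" and "low_quality" in log[0][1]

    def test_n_fraction_boundary_is_strict(self):
        # 18/90 = 20% exactly -> kept; 19 -> discarded
        keep = _read("k", "N" * 18 + "A" * 72, [30] * 90)
        drop = _read("d", "N" * 19 + "A" * 71, [30] * 90)
        kept, log = pp.filter_reads([keep, drop])
        assert [r.id for r in kept] == ["k"]
        assert "n_fraction" in log[0][1]

    def test_clean_read_kept(self):
        kept, log = pp.filter_reads([_read("x", "ACGT" * 10, [40] * 40)])
        assert len(kept) == 1 and not log

    def test_malformed_record_names_read(self):
        with pytest.raises(ValueError, match="bad_read"):
            pp.filter_reads([_read("bad_read", "ACGT", [30] * 3)])

    def test_idempotence(self, rng):
        reads = []
        for i in range(200):
            n = int(rng.integers(50, 120))
            bases = "".join(rng.choice(list("ACGTN"), n))
            quals = rng.integers(2, 41, n).tolist()
            reads.append(_read(f"r{i}", bases, quals))
        once, _ = pp.filter_reads(reads)
        twice, log2 = pp.filter_reads(once)
        assert [r.id for r in twice] == [r.id for r in once]
        assert not log2


class TestFilterContigs:
    def test_length_boundary_inclusive(self):
        ts = [pp.Transcript("a", "t1", "A" * 150),
              pp.Transcript("b", "t1", "A" * 149)]
        kept = pp.filter_contigs(ts)
        assert [t.id for t in kept] == ["a"]

    def test_empty_input_and_order(self):
        assert pp.filter_contigs([]) == []
        ts = [pp.Transcript(i, "t", "A" * (150 + k))
              for k, i in enumerate("zyx")]
        assert [t.id for t in pp.filter_contigs(ts)] == ["z", "y", "x"]


class TestCollapseRedundant:
    def test_identical_pair_collapses_to_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        ts = [pp.Transcript("a", "t", seq), pp.Transcript("b", "t", seq)]
        kept = pp.collapse_redundant(ts)
        assert len(kept) == 1 and kept[0].id == "a"  # length tie -> id order

    def test_unrelated_sequences_both_kept(self, rng):
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        kept = pp.collapse_redundant([pp.Transcript("a", "t", a),
                                      pp.Transcript("b", "t", b)])
        assert len(kept) == 2

    def test_exact_substring_dropped(self, rng):
        big = "".join(rng.choice(list("ACGT"), 900))
        ts = [pp.Transcript("big", "t", big),
              pp.Transcript("sub", "t", big[200:500])]
        kept = pp.collapse_redundant(ts)
        assert [t.id for t in kept] == ["big"]


@pytest.fixture(scope="module")
def reference():
    fams = sd.simulate_gene_families(
        sd.simulate_species_tree(4, seed=1), 3, seed=2)
    sd.simulate_family_sequences(fams, n_codons=80, seed=3)
    seqs = {}
    for f in fams:
        g = sorted(f.sequences)[0]
        seqs[g] = f.sequences[g]
    return {g: sd.translate_cds(s) for g, s in seqs.items()}, seqs


class TestExtractCds:

    def test_exact_in_frame_copy_found(self, reference, rng):
        prots, cds = reference
        gid = sorted(cds)[0]
        flank5 = "".join(rng.choice(list("ACGT"), 7))
        tx = pp.Transcript("tx1", "t", flank5 + cds[gid] + "TAAGG")
        res = pp.extract_cds(tx, prots)
        assert res is not None
        assert res.strand == "+"
        assert cds[gid] in res.cds or res.cds in (flank5 + cds[gid])
        assert res.protein.endswith(prots[gid]) or prots[gid] in res.protein
        res.validate()

    def test_reverse_complement_recovers_minus_strand(self, reference, rng):
        prots, cds = reference
        gid = sorted(cds)[0]
        comp = str.maketrans("ACGT", "TGCA")
        tx_fwd = "".join(rng.choice(list("ACGT"), 5)) + cds[gid]
        tx = pp.Transcript("tx2", "t", tx_fwd.translate(comp)[::-1])
        res = pp.extract_cds(tx, prots)
        assert res is not None and res.strand == "-"
        assert prots[gid] in res.protein

    def test_random_transcript_yields_none(self, reference, rng):
        prots, _ = reference
        junk = "".join(rng.choice(list("ACGT"), 400))
        res = pp.extract_cds(pp.Transcript("tx3", "t", junk), prots,
                             min_score=120)
        assert res is None

    def test_recovers_true_frame_and_length_without_degradation(self,
                                                                reference):
        prots, cds = reference
        for gid, seq in cds.items():
            res = pp.extract_cds(pp.Transcript(gid, "t", seq), prots)
            assert res is not None
            assert res.frame == 0 and res.strand == "+"
            assert len(res.cds) >= 0.95 * len(seq)

    def test_too_short_transcript(self, reference):
        prots, _ = reference
        assert pp.extract_cds(pp.Transcript("s", "t", "AC"), prots) is None


# ---------------------------------------------------------------- properties
from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.tuples(st.text(alphabet="ACGTN", min_size=1, max_size=60),
                          st.integers(0, 41)), min_size=0, max_size=20))
def test_filter_reads_keeps_only_reads_passing_both_rules(spec_list):
    """Every kept read satisfies both screening rules; every discarded read
    violates at least one."""
    reads = [pp.ReadRecord(f"r{i}", bases, [q] * len(bases))
             for i, (bases, q) in enumerate(spec_list)]
    kept, log = pp.filter_reads(reads)
    assert len(kept) + len(log) == len(reads)
    for r in kept:
        n_low = sum(1 for q in r.qualities if q <= 7)
        assert n_low <= 40
        assert r.bases.count("N") / len(r.bases) <= 0.20
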