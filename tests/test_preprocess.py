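"""Clean-read criteria, adapter trimming, hierarchical species mapping."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from seednet import (
    SmallRNARead,
    composition_report,
    count_features,
    filter_reads,
    generate_reads,
    map_reads_hierarchical,
    trim_adapter,
)
from seednet.preprocess import QcReport

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _read(seq, quals=None, rid="r1"):
    quals = quals if quals is not None else [30] * len(seq)
    return SmallRNARead(rid, seq, tuple(quals))


def _rec(rid, seq):
    return SeqRecord(Seq(seq), id=rid)


class TestFilterReads:
    def test_clean_read_is_kept(self):
        kept, qc = filter_reads([_read("ACGT" * 5)], adapter=ADAPTER)
        assert len(kept) == 1 and qc.kept == 1

    def test_short_insert_discarded_by_length(self):
        # 10-nt insert followed by adapter: post-trim 10 < 17
        kept, qc = filter_reads([_read("ACGTACGTAC" + ADAPTER)], adapter=ADAPTER)
        assert kept == [] and qc.discarded_length == 1

    def test_low_quality_discarded(self):
        # 7 of 20 bases (35%) below Q20
        quals = [15] * 7 + [30] * 13
        kept, qc = filter_reads([_read("ACGT" * 5, quals)], adapter=ADAPTER)
        assert kept == [] and qc.discarded_quality == 1

    def test_exactly_30_percent_low_quality_is_kept(self):
        # the rule is strict: discard only when the fraction exceeds 0.30
        quals = [10] * 6 + [30] * 14
        kept, _ = filter_reads([_read("ACGT" * 5, quals)], adapter=ADAPTER)
        assert len(kept) == 1

    def test_adapter_only_read(self):
        kept, qc = filter_reads([_read(ADAPTER + "ACG")], adapter=ADAPTER)
        assert kept == [] and qc.discarded_adapter_only == 1

    def test_conservation_identity_on_random_reads(self, rng):
        reads = []
        for i in range(500):
            n = int(rng.integers(8, 40))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            if rng.random() < 0.3:
                seq = seq[:8] + ADAPTER[:10]
            quals = rng.integers(2, 41, size=len(seq)).tolist()
            reads.append(SmallRNARead(f"r{i}", seq, tuple(quals)))
        kept, qc = filter_reads(reads, adapter=ADAPTER)
        assert (
            qc.total_raw
            == qc.kept + qc.discarded_quality + qc.discarded_length + qc.discarded_adapter_only
        )
        assert qc.kept == len(kept)

    def test_quality_length_mismatch_names_read(self):
        with pytest.raises(ValueError, match="rX"):
            SmallRNARead("rX", "ACGT", (30, 30))


class TestTrimAdapter:
    def test_insert_plus_adapter_yields_insert(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        r = trim_adapter(_read(insert + ADAPTER), ADAPTER)
        assert r.sequence == insert and len(r.qualities) == len(insert)

    def test_no_adapter_unchanged(self):
        r = _read("ACGTACGTACGTACGTACGT")
        assert trim_adapter(r, ADAPTER) == r

    def test_adapter_at_position_zero_empties_read(self):
        r = trim_adapter(_read(ADAPTER), ADAPTER)
        assert r.sequence == "" and r.qualities == ()

    def test_only_first_8nt_of_adapter_matter(self):
        insert = "ACGTACGTACGTACGTAC"
        r = trim_adapter(_read(insert + ADAPTER[:8] + "NNNN"), ADAPTER)
        assert r.sequence == insert


class TestHierarchicalMapping:
    SEQ = "ACGGUUACGGAUCCGGAAUUCGAU"  # 24 nt

    def _refs(self):
        dre = [_rec("dre-miR-1", self.SEQ), _rec("dre-miR-2", "UGCAUGCAUGCAUGCAUGCAUGCA")]
        rno = [_rec("rno-miR-9", "CCCGGGAAAUUUCCCGGGAAAUUU")]
        mmu = [_rec("mmu-miR-5", self.SEQ)]  # same sequence as dre-miR-1
        return [("dre", dre), ("rno", rno), ("mmu", mmu)]

    def test_first_species_wins(self):
        reads = [_read(self.SEQ.replace("U", "T"))]
        assignments, unmapped = map_reads_hierarchical(reads, self._refs())
        assert unmapped == []
        a = assignments[0]
        assert a.mirna_id == "dre-miR-1" and a.species == "dre" and not a.cross_species

    def test_cross_species_tagged(self):
        reads = [_read("CCCGGGAAATTTCCCGGGAAATTT")]
        assignments, _ = map_reads_hierarchical(reads, self._refs())
        assert assignments[0].species == "rno" and assignments[0].cross_species

    def test_unmapped_complement(self):
        reads = [_read("T" * 24)]
        assignments, unmapped = map_reads_hierarchical(reads, self._refs())
        assert assignments == [] and len(unmapped) == 1

    def test_containment_works_both_directions(self):
        sub = self.SEQ[2:21].replace("U", "T")  # 19-nt read inside the reference
        sup = (self.SEQ + "ACG").replace("U", "T")  # read containing the reference
        assignments, _ = map_reads_hierarchical([_read(sub), _read(sup)], self._refs())
        assert [a.mirna_id for a in assignments] == ["dre-miR-1", "dre-miR-1"]
        assert [a.overlap for a in assignments] == [19, 24]

    def test_below_min_overlap_not_mapped(self):
        short = self.SEQ[:16].replace("U", "T")
        assignments, unmapped = map_reads_hierarchical([_read(short)], self._refs())
        assert assignments == [] and len(unmapped) == 1

    def test_tie_breaks_lexicographically(self):
        refs = [("dre", [_rec("dre-miR-b", self.SEQ), _rec("dre-miR-a", self.SEQ)])]
        assignments, _ = map_reads_hierarchical([_read(self.SEQ.replace("U", "T"))], refs)
        assert assignments[0].mirna_id == "dre-miR-a"

    def test_read_order_independent(self, rng):
        reads = [
            _read(self.SEQ.replace("U", "T"), rid="a"),
            _read("CCCGGGAAATTTCCCGGGAAATTT", rid="b"),
            _read("T" * 24, rid="c"),
        ]
        fwd, _ = map_reads_hierarchical(reads, self._refs())
        rev, _ = map_reads_hierarchical(reads[::-1], self._refs())
        assert {a.read_id: a.mirna_id for a in fwd} == {a.read_id: a.mirna_id for a in rev}

    def test_one_mismatch_tolerance_knob(self):
        mutated = ("T" + self.SEQ[1:]).replace("U", "T")
        exact, _ = map_reads_hierarchical([_read(mutated)], self._refs())
        loose, _ = map_reads_hierarchical([_read(mutated)], self._refs(), max_mismatches=1)
        assert exact == []
        assert loose[0].mirna_id == "dre-miR-1" and loose[0].mismatches == 1

    def test_empty_reference_fails(self):
        with pytest.raises(ValueError):
            map_reads_hierarchical([], [])


class TestCountsAndComposition:
    def test_tally(self):
        from seednet.preprocess import ReadAssignment

        mk = lambda rid, mid: ReadAssignment(rid, mid, "dre", 20, 0, False)
        col = count_features([mk("r1", "m1"), mk("r2", "m1"), mk("r3", "m1"), mk("r4", "m2")], "s")
        assert col.to_dict() == {"m1": 3, "m2": 1}
        assert col.sum() == 4

    def test_empty_assignments(self):
        col = count_features([], "s")
        assert col.empty

    def test_composition_fractions(self):
        qc = QcReport(sample="s", total_raw=120, kept=100, discarded_quality=20,
                      mapped_focal=80, mapped_cross=5, unmapped=15)
        rep = composition_report({"s": qc})
        row = rep.loc["s"]
        assert (row["frac_focal"], row["frac_cross_species"], row["frac_unmapped"]) == (
            0.80, 0.05, 0.15)
        assert abs(row[["frac_focal", "frac_cross_species", "frac_unmapped"]].sum() - 1) < 1e-9

    def test_zero_kept_flagged_degenerate(self):
        qc = QcReport(sample="s", total_raw=5, discarded_quality=5)
        rep = composition_report({"s": qc})
        assert rep.loc["s", "degenerate"]
        assert rep.loc["s", "frac_focal"] == 0.0


class TestSyntheticEndToEnd:
    """On generated reads with unique 17-mers every kept library read maps
    back to its source miRNA, and the contaminant fraction is recovered."""

    def test_reads_map_to_their_source(self, reference):
        abundance = {r.id: 30 for r in reference[:40]}
        recs = generate_reads(reference, abundance, contaminant_fraction=0.2, seed=31)
        reads = [
            SmallRNARead(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
            for r in recs
        ]
        kept, qc = filter_reads(reads, adapter=ADAPTER)
        refs = [("dre", [r for r in reference if r.id.startswith("dre")]),
                ("rno", [r for r in reference if r.id.startswith("rno")]),
                ("mmu", [r for r in reference if r.id.startswith("mmu")]),
                ("hsa", [r for r in reference if r.id.startswith("hsa")])]
        assignments, unmapped = map_reads_hierarchical(kept, refs)
        source = {}
        for r in reads:
            source[r.id] = r.id.split("|")[1]
        for a in assignments:
            assert a.mirna_id == source[a.read_id], "read mapped to a foreign miRNA"
        # every kept non-contaminant read is assigned
        kept_lib = [r for r in kept if source[r.id] != "contaminant"]
        assert len(assignments) == len(kept_lib)
        # observed contaminant (unmapped) fraction within 4 sigma of 0.2
        n, f = qc.kept, 0.2
        frac = len(unmapped) / n
        assert abs(frac - f) < 4 * np.sqrt(f * (1 - f) / n)
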