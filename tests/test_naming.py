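"""First-ATG ORF assignment, by-splicing variants and truncation calls."""

import logging

import pytest

from adenotx.classify import TranscriptClass, read_classes
from adenotx.genome import FeatureTable, Genome, OrfFeature, feature_protein, load_features
from adenotx.naming import (
    CODES_ORF,
    NONE_FROM_LIST,
    TRUNCATED,
    VARIANT_BYSPLICING,
    assign_orf,
    first_start_codon,
    name_classes,
    read_named,
    splice_sequence,
    translate,
    transcript_to_genomic,
    write_named,
)


class TestSequenceOps:
    GENOME = Genome("g", "ATGCCCGGGT")

    def test_splice_sequence_plus(self):
        assert splice_sequence(self.GENOME, [(0, 3), (6, 9)], "+") == "ATGGGG"

    def test_splice_sequence_minus_is_revcomp(self):
        assert splice_sequence(self.GENOME, [(0, 3), (6, 9)], "-") == "CCCCAT"

    def test_whole_genome_identity(self):
        assert splice_sequence(self.GENOME, [(0, 10)], "+") == self.GENOME.sequence

    @pytest.mark.parametrize(
        "seq,expected", [("CCATGA", 2), ("CCCCCC", None), ("ATGATG", 0)]
    )
    def test_first_start_codon(self, seq, expected):
        assert first_start_codon(seq) == expected

    @pytest.mark.parametrize(
        "seq,offset,prot,run_through",
        [
            ("ATGAAATAA", 0, "MK", False),
            ("ATGTGA", 0, "M", False),
            ("CCATGAAAAAA", 2, "MKK", True),
        ],
    )
    def test_translate(self, seq, offset, prot, run_through):
        assert translate(seq, offset) == (prot, run_through)

    def test_transcript_to_genomic_both_strands(self):
        blocks = [(0, 3), (6, 9)]
        assert [transcript_to_genomic(blocks, "+", i) for i in range(6)] == [0, 1, 2, 6, 7, 8]
        assert [transcript_to_genomic(blocks, "-", i) for i in range(6)] == [8, 7, 6, 2, 1, 0]


def _scenario_named(run):
    classes, samples = read_classes(run["outputs"]["classes"])
    named, _ = read_named(run["outputs"]["named_classes"])
    return classes, named, samples


def _match(named, iso, tss_window=50, end_window=30):
    hits = [
        nc for nc in named
        if nc.cls.strand == iso.strand and nc.cls.introns == iso.introns
        and abs(nc.cls.rep_start - iso.tss) <= tss_window
        and abs(nc.cls.rep_end - iso.polya_site) <= end_window
    ]
    assert len(hits) == 1, f"{iso.name}: {len(hits)} matching classes"
    return hits[0]


class TestScenarioAssignments:
    def test_late_precursor_class_codes_orf(self, sim):
        _, named, _ = _scenario_named(sim)
        spec = sim["spec"]
        nc = _match(named, next(i for i in spec.isoforms if i.name == "preVII"))
        assert (nc.category, nc.orf_name, nc.display_name) == (
            CODES_ORF, "preVII", "L2_preVII"
        )
        assert nc.protein_seq.startswith("M") and not nc.run_through

    def test_mature_variant_called_bysplicing(self, sim):
        _, named, _ = _scenario_named(sim)
        spec = sim["spec"]
        nc = _match(named, next(i for i in spec.isoforms if i.name == "VII_mat"))
        assert (nc.category, nc.display_name) == (VARIANT_BYSPLICING, "L2_VII_bysplicing")

    def test_mature_protein_is_cleaved_precursor_suffix(self, sim, sim_genome):
        """The by-splicing product equals the precursor product with its
        N-terminal segment through the cleavage-site methionine removed."""
        _, named, _ = _scenario_named(sim)
        spec = sim["spec"]
        nc = _match(named, next(i for i in spec.isoforms if i.name == "VII_mat"))
        pre = feature_protein(sim_genome, spec.features.get("preVII"))
        assert nc.protein_seq == pre[24:]  # internal Met at codon 24
        assert nc.protein_seq.startswith("M")

    def test_intergenic_decoy_is_none_from_list(self, sim):
        _, named, _ = _scenario_named(sim)
        spec = sim["spec"]
        nc = _match(named, next(i for i in spec.isoforms if i.name == "dInter"))
        assert nc.category == NONE_FROM_LIST

    def test_body_truncated_decoy_flagged_truncated(self, sim):
        _, named, _ = _scenario_named(sim)
        spec = sim["spec"]
        nc = _match(named, next(i for i in spec.isoforms if i.name == "dTrunc"))
        assert (nc.category, nc.orf_name) == (TRUNCATED, "hexon")

    def test_antisense_and_unnamed_never_coding(self, sim):
        """No minus-strand class inside the forward late unit gets a name."""
        _, named, _ = _scenario_named(sim)
        for nc in named:
            if nc.cls.strand == "-" and nc.cls.rep_end > 5000 and nc.cls.rep_start < 18000:
                assert nc.category in (NONE_FROM_LIST, TRUNCATED)

    def test_categories_partition_all_classes(self, sim):
        classes, named, samples = _scenario_named(sim)
        assert len(named) == len(classes)
        per_sample_total = {
            s: sum(nc.cls.counts.get(s, 0) for nc in named) for s in samples
        }
        expected = sim["spec"].reads_per_sample
        assert per_sample_total == expected


class TestBruteForceOracle:
    def test_codes_orf_agrees_with_translate_and_match(self, sim, sim_genome):
        """assign_orf's coding decision must equal a brute-force oracle that
        translates from the 5'-most ATG and string-matches the product
        against every catalogued ORF's protein."""
        classes, named, _ = _scenario_named(sim)
        features = load_features(sim["arts"]["features"], sim_genome)
        products = {feature_protein(sim_genome, f): f.name for f in features}
        for cls, nc in zip(classes, named):
            seq = splice_sequence(sim_genome, cls.blocks, cls.strand)
            off = first_start_codon(seq)
            if off is None:
                oracle = None
            else:
                prot, _ = translate(seq, off)
                oracle = products.get(prot)
            got = nc.orf_name if nc.category == CODES_ORF else None
            assert got == oracle, f"{cls.class_id}: oracle {oracle}, got {got}"


class TestIsolatedRules:
    GENOME = Genome(
        "g",
        "CC" + "ATG" + "AAA" + "TAA" + "CCCC"  # ORF1 at 2..11
        + "ATG" + "CAA" + "TAA" + "CC",        # ORF2 at 15..24
    )

    def _features(self, tss1=0, tss2=0):
        return FeatureTable(
            [
                OrfFeature("orf1", "E1A", "+", 2, 11, tss1, "early"),
                OrfFeature("orf2", "E1B", "+", 15, 24, tss2, "early"),
            ]
        )

    def test_overlapping_starts_resolved_by_expected_tss(self, caplog):
        features = FeatureTable(
            [
                OrfFeature("near", "E1A", "+", 2, 11, 1, "early"),
                OrfFeature("far", "E1B", "+", 2, 11, 0, "early"),
            ]
        )
        cls = TranscriptClass("c1", "+", (), rep_start=1, rep_end=12, counts={"s": 1})
        with caplog.at_level(logging.WARNING):
            nc = assign_orf(cls, features, self.GENOME)
        assert nc.orf_name == "near"
        assert any("several ORF starts" in r.message for r in caplog.records)

    def test_downstream_start_same_signature_is_truncated(self):
        """A class identical to a named class except for a far-downstream 5'
        end lands in the truncated bin (its first ATG is internal)."""
        features = self._features()
        parent_cls = TranscriptClass("c1", "+", (), rep_start=2, rep_end=24, counts={"s": 9})
        parent = assign_orf(parent_cls, features, self.GENOME)
        assert parent.category == CODES_ORF
        child = TranscriptClass("c2", "+", (), rep_start=16, rep_end=24, counts={"s": 1})
        nc = assign_orf(child, features, self.GENOME, parents=[parent], tss_window=5)
        assert (nc.category, nc.orf_name) == (TRUNCATED, "orf1")

    def test_named_table_round_trip(self, tmp_path, sim):
        named, samples = read_named(sim["outputs"]["named_classes"])
        out = tmp_path / "named.tsv"
        write_named(named, samples, out)
        again, samples2 = read_named(out)
        assert samples2 == samples
        assert [(n.cls, n.category, n.orf_name, n.display_name, n.protein_seq)
                for n in again] == \
               [(n.cls, n.category, n.orf_name, n.display_name, n.protein_seq)
                for n in named]
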