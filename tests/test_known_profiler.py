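"""Known-miRNA family grouping, representatives, 3' tails and precursors."""

from __future__ import annotations

import numpy as np
import pytest

from srnapipe._seq import revcomp
from srnapipe.genome_mapper import build_index
from srnapipe.known_profiler import (
    FamilyReference,
    MiRNAFamilyRecord,
    annotate_tail_variants,
    assign_family,
    build_family_records,
    classify_3prime_tail,
    locate_known_precursors,
    representative_sequences,
)
from srnapipe.sequence_io import CollapsedRead
from srnapipe.synthetic_data import SimulationParams, _build_validated_region

REF156 = "TGACAGAAGAGAGTGAGCACA"
REF172 = "AGAATCTTGATGATGCTGCAT"


def _refset():
    return FamilyReference(
        name="known_miRNA",
        sequences=[("156|a", REF156), ("172|a", REF172)],
        max_mismatches=2,
    )


class TestAssignFamily:
    def test_exact_match(self):
        read = CollapsedRead(REF156, {"l1": 1})
        assert assign_family(read, _refset()) == "156"

    def test_two_mismatches_accepted_three_rejected(self):
        two = "CC" + REF156[2:]
        three = "CCC" + REF156[3:]
        assert assign_family(CollapsedRead(two, {"l1": 1}), _refset()) == "156"
        assert assign_family(CollapsedRead(three, {"l1": 1}), _refset()) is None

    def test_equidistant_tie_breaks_to_more_abundant_family(self):
        refs = FamilyReference(
            "known_miRNA",
            [("aaa|x", "A" * 21), ("bbb|x", "A" * 20 + "C")],
            max_mismatches=2,
        )
        query = CollapsedRead("A" * 20 + "G", {"l1": 1})  # 1 mismatch to both
        assert assign_family(query, refs) == "aaa"  # lexicographic default
        assert assign_family(query, refs, family_abundance={"bbb": 10}) == "bbb"

    def test_family_totals_are_conserved(self):
        reads = [
            CollapsedRead(REF156, {"l1": 5, "l2": 2}),
            CollapsedRead("CC" + REF156[2:], {"l1": 1}),
            CollapsedRead(REF172, {"l2": 4}),
            CollapsedRead("G" * 21, {"l1": 9}),  # matches nothing
        ]
        records = build_family_records(reads, _refset())
        assigned_total = sum(r.total_count() for r in records.values())
        matching_total = sum(
            r.total_count
            for r in reads
            if assign_family(r, _refset()) is not None
        )
        assert assigned_total == matching_total == 12


class TestRepresentatives:
    def _record(self, counts_by_member):
        rec = MiRNAFamilyRecord(family="156")
        rec.members = counts_by_member
        return rec

    def test_uniform_dominance_no_divergence(self):
        rec = self._record({"X" : {"l1": 10, "l2": 8}, "Y": {"l1": 2, "l2": 1}})
        reps, divergent = representative_sequences(rec, ["l1", "l2"])
        assert reps == {"l1": "X", "l2": "X"} and not divergent

    def test_representative_switch_flags_divergence(self):
        rec = self._record({"X": {"l1": 10, "l2": 1}, "Y": {"l1": 2, "l2": 9}})
        reps, divergent = representative_sequences(rec, ["l1", "l2"])
        assert reps == {"l1": "X", "l2": "Y"} and divergent

    def test_single_member_family_never_diverges(self):
        rec = self._record({"X": {"l1": 3, "l2": 4}})
        _, divergent = representative_sequences(rec, ["l1", "l2"])
        assert not divergent

    def test_zero_count_library_reports_none(self):
        rec = self._record({"X": {"l1": 3}})
        reps, divergent = representative_sequences(rec, ["l1", "l2"])
        assert reps["l2"] is None and not divergent

    def test_scale_invariance(self):
        members = {"X": {"l1": 10, "l2": 2}, "Y": {"l1": 4, "l2": 7}}
        scaled = {s: {"l1": c["l1"] * 13, "l2": c["l2"]} for s, c in members.items()}
        a = representative_sequences(self._record(members), ["l1", "l2"])
        b = representative_sequences(self._record(scaled), ["l1", "l2"])
        assert a == b


class TestTailVariants:
    BODY = "TGAAGCTGCCAGCATGATCTC"

    def test_mono_adenylation_detected(self):
        var = classify_3prime_tail("UGAAGCUGCCAGCAUGAUCUCA", self.BODY)
        assert var is not None
        assert var.tail == "A" and var.is_adenylated

    def test_identical_read_has_empty_tail(self):
        var = classify_3prime_tail(self.BODY, self.BODY)
        assert var is not None and var.tail == ""

    def test_three_extra_nucleotides_rejected(self):
        assert classify_3prime_tail(self.BODY + "AAA", self.BODY) is None

    def test_shorter_read_is_not_a_variant(self):
        assert classify_3prime_tail(self.BODY[:-1], self.BODY) is None

    def test_variant_annotation_never_double_counts(self):
        rec = MiRNAFamilyRecord(family="167")
        rec.members = {
            self.BODY: {"l1": 10},
            self.BODY + "A": {"l1": 25},
        }
        variants = annotate_tail_variants(rec, [("167|a", self.BODY)])
        assert set(variants) == {self.BODY + "A"}
        assert len(rec.members) == 2  # the variant stays a single member


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(13)
    mature = "T" + "".join(rng.choice(list("ACGT"), 20))
    region, summit, _ = _build_validated_region(rng, mature, SimulationParams(), None)
    return mature, region, summit


class TestLocatePrecursors:

    def test_hairpin_context_yields_genome_locus(self, planted):
        mature, region, _ = planted
        rec = MiRNAFamilyRecord(family="x")
        rec.members = {mature: {"l1": 5}}
        dbs = {"genome": build_index({"c1": region})}
        loci = locate_known_precursors(rec, dbs)
        assert any(l.source_db == "genome" for l in loci)
        assert rec.arm[mature] in ("5p", "3p")

    def test_non_hairpin_context_yields_nothing(self, planted):
        mature, _, _ = planted
        rng = np.random.default_rng(14)
        flat = "".join(rng.choice(list("ACGT"), 300))
        genome = flat[:150] + mature + flat[150:]
        rec = MiRNAFamilyRecord(family="x")
        rec.members = {mature: {"l1": 5}}
        loci = locate_known_precursors(rec, {"genome": build_index({"c1": genome})})
        assert loci == []

    def test_mature_in_two_databases_reports_both_sources(self, planted):
        mature, region, _ = planted
        rec = MiRNAFamilyRecord(family="x")
        rec.members = {mature: {"l1": 5}}
        dbs = {
            "genome": build_index({"c1": region}),
            "EST": build_index({"est1": region}),
        }
        loci = locate_known_precursors(rec, dbs)
        assert {"genome", "EST"} <= {l.source_db for l in loci}


class TestOnSyntheticBundle:
    def test_planted_divergent_family_is_flagged(self, bundle, pipeline_result):
        rec = pipeline_result.family_records["mir172"]
        reps, divergent = representative_sequences(rec, list(bundle.truth.libraries))
        assert divergent
        assert reps["dpa20"] != reps["dpa05"]

    def test_planted_adenylated_variant_recovered(self, bundle, pipeline_result):
        rec = pipeline_result.family_records["mir167"]
        assert any(v.tail == "A" for v in rec.variants.values())

    def test_planted_extra_database_sources_found(self, pipeline_result):
        sources_396 = {l.source_db for l in pipeline_result.family_records["mir396"].precursors}
        sources_482 = {l.source_db for l in pipeline_result.family_records["mir482"].precursors}
        assert {"genome", "EST"} <= sources_396
        assert {"genome", "GSS"} <= sources_482
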