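"""Annotation-class assignment, mismatch matching and RPTM normalisation."""

from __future__ import annotations

import numpy as np
import pytest

from srnapipe.read_classifier import (
    ReferenceSet,
    classify_collapsed_reads,
    length_distribution,
    match_with_mismatches,
    rptm_normalize,
)
from srnapipe.sequence_io import CollapsedRead


def _brute_force_best(query: str, refs: list[str], max_mm: int):
    """Independent all-offsets Hamming scan (the oracle)."""
    best = None
    for ref in refs:
        short, long_ = (query, ref) if len(query) <= len(ref) else (ref, query)
        for off in range(len(long_) - len(short) + 1):
            mm = sum(a != b for a, b in zip(short, long_[off : off + len(short)]))
            if mm <= max_mm and (best is None or mm < best):
                best = mm
    return best


class TestMatchWithMismatches:
    def test_identity_hits_with_zero_mismatches(self):
        rs = ReferenceSet("known", [("m1", "TGGAGCTCCCTTCACTCCAAT")], 2)
        hit = match_with_mismatches("TGGAGCTCCCTTCACTCCAAT", rs)
        assert hit is not None and hit.mismatches == 0

    def test_three_substitutions_exceed_threshold(self):
        rs = ReferenceSet("known", [("m1", "A" * 21)], 2)
        assert match_with_mismatches("A" * 18 + "CCC", rs) is None

    def test_single_substitution(self):
        rs = ReferenceSet("known", [("m1", "TGAAGCTGCCAGCATGATCTG")], 2)
        hit = match_with_mismatches("TGAAGCTGCCAGCATGATCTA", rs)
        assert hit is not None and hit.mismatches == 1

    def test_rna_query_matches_dna_reference(self):
        rs = ReferenceSet("known", [("m1", "TGAAGCTGCCAGCATGATCTC")], 2)
        hit = match_with_mismatches("UGAAGCUGCCAGCAUGAUCUC", rs)
        assert hit is not None and hit.mismatches == 0

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            qlen = int(rng.integers(18, 25))
            rlen = int(rng.integers(18, 25))
            query = "".join(rng.choice(bases, qlen))
            ref = "".join(rng.choice(bases, rlen))
            if rng.random() < 0.5:  # force near-matches to exist sometimes
                ref = query[: min(qlen, rlen)]
                for pos in rng.choice(len(ref), size=int(rng.integers(0, 4)), replace=False):
                    ref = ref[:pos] + "ACGT"[int(rng.integers(4))] + ref[pos + 1 :]
            rs = ReferenceSet("c", [("r", ref)], 2)
            hit = match_with_mismatches(query, rs)
            oracle = _brute_force_best(query, [ref], 2)
            assert (hit.mismatches if hit else None) == oracle


class TestClassify:
    def _reads(self):
        return [
            CollapsedRead("TGGAGCTCCCTTCACTCCAAT", {"l1": 5}),  # known miRNA
            CollapsedRead("CCCTTTGGGAAACCCTTTGGGAAA", {"l1": 3}),  # rRNA fragment
            CollapsedRead("ATATATATGCGCGCGCATAT", {"l1": 2}),  # nothing
        ]

    def _refsets(self):
        return [
            ReferenceSet("known_miRNA", [("m1", "TGGAGCTCCCTTCACTCCAAT")], 2),
            ReferenceSet("rRNA", [("r1", "GG" + "CCCTTTGGGAAACCCTTTGGGAAA" + "TT")], 0),
        ]

    def test_precedence_order_wins(self):
        # a read matching both sets is labelled with the first refset
        read = CollapsedRead("TGGAGCTCCCTTCACTCCAAT", {"l1": 1})
        refsets = [
            ReferenceSet("known_miRNA", [("m1", read.sequence)], 2),
            ReferenceSet("rRNA", [("r1", read.sequence)], 0),
        ]
        _, labels = classify_collapsed_reads([read], refsets, ["l1"])
        assert labels[0].class_name == "known_miRNA"

    def test_unmatched_reads_fall_into_others(self):
        table, labels = classify_collapsed_reads(self._reads(), self._refsets(), ["l1"])
        assert labels[2].class_name == "others"
        assert table.total_reads["others"]["l1"] == 2

    def test_class_table_conservation(self):
        table, _ = classify_collapsed_reads(self._reads(), self._refsets(), ["l1"])
        table.check_conservation()  # raises on violation
        assert table.clean_total["l1"] == 10
        assert table.total_reads["known_miRNA"]["l1"] == 5

    def test_planted_class_counts_recovered(self, bundle, pipeline_result):
        """Every planted annotation-decoy read lands in its planted class."""
        truth = bundle.truth
        table = pipeline_result.class_table
        for cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "protein_coding"):
            n_unique = sum(
                1 for e in truth.entities if e.category == "annotation" and e.parent == cls
            )
            for lib in truth.libraries:
                assert table.unique_reads[cls][lib] <= n_unique
            assert sum(table.unique_reads[cls].values()) > 0
        table.check_conservation()

    def test_duplicate_class_labels_rejected(self):
        rs = ReferenceSet("x", [("a", "ACGT" * 6)], 0)
        with pytest.raises(ValueError):
            classify_collapsed_reads([], [rs, rs], ["l1"])


class TestRPTM:
    def test_zero_count(self):
        assert rptm_normalize(0, 100) == 0.0

    def test_full_library_is_ten_million(self):
        assert rptm_normalize(12345, 12345) == 1e7

    def test_reported_library_scale(self):
        # 307,112 known-miRNA reads in a 17,979,849-read library
        assert rptm_normalize(307_112, 17_979_849) == pytest.approx(170_809, abs=1)

    def test_zero_total_is_fatal(self):
        with pytest.raises(ValueError):
            rptm_normalize(1, 0)

    def test_rptm_sums_to_ten_million_over_whole_library(self):
        reads = [CollapsedRead(f"ACGT{'A' * 14}{b}", {"l1": n}) for b, n in
                 zip("ACGT", (5, 10, 2, 83))]
        total = sum(r.count_in("l1") for r in reads)
        s = sum(rptm_normalize(r.count_in("l1"), total) for r in reads)
        assert s == pytest.approx(1e7, abs=1e-3)


class TestLengthDistribution:
    def test_single_length(self):
        reads = [CollapsedRead("A" * 24, {"l1": 7})]
        assert length_distribution(reads, "l1") == {24: 1.0}

    def test_weighted_fractions(self):
        reads = [
            CollapsedRead("A" * 21, {"l1": 2}),
            CollapsedRead("C" * 21, {"l1": 1}),
            CollapsedRead("G" * 24, {"l1": 1}),
        ]
        dist = length_distribution(reads, "l1")
        assert dist == {21: 0.75, 24: 0.25}

    def test_empty_library(self):
        assert length_distribution([], "l1") == {}

    def test_planted_background_spectrum_recovered(self, bundle, pipeline_result):
        """The dominant planted background length (24 nt) dominates 'others'."""
        truth = bundle.truth
        weights = truth.params.background_length_weights
        for lib in truth.libraries:
            dist = pipeline_result.length_distributions[lib]
            assert sum(dist.values()) == pytest.approx(1.0)
        # among pure background lengths (23 vs 24 nt carry no planted reads
        # besides background), the planted ratio should be visible
        dist = pipeline_result.length_distributions[truth.libraries[0]]
        assert dist[24] > dist[23]
        assert weights[24] > weights[23]
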