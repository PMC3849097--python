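"""Folding, duplex geometry and the novel-miRNA acceptance rules."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe._seq import revcomp
from srnapipe.genome_mapper import GenomeHit, ReadLocus
from srnapipe.hairpin_miner import (
    Bulge,
    DuplexReport,
    FoldedPrecursor,
    PrecursorRead,
    apply_read_support_rule,
    call_novel_mirna,
    evaluate_duplex,
    extract_windows,
    fold_hairpin,
    tabulate_5prime_by_length,
)
from srnapipe.synthetic_data import (
    SimulationParams,
    _best_window_duplex,
    _build_validated_region,
)

# ---------------------------------------------------------------------------
# folding


class TestFold:
    def test_perfect_inverted_repeat_forms_long_stem(self):
        arm = "GCAGTCAGGTCACGGATCCAGTCAGGACGG"  # 30 nt
        seq = arm + "TTTCTT" + revcomp(arm)
        fp = fold_hairpin(seq)
        assert fp is not None
        assert fp.structure.count("(") >= 28
        # a single terminal loop: exactly one helix turn-around
        assert fp.structure.replace(".", "").count("()") == 1

    def test_homopolymer_has_no_base_pairs(self):
        fp = fold_hairpin("A" * 100)
        assert fp is not None
        assert set(fp.structure) == {"."}

    def test_folding_is_deterministic(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(np.array(list("ACGT")), 150))
        a, b = fold_hairpin(seq), fold_hairpin(seq)
        assert a.structure == b.structure and a.score == b.score

    def test_length_bounds_and_n_content(self):
        assert fold_hairpin("ACGT" * 5) is None  # below minimum length
        assert fold_hairpin("A" * 500) is None  # above maximum length
        assert fold_hairpin("N" * 30 + "ACGT" * 30) is None  # >10% N


# ---------------------------------------------------------------------------
# duplex geometry on hand-written dot-bracket fixtures (engine-independent)


def _perfect_hairpin():
    """23-bp stem, 6-nt loop; mature (2,23) on the 5' arm."""
    arm = "GCAGTCAGGTCACGGATCCAGTC"  # 23 nt
    seq = arm + "TTTCTT" + revcomp(arm)
    structure = "(" * 23 + "." * 6 + ")" * 23
    return FoldedPrecursor(seq, structure, -30.0)


class TestEvaluateDuplex:
    def test_perfect_duplex_has_clean_geometry(self):
        rep = evaluate_duplex(_perfect_hairpin(), (2, 23))
        assert rep.ok
        assert rep.mismatch_count == 0
        assert rep.bulges == []
        assert rep.star_overhang_ok
        assert rep.star_interval == (31, 52)
        assert rep.arm == "5p"

    def test_five_unpaired_body_positions_count_five_mismatches(self):
        fp = _perfect_hairpin()
        structure = list(fp.structure)
        for i in (5, 8, 11, 14, 17):  # open 1x1 symmetric loops
            structure[i] = "."
            structure[51 - i] = "."
        rep = evaluate_duplex(
            FoldedPrecursor(fp.sequence, "".join(structure), -20.0), (2, 23)
        )
        assert rep.mismatch_count == 5
        assert not rep.rule3_pass()  # "less than five" is strict

    def test_three_nt_asymmetric_bulge_fails_rule3(self):
        # 23-bp stem with 3 unpaired star-arm bases opposite mature 11/12
        arm = "GCAGTCAGGTCACGGATCCAGTC"
        seq = arm + "TTTCTT" + revcomp(arm)[:11] + "AAA" + revcomp(arm)[11:]
        structure = "(" * 23 + "." * 6 + ")" * 11 + "..." + ")" * 12
        rep = evaluate_duplex(FoldedPrecursor(seq, structure, -25.0), (2, 23))
        assert rep.mismatch_count == 0
        assert [(b.arm, b.size) for b in rep.bulges] == [("star", 3)]
        assert not rep.rule3_pass()

    def test_loop_spanning_mature_is_rejected(self):
        rep = evaluate_duplex(_perfect_hairpin(), (15, 36))
        assert not rep.ok
        assert rep.reject_reason == "loop-spanning"

    def test_unpaired_mature_is_rejected(self):
        fp = FoldedPrecursor("A" * 60, "." * 60, 0.0)
        rep = evaluate_duplex(fp, (5, 26))
        assert not rep.ok

    def test_symmetry_between_mature_and_star_roles(self):
        """Swapping mature and star gives the same mismatch/bulge counts."""
        fixtures = []
        fp = _perfect_hairpin()
        fixtures.append((fp, (2, 23), (31, 52)))
        arm = "GCAGTCAGGTCACGGATCCAGTC"
        seq = arm + "TTTCTT" + revcomp(arm)[:11] + "AAA" + revcomp(arm)[11:]
        structure = "(" * 23 + "." * 6 + ")" * 11 + "..." + ")" * 12
        fixtures.append((FoldedPrecursor(seq, structure, -25.0), (2, 23), (31, 55)))
        for fp, mature, star in fixtures:
            a = evaluate_duplex(fp, mature)
            b = evaluate_duplex(fp, star)
            assert a.mismatch_count == b.mismatch_count
            assert sorted(x.size for x in a.bulges) == sorted(x.size for x in b.bulges)


class TestRule3Boundaries:
    def _report(self, mismatches=0, bulges=()):
        return DuplexReport(
            mature_interval=(0, 21),
            star_interval=(40, 61),
            mismatch_count=mismatches,
            bulges=[Bulge("star", s) for s in bulges],
            star_overhang_ok=True,
        )

    @pytest.mark.parametrize(
        "mismatches,bulges,expected",
        [
            (4, (), True),  # just under the mismatch limit
            (5, (), False),  # at the limit: "less than five" is strict
            (0, (2,), True),  # bulge of 2 is allowed
            (0, (3,), False),  # "larger than two nucleotides"
            (0, (1, 2), True),  # two bulges allowed
            (0, (1, 1, 1), False),  # "no more than two asymmetric bulges"
        ],
    )
    def test_thresholds(self, mismatches, bulges, expected):
        assert self._report(mismatches, bulges).rule3_pass() is expected


# ---------------------------------------------------------------------------
# rule 1 (read support)


def _stack(*items):
    return [PrecursorRead(seq, start, count) for seq, start, count in items]


class TestReadSupportRule:
    MATURE = (100, 121)
    STAR = (140, 161)

    def test_both_thresholds_cleared(self):
        stack = _stack(("A" * 21, 100, 80), ("C" * 21, 101, 16), ("G" * 21, 130, 4))
        rep = apply_read_support_rule(stack, self.MATURE, self.STAR)
        assert rep.precursor_mapped_total == 100
        assert rep.candidate_set_total == 96
        assert rep.reliable_reads_total == 96
        assert rep.passed

    def test_exactly_95_percent_fails_strictly(self):
        stack = _stack(("A" * 21, 100, 95), ("G" * 21, 130, 5))
        rep = apply_read_support_rule(stack, self.MATURE, self.STAR)
        assert rep.candidate_set_fraction == pytest.approx(0.95)
        assert not rep.passed

    def test_all_candidate_but_no_reliable_read_fails(self):
        stack = _stack(("A" * 21, 100, 4), ("C" * 21, 101, 4), ("G" * 21, 102, 4))
        rep = apply_read_support_rule(stack, self.MATURE, self.STAR)
        assert rep.candidate_set_fraction == 1.0
        assert rep.reliable_reads_total == 0
        assert not rep.passed

    def test_count_five_is_reliable(self):
        stack = _stack(("A" * 21, 100, 5))
        rep = apply_read_support_rule(stack, self.MATURE, self.STAR)
        assert rep.reliable_fraction == 1.0 and rep.passed

    def test_exactly_75_percent_reliable_fails_strictly(self):
        stack = _stack(("A" * 21, 100, 75), ("C" * 20, 101, 4), ("C" * 21, 101, 4),
                       ("C" * 22, 102, 4), ("C" * 23, 99, 4), ("C" * 24, 98, 4),
                       ("C" * 25, 100, 4), ("T" * 21, 100, 1))
        rep = apply_read_support_rule(stack, self.MATURE, self.STAR)
        assert rep.candidate_set_total == 100
        assert rep.reliable_fraction == pytest.approx(0.75)
        assert not rep.passed

    def test_empty_stack_fails_with_reason(self):
        rep = apply_read_support_rule([], self.MATURE, self.STAR)
        assert not rep.passed and rep.reason == "no reads"

    @given(
        st.lists(
            st.tuples(st.integers(90, 130), st.integers(1, 50)),
            min_size=1,
            max_size=12,
        ),
        st.floats(0.5, 0.99),
        st.floats(0.5, 0.99),
        st.floats(0.0, 0.049),
        st.floats(0.0, 0.049),
    )
    @settings(max_examples=100, deadline=None)
    def test_raising_thresholds_is_monotone(self, items, f1, f2, d1, d2):
        """Raising either rule-1 fraction never converts reject to accept."""
        stack = [
            PrecursorRead("ACGT" * 5 + "A", start, count) for start, count in items
        ]
        lo = apply_read_support_rule(stack, self.MATURE, self.STAR,
                                     frac_locus=f1, frac_reliable=f2)
        hi = apply_read_support_rule(stack, self.MATURE, self.STAR,
                                     frac_locus=min(f1 + d1, 1.0),
                                     frac_reliable=min(f2 + d2, 1.0))
        assert not (hi.passed and not lo.passed)


# ---------------------------------------------------------------------------
# windows


class TestExtractWindows:
    def _locus(self, genome, start, end, strand="+"):
        seq = genome["c"][start:end]
        read = seq if strand == "+" else revcomp(seq)
        hit = GenomeHit(read, "c", start, end, strand)
        return ReadLocus("c", strand, start, end, [hit], {read: 10})

    def test_windows_contain_the_summit(self):
        rng = np.random.default_rng(1)
        genome = {"c": "".join(rng.choice(np.array(list("ACGT")), 3000))}
        locus = self._locus(genome, 1000, 1021)
        for w in extract_windows(locus, genome):
            assert w.start <= locus.summit < w.end

    def test_clipping_at_chromosome_start(self):
        rng = np.random.default_rng(2)
        genome = {"c": "".join(rng.choice(np.array(list("ACGT")), 500))}
        locus = self._locus(genome, 10, 31)
        for w in extract_windows(locus, genome):
            assert w.start >= 0 and w.end <= 500

    def test_minus_strand_windows_are_reverse_complemented(self):
        rng = np.random.default_rng(3)
        genome = {"c": "".join(rng.choice(np.array(list("ACGT")), 2000))}
        locus = self._locus(genome, 900, 921, strand="-")
        for w in extract_windows(locus, genome):
            assert w.sequence == revcomp(genome["c"][w.start : w.end])


# ---------------------------------------------------------------------------
# decision logic: all 8 rule combinations on constructed fixtures


@pytest.fixture(scope="module")
def engineered_regions():
    params = SimulationParams()
    rng = np.random.default_rng(5)
    mature = "T" + "".join(np.random.default_rng(9).choice(list("ACGT"), 20))
    clean = _build_validated_region(rng, mature, params, None)
    broken = _build_validated_region(rng, mature, params, "mismatch")
    return {"clean": clean, "broken": broken}


def _call_with_rules(region, summit, r1, r2):
    ws, _, duplex = _best_window_duplex(region, summit, 21)
    matseq = region[summit : summit + 21]
    hits = [GenomeHit(matseq, "chr1", summit, summit + 21, "+")]
    counts = {matseq: 100}
    if r2 and duplex.star_interval:
        s0, s1 = duplex.star_interval
        starseq = region[ws + s0 : ws + s1]
        hits.append(GenomeHit(starseq, "chr1", ws + s0, ws + s1, "+"))
        counts[starseq] = 20
    if not r1:
        offseq = region[summit + 7 : summit + 28]
        hits.append(GenomeHit(offseq, "chr1", summit + 7, summit + 28, "+"))
        counts[offseq] = 100
    locus = ReadLocus(
        "chr1", "+",
        min(h.start for h in hits), max(h.end for h in hits), hits, counts,
    )
    return call_novel_mirna(locus, {"chr1": region})


@pytest.mark.parametrize("r1,r2,r3", list(product([True, False], repeat=3)))
def test_decision_is_rule1_and_rule2_or_rule3(engineered_regions, r1, r2, r3):
    region, summit, _ = engineered_regions["clean" if r3 else "broken"]
    call = _call_with_rules(region, summit, r1, r2)
    assert call.rule_trace["rule1"] is r1
    assert call.rule_trace["rule2"] is r2
    assert call.rule_trace["rule3"] is r3
    assert call.decision == (r1 and (r2 or r3))


def test_star_supported_call_reports_star_sequence(engineered_regions):
    region, summit, _ = engineered_regions["clean"]
    call = _call_with_rules(region, summit, True, True)
    assert call.decision and call.duplex.star_observed
    assert call.star_sequence is not None


# ---------------------------------------------------------------------------
# tabulation


class TestTabulate:
    def test_single_call(self):
        table = tabulate_5prime_by_length([("U", 21)])
        assert table.loc["U", 21] == 1
        assert table.loc["Total", "Total"] == 1

    def test_empty(self):
        table = tabulate_5prime_by_length([])
        assert table.loc["Total", "Total"] == 0

    def test_marginals_sum(self):
        pairs = [("U", 21)] * 3 + [("A", 24)] * 5 + [("C", 22)] * 2
        table = tabulate_5prime_by_length(pairs)
        assert table.loc["Total", "Total"] == 10
        assert table.loc["A", "Total"] == 5
        assert table.loc["Total", 21] == 3
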