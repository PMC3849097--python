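"""Novel-miRNA discovery from expressed genomic loci.

Candidate precursor windows are cut around each locus summit, folded into a
secondary structure, and the putative miRNA/miRNA* duplex is located from
the read stack.  A candidate is accepted as a novel miRNA when

    rule 1   the candidate read set (reads whose 5' ends sit within +-2 nt
             of the mature or star 5' end) accounts for more than 95% of all
             precursor-mapped reads, and reliable reads (collapsed count of
             at least 5) for more than 75% of that candidate set;
    rule 2   star reads are observed at the duplex position that gives both
             strands the Dicer-type 2-nt 3' overhang; OR
    rule 3   duplex geometry is clean: fewer than five base-pairing
             mismatches between the mature arm and the opposite arm, no
             asymmetric bulge larger than two nucleotides, and no more than
             two asymmetric bulges within the duplex.

The decision is exactly ``rule1 AND (rule2 OR rule3)``.

Folding goes through a thermodynamic engine (ViennaRNA bindings) when
available, with a base-pair-maximisation dynamic program as fallback; all
duplex geometry is computed from the dot-bracket string only, so the duplex
logic is engine-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp, to_rna
from .genome_mapper import GenomeIndex, ReadLocus

try:  # thermodynamic folding engine
    import RNA as _vienna
except ImportError:  # pragma: no cover - bindings present in supported envs
    _vienna = None

# window flank pairs (upstream, downstream of the summit, read orientation)
DEFAULT_FLANKS: tuple[tuple[int, int], ...] = (
    (20, 180),
    (60, 140),
    (100, 100),
    (140, 60),
    (180, 20),
)
MIN_PRECURSOR_LEN = 50
MAX_PRECURSOR_LEN = 400

RULE1_FRAC_LOCUS = 0.95
RULE1_FRAC_RELIABLE = 0.75
RULE1_MIN_RELIABLE = 5
RULE3_MAX_MISMATCH = 5  # strict: pass requires mismatch_count < 5
RULE3_MAX_BULGE_SIZE = 2
RULE3_MAX_BULGE_COUNT = 2
STAR_OVERHANG = 2


# ---------------------------------------------------------------------------
# folding


@dataclass
class FoldedPrecursor:
    sequence: str  # DNA-space
    structure: str  # dot-bracket
    score: float  # free-energy-like; lower is better

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure length differs from sequence length")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")


def _nussinov(seq: str, min_loop: int = 3) -> tuple[str, float]:
    """Base-pair maximisation DP; fallback when no thermodynamic engine."""
    n = len(seq)
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    best = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            cand = best[i][j - 1]
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in pairs:
                    left = best[i][k - 1] if k > i else 0
                    cand = max(cand, left + 1 + best[k + 1][j - 1])
            best[i][j] = cand
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if best[i][j] == best[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in pairs:
                    left = best[i][k - 1] if k > i else 0
                    if best[i][j] == left + 1 + best[k + 1][j - 1]:
                        structure[k] = "("
                        structure[j] = ")"
                        if k > i:
                            traceback(i, k - 1)
                        i, j = k + 1, j - 1
                        break
            else:  # pragma: no cover - defensive
                break

    traceback(0, n - 1)
    return "".join(structure), -float(best[0][n - 1])


def fold_hairpin(
    sequence: str,
    min_len: int = MIN_PRECURSOR_LEN,
    max_len: int = MAX_PRECURSOR_LEN,
) -> FoldedPrecursor | None:
    """Fold a candidate precursor; None when it cannot be considered.

    Rejects sequences outside the configured length bounds or with more
    than 10% ambiguous bases.  Deterministic for fixed input.
    """
    seq = sequence.upper().replace("U", "T")
    if not (min_len <= len(seq) <= max_len):
        return None
    if seq.count("N") > 0.10 * len(seq):
        return None
    if _vienna is not None:
        structure, mfe = _vienna.fold(seq.replace("T", "U"))
        return FoldedPrecursor(seq, structure, float(mfe))
    structure, score = _nussinov(seq)
    return FoldedPrecursor(seq, structure, score)


def pair_table(structure: str) -> list[int | None]:
    """Dot-bracket -> partner index per position (None if unpaired)."""
    table: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced structure")
    return table


# ---------------------------------------------------------------------------
# duplex geometry


@dataclass
class Bulge:
    arm: str  # 'mature' or 'star'
    size: int


@dataclass
class DuplexReport:
    mature_interval: tuple[int, int]  # 0-based half-open on the precursor
    star_interval: tuple[int, int] | None
    mismatch_count: int
    bulges: list[Bulge]
    star_overhang_ok: bool
    star_observed: bool = False
    arm: str | None = None  # '5p' or '3p'
    reject_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.reject_reason is None

    def rule3_pass(
        self,
        max_mismatch: int = RULE3_MAX_MISMATCH,
        max_bulge_size: int = RULE3_MAX_BULGE_SIZE,
        max_bulge_count: int = RULE3_MAX_BULGE_COUNT,
    ) -> bool:
        if not self.ok:
            return False
        return (
            self.mismatch_count < max_mismatch
            and all(b.size <= max_bulge_size for b in self.bulges)
            and len(self.bulges) <= max_bulge_count
        )


def _rejected(mature: tuple[int, int], reason: str) -> DuplexReport:
    return DuplexReport(
        mature_interval=mature,
        star_interval=None,
        mismatch_count=0,
        bulges=[],
        star_overhang_ok=False,
        reject_reason=reason,
    )


def evaluate_duplex(
    fp: FoldedPrecursor, mature_interval: tuple[int, int]
) -> DuplexReport:
    """Locate the star arm of a mature interval and score the duplex.

    The star interval is the structure-paired partner of the mature,
    shifted so both duplex ends carry 2-nt 3' overhangs.  Mismatches are
    unpaired mature positions inside the duplex body (the 2-nt 3' overhang
    is excluded; positions inside one-arm bulge runs count as bulges, not
    mismatches).  Asymmetric bulges are contiguous unpaired runs on a
    single arm, one event per run.
    """
    m0, m1 = mature_interval
    n = len(fp.sequence)
    if not (0 <= m0 < m1 <= n):
        return _rejected(mature_interval, "mature-outside-precursor")
    pt = pair_table(fp.structure)
    paired = [i for i in range(m0, m1) if pt[i] is not None]
    if not paired:
        return _rejected(mature_interval, "mature-unpaired")
    ups = sum(1 for i in paired if pt[i] > i)
    downs = len(paired) - ups
    if ups and downs:
        return _rejected(mature_interval, "loop-spanning")
    arm = "5p" if ups else "3p"

    # anchor the duplex: partner of the 3'-overhang boundary gives the star
    # 5' start; partner of the mature 5' start (+2) gives the star 3' end.
    body_end = m1 - STAR_OVERHANG  # exclusive; last 2 nt are the 3' overhang
    i1 = next((i for i in range(body_end - 1, m0 - 1, -1) if pt[i] is not None), None)
    i2 = next((i for i in range(m0, m1) if pt[i] is not None), None)
    if i1 is None or i2 is None:
        return _rejected(mature_interval, "mature-unpaired")
    s_start = pt[i1] - (body_end - 1 - i1)
    s_end = pt[i2] + (i2 - m0) + STAR_OVERHANG + 1  # exclusive
    star_ok = 0 <= s_start < s_end <= n
    if star_ok and not (s_end <= m0 or s_start >= m1):
        star_ok = False  # star overlapping mature: degenerate fold
    star_interval = (s_start, s_end) if star_ok else None

    # walk the duplex body between consecutive paired mature positions
    lo, hi = (s_start - 4 if star_ok else 0), (s_end + 4 if star_ok else n)
    body_paired = [
        i
        for i in range(m0, body_end)
        if pt[i] is not None and (not star_ok or lo <= pt[i] < hi)
    ]
    mismatches = 0
    bulges: list[Bulge] = []
    if body_paired:
        mismatches += body_paired[0] - m0  # unpaired overhang at duplex end
        mismatches += (body_end - 1) - body_paired[-1]
        for i, j in zip(body_paired, body_paired[1:]):
            gap_m = j - i - 1
            gap_s = pt[i] - pt[j] - 1
            if gap_m > 0 and gap_s <= 0:
                bulges.append(Bulge("mature", gap_m))
            elif gap_s > 0 and gap_m == 0:
                bulges.append(Bulge("star", gap_s))
            elif gap_m > 0 and gap_s > 0:
                mismatches += gap_m  # (a)symmetric internal loop
    else:
        mismatches = body_end - m0

    return DuplexReport(
        mature_interval=mature_interval,
        star_interval=star_interval,
        mismatch_count=mismatches,
        bulges=bulges,
        star_overhang_ok=star_ok,
        arm=arm,
    )


# ---------------------------------------------------------------------------
# read support (rule 1)


@dataclass
class PrecursorRead:
    """A collapsed read placed on a precursor window (sense orientation)."""

    sequence: str
    start: int  # 5' end, 0-based on the precursor
    count: int  # collapsed total count

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class ReadSupportReport:
    precursor_mapped_total: int
    candidate_set_total: int
    candidate_set_fraction: float
    reliable_reads_total: int
    reliable_fraction: float
    passed: bool
    reason: str | None = None


def apply_read_support_rule(
    stack: Sequence[PrecursorRead],
    mature_interval: tuple[int, int],
    star_interval: tuple[int, int] | None,
    frac_locus: float = RULE1_FRAC_LOCUS,
    frac_reliable: float = RULE1_FRAC_RELIABLE,
    min_reliable: int = RULE1_MIN_RELIABLE,
    position_tolerance: int = 2,
) -> ReadSupportReport:
    """Rule 1: candidate-set and reliable-read fractions, strict thresholds.

    The candidate set is the reads whose 5' ends lie within
    ``position_tolerance`` of the mature or star 5' end; reliable reads are
    candidate reads whose collapsed count is at least ``min_reliable``.
    Both fraction comparisons are strict (> not >=).
    """
    if not (0 < frac_locus <= 1 and 0 < frac_reliable <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    if min_reliable < 1:
        raise ValueError("min_reliable must be >= 1")
    total = sum(r.count for r in stack)
    if total == 0:
        return ReadSupportReport(0, 0, 0.0, 0, 0.0, False, reason="no reads")
    anchors = [mature_interval[0]]
    if star_interval is not None:
        anchors.append(star_interval[0])
    candidate = [
        r
        for r in stack
        if any(abs(r.start - a) <= position_tolerance for a in anchors)
    ]
    cand_total = sum(r.count for r in candidate)
    reliable_total = sum(r.count for r in candidate if r.count >= min_reliable)
    cand_frac = cand_total / total
    rel_frac = reliable_total / cand_total if cand_total else 0.0
    passed = cand_frac > frac_locus and rel_frac > frac_reliable
    return ReadSupportReport(
        precursor_mapped_total=total,
        candidate_set_total=cand_total,
        candidate_set_fraction=cand_frac,
        reliable_reads_total=reliable_total,
        reliable_fraction=rel_frac,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# windows and calling


@dataclass
class PrecursorWindow:
    chrom: str
    start: int  # genomic, forward coordinates
    end: int
    strand: str
    sequence: str  # read-orientation (revcomp'd for minus strand)

    def to_window_coord(self, genomic_start: int, genomic_end: int) -> tuple[int, int]:
        """Genomic interval -> window-local interval in read orientation."""
        if self.strand == "+":
            return genomic_start - self.start, genomic_end - self.start
        return self.end - genomic_end, self.end - genomic_start


def extract_windows(
    locus: ReadLocus,
    genome: Mapping[str, str],
    flanks: Sequence[tuple[int, int]] = DEFAULT_FLANKS,
) -> list[PrecursorWindow]:
    """Candidate precursor windows around the locus summit.

    Flanks are in read orientation (upstream, downstream of the summit);
    on the minus strand upstream means genomically rightward.  Windows are
    clipped at chromosome ends and always contain the summit.
    """
    chrom_seq = genome[locus.chrom]
    summit = locus.summit
    windows = []
    for f5, f3 in flanks:
        if locus.strand == "+":
            start, end = summit - f5, summit + f3 + 1
        else:
            start, end = summit - f3, summit + f5 + 1
        start = max(0, start)
        end = min(len(chrom_seq), end)
        seq = chrom_seq[start:end]
        if locus.strand == "-":
            seq = revcomp(seq)
        windows.append(
            PrecursorWindow(locus.chrom, start, end, locus.strand, seq)
        )
    return windows


@dataclass
class NovelMiRNACall:
    mature_sequence: str  # DNA-space
    chrom: str
    strand: str
    precursor_interval: tuple[int, int]  # genomic forward coordinates
    mature_genomic: tuple[int, int]
    structure: str | None
    fold_score: float | None
    decision: bool
    rule_trace: dict[str, bool | None]
    support: ReadSupportReport | None
    duplex: DuplexReport | None
    star_sequence: str | None = None
    precursor_sequence: str | None = None

    @property
    def five_prime(self) -> str:
        return to_rna(self.mature_sequence[0])

    @property
    def length(self) -> int:
        return len(self.mature_sequence)


def _window_stack(
    locus: ReadLocus, window: PrecursorWindow
) -> list[PrecursorRead]:
    stack = []
    for hit in locus.hits:
        if hit.start < window.start or hit.end > window.end:
            continue
        w0, _ = window.to_window_coord(hit.start, hit.end)
        stack.append(
            PrecursorRead(
                sequence=hit.read_sequence,
                start=w0,
                count=locus.counts.get(hit.read_sequence, 1),
            )
        )
    stack.sort(key=lambda r: (r.start, r.sequence))
    return stack


def call_novel_mirna(
    locus: ReadLocus,
    genome: Mapping[str, str],
    flanks: Sequence[tuple[int, int]] = DEFAULT_FLANKS,
    frac_locus: float = RULE1_FRAC_LOCUS,
    frac_reliable: float = RULE1_FRAC_RELIABLE,
    min_reliable: int = RULE1_MIN_RELIABLE,
    max_mismatch: int = RULE3_MAX_MISMATCH,
    max_bulge_size: int = RULE3_MAX_BULGE_SIZE,
    max_bulge_count: int = RULE3_MAX_BULGE_COUNT,
    star_tolerance: int = 0,
) -> NovelMiRNACall:
    """Evaluate one expressed locus against the novel-miRNA rules.

    The best-folding window (lowest score; ties to the shorter, then the
    leftmost window) is reported; the mature is the most abundant read in
    that window's stack.  ``rule_trace`` records every sub-check; the
    decision is rule1 AND (rule2 OR rule3).
    """
    trace: dict[str, bool | None] = {
        "folded": False,
        "rule1": False,
        "rule1_fraction": None,
        "rule1_reliable": None,
        "rule2": False,
        "rule3": False,
        "rule3_mismatch": None,
        "rule3_bulge_size": None,
        "rule3_bulge_count": None,
    }

    candidates = []
    for window in extract_windows(locus, genome, flanks):
        folded = fold_hairpin(window.sequence)
        if folded is None:
            continue
        candidates.append((folded.score, len(window.sequence), window.start, window, folded))
    if not candidates:
        return NovelMiRNACall(
            mature_sequence="",
            chrom=locus.chrom,
            strand=locus.strand,
            precursor_interval=(locus.start, locus.end),
            mature_genomic=(locus.start, locus.end),
            structure=None,
            fold_score=None,
            decision=False,
            rule_trace=trace,
            support=None,
            duplex=None,
        )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, _, window, folded = candidates[0]
    trace["folded"] = True

    stack = _window_stack(locus, window)
    if not stack:
        support = ReadSupportReport(0, 0, 0.0, 0, 0.0, False, reason="no reads")
        return NovelMiRNACall(
            mature_sequence="",
            chrom=locus.chrom,
            strand=locus.strand,
            precursor_interval=(window.start, window.end),
            mature_genomic=(locus.start, locus.end),
            structure=folded.structure,
            fold_score=folded.score,
            decision=False,
            rule_trace=trace,
            support=support,
            duplex=None,
            precursor_sequence=folded.sequence,
        )
    mature = max(stack, key=lambda r: (r.count, -r.start))
    mature_interval = (mature.start, mature.end)
    duplex = evaluate_duplex(folded, mature_interval)

    support = apply_read_support_rule(
        stack,
        mature_interval,
        duplex.star_interval,
        frac_locus=frac_locus,
        frac_reliable=frac_reliable,
        min_reliable=min_reliable,
    )
    trace["rule1"] = support.passed
    trace["rule1_fraction"] = support.candidate_set_fraction > frac_locus
    trace["rule1_reliable"] = support.reliable_fraction > frac_reliable

    star_seq = None
    if duplex.ok and duplex.star_interval is not None and duplex.star_overhang_ok:
        s0, s1 = duplex.star_interval
        star_seq = folded.sequence[s0:s1]
        duplex.star_observed = any(
            abs(r.start - s0) <= star_tolerance for r in stack
        )
    trace["rule2"] = bool(duplex.star_observed and duplex.star_overhang_ok)
    trace["rule3"] = duplex.rule3_pass(max_mismatch, max_bulge_size, max_bulge_count)
    if duplex.ok:
        trace["rule3_mismatch"] = duplex.mismatch_count < max_mismatch
        trace["rule3_bulge_size"] = all(b.size <= max_bulge_size for b in duplex.bulges)
        trace["rule3_bulge_count"] = len(duplex.bulges) <= max_bulge_count

    decision = bool(trace["rule1"] and (trace["rule2"] or trace["rule3"]))

    if window.strand == "+":
        mature_genomic = (window.start + mature.start, window.start + mature.end)
    else:
        mature_genomic = (window.end - mature.end, window.end - mature.start)

    return NovelMiRNACall(
        mature_sequence=mature.sequence,
        chrom=locus.chrom,
        strand=locus.strand,
        precursor_interval=(window.start, window.end),
        mature_genomic=mature_genomic,
        structure=folded.structure,
        fold_score=folded.score,
        decision=decision,
        rule_trace=trace,
        support=support,
        duplex=duplex,
        star_sequence=star_seq,
        precursor_sequence=folded.sequence,
    )


# ---------------------------------------------------------------------------
# reporting


def tabulate_5prime_by_length(calls: Iterable) -> pd.DataFrame:
    """5'-terminal nucleotide x mature length contingency table.

    Accepts accepted :class:`NovelMiRNACall` objects or plain
    ``(five_prime, length)`` tuples (RNA alphabet).  Returns a DataFrame
    with a Total row and column; cells sum to the number of calls.
    """
    pairs = []
    for item in calls:
        if isinstance(item, tuple):
            nt, length = item
        else:
            nt, length = item.five_prime, item.length
        pairs.append((nt.upper().replace("T", "U"), int(length)))
    nts = ["A", "C", "G", "U"]
    lengths = sorted({length for _, length in pairs})
    table = pd.DataFrame(0, index=nts, columns=lengths, dtype=int)
    for nt, length in pairs:
        table.loc[nt, length] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def write_calls_gff3(calls: Sequence[NovelMiRNACall], path: str | Path) -> None:
    """Accepted calls as GFF3 (primary transcript + mature miRNA features)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for i, call in enumerate(calls, start=1):
            if not call.decision:
                continue
            pid = f"novel_mir_{i}"
            p0, p1 = call.precursor_interval
            m0, m1 = call.mature_genomic
            out.write(
                f"{call.chrom}\t.\tmiRNA_primary_transcript\t{p0 + 1}\t{p1}\t.\t"
                f"{call.strand}\t.\tID={pid}\n"
            )
            out.write(
                f"{call.chrom}\t.\tmiRNA\t{m0 + 1}\t{m1}\t.\t{call.strand}\t.\t"
                f"ID={pid}.mature;Parent={pid};sequence={to_rna(call.mature_sequence)}\n"
            )


def write_rule_trace_tsv(calls: Sequence[NovelMiRNACall], path: str | Path) -> None:
    keys = [
        "folded",
        "rule1",
        "rule1_fraction",
        "rule1_reliable",
        "rule2",
        "rule3",
        "rule3_mismatch",
        "rule3_bulge_size",
        "rule3_bulge_count",
    ]
    with open(path, "w") as out:
        out.write("mature\tchrom\tstrand\tdecision\t" + "\t".join(keys) + "\n")
        for call in calls:
            vals = "\t".join(
                "NA" if call.rule_trace.get(k) is None else str(call.rule_trace[k])
                for k in keys
            )
            out.write(
                f"{to_rna(call.mature_sequence)}\t{call.chrom}\t{call.strand}\t"
                f"{call.decision}\t{vals}\n"
            )


def write_structures(calls: Sequence[NovelMiRNACall], path: str | Path) -> None:
    """Vienna-style two-line records (RNA sequence, dot-bracket)."""
    with open(path, "w") as out:
        for i, call in enumerate(calls, start=1):
            if call.structure is None:
                continue
            p0, p1 = call.precursor_interval
            out.write(f">precursor_{i} {call.chrom}:{p0 + 1}-{p1}({call.strand})\n")
            if call.precursor_sequence is not None:
                out.write(f"{to_rna(call.precursor_sequence)}\n")
            out.write(f"{call.structure}\n")
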