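"""tasiRNA (TAS-like) locus detection by 21-nt phasing.

A trigger miRNA (miR390-type) sets the phase register: its complementary
target site on a transcript is cleaved between the nucleotides pairing
trigger positions 10 and 11, and downstream small RNAs are produced in
21-nt increments from that cut.  TAS3-type transcripts carry *two* trigger
sites; the phased cluster lies between them.  Phase windows are named
D1, D2, ... downstream of the 5' site's cleavage point, so the dominant
product of the canonical locus is labelled like ``5'D7(+)``.

Target-site scoring follows common plant-miRNA complementarity practice:
+1 per mismatch, +0.5 per G:U wobble over the full trigger length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from ._seq import normalize, revcomp
from .sequence_io import CollapsedRead

DEFAULT_PERIOD = 21
DEFAULT_MAX_PENALTY = 4.0
DEFAULT_TOLERANCE = 1
DEFAULT_MIN_FRACTION = 0.5
DEFAULT_MIN_POSITIONS = 4
CLEAVAGE_OFFSET = 10  # cut between nucleotides pairing trigger pos 10 and 11

_WOBBLE = {("G", "T"), ("T", "G")}  # trigger base, transcript base (DNA-space)
_COMPLEMENT = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class TargetSite:
    transcript_id: str
    start: int  # 1-based inclusive on the transcript
    end: int  # 1-based inclusive
    penalty: float
    cleavage_after: int  # cut falls between this 1-based position and the next


def _site_penalty(trigger: str, window: str) -> float:
    """Complementarity penalty of a trigger against a same-length window.

    The trigger binds antiparallel: trigger position i (1-based, 5'->3')
    pairs the window base at position len-i+1.
    """
    penalty = 0.0
    n = len(trigger)
    for i in range(n):
        t = trigger[i]
        w = window[n - 1 - i]
        if (t, w) in _COMPLEMENT:
            continue
        if (t, w) in _WOBBLE:
            penalty += 0.5
        else:
            penalty += 1.0
    return penalty


def find_target_sites(
    transcript: str,
    trigger: str,
    max_penalty: float = DEFAULT_MAX_PENALTY,
    transcript_id: str = "transcript",
) -> list[TargetSite]:
    """All trigger-complementary sites within the penalty budget.

    The inferred cleavage position is opposite trigger positions 10/11:
    for a site ending at 1-based position e, the cut falls between
    transcript positions e-10 and e-9.
    """
    transcript = normalize(transcript)
    trigger = normalize(trigger)
    if not (20 <= len(trigger) <= 24):
        raise ValueError("trigger length must be 20-24 nt")
    n = len(trigger)
    sites = []
    for start0 in range(len(transcript) - n + 1):
        window = transcript[start0 : start0 + n]
        penalty = _site_penalty(trigger, window)
        if penalty <= max_penalty:
            end1 = start0 + n  # 1-based inclusive end
            sites.append(
                TargetSite(
                    transcript_id=transcript_id,
                    start=start0 + 1,
                    end=end1,
                    penalty=penalty,
                    cleavage_after=end1 - CLEAVAGE_OFFSET,
                )
            )
    return sites


def phase_register(
    cleavage_after: int,
    period: int = DEFAULT_PERIOD,
    k_max: int = 11,
    transcript_length: int | None = None,
) -> list[tuple[int, int]]:
    """D-windows downstream of a cleavage point (1-based inclusive).

    ``Dk = [t+1+period*(k-1), t+period*k]`` where t is the position the
    cut falls after.  Windows are contiguous and non-overlapping; windows
    running past the transcript end are dropped.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    t = cleavage_after
    windows = []
    for k in range(1, k_max + 1):
        lo = t + 1 + period * (k - 1)
        hi = t + period * k
        if transcript_length is not None and hi > transcript_length:
            break
        windows.append((lo, hi))
    return windows


@dataclass
class TranscriptRead:
    """A read placed on the sense strand of a transcript."""

    sequence: str
    start: int  # 1-based 5' position on the transcript
    counts: dict[str, int] = field(default_factory=dict)  # library -> count

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PhaseProfile:
    in_phase_fraction: float
    per_position: dict[int, dict[str, int]]  # D-index -> library -> count
    in_phase_positions: list[int]  # D-indices holding in-phase reads

    def position_total(self, k: int) -> int:
        return sum(self.per_position.get(k, {}).values())

    def total(self) -> int:
        return sum(self.position_total(k) for k in self.per_position)


def score_phased_cluster(
    reads: Sequence[TranscriptRead],
    register: Sequence[tuple[int, int]],
    tolerance: int = DEFAULT_TOLERANCE,
) -> PhaseProfile:
    """In-phase fraction and per-D-position profile of a read cluster.

    A read is in phase iff its 5' end lies within +-tolerance of a window
    start.  Every read is assigned to the D-window containing its 5' end
    (reads before D1 or past the last window go to the nearest window), so
    the profile conserves the cluster's total count.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    profile: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    in_phase_positions: set[int] = set()
    if not register:
        return PhaseProfile(0.0, {}, [])
    period = register[1][0] - register[0][0] if len(register) > 1 else (
        register[0][1] - register[0][0] + 1
    )
    first = register[0][0]
    total = 0
    in_phase = 0
    for read in reads:
        n = read.total
        total += n
        k = (read.start - first) // period + 1
        k = min(max(k, 1), len(register))
        for lib, c in read.counts.items():
            profile[k][lib] += c
        if any(abs(read.start - lo) <= tolerance for lo, _ in register):
            in_phase += n
            in_phase_positions.add(k)
    fraction = in_phase / total if total else 0.0
    return PhaseProfile(
        in_phase_fraction=fraction,
        per_position={k: dict(v) for k, v in sorted(profile.items())},
        in_phase_positions=sorted(in_phase_positions),
    )


@dataclass
class PhasedLocusReport:
    transcript_id: str
    five_prime_site: TargetSite
    three_prime_site: TargetSite
    period: int
    profile: PhaseProfile
    dominant_position: int  # D-index with the highest total count
    dominant_label: str  # e.g. "5'D7(+)"

    @property
    def in_phase_fraction(self) -> float:
        return self.profile.in_phase_fraction


def map_reads_to_transcript(
    reads: Sequence[CollapsedRead], transcript: str
) -> list[TranscriptRead]:
    """Exact sense-strand placements of collapsed reads on a transcript."""
    transcript = normalize(transcript)
    out = []
    for read in reads:
        start = transcript.find(read.sequence)
        while start != -1:
            out.append(
                TranscriptRead(
                    sequence=read.sequence, start=start + 1, counts=dict(read.counts)
                )
            )
            start = transcript.find(read.sequence, start + 1)
    out.sort(key=lambda r: (r.start, r.sequence))
    return out


def call_tas_locus(
    transcript: str,
    trigger: str,
    reads: Sequence[CollapsedRead],
    transcript_id: str = "transcript",
    max_penalty: float = DEFAULT_MAX_PENALTY,
    period: int = DEFAULT_PERIOD,
    tolerance: int = DEFAULT_TOLERANCE,
    min_sites: int = 2,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_positions: int = DEFAULT_MIN_POSITIONS,
) -> PhasedLocusReport | None:
    """Dual-site phased-locus caller.

    Requires at least ``min_sites`` trigger-complementary sites; the phase
    register anchors at the 5'-most site's cleavage position and the
    cluster is the set of sense reads lying between the 5' cleavage point
    and the start of the 3' site.  Reported iff the in-phase fraction
    reaches ``min_fraction`` over at least ``min_positions`` distinct
    D-positions.
    """
    sites = find_target_sites(
        transcript, trigger, max_penalty=max_penalty, transcript_id=transcript_id
    )
    if len(sites) < min_sites:
        return None
    sites.sort(key=lambda s: s.start)
    five, three = sites[0], sites[-1]
    t = five.cleavage_after
    span_hi = three.start - 1
    register = [
        (lo, hi)
        for lo, hi in phase_register(
            t, period=period, k_max=(span_hi - t) // period + 2,
            transcript_length=len(transcript),
        )
        if hi <= span_hi
    ]
    if not register:
        return None
    placed = map_reads_to_transcript(reads, transcript)
    cluster = [r for r in placed if t < r.start <= span_hi]
    profile = score_phased_cluster(cluster, register, tolerance=tolerance)
    if profile.in_phase_fraction < min_fraction:
        return None
    if len(profile.in_phase_positions) < min_positions:
        return None
    dominant = min(
        profile.per_position,
        key=lambda k: (-profile.position_total(k), k),
    )
    return PhasedLocusReport(
        transcript_id=transcript_id,
        five_prime_site=five,
        three_prime_site=three,
        period=period,
        profile=profile,
        dominant_position=dominant,
        dominant_label=f"5'D{dominant}(+)",
    )


def write_phase_profile_tsv(
    report: PhasedLocusReport, libraries: Sequence[str], path: str | Path
) -> None:
    """Per-D-position per-library count table suitable for plotting."""
    with open(path, "w") as out:
        out.write("position\t" + "\t".join(libraries) + "\ttotal\n")
        for k in sorted(report.profile.per_position):
            row = report.profile.per_position[k]
            counts = [str(row.get(lib, 0)) for lib in libraries]
            out.write(f"D{k}\t" + "\t".join(counts) + f"\t{sum(row.values())}\n")
        out.write(
            f"# transcript={report.transcript_id} period={report.period} "
            f"in_phase_fraction={report.in_phase_fraction:.4f} "
            f"dominant={report.dominant_label}\n"
        )
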