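"""Known-miRNA family profiling.

Reads matching a known mature miRNA (at most two substitutions over an
ungapped full overlap) are grouped into families; per library the most
abundant member is reported as the representative sequence, with a
divergence flag when representatives differ between libraries.  3'-end
tailing variants (mono-/di-adenylation and other 1-2 nt extensions of a
reference body) are detected separately, and family precursors are located
in any of the supplied sequence databases (genome / EST / GSS) by exact
mature placement plus a hairpin-geometry check.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from ._seq import normalize, to_rna
from .genome_mapper import GenomeIndex, map_sequence
from .hairpin_miner import evaluate_duplex, fold_hairpin
from .read_classifier import ReferenceSet, match_with_mismatches, rptm_normalize
from .sequence_io import CollapsedRead

MAX_FAMILY_MISMATCHES = 2
MAX_TAIL_LEN = 2


@dataclass
class FamilyReference(ReferenceSet):
    """Known-miRNA reference set whose identifiers carry family labels.

    Identifiers are expected as ``family|member`` or plain family names;
    everything before the first ``|`` is the family label.
    """

    @staticmethod
    def family_of(reference_id: str) -> str:
        return reference_id.split("|", 1)[0]


@dataclass
class TailVariant:
    read_sequence: str
    reference_id: str
    tail: str  # appended 3' nucleotides, DNA-space

    @property
    def is_adenylated(self) -> bool:
        return set(self.tail) == {"A"}


@dataclass
class PrecursorLocus:
    family: str
    source_db: str  # 'genome', 'EST', 'GSS', ...
    chrom: str
    start: int
    end: int
    strand: str
    arm: str  # '5p' / '3p'
    structure: str


@dataclass
class MiRNAFamilyRecord:
    family: str
    members: dict[str, dict[str, int]] = field(default_factory=dict)  # seq -> lib -> n
    arm: dict[str, str] = field(default_factory=dict)  # seq -> 5p/3p/unknown
    precursors: list[PrecursorLocus] = field(default_factory=list)
    # members that are 3'-tailed variants of a reference (never double-counted:
    # a variant stays a single member, annotated here rather than listed twice)
    variants: dict[str, TailVariant] = field(default_factory=dict)

    def member_count(self, library: str) -> int:
        return sum(counts.get(library, 0) for counts in self.members.values())

    def total_count(self) -> int:
        return sum(sum(c.values()) for c in self.members.values())


def assign_family(
    read: CollapsedRead,
    refset: FamilyReference,
    family_abundance: Mapping[str, int] | None = None,
) -> str | None:
    """Family of the minimal-mismatch known hit (<= 2 substitutions).

    When two families tie at the same distance, the more abundant family in
    the current dataset wins; remaining ties break lexicographically.
    """
    query = normalize(read.sequence)
    by_family: dict[str, int] = {}
    for rid, ref in refset.sequences:
        from .read_classifier import _best_ungapped

        mm = _best_ungapped(query, ref, refset.max_mismatches)
        if mm is None:
            continue
        fam = FamilyReference.family_of(rid)
        if fam not in by_family or mm < by_family[fam]:
            by_family[fam] = mm
    if not by_family:
        return None
    best_mm = min(by_family.values())
    tied = sorted(f for f, mm in by_family.items() if mm == best_mm)
    if len(tied) == 1 or family_abundance is None:
        return tied[0]
    return sorted(tied, key=lambda f: (-family_abundance.get(f, 0), f))[0]


def build_family_records(
    reads: Sequence[CollapsedRead],
    refset: FamilyReference,
) -> dict[str, MiRNAFamilyRecord]:
    """Group family-matching reads into :class:`MiRNAFamilyRecord`s.

    Runs two passes: the first accumulates per-family abundance so that
    equal-distance ties in the second pass resolve toward the family that
    is more abundant in this dataset.
    """
    provisional: dict[str, int] = defaultdict(int)
    hits: list[tuple[CollapsedRead, str | None]] = []
    for read in reads:
        fam = assign_family(read, refset)
        hits.append((read, fam))
        if fam is not None:
            provisional[fam] += read.total_count
    records: dict[str, MiRNAFamilyRecord] = {}
    for read, _ in hits:
        fam = assign_family(read, refset, family_abundance=provisional)
        if fam is None:
            continue
        rec = records.setdefault(fam, MiRNAFamilyRecord(family=fam))
        rec.members[read.sequence] = dict(read.counts)
        rec.arm.setdefault(read.sequence, "unknown")
    return records


def representative_sequences(
    record: MiRNAFamilyRecord, libraries: Sequence[str]
) -> tuple[dict[str, str | None], bool]:
    """Per-library most-abundant member and the divergence flag.

    Libraries where the family has no reads report None and are excluded
    from the divergence comparison.  Ties break lexicographically so the
    result is scale-invariant and deterministic.
    """
    reps: dict[str, str | None] = {}
    for lib in libraries:
        scored = [
            (counts.get(lib, 0), seq)
            for seq, counts in record.members.items()
            if counts.get(lib, 0) > 0
        ]
        if not scored:
            reps[lib] = None
            continue
        scored.sort(key=lambda x: (-x[0], x[1]))
        reps[lib] = scored[0][1]
    seen = {r for r in reps.values() if r is not None}
    return reps, len(seen) > 1


def classify_3prime_tail(
    read_sequence: str,
    reference_sequence: str,
    max_tail: int = MAX_TAIL_LEN,
    max_body_mismatches: int = MAX_FAMILY_MISMATCHES,
    reference_id: str = "",
) -> TailVariant | None:
    """Detect a 1-2 nt untemplated 3' extension over a reference body.

    The read must equal the reference (up to ``max_body_mismatches``
    substitutions over the full reference length) followed by 1..max_tail
    extra 3' nucleotides.  A read identical to the reference returns a
    variant with an empty tail; anything else returns None.
    """
    read = normalize(read_sequence)
    ref = normalize(reference_sequence)
    if len(read) < len(ref):
        return None
    tail_len = len(read) - len(ref)
    if tail_len > max_tail:
        return None
    body, tail = read[: len(ref)], read[len(ref) :]
    mismatches = sum(a != b for a, b in zip(body, ref))
    if mismatches > max_body_mismatches:
        return None
    return TailVariant(read_sequence=read, reference_id=reference_id, tail=tail)


def annotate_tail_variants(
    record: MiRNAFamilyRecord,
    references: Sequence[tuple[str, str]],
    max_tail: int = MAX_TAIL_LEN,
) -> dict[str, TailVariant]:
    """Flag members that are 3'-tailed forms of one of the family references.

    Only non-empty tails with an exact body match are recorded (a member
    equal to a reference is not a variant).  The member keeps its single
    entry in ``members``; the annotation lives in ``record.variants``.
    """
    fam_refs = [
        (rid, seq)
        for rid, seq in references
        if FamilyReference.family_of(rid) == record.family
    ]
    for member in sorted(record.members):
        for rid, ref in fam_refs:
            variant = classify_3prime_tail(
                member, ref, max_tail=max_tail, max_body_mismatches=0,
                reference_id=rid,
            )
            if variant is not None and variant.tail:
                record.variants[member] = variant
                break
    return record.variants


def locate_known_precursors(
    record: MiRNAFamilyRecord,
    databases: Mapping[str, GenomeIndex],
    flank: int = 180,
) -> list[PrecursorLocus]:
    """Find hairpin-validated precursor loci of a family's members.

    For every member sequence and database, each exact placement is
    extended by ``flank`` nt on both sides, folded, and kept iff the
    mature sits on one arm of a stem-loop passing the duplex-geometry
    (rule 3) check.  Loci are labelled with the database name; member arms
    (5p/3p) are annotated from the structure of the first validated locus.
    """
    loci: list[PrecursorLocus] = []
    seen: set[tuple[str, str, int, int, str]] = set()
    for member in sorted(record.members):
        for db_name, index in databases.items():
            for hit in map_sequence(member, index):
                w_start = max(0, hit.start - flank)
                w_end = min(index.chrom_length(hit.chrom), hit.end + flank)
                seq = index.genome[hit.chrom][w_start:w_end]
                if hit.strand == "-":
                    from ._seq import revcomp

                    seq = revcomp(seq)
                    m0 = w_end - hit.end
                else:
                    m0 = hit.start - w_start
                folded = fold_hairpin(seq)
                if folded is None:
                    continue
                duplex = evaluate_duplex(folded, (m0, m0 + len(member)))
                if not (duplex.ok and duplex.rule3_pass()):
                    continue
                key = (db_name, hit.chrom, w_start, w_end, hit.strand)
                if key in seen:
                    continue
                seen.add(key)
                loci.append(
                    PrecursorLocus(
                        family=record.family,
                        source_db=db_name,
                        chrom=hit.chrom,
                        start=w_start,
                        end=w_end,
                        strand=hit.strand,
                        arm=duplex.arm or "unknown",
                        structure=folded.structure,
                    )
                )
                if record.arm.get(member, "unknown") == "unknown":
                    record.arm[member] = duplex.arm or "unknown"
    record.precursors.extend(loci)
    return loci


def write_family_table(
    records: Mapping[str, MiRNAFamilyRecord],
    libraries: Sequence[str],
    clean_totals: Mapping[str, int],
    path: str | Path,
) -> None:
    """Family table TSV: counts, RPTM, representative, divergence flag."""
    with open(path, "w") as out:
        header = ["family"]
        header += [f"count_{lib}" for lib in libraries]
        header += [f"rptm_{lib}" for lib in libraries]
        header += [f"representative_{lib}" for lib in libraries]
        header += ["divergent", "n_members", "n_precursors"]
        out.write("\t".join(header) + "\n")
        for fam in sorted(records):
            rec = records[fam]
            reps, divergent = representative_sequences(rec, libraries)
            row = [fam]
            row += [str(rec.member_count(lib)) for lib in libraries]
            row += [
                f"{rptm_normalize(rec.member_count(lib), clean_totals[lib]):.1f}"
                for lib in libraries
            ]
            row += [to_rna(reps[lib]) if reps[lib] else "none" for lib in libraries]
            row += [str(divergent), str(len(rec.members)), str(len(rec.precursors))]
            out.write("\t".join(row) + "\n")


def write_precursor_table(
    records: Mapping[str, MiRNAFamilyRecord], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("family\tsource_db\tchrom\tstart\tend\tstrand\tarm\tstructure\n")
        for fam in sorted(records):
            for loc in records[fam].precursors:
                out.write(
                    f"{fam}\t{loc.source_db}\t{loc.chrom}\t{loc.start}\t{loc.end}\t"
                    f"{loc.strand}\t{loc.arm}\t{loc.structure}\n"
                )
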