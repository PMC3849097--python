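"""Annotation-class assignment and abundance normalisation.

Each collapsed read is compared against an ordered list of reference sets
(known miRNAs first, then the structural-RNA and repeat/mRNA decoy classes)
and labelled with the first class that matches; everything else falls into
the unclassified "others" bin, the pool novel-miRNA discovery draws from.
Known-miRNA matching tolerates up to two substitutions over an ungapped
full-length overlap of the shorter sequence; the other classes require an
exact substring match of a reference by default.

Abundances are normalised to reads per ten million (RPTM):
``count / library_clean_total * 1e7``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import normalize
from .sequence_io import CollapsedRead

RPTM_FACTOR = 10_000_000

UNCLASSIFIED = "others"


@dataclass
class ReferenceSet:
    """A named annotation class backed by reference sequences.

    ``max_mismatches`` > 0 enables the ungapped substitution-tolerant scan
    used for known miRNAs; 0 means exact substring containment (either the
    query inside a reference or, for short references, vice versa).
    """

    name: str
    sequences: list[tuple[str, str]]  # (identifier, sequence)
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        self.sequences = [(rid, normalize(seq)) for rid, seq in self.sequences]


@dataclass
class Hit:
    reference_id: str
    mismatches: int


def _best_ungapped(query: str, ref: str, max_mm: int) -> int | None:
    """Minimal substitution count over all ungapped full-overlap offsets.

    The shorter sequence slides along the longer one; at each offset the
    substitution (Hamming) distance over the full shorter length is taken.
    Returns the minimum if it is <= max_mm, else None.
    """
    short, long_ = (query, ref) if len(query) <= len(ref) else (ref, query)
    n, m = len(short), len(long_)
    best: int | None = None
    for off in range(m - n + 1):
        mm = 0
        window = long_[off : off + n]
        for a, b in zip(short, window):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            if best is None or mm < best:
                best = mm
                if best == 0:
                    return 0
    return best


def match_with_mismatches(query: str, refset: ReferenceSet) -> Hit | None:
    """Best substitution-tolerant ungapped hit of *query* in *refset*.

    Among references within the mismatch budget, the minimal mismatch count
    wins; ties go to the first reference in the set's order (deterministic).
    Returns None when nothing is within budget.
    """
    query = normalize(query)
    best: Hit | None = None
    for rid, ref in refset.sequences:
        if refset.max_mismatches == 0:
            if query in ref or ref in query:
                return Hit(rid, 0)
            continue
        mm = _best_ungapped(query, ref, refset.max_mismatches)
        if mm is not None and (best is None or mm < best.mismatches):
            best = Hit(rid, mm)
            if mm == 0:
                break
    return best


@dataclass
class ReadLabel:
    sequence: str
    class_name: str
    reference_id: str | None
    mismatches: int | None
    genome_matched: bool


@dataclass
class ClassTable:
    """Per-(class, library) total/unique read counts, Table-style.

    Row order: clean totals, genome-matched, each annotation class, then the
    unclassified remainder.  Conservation: over the annotation classes plus
    "others", total (and unique) reads sum to the clean totals per library.
    """

    libraries: list[str]
    total_reads: dict[str, dict[str, int]]  # class -> lib -> count
    unique_reads: dict[str, dict[str, int]]
    clean_total: dict[str, int]
    clean_unique: dict[str, int]
    genome_total: dict[str, int] = field(default_factory=dict)
    genome_unique: dict[str, int] = field(default_factory=dict)

    def class_names(self) -> list[str]:
        return list(self.total_reads)

    def check_conservation(self) -> None:
        for lib in self.libraries:
            t = sum(self.total_reads[c].get(lib, 0) for c in self.total_reads)
            u = sum(self.unique_reads[c].get(lib, 0) for c in self.unique_reads)
            if t != self.clean_total[lib] or u != self.clean_unique[lib]:
                raise AssertionError(
                    f"class table not conservative in library {lib}: "
                    f"{t}/{self.clean_total[lib]} total, "
                    f"{u}/{self.clean_unique[lib]} unique"
                )

    def fraction(self, class_name: str, library: str, unique: bool = False) -> float:
        """Share of a class among clean reads of one library."""
        if unique:
            return self.unique_reads[class_name][library] / self.clean_unique[library]
        return self.total_reads[class_name][library] / self.clean_total[library]

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        rows["clean_reads"] = {
            **{(lib, "total"): self.clean_total[lib] for lib in self.libraries},
            **{(lib, "unique"): self.clean_unique[lib] for lib in self.libraries},
        }
        if self.genome_total:
            rows["match_genome"] = {
                **{(lib, "total"): self.genome_total.get(lib, 0) for lib in self.libraries},
                **{(lib, "unique"): self.genome_unique.get(lib, 0) for lib in self.libraries},
            }
        for cls in self.total_reads:
            rows[cls] = {
                **{(lib, "total"): self.total_reads[cls].get(lib, 0) for lib in self.libraries},
                **{(lib, "unique"): self.unique_reads[cls].get(lib, 0) for lib in self.libraries},
            }
        frame = pd.DataFrame(rows).T
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return frame.fillna(0).astype(int)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def classify_collapsed_reads(
    reads: Sequence[CollapsedRead],
    refsets: Sequence[ReferenceSet],
    libraries: Sequence[str],
    genome_hits: Mapping[str, bool] | None = None,
) -> tuple[ClassTable, list[ReadLabel]]:
    """Label every read with its first matching class, in precedence order.

    ``genome_hits`` maps read sequence -> bool; genome matching is reported
    as an independent row, never as a class.  Duplicate class labels in
    ``refsets`` are a configuration error.
    """
    names = [r.name for r in refsets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class labels in reference sets")
    genome_hits = genome_hits or {}

    labels: list[ReadLabel] = []
    classes = names + [UNCLASSIFIED]
    total = {c: {lib: 0 for lib in libraries} for c in classes}
    unique = {c: {lib: 0 for lib in libraries} for c in classes}
    clean_total = {lib: 0 for lib in libraries}
    clean_unique = {lib: 0 for lib in libraries}
    genome_total = {lib: 0 for lib in libraries}
    genome_unique = {lib: 0 for lib in libraries}

    for read in reads:
        assigned = UNCLASSIFIED
        hit: Hit | None = None
        for refset in refsets:
            hit = match_with_mismatches(read.sequence, refset)
            if hit is not None:
                assigned = refset.name
                break
        matched_genome = bool(genome_hits.get(read.sequence, False))
        labels.append(
            ReadLabel(
                sequence=read.sequence,
                class_name=assigned,
                reference_id=hit.reference_id if hit else None,
                mismatches=hit.mismatches if hit else None,
                genome_matched=matched_genome,
            )
        )
        for lib in libraries:
            n = read.count_in(lib)
            clean_total[lib] += n
            total[assigned][lib] += n
            if n > 0:
                clean_unique[lib] += 1
                unique[assigned][lib] += 1
                if matched_genome:
                    genome_total[lib] += n
                    genome_unique[lib] += 1

    table = ClassTable(
        libraries=list(libraries),
        total_reads=total,
        unique_reads=unique,
        clean_total=clean_total,
        clean_unique=clean_unique,
        genome_total=genome_total,
        genome_unique=genome_unique,
    )
    table.check_conservation()
    return table, labels


def rptm_normalize(count: int, library_clean_total: int) -> float:
    """Reads-per-ten-million normalisation of a raw count."""
    if library_clean_total <= 0:
        raise ValueError("library clean total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / library_clean_total * RPTM_FACTOR


def length_distribution(
    reads: Iterable[CollapsedRead], library: str
) -> dict[int, float]:
    """Read-length spectrum of one library as fractions of *total* reads."""
    counts: dict[int, int] = {}
    for read in reads:
        n = read.count_in(library)
        if n:
            counts[len(read.sequence)] = counts.get(len(read.sequence), 0) + n
    total = sum(counts.values())
    if total == 0:
        return {}
    return {length: n / total for length, n in sorted(counts.items())}


def write_labels_tsv(labels: Sequence[ReadLabel], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("sequence\tclass\tmismatches\treference_id\tgenome_matched\n")
        for lab in labels:
            out.write(
                f"{lab.sequence}\t{lab.class_name}\t"
                f"{'' if lab.mismatches is None else lab.mismatches}\t"
                f"{lab.reference_id or ''}\t{int(lab.genome_matched)}\n"
            )
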