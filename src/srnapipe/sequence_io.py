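"""Reading, filtering, collapsing and serialising small-RNA reads.

Raw reads arrive as FASTA or FASTQ (optionally gzipped), one file per
library.  Adapter removal is assumed to have happened upstream; this module
only validates the alphabet and applies the length window (default 18-30 nt:
the computational minimum plus the gel size-selection ceiling typical of
plant small-RNA protocols).  Distinct sequences are then collapsed into
:class:`CollapsedRead` records carrying per-library counts -- the "unique
read" unit every later stage operates on.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

from ._seq import is_valid, normalize, to_rna

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30


@dataclass
class RawRead:
    """A single sequenced small RNA prior to collapsing."""

    sequence: str
    library_id: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality string length differs from sequence length")


@dataclass
class CollapsedRead:
    """A unique sequence (DNA-space) with per-library occurrence counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def count_in(self, library_id: str) -> int:
        return self.counts.get(library_id, 0)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterStats:
    """Per-library tally of reads discarded during parsing, by reason."""

    library_id: str
    passed: int = 0
    too_short: int = 0
    too_long: int = 0
    ambiguous: int = 0  # contains N or other non-ACGTU characters
    malformed: int = 0

    @property
    def discarded(self) -> int:
        return self.too_short + self.too_long + self.ambiguous + self.malformed


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def parse_and_filter_reads(
    path: str | Path,
    library_id: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    stats: FilterStats | None = None,
) -> Iterator[RawRead]:
    """Stream length- and alphabet-filtered reads from a FASTA/FASTQ file.

    Bounds are inclusive on both ends.  Reads containing characters outside
    A/C/G/T/U (notably N) are discarded and tallied separately.  Pass a
    :class:`FilterStats` to collect the discard ledger.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    fmt = _sniff_format(path)
    if stats is None:
        stats = FilterStats(library_id)
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, fmt)
        while True:
            try:
                record = next(parser)
            except StopIteration:
                break
            except ValueError as exc:  # malformed record: count, stop cleanly
                stats.malformed += 1
                import warnings

                warnings.warn(f"malformed {fmt} record in {path}: {exc}")
                break
            seq = str(record.seq).upper()
            if not is_valid(seq):
                stats.ambiguous += 1
                continue
            if len(seq) < min_len:
                stats.too_short += 1
                continue
            if len(seq) > max_len:
                stats.too_long += 1
                continue
            qual = None
            if "phred_quality" in record.letter_annotations:
                qual = "".join(
                    chr(q + 33) for q in record.letter_annotations["phred_quality"]
                )
            stats.passed += 1
            yield RawRead(sequence=seq, library_id=library_id, quality=qual)


def collapse_reads(
    reads: Iterable[RawRead], libraries: Sequence[str]
) -> list[CollapsedRead]:
    """Collapse raw reads into unique sequences with per-library counts.

    Total read count is conserved: the sum of ``total_count`` over the output
    equals the number of input reads.  Sequences are U/T-normalised, so an
    RNA- and a DNA-spelled copy of the same molecule collapse together.
    """
    libset = set(libraries)
    counter: dict[str, Counter] = {}
    for read in reads:
        if read.library_id not in libset:
            raise ValueError(f"unknown library_id {read.library_id!r}")
        seq = normalize(read.sequence)
        counter.setdefault(seq, Counter())[read.library_id] += 1
    return [
        CollapsedRead(sequence=seq, counts=dict(counts))
        for seq, counts in sorted(counter.items())
    ]


def expand_reads(collapsed: Iterable[CollapsedRead]) -> Iterator[RawRead]:
    """Inverse of :func:`collapse_reads` (order is by sequence then library)."""
    for rec in collapsed:
        for lib, n in sorted(rec.counts.items()):
            for _ in range(n):
                yield RawRead(sequence=rec.sequence, library_id=lib)


def write_collapsed_fasta(
    collapsed: Sequence[CollapsedRead], path: str | Path, rna: bool = False
) -> None:
    """Write the collapsed-FASTA dialect: ``>u<i>_x<total> lib=<n>;...``."""
    with open(path, "w") as out:
        for i, rec in enumerate(collapsed, start=1):
            libinfo = ";".join(f"{lib}={n}" for lib, n in sorted(rec.counts.items()))
            seq = to_rna(rec.sequence) if rna else rec.sequence
            out.write(f">u{i}_x{rec.total_count} {libinfo}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    records = []
    with _open_text(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:]
            else:
                parts = header.split(None, 1)
                counts: dict[str, int] = {}
                if len(parts) > 1:
                    for item in parts[1].split(";"):
                        lib, _, n = item.partition("=")
                        counts[lib] = int(n)
                records.append(
                    CollapsedRead(sequence=normalize(line), counts=counts)
                )
    return records


def write_collapsed_tsv(
    collapsed: Sequence[CollapsedRead], libraries: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("sequence\t" + "\t".join(libraries) + "\ttotal\n")
        for rec in collapsed:
            row = "\t".join(str(rec.count_in(lib)) for lib in libraries)
            out.write(f"{rec.sequence}\t{row}\t{rec.total_count}\n")


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Plain FASTA -> {id: DNA-space sequence} (for genomes and reference sets)."""
    with _open_text(path) as handle:
        return {
            rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(handle, "fasta")
        }
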