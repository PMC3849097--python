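"""Exact multi-hit mapping of collapsed reads and grouping into loci.

Mapping is deliberately exact (substitution-free) on both strands: every
occurrence of a read or its reverse complement is reported, multi-mappers
keep their full count at every site, and minus-strand hits are stored in
forward coordinates with a strand flag.  Hits on the same chromosome and
strand are then merged (transitively, within ``max_gap``) into read loci --
the units handed to hairpin mining.

The index is a seed table of fixed-length k-mers (k = the minimum read
length) pointing at genome positions; seed hits are verified by direct
string comparison, so results are identical to a naive full scan.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp
from .sequence_io import CollapsedRead


@dataclass(frozen=True)
class GenomeHit:
    read_sequence: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit interval")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


class GenomeIndex:
    """Seed-and-verify exact-match index over a genome dict."""

    def __init__(self, genome: Mapping[str, str], seed_len: int = 18):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.seed_len = seed_len
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                self._seeds[kmer].append((chrom, i))

    def chrom_length(self, chrom: str) -> int:
        return len(self.genome[chrom])

    def find_exact(self, query: str) -> list[tuple[str, int]]:
        """All forward-strand occurrence positions of *query* (exact)."""
        query = query.upper()
        if len(query) < self.seed_len or "N" in query:
            return []
        seed = query[: self.seed_len]
        out = []
        for chrom, pos in self._seeds.get(seed, ()):
            if self.genome[chrom][pos : pos + len(query)] == query:
                out.append((chrom, pos))
        return out


def build_index(genome: Mapping[str, str], seed_len: int = 18) -> GenomeIndex:
    return GenomeIndex(genome, seed_len=seed_len)


def map_sequence(sequence: str, index: GenomeIndex) -> list[GenomeHit]:
    """All exact hits of a sequence on both strands, forward coordinates."""
    hits: list[GenomeHit] = []
    n = len(sequence)
    for chrom, pos in index.find_exact(sequence):
        hits.append(GenomeHit(sequence, chrom, pos, pos + n, "+"))
    rc = revcomp(sequence)
    for chrom, pos in index.find_exact(rc):
        # a palindromic read would hit the same interval on both strands;
        # keep both, mirroring how an aligner reports strandedness
        hits.append(GenomeHit(sequence, chrom, pos, pos + n, "-"))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def map_read(read: CollapsedRead, index: GenomeIndex) -> list[GenomeHit]:
    return map_sequence(read.sequence, index)


def map_all(
    reads: Iterable[CollapsedRead], index: GenomeIndex
) -> dict[str, list[GenomeHit]]:
    """Map every read; returns {sequence: hits} (possibly empty lists)."""
    return {read.sequence: map_read(read, index) for read in reads}


@dataclass
class ReadLocus:
    """A maximal same-strand cluster of overlapping/nearby hits."""

    chrom: str
    strand: str
    start: int
    end: int
    hits: list[GenomeHit] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)  # sequence -> total count

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def summit(self) -> int:
        """Position with the deepest stack of (count-weighted) 5' ends.

        The 5' end of a minus-strand hit is its rightmost forward coordinate.
        Ties break to the leftmost position.
        """
        depth: dict[int, int] = defaultdict(int)
        for hit in self.hits:
            five = hit.start if hit.strand == "+" else hit.end - 1
            depth[five] += self.counts.get(hit.read_sequence, 1)
        return min(sorted(depth), key=lambda p: (-depth[p], p))


def cluster_loci(
    hits: Sequence[GenomeHit],
    counts: Mapping[str, int],
    max_gap: int = 200,
) -> list[ReadLocus]:
    """Merge hits into maximal loci: same chrom+strand, gaps <= max_gap.

    The result partitions the input hits and is invariant under input order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    groups: dict[tuple[str, str], list[GenomeHit]] = defaultdict(list)
    for hit in hits:
        groups[(hit.chrom, hit.strand)].append(hit)
    loci: list[ReadLocus] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.start, h.end))
        current: list[GenomeHit] = []
        cur_end = None
        for hit in members:
            if cur_end is not None and hit.start > cur_end + max_gap:
                loci.append(_make_locus(chrom, strand, current, counts))
                current = []
                cur_end = None
            current.append(hit)
            cur_end = hit.end if cur_end is None else max(cur_end, hit.end)
        if current:
            loci.append(_make_locus(chrom, strand, current, counts))
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return loci


def _make_locus(
    chrom: str, strand: str, members: list[GenomeHit], counts: Mapping[str, int]
) -> ReadLocus:
    locus = ReadLocus(
        chrom=chrom,
        strand=strand,
        start=min(h.start for h in members),
        end=max(h.end for h in members),
        hits=list(members),
    )
    for hit in members:
        locus.counts[hit.read_sequence] = counts.get(hit.read_sequence, 1)
    return locus


def write_hits_bed(
    hits: Sequence[GenomeHit], counts: Mapping[str, int], path: str | Path
) -> None:
    """BED6; the name field carries the read sequence, score its total count."""
    with open(path, "w") as out:
        for hit in hits:
            out.write(
                f"{hit.chrom}\t{hit.start}\t{hit.end}\t{hit.read_sequence}\t"
                f"{counts.get(hit.read_sequence, 1)}\t{hit.strand}\n"
            )


def write_loci_bed(loci: Sequence[ReadLocus], path: str | Path) -> None:
    with open(path, "w") as out:
        for i, locus in enumerate(loci, start=1):
            out.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\tlocus{i}"
                f";summit={locus.summit}\t{locus.total_count}\t{locus.strand}\n"
            )
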