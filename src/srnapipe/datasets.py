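"""Bundled literature-reported summary tables for validation arithmetic.

These are printed summary values from a published study of four elongating
cotton fiber small-RNA libraries (5, 10, 15 and 20 days post-anthesis):
the per-class read-count table, the abundance anchors of the four most
abundant known-miRNA families, and the 5'-nucleotide x length cells of the
reported novel miRNAs.  They serve as *inputs* to the package's own
containers and tabulators, so that the arithmetic those components perform
(class fractions, abundance shares, contingency marginals) can be checked
against the printed numbers.
"""

from __future__ import annotations

from .read_classifier import ClassTable

FIBER_LIBRARIES = ("5dpa", "10dpa", "15dpa", "20dpa")

_CLEAN_TOTAL = {
    "5dpa": 17_979_849,
    "10dpa": 18_747_051,
    "15dpa": 19_597_538,
    "20dpa": 17_845_500,
}
_CLEAN_UNIQUE = {
    "5dpa": 7_335_047,
    "10dpa": 7_111_913,
    "15dpa": 6_491_658,
    "20dpa": 4_878_094,
}
_GENOME_TOTAL = {
    "5dpa": 4_983_316,
    "10dpa": 7_113_695,
    "15dpa": 7_107_883,
    "20dpa": 8_871_116,
}
_GENOME_UNIQUE = {
    "5dpa": 1_828_847,
    "10dpa": 1_876_311,
    "15dpa": 1_731_526,
    "20dpa": 1_299_290,
}

# class -> (total reads per library, unique reads per library)
_CLASS_ROWS: dict[str, tuple[tuple[int, int, int, int], tuple[int, int, int, int]]] = {
    "protein_coding": ((198_666, 175_439, 189_071, 160_087), (82_988, 90_480, 112_705, 101_770)),
    "known_miRNA": ((307_112, 641_621, 553_022, 419_974), (803, 942, 909, 809)),
    "repeat": ((467_372, 509_173, 454_975, 441_256), (197_195, 182_749, 162_696, 125_578)),
    "rRNA": ((395_288, 992_921, 1_363_365, 2_212_532), (14_564, 22_415, 26_009, 33_079)),
    "tRNA": ((174_510, 1_106_240, 1_104_728, 2_040_671), (2_418, 3_772, 4_456, 6_779)),
    "snRNA": ((1_487, 2_743, 3_654, 5_026), (585, 940, 1_111, 1_288)),
    "snoRNA": ((301, 511, 629, 540), (187, 267, 302, 256)),
    "others": ((16_435_113, 15_318_403, 15_928_094, 12_565_414), (7_036_307, 6_810_348, 6_183_470, 4_608_535)),
}


def fiber_class_table() -> ClassTable:
    """The reported per-class read distribution as a ClassTable.

    The rows are conservative (classes plus the unclassified remainder sum
    to the clean totals in every library), which the container asserts.
    """
    libs = list(FIBER_LIBRARIES)
    total = {
        cls: dict(zip(libs, rows[0])) for cls, rows in _CLASS_ROWS.items()
    }
    unique = {
        cls: dict(zip(libs, rows[1])) for cls, rows in _CLASS_ROWS.items()
    }
    table = ClassTable(
        libraries=libs,
        total_reads=total,
        unique_reads=unique,
        clean_total=dict(_CLEAN_TOTAL),
        clean_unique=dict(_CLEAN_UNIQUE),
        genome_total=dict(_GENOME_TOTAL),
        genome_unique=dict(_GENOME_UNIQUE),
    )
    table.check_conservation()
    return table


# family -> reported mean abundance in reads per ten million; the share of
# all known-miRNA reads is reported for the most abundant family (anchor)
KNOWN_FAMILY_RPTM = {
    "mir167": 164_706.0,
    "mir156/157": 86_430.0,
    "mir165/166": 71_375.0,
    "mir894": 39_985.0,
}
ANCHOR_FAMILY = "mir167"
ANCHOR_SHARE_PERCENT = 41.3


def family_share_percent(family: str) -> float:
    """Share of all known-miRNA reads held by one family, in percent.

    Derived from the anchor family's reported share: the total known-miRNA
    RPTM pool is anchor_rptm / anchor_share, and every family's share is
    its RPTM over that pool.
    """
    pool = KNOWN_FAMILY_RPTM[ANCHOR_FAMILY] / (ANCHOR_SHARE_PERCENT / 100.0)
    return 100.0 * KNOWN_FAMILY_RPTM[family] / pool


# reported 5'-terminal nucleotide x mature length cells of the novel miRNAs
NOVEL_5PRIME_LENGTH_CELLS: dict[tuple[str, int], int] = {
    ("A", 20): 3, ("A", 21): 23, ("A", 22): 1, ("A", 23): 6, ("A", 24): 54,
    ("C", 20): 1, ("C", 21): 11, ("C", 22): 1, ("C", 23): 2, ("C", 24): 15,
    ("G", 20): 0, ("G", 21): 5, ("G", 22): 2, ("G", 23): 2, ("G", 24): 8,
    ("U", 20): 3, ("U", 21): 48, ("U", 22): 6, ("U", 23): 13, ("U", 24): 53,
}


def novel_5prime_length_pairs() -> list[tuple[str, int]]:
    """The reported cells expanded to one (5' nt, length) pair per miRNA."""
    pairs = []
    for (nt, length), n in sorted(NOVEL_5PRIME_LENGTH_CELLS.items()):
        pairs.extend([(nt, length)] * n)
    return pairs
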