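"""Synthetic genome, reference sets and read libraries with planted truth.

The generator emulates the statistical structure of a four-time-point
plant small-RNA experiment (libraries named after 5/10/15/20 days
post-anthesis fiber samples):

* known-miRNA hairpins planted in a random genome, with family-level
  temporal abundance patterns (rising / mid-peaking / declining), a
  3'-adenylated variant family and a family whose representative sequence
  switches in the last library;
* novel hairpins engineered to pass the discovery rules with wide margins
  (candidate-set fraction ~0.99, reliable fraction ~0.9, clean duplexes),
  a subset with star reads at the exact 2-nt-overhang partner position;
* decoy hairpins violating exactly one named rule each (rule-1 fraction,
  rule-1 reliable count, duplex mismatches, bulge size, bulge count);
* a TAS3-like transcript carrying two trigger-complementary sites 231 nt
  apart (11 phase windows) with perfectly phased 21-nt reads dominated by
  the D7 window;
* annotation decoy reference sets (rRNA/tRNA/snRNA/snoRNA/repeat/mRNA)
  with matching reads, and uniform background reads from non-feature
  genome regions.

Counts are drawn per library from a gamma-Poisson (negative-binomial
style) model around planted means; structurally critical low-count reads
(5'-jitter and off-candidate reads) are emitted at fixed counts so rule
margins cannot drift.  Every planted hairpin is validated at generation
time with the pipeline's own folding/duplex evaluator, so the ledgered
truth holds for any seed.  All output is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._seq import revcomp, to_rna
from .hairpin_miner import (
    DEFAULT_FLANKS,
    DuplexReport,
    evaluate_duplex,
    fold_hairpin,
)

LIBRARIES: tuple[str, ...] = ("dpa05", "dpa10", "dpa15", "dpa20")

# per-library relative abundance archetypes (5,10,15,20 dpa analogues)
TYPE_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "A": (0.10, 0.20, 0.40, 1.00),  # rising to the last time point
    "B10": (0.15, 1.00, 0.70, 0.10),  # peaking at the second
    "B15": (0.15, 0.70, 1.00, 0.10),  # peaking at the third
    "C": (1.00, 0.50, 0.20, 0.10),  # declining from the first
    "flat": (1.00, 1.00, 1.00, 1.00),
    "late_only": (0.04, 0.04, 0.04, 1.00),
}
TYPE_LABEL: dict[str, str | None] = {
    "A": "A",
    "B10": "B",
    "B15": "B",
    "C": "C",
    "flat": None,
    "late_only": None,
}

# family name, temporal archetype, peak-library mean count, extra databases
KNOWN_FAMILY_SPEC: tuple[tuple[str, str, int, tuple[str, ...]], ...] = (
    ("mir156", "A", 600, ()),
    ("mir159", "C", 500, ()),
    ("mir167", "B10", 800, ()),  # carries the 3'-adenylated variant
    ("mir172", "B15", 400, ()),  # representative switches at the last library
    ("mir390", "C", 450, ()),  # the tasiRNA trigger
    ("mir396", "B10", 500, ("EST",)),
    ("mir482", "A", 350, ("GSS",)),
    ("mir2948", "flat", 300, ()),
)

# name, mature length, 5' nucleotide (DNA-space), archetype, peak mean, star?
NOVEL_SPEC: tuple[tuple[str, int, str, str, int, bool], ...] = (
    ("novel01", 21, "T", "A", 200, True),
    ("novel02", 21, "T", "B10", 180, False),
    ("novel03", 21, "T", "B15", 160, True),
    ("novel04", 21, "T", "C", 220, False),
    ("novel05", 21, "T", "A", 150, False),
    ("novel06", 24, "A", "B10", 200, True),
    ("novel07", 24, "A", "C", 170, False),
    ("novel08", 24, "A", "A", 190, False),
    ("novel09", 22, "C", "B15", 210, False),
    ("novel10", 20, "G", "B10", 140, False),
)

# decoy name -> the single rule each one violates
DECOY_SPEC: tuple[tuple[str, str], ...] = (
    ("decoy_frac", "rule1_fraction"),
    ("decoy_rel", "rule1_reliable"),
    ("decoy_mm1", "mismatch"),
    ("decoy_mm2", "mismatch"),
    ("decoy_bsize", "bulge_size"),
    ("decoy_bcount", "bulge_count"),
)

# rule label -> rule-trace key that must be False on the decoy's call
DECOY_TRACE_KEY: dict[str, str] = {
    "rule1_fraction": "rule1_fraction",
    "rule1_reliable": "rule1_reliable",
    "mismatch": "rule3_mismatch",
    "bulge_size": "rule3_bulge_size",
    "bulge_count": "rule3_bulge_count",
}

ANNOTATION_CLASSES: tuple[str, ...] = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "protein_coding",
)

_REGION_FLANK = 320  # random context kept on each side of a planted hairpin
_REGION_SPACING = 800
_FIRST_REGION = 1000


@dataclass
class SimulationParams:
    genome_length: int = 100_000
    chrom_name: str = "chr1"
    ext_len: int = 10  # stem extension beyond the duplex on each arm
    loop_len: int = 12
    background_reads_per_library: int = 1200
    background_fraction_note: float = 0.30  # informational share of depth
    background_length_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.05, 21: 0.15, 22: 0.10, 23: 0.10, 24: 0.60}
    )
    overdispersion: float = 0.01  # gamma-Poisson phi; var = mu + phi*mu^2
    star_ratio: float = 0.15  # star:mature mean-count ratio
    adenylation_weights: tuple[float, ...] = (1.5, 1.5, 1.5, 0.25)
    positional_jitter: int = 0  # 5'-end jitter of phased reads, in nt
    phase_period: int = 21
    tas_windows: int = 11
    tas_planted_positions: tuple[int, ...] = (2, 3, 5, 6, 7, 8, 9, 10)
    tas_dominant_position: int = 7
    tas_dominant_weight: float = 4.0
    tas_profile: tuple[float, float, float, float] = (30.0, 100.0, 60.0, 15.0)
    annotation_read_mean: float = 25.0

    def validate(self) -> None:
        if self.genome_length < _FIRST_REGION + 30 * _REGION_SPACING:
            raise ValueError("genome too short for the planted feature layout")
        if not 0 <= self.star_ratio <= 1:
            raise ValueError("star_ratio must lie in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.positional_jitter < 0:
            raise ValueError("positional_jitter must be >= 0")
        if abs(sum(self.background_length_weights.values()) - 1.0) > 1e-9:
            raise ValueError("background length weights must sum to 1")
        if self.tas_dominant_position not in self.tas_planted_positions:
            raise ValueError("dominant phase position must be planted")


@dataclass
class ReadEntity:
    """One planted read sequence with per-library mean counts."""

    entity_id: str
    sequence: str
    category: str  # mature/star/jitter/off/tail/annotation/phased
    parent: str | None
    mean_counts: dict[str, float]
    fixed: bool = False  # emitted at round(mean), exempt from count noise

    def expected_sd(self, phi: float) -> dict[str, float]:
        if self.fixed:
            return {lib: 0.0 for lib in self.mean_counts}
        return {
            lib: float(np.sqrt(mu + phi * mu * mu))
            for lib, mu in self.mean_counts.items()
        }


@dataclass
class PlantedHairpin:
    name: str
    kind: str  # 'known' | 'novel' | 'decoy'
    family: str | None
    mature: str
    star: str | None
    chrom: str
    region_start: int
    region_end: int
    mature_start: int  # genomic 0-based
    star_start: int | None
    profile_key: str | None
    violated_rule: str | None = None
    expect_accept: bool | None = None


@dataclass
class PlantedTas:
    transcript_id: str
    transcript: str
    trigger_family: str
    trigger: str
    site5: tuple[int, int]  # 1-based inclusive
    site3: tuple[int, int]
    cleavage_after: int
    planted_positions: tuple[int, ...]
    dominant_position: int
    window_means: dict[int, dict[str, float]]


@dataclass
class TruthSet:
    seed: int
    params: SimulationParams
    libraries: tuple[str, ...]
    hairpins: list[PlantedHairpin]
    tas: PlantedTas
    entities: list[ReadEntity]
    known_types: dict[str, str | None]  # family -> planted A/B/C or None
    novel_types: dict[str, str]  # novel name -> planted A/B/C
    novel_matures: dict[str, str]  # novel name -> mature (DNA-space)
    decoy_rules: dict[str, str]  # decoy name -> violated rule label

    def hairpin(self, name: str) -> PlantedHairpin:
        return next(h for h in self.hairpins if h.name == name)

    def expected_accepted_matures(self) -> set[str]:
        return set(self.novel_matures.values())

    def planted_type_by_family(self) -> dict[str, str]:
        """Family/novel-name -> planted temporal label, typed entries only."""
        out = {f: t for f, t in self.known_types.items() if t is not None}
        out.update(self.novel_types)
        return out


@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    known_mirnas: dict[str, str]  # reference id (family|member) -> sequence
    annotation_refs: dict[str, dict[str, str]]  # class -> {id: seq}
    est_db: dict[str, str]
    gss_db: dict[str, str]
    transcripts: dict[str, str]
    truth: TruthSet


# ---------------------------------------------------------------------------
# primitive builders


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _min_ungapped_distance(a: str, b: str) -> int:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = len(short)
    for off in range(len(long_) - len(short) + 1):
        d = sum(x != y for x, y in zip(short, long_[off : off + len(short)]))
        best = min(best, d)
    return best


def _distinct_mature(
    rng: np.random.Generator, length: int, first: str, existing: Sequence[str]
) -> str:
    for _ in range(200):
        seq = first + _random_seq(rng, length - 1)
        if all(_min_ungapped_distance(seq, e) > 2 for e in existing):
            return seq
    raise RuntimeError("could not sample a distinct mature sequence")


def _core_sequence(
    rng: np.random.Generator,
    mature: str,
    ext_len: int,
    loop_len: int,
    violated: str | None,
) -> str:
    """Stem-loop core: ext+mature / loop / (possibly corrupted) partner arm."""
    ext = _random_seq(rng, ext_len)
    arm1 = ext + mature
    loop = "A" + _random_seq(rng, loop_len - 1)  # leading A templates +A tails
    arm2 = list(revcomp(arm1))
    n = len(arm1)
    L = len(mature)

    def partner(i: int) -> int:  # arm2 index pairing mature position i
        return n - 1 - (ext_len + i)

    if violated == "mismatch":
        for i in (2, 4, 6, 9, 12, 15, 17):
            arm2[partner(i)] = mature[i]  # identical bases cannot pair
    elif violated == "bulge_size":
        q = partner(10)
        arm2[q + 1 : q + 1] = list(_random_seq(rng, 4))
    elif violated == "bulge_count":
        for i in (4, 8, 12, 16):  # ascending i = descending arm2 index
            q = partner(i)
            arm2[q + 1 : q + 1] = [rng.choice(list("ACGT"))]
    return arm1 + loop + "".join(arm2)


def _best_window_duplex(
    region: str, summit: int, mature_len: int
) -> tuple[int, int, DuplexReport] | None:
    """Replicate the miner's window choice on a planted region.

    Returns (window_start, window_end, duplex) in region coordinates for
    the best-folding window, or None when nothing folds.
    """
    best = None
    for f5, f3 in DEFAULT_FLANKS:
        ws, we = max(0, summit - f5), min(len(region), summit + f3 + 1)
        folded = fold_hairpin(region[ws:we])
        if folded is None:
            continue
        key = (folded.score, we - ws, ws)
        if best is None or key < best[0]:
            best = (key, ws, we, folded)
    if best is None:
        return None
    _, ws, we, folded = best
    duplex = evaluate_duplex(folded, (summit - ws, summit - ws + mature_len))
    return ws, we, duplex


def _duplex_matches_expectation(duplex: DuplexReport, violated: str | None) -> bool:
    if not duplex.ok:
        return False
    mm_ok = duplex.mismatch_count < 5
    size_ok = all(b.size <= 2 for b in duplex.bulges)
    count_ok = len(duplex.bulges) <= 2
    if violated in (None, "rule1_fraction", "rule1_reliable"):
        # clean geometry, at least 2 units from every rule-3 threshold
        return (
            duplex.mismatch_count <= 2
            and size_ok
            and len(duplex.bulges) <= 0
            and duplex.star_overhang_ok
        )
    if violated == "mismatch":
        return duplex.mismatch_count >= 6 and size_ok and count_ok
    if violated == "bulge_size":
        return mm_ok and count_ok and any(b.size >= 4 for b in duplex.bulges)
    if violated == "bulge_count":
        return mm_ok and size_ok and len(duplex.bulges) >= 4
    raise ValueError(violated)


def _build_validated_region(
    rng: np.random.Generator,
    mature: str,
    params: SimulationParams,
    violated: str | None,
) -> tuple[str, int, int | None]:
    """Random-flank region around a planted hairpin, fold-validated.

    Returns (region, mature_offset, star_offset); regenerates the random
    parts until the best-folding window's duplex matches the planted
    expectation, so the truth ledger is honest for any seed.
    """
    for _ in range(60):
        core = _core_sequence(
            rng, mature, params.ext_len, params.loop_len, violated
        )
        region = (
            _random_seq(rng, _REGION_FLANK) + core + _random_seq(rng, _REGION_FLANK)
        )
        summit = _REGION_FLANK + params.ext_len
        picked = _best_window_duplex(region, summit, len(mature))
        if picked is None:
            continue
        ws, _, duplex = picked
        if not _duplex_matches_expectation(duplex, violated):
            continue
        star_offset = None
        if duplex.star_interval is not None and duplex.star_overhang_ok:
            star_offset = ws + duplex.star_interval[0]
        if violated is None and star_offset is None:
            continue
        return region, summit, star_offset
    raise RuntimeError(f"could not engineer hairpin (violated={violated!r})")


# ---------------------------------------------------------------------------
# genome + truth assembly


def _profile_means(profile_key: str, scale: float) -> dict[str, float]:
    return {
        lib: scale * w for lib, w in zip(LIBRARIES, TYPE_PROFILES[profile_key])
    }


def _jitter_entities(
    name: str,
    genome: str,
    mature_start: int,
    mature_len: int,
) -> list[ReadEntity]:
    """Low-count 5'-jitter reads around a mature (fixed count 1/library)."""
    combos = [
        (-2, 0),
        (-1, 0),
        (1, 0),
        (2, 0),
        (0, -1),
        (0, 1),
        (-1, -1),
        (1, 1),
        (2, -1),
    ]
    out = []
    for i, (off, dlen) in enumerate(combos):
        start = mature_start + off
        length = mature_len + dlen
        seq = genome[start : start + length]
        out.append(
            ReadEntity(
                entity_id=f"{name}_jit{i}",
                sequence=seq,
                category="jitter",
                parent=name,
                mean_counts={lib: 1.0 for lib in LIBRARIES},
                fixed=True,
            )
        )
    return out


def _reliable_decoy_entities(
    name: str, genome: str, mature_start: int, mature_len: int
) -> list[ReadEntity]:
    """All-low-count candidate stack: every read stays below 5 copies."""
    combos = [
        (-1, 0),
        (-1, 1),
        (0, -1),
        (0, 0),
        (0, 1),
        (1, -1),
        (1, 0),
        (1, 1),
    ]
    out = []
    for i, (off, dlen) in enumerate(combos):
        start = mature_start + off
        length = mature_len + dlen
        out.append(
            ReadEntity(
                entity_id=f"{name}_lc{i}",
                sequence=genome[start : start + length],
                category="jitter",
                parent=name,
                mean_counts={lib: 1.0 for lib in LIBRARIES},
                fixed=True,
            )
        )
    return out


def synthesize_genome(
    params: SimulationParams | None = None, seed: int = 1
) -> SyntheticBundle:
    """Build the genome, reference sets, TAS transcript and truth ledger."""
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng([int(seed), 11])

    genome = list(_random_seq(rng, params.genome_length))
    matures: list[str] = []
    hairpins: list[PlantedHairpin] = []
    entities: list[ReadEntity] = []
    known_refs: dict[str, str] = {}
    known_types: dict[str, str | None] = {}
    est_db: dict[str, str] = {}
    gss_db: dict[str, str] = {}

    region_slots = iter(range(_FIRST_REGION, params.genome_length, _REGION_SPACING))

    def place(region: str) -> int:
        pos = next(region_slots)
        genome[pos : pos + len(region)] = list(region)
        return pos

    # --- known families -----------------------------------------------------
    for fam, profile_key, scale, extra_dbs in KNOWN_FAMILY_SPEC:
        mature = _distinct_mature(rng, 21, "T", matures)
        matures.append(mature)
        region, summit, _ = _build_validated_region(rng, mature, params, None)
        pos = place(region)
        hairpins.append(
            PlantedHairpin(
                name=fam,
                kind="known",
                family=fam,
                mature=mature,
                star=None,
                chrom=params.chrom_name,
                region_start=pos,
                region_end=pos + len(region),
                mature_start=pos + summit,
                star_start=None,
                profile_key=profile_key,
            )
        )
        known_refs[f"{fam}|a"] = mature
        known_types[fam] = TYPE_LABEL[profile_key]
        precursor = region[
            _REGION_FLANK - 20 : _REGION_FLANK + len(region) - 2 * _REGION_FLANK + 20
        ]
        for db_name in extra_dbs:
            target = est_db if db_name == "EST" else gss_db
            target[f"{db_name}_{fam}_pre"] = precursor

        means = _profile_means(profile_key, scale)
        if fam == "mir167":
            # adenylated 3' variant dominates the first three libraries
            weights = dict(zip(LIBRARIES, params.adenylation_weights))
            variant = mature + "A"  # templated by the loop's leading A
            entities.append(
                ReadEntity(
                    entity_id=f"{fam}_mature",
                    sequence=mature,
                    category="mature",
                    parent=fam,
                    mean_counts=means,
                )
            )
            entities.append(
                ReadEntity(
                    entity_id=f"{fam}_tailA",
                    sequence=variant,
                    category="tail",
                    parent=fam,
                    mean_counts={lib: means[lib] * weights[lib] for lib in LIBRARIES},
                )
            )
        elif fam == "mir172":
            # second member takes over as representative in the last library
            member2 = mature[:10] + _flip_bases(mature[10:12]) + mature[12:]
            entities.append(
                ReadEntity(
                    entity_id=f"{fam}_mature",
                    sequence=mature,
                    category="mature",
                    parent=fam,
                    mean_counts=means,
                )
            )
            entities.append(
                ReadEntity(
                    entity_id=f"{fam}_member2",
                    sequence=member2,
                    category="mature",
                    parent=fam,
                    mean_counts=_profile_means("late_only", 120),
                )
            )
        else:
            entities.append(
                ReadEntity(
                    entity_id=f"{fam}_mature",
                    sequence=mature,
                    category="mature",
                    parent=fam,
                    mean_counts=means,
                )
            )

    # --- novel miRNAs -------------------------------------------------------
    novel_types: dict[str, str] = {}
    novel_matures: dict[str, str] = {}
    for name, length, first, profile_key, scale, has_star in NOVEL_SPEC:
        mature = _distinct_mature(rng, length, first, matures)
        matures.append(mature)
        region, summit, star_off = _build_validated_region(rng, mature, params, None)
        pos = place(region)
        gstart = pos + summit
        star_start = pos + star_off if star_off is not None else None
        star_seq = None
        if has_star and star_start is not None:
            star_seq = "".join(genome[star_start : star_start + length])
        hairpins.append(
            PlantedHairpin(
                name=name,
                kind="novel",
                family=None,
                mature=mature,
                star=star_seq,
                chrom=params.chrom_name,
                region_start=pos,
                region_end=pos + len(region),
                mature_start=gstart,
                star_start=star_start if has_star else None,
                profile_key=profile_key,
                expect_accept=True,
            )
        )
        novel_types[name] = TYPE_LABEL[profile_key]  # type: ignore[assignment]
        novel_matures[name] = mature
        means = _profile_means(profile_key, scale)
        entities.append(
            ReadEntity(
                entity_id=f"{name}_mature",
                sequence=mature,
                category="mature",
                parent=name,
                mean_counts=means,
            )
        )
        if has_star and star_seq is not None:
            entities.append(
                ReadEntity(
                    entity_id=f"{name}_star",
                    sequence=star_seq,
                    category="star",
                    parent=name,
                    mean_counts={
                        lib: params.star_ratio * mu for lib, mu in means.items()
                    },
                )
            )
        genome_str = "".join(genome)
        entities.extend(_jitter_entities(name, genome_str, gstart, length))
        entities.append(
            ReadEntity(
                entity_id=f"{name}_off",
                sequence=genome_str[gstart + 7 : gstart + 7 + length],
                category="off",
                parent=name,
                mean_counts={lib: 1.0 for lib in LIBRARIES},
                fixed=True,
            )
        )

    # --- decoy hairpins -----------------------------------------------------
    decoy_rules: dict[str, str] = {}
    for name, rule in DECOY_SPEC:
        mature = _distinct_mature(rng, 21, "T", matures)
        matures.append(mature)
        geometry = rule if rule in ("mismatch", "bulge_size", "bulge_count") else rule
        region, summit, _ = _build_validated_region(rng, mature, params, geometry)
        pos = place(region)
        gstart = pos + summit
        hairpins.append(
            PlantedHairpin(
                name=name,
                kind="decoy",
                family=None,
                mature=mature,
                star=None,
                chrom=params.chrom_name,
                region_start=pos,
                region_end=pos + len(region),
                mature_start=gstart,
                star_start=None,
                profile_key="flat",
                violated_rule=rule,
                expect_accept=False,
            )
        )
        decoy_rules[name] = rule
        genome_str = "".join(genome)
        if rule == "rule1_reliable":
            entities.extend(
                _reliable_decoy_entities(name, genome_str, gstart, len(mature))
            )
            continue
        means = _profile_means("flat", 100)
        entities.append(
            ReadEntity(
                entity_id=f"{name}_mature",
                sequence=mature,
                category="mature",
                parent=name,
                mean_counts=means,
            )
        )
        entities.extend(_jitter_entities(name, genome_str, gstart, len(mature)))
        if rule == "rule1_fraction":
            off_slice = genome_str[gstart + 7 : gstart + 7 + len(mature)]
            entities.append(
                ReadEntity(
                    entity_id=f"{name}_off",
                    sequence=off_slice,
                    category="off",
                    parent=name,
                    mean_counts={lib: 0.35 * mu for lib, mu in means.items()},
                )
            )
            # antisense copy so the mirror-strand locus fails rule 1 too
            entities.append(
                ReadEntity(
                    entity_id=f"{name}_off_as",
                    sequence=revcomp(off_slice),
                    category="off",
                    parent=name,
                    mean_counts={lib: 0.35 * mu for lib, mu in means.items()},
                )
            )
        else:
            entities.append(
                ReadEntity(
                    entity_id=f"{name}_off",
                    sequence=genome_str[gstart + 7 : gstart + 7 + len(mature)],
                    category="off",
                    parent=name,
                    mean_counts={lib: 1.0 for lib in LIBRARIES},
                    fixed=True,
                )
            )

    # --- TAS3-like transcript ----------------------------------------------
    trigger = known_refs["mir390|a"]
    tas = _build_tas(rng, trigger, params)
    for k, means in tas.window_means.items():
        start0 = tas.cleavage_after + params.phase_period * (k - 1)  # 0-based
        seq = tas.transcript[start0 : start0 + params.phase_period]
        entities.append(
            ReadEntity(
                entity_id=f"tas_D{k}",
                sequence=seq,
                category="phased",
                parent=tas.transcript_id,
                mean_counts=means,
            )
        )

    # --- annotation decoy classes -------------------------------------------
    annotation_refs: dict[str, dict[str, str]] = {}
    for cls in ANNOTATION_CLASSES:
        refs = {}
        for i in range(3):
            refs[f"{cls}_{i}"] = _random_seq(rng, 150)
        annotation_refs[cls] = refs
        for i, (rid, rseq) in enumerate(refs.items()):
            for j, off in enumerate((10, 60)):
                entities.append(
                    ReadEntity(
                        entity_id=f"{cls}_{i}_{j}",
                        sequence=rseq[off : off + 24],
                        category="annotation",
                        parent=cls,
                        mean_counts={
                            lib: params.annotation_read_mean for lib in LIBRARIES
                        },
                    )
                )

    genome_str = "".join(genome)
    est_db[tas.transcript_id] = tas.transcript

    truth = TruthSet(
        seed=int(seed),
        params=params,
        libraries=LIBRARIES,
        hairpins=hairpins,
        tas=tas,
        entities=entities,
        known_types=known_types,
        novel_types={k: v for k, v in novel_types.items() if v is not None},
        novel_matures=novel_matures,
        decoy_rules=decoy_rules,
    )
    return SyntheticBundle(
        genome={params.chrom_name: genome_str},
        known_mirnas=known_refs,
        annotation_refs=annotation_refs,
        est_db=est_db,
        gss_db=gss_db,
        transcripts={tas.transcript_id: tas.transcript},
        truth=truth,
    )


def _flip_bases(s: str) -> str:
    flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
    return "".join(flip[c] for c in s)


def _build_tas(
    rng: np.random.Generator, trigger: str, params: SimulationParams
) -> PlantedTas:
    """Transcript with two trigger-complementary sites and a phased cluster.

    The 5' site is a perfect complement; the 3' site carries two G:U
    wobbles (penalty 1.0).  The sites sit 11 phase windows apart so the
    inter-site span holds D1..D11 exactly.
    """
    period = params.phase_period
    n_win = params.tas_windows
    site_len = len(trigger)
    site5_start0 = 60
    site5 = revcomp(trigger)  # perfect complementarity
    t = site5_start0 + site_len - 10  # cleavage_after, 1-based
    site3_start0 = t + period * n_win  # 0-based; 1-based start = span end + 1
    site3 = list(revcomp(trigger))
    wobbled = 0
    for i, base in enumerate(trigger):  # trigger pos i pairs site pos n-1-i
        if base == "G" and wobbled < 2:
            site3[site_len - 1 - i] = "T"  # G:U wobble
            wobbled += 1
    if wobbled < 2:  # trigger had <2 G's; wobble U:G instead
        for i, base in enumerate(trigger):
            if base == "T" and wobbled < 2:
                site3[site_len - 1 - i] = "G"
                wobbled += 1
    length = site3_start0 + site_len + 60
    transcript = list(_random_seq(rng, length))
    transcript[site5_start0 : site5_start0 + site_len] = list(site5)
    transcript[site3_start0 : site3_start0 + site_len] = list(site3)
    transcript_str = "".join(transcript)

    window_means: dict[int, dict[str, float]] = {}
    for k in params.tas_planted_positions:
        weight = (
            params.tas_dominant_weight if k == params.tas_dominant_position else 1.0
        )
        window_means[k] = {
            lib: weight * w for lib, w in zip(LIBRARIES, params.tas_profile)
        }
    return PlantedTas(
        transcript_id="EST_TAS3_like",
        transcript=transcript_str,
        trigger_family="mir390",
        trigger=trigger,
        site5=(site5_start0 + 1, site5_start0 + site_len),
        site3=(site3_start0 + 1, site3_start0 + site_len),
        cleavage_after=t,
        planted_positions=params.tas_planted_positions,
        dominant_position=params.tas_dominant_position,
        window_means=window_means,
    )


# ---------------------------------------------------------------------------
# read simulation


def _draw_count(
    rng: np.random.Generator, mean: float, phi: float
) -> int:
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    lam = mean * rng.gamma(shape=1.0 / phi, scale=phi)
    return int(rng.poisson(lam))


def simulate_read_libraries(
    bundle: SyntheticBundle,
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write one FASTQ per library; deterministic for a fixed seed.

    Planted entities are realised with gamma-Poisson noise (fixed-count
    entities exactly); background reads are drawn uniformly from
    non-feature genome regions with the configured length spectrum.
    Returns {library_id: fastq_path}.
    """
    params = bundle.truth.params
    seed = bundle.truth.seed if seed is None else int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = bundle.genome[params.chrom_name]

    blocked: list[tuple[int, int]] = [
        (h.region_start - 210, h.region_end + 210) for h in bundle.truth.hairpins
    ]

    def is_blocked(start: int, end: int) -> bool:
        return any(start < b1 and end > b0 for b0, b1 in blocked)

    lengths = sorted(params.background_length_weights)
    weights = np.array([params.background_length_weights[l] for l in lengths])
    weights = weights / weights.sum()

    paths: dict[str, Path] = {}
    for lib_idx, lib in enumerate(bundle.truth.libraries):
        rng = np.random.default_rng([seed, 17, lib_idx])
        path = outdir / f"{lib}.fastq"
        with open(path, "w") as out:
            serial = 0

            def emit(seq: str, tag: str, copies: int) -> None:
                nonlocal serial
                for _ in range(copies):
                    serial += 1
                    out.write(
                        f"@{lib}_{serial} {tag}\n{seq}\n+\n{'I' * len(seq)}\n"
                    )

            for ent in bundle.truth.entities:
                mean = ent.mean_counts.get(lib, 0.0)
                n = (
                    int(round(mean))
                    if ent.fixed
                    else _draw_count(rng, mean, params.overdispersion)
                )
                if n > 0:
                    emit(ent.sequence, ent.entity_id, n)
            for _ in range(params.background_reads_per_library):
                for _attempt in range(100):
                    length = int(rng.choice(lengths, p=weights))
                    start = int(rng.integers(0, len(genome) - length))
                    if not is_blocked(start, start + length):
                        break
                emit(genome[start : start + length], "background", 1)
        paths[lib] = path
    return paths


# ---------------------------------------------------------------------------
# serialisation


def _write_fasta(records: Mapping[str, str], path: Path, rna: bool = False) -> None:
    with open(path, "w") as out:
        for rid, seq in records.items():
            out.write(f">{rid}\n{to_rna(seq) if rna else seq}\n")


def write_bundle(
    bundle: SyntheticBundle, outdir: str | Path
) -> dict[str, Path]:
    """Serialise genome, reference sets, transcripts, truth and params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    _write_fasta(bundle.genome, outdir / "genome.fa")
    paths["genome"] = outdir / "genome.fa"
    _write_fasta(bundle.known_mirnas, outdir / "known_mirnas.fa", rna=True)
    paths["known_mirnas"] = outdir / "known_mirnas.fa"
    for cls, refs in bundle.annotation_refs.items():
        p = outdir / f"ref_{cls}.fa"
        _write_fasta(refs, p)
        paths[cls] = p
    _write_fasta(bundle.est_db, outdir / "est.fa")
    paths["est"] = outdir / "est.fa"
    _write_fasta(bundle.gss_db, outdir / "gss.fa")
    paths["gss"] = outdir / "gss.fa"
    _write_fasta(bundle.transcripts, outdir / "transcripts.fa")
    paths["transcripts"] = outdir / "transcripts.fa"
    write_truth_tsv(bundle.truth, outdir / "truth.tsv")
    paths["truth"] = outdir / "truth.tsv"
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": bundle.truth.seed,
                "libraries": list(bundle.truth.libraries),
                "params": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(bundle.truth.params).items()
                    if not isinstance(v, dict)
                },
            },
            fh,
        )
    paths["params"] = outdir / "params.yaml"
    return paths


def write_truth_tsv(truth: TruthSet, path: str | Path) -> None:
    """TruthSet as a sectioned TSV ledger."""
    with open(path, "w") as out:
        out.write("#section=hairpins\n")
        out.write(
            "name\tkind\tfamily\tmature\tstar\tchrom\tmature_start\t"
            "region_start\tregion_end\tprofile\tviolated_rule\texpect_accept\n"
        )
        for h in truth.hairpins:
            out.write(
                f"{h.name}\t{h.kind}\t{h.family or '.'}\t{h.mature}\t"
                f"{h.star or '.'}\t{h.chrom}\t{h.mature_start}\t{h.region_start}\t"
                f"{h.region_end}\t{h.profile_key or '.'}\t"
                f"{h.violated_rule or '.'}\t{h.expect_accept}\n"
            )
        out.write("#section=tas\n")
        t = truth.tas
        out.write(
            "transcript_id\ttrigger_family\tsite5\tsite3\tcleavage_after\t"
            "dominant\tplanted_positions\n"
        )
        out.write(
            f"{t.transcript_id}\t{t.trigger_family}\t{t.site5[0]}-{t.site5[1]}\t"
            f"{t.site3[0]}-{t.site3[1]}\t{t.cleavage_after}\tD{t.dominant_position}\t"
            f"{','.join(map(str, t.planted_positions))}\n"
        )
        out.write("#section=expected_counts\n")
        out.write(
            "entity_id\tcategory\tparent\tfixed\t"
            + "\t".join(f"mean_{lib}" for lib in truth.libraries)
            + "\t"
            + "\t".join(f"sd_{lib}" for lib in truth.libraries)
            + "\n"
        )
        phi = truth.params.overdispersion
        for ent in truth.entities:
            sds = ent.expected_sd(phi)
            out.write(
                f"{ent.entity_id}\t{ent.category}\t{ent.parent or '.'}\t{ent.fixed}\t"
                + "\t".join(
                    f"{ent.mean_counts.get(lib, 0.0):.2f}" for lib in truth.libraries
                )
                + "\t"
                + "\t".join(f"{sds.get(lib, 0.0):.2f}" for lib in truth.libraries)
                + "\n"
            )
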