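"""End-to-end orchestration of the small-RNA analysis stages.

``run_pipeline`` takes a validated :class:`PipelineConfig`, executes the
stages in order (collapse -> map -> classify -> known profiling -> novel
discovery -> phasing -> differential expression) and writes the report
bundle: a class-count table, length distributions, the known-family and
precursor tables, novel calls (GFF3 + rule traces + 5'x-length table),
the phased-locus report, the DE/cluster/type tables and a run manifest
with per-stage checksums.  Everything is deterministic for a fixed config
and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import (
    expression_analyzer,
    genome_mapper,
    hairpin_miner,
    known_profiler,
    phasing_detector,
    read_classifier,
    sequence_io,
)
from ._seq import to_rna
from .read_classifier import UNCLASSIFIED

ANNOTATION_PRECEDENCE = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "protein_coding",
)


@dataclass
class PipelineConfig:
    """All file paths and numeric thresholds of one pipeline run.

    Threshold defaults encode the discovery conventions the pipeline
    implements: length window 18-30 nt, at most 2 substitutions against
    known miRNAs, rule-1 fractions 0.95/0.75 with a reliable count of 5,
    rule-3 limits (<5 mismatches, bulges <=2 nt and <=2 events), 2-nt star
    overhangs, a 21-nt phase period with +-1 nt tolerance, RPTM scaling by
    1e7, a 100-RPTM expression floor and a 0.01 significance level.
    """

    reads: dict[str, str]  # ordered library_id -> FASTA/FASTQ path
    genome: str
    known_mirnas: str
    refsets: dict[str, str] = field(default_factory=dict)  # class -> path
    est: str | None = None
    gss: str | None = None
    transcripts: str | None = None
    outdir: str = "srnapipe_out"
    seed: int = 1

    min_len: int = 18
    max_len: int = 30
    known_max_mismatches: int = 2
    max_gap: int = 200
    rule1_frac_locus: float = 0.95
    rule1_frac_reliable: float = 0.75
    rule1_min_reliable: int = 5
    rule3_max_mismatch: int = 5
    rule3_max_bulge_size: int = 2
    rule3_max_bulge_count: int = 2
    star_overhang: int = 2
    phase_period: int = 21
    phase_tolerance: int = 1
    min_phase_fraction: float = 0.5
    min_phase_positions: int = 4
    trigger_family: str = "mir390"
    de_min_rptm: float = 100.0
    de_alpha: float = 0.01

    def validate(self) -> None:
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid read-length window")
        if len(self.reads) < 2:
            raise ValueError("at least two read libraries required")
        if self.known_max_mismatches < 0:
            raise ValueError("known_max_mismatches must be >= 0")
        for frac in (self.rule1_frac_locus, self.rule1_frac_reliable):
            if not 0 < frac <= 1:
                raise ValueError("rule-1 fractions must lie in (0, 1]")
        if self.rule1_min_reliable < 1:
            raise ValueError("rule1_min_reliable must be >= 1")
        if self.phase_period < 1 or self.phase_tolerance < 0:
            raise ValueError("invalid phasing parameters")
        if not 0 < self.de_alpha < 1:
            raise ValueError("de_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    libraries: list[str]
    collapsed: list[sequence_io.CollapsedRead]
    clean_totals: dict[str, int]
    class_table: read_classifier.ClassTable
    labels: list[read_classifier.ReadLabel]
    length_distributions: dict[str, dict[int, float]]
    family_records: dict[str, known_profiler.MiRNAFamilyRecord]
    novel_calls: list[hairpin_miner.NovelMiRNACall]
    accepted_novel: dict[str, list[hairpin_miner.NovelMiRNACall]]  # mature -> calls
    tas_reports: list[phasing_detector.PhasedLocusReport]
    matrix: expression_analyzer.ExpressionMatrix | None
    de_results: list[expression_analyzer.DEResult]
    cluster: expression_analyzer.ClusterResult | None
    manifest: dict

    def de_types(self) -> dict[str, str]:
        """family id -> assigned temporal type, significant families only."""
        return {
            r.family: r.temporal_type
            for r in self.de_results
            if r.significant and r.temporal_type
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_refset(
    name: str, path: str, max_mismatches: int = 0
) -> read_classifier.ReferenceSet:
    seqs = sequence_io.read_fasta_dict(path)
    return read_classifier.ReferenceSet(
        name=name,
        sequences=sorted(seqs.items()),
        max_mismatches=max_mismatches,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def finish_stage(name: str, t0: float, *paths: Path) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        written.extend(paths)

    # --- stage 1: parse + collapse -----------------------------------------
    t0 = time.time()
    libraries = list(config.reads)
    raw = []
    filter_stats = {}
    for lib, path in config.reads.items():
        stats = sequence_io.FilterStats(lib)
        raw.extend(
            sequence_io.parse_and_filter_reads(
                path, lib, config.min_len, config.max_len, stats=stats
            )
        )
        filter_stats[lib] = stats
    collapsed = sequence_io.collapse_reads(raw, libraries)
    del raw
    clean_totals = {
        lib: sum(r.count_in(lib) for r in collapsed) for lib in libraries
    }
    collapsed_path = outdir / "collapsed.tsv"
    sequence_io.write_collapsed_tsv(collapsed, libraries, collapsed_path)
    manifest["filter_stats"] = {
        lib: vars(stats) for lib, stats in filter_stats.items()
    }
    finish_stage("collapse", t0, collapsed_path)

    # --- stage 2: genome mapping -------------------------------------------
    t0 = time.time()
    genome = sequence_io.read_fasta_dict(config.genome)
    index = genome_mapper.build_index(genome, seed_len=config.min_len)
    hits_by_seq = genome_mapper.map_all(collapsed, index)
    genome_hit_flags = {seq: bool(h) for seq, h in hits_by_seq.items()}
    finish_stage("map", t0)

    # --- stage 3: classification -------------------------------------------
    t0 = time.time()
    known_refset = known_profiler.FamilyReference(
        name="known_miRNA",
        sequences=sorted(sequence_io.read_fasta_dict(config.known_mirnas).items()),
        max_mismatches=config.known_max_mismatches,
    )
    refsets: list[read_classifier.ReferenceSet] = [known_refset]
    for cls in ANNOTATION_PRECEDENCE:
        if cls in config.refsets:
            refsets.append(_load_refset(cls, config.refsets[cls]))
    class_table, labels = read_classifier.classify_collapsed_reads(
        collapsed, refsets, libraries, genome_hits=genome_hit_flags
    )
    class_path = outdir / "class_table.tsv"
    class_table.write_tsv(class_path)
    labels_path = outdir / "read_labels.tsv"
    read_classifier.write_labels_tsv(labels, labels_path)
    length_dists = {
        lib: read_classifier.length_distribution(collapsed, lib) for lib in libraries
    }
    ld_path = outdir / "length_distribution.tsv"
    with open(ld_path, "w") as out:
        out.write("library\tlength\tfraction\n")
        for lib, dist in length_dists.items():
            for length, frac in dist.items():
                out.write(f"{lib}\t{length}\t{frac:.6f}\n")
    finish_stage("classify", t0, class_path, labels_path, ld_path)

    # --- stage 4: known-family profiling -----------------------------------
    t0 = time.time()
    label_by_seq = {lab.sequence: lab for lab in labels}
    known_reads = [
        r for r in collapsed if label_by_seq[r.sequence].class_name == "known_miRNA"
    ]
    family_records = known_profiler.build_family_records(known_reads, known_refset)
    databases: dict[str, genome_mapper.GenomeIndex] = {"genome": index}
    if config.est:
        databases["EST"] = genome_mapper.build_index(
            sequence_io.read_fasta_dict(config.est), seed_len=config.min_len
        )
    if config.gss:
        databases["GSS"] = genome_mapper.build_index(
            sequence_io.read_fasta_dict(config.gss), seed_len=config.min_len
        )
    for rec in family_records.values():
        known_profiler.annotate_tail_variants(rec, known_refset.sequences)
        known_profiler.locate_known_precursors(rec, databases)
    family_path = outdir / "family_table.tsv"
    known_profiler.write_family_table(
        family_records, libraries, clean_totals, family_path
    )
    precursor_path = outdir / "precursor_table.tsv"
    known_profiler.write_precursor_table(family_records, precursor_path)
    finish_stage("known", t0, family_path, precursor_path)

    # --- stage 5: novel discovery ------------------------------------------
    t0 = time.time()
    novel_pool = [
        r
        for r in collapsed
        if label_by_seq[r.sequence].class_name == UNCLASSIFIED
        and genome_hit_flags[r.sequence]
    ]
    counts = {r.sequence: r.total_count for r in novel_pool}
    all_hits = [h for r in novel_pool for h in hits_by_seq[r.sequence]]
    loci = genome_mapper.cluster_loci(all_hits, counts, max_gap=config.max_gap)
    calls = []
    for locus in loci:
        if locus.total_count < config.rule1_min_reliable:
            continue  # cannot satisfy the reliable-read requirement
        calls.append(
            hairpin_miner.call_novel_mirna(
                locus,
                genome,
                frac_locus=config.rule1_frac_locus,
                frac_reliable=config.rule1_frac_reliable,
                min_reliable=config.rule1_min_reliable,
                max_mismatch=config.rule3_max_mismatch,
                max_bulge_size=config.rule3_max_bulge_size,
                max_bulge_count=config.rule3_max_bulge_count,
            )
        )
    accepted: dict[str, list[hairpin_miner.NovelMiRNACall]] = {}
    for call in calls:
        if call.decision:
            accepted.setdefault(call.mature_sequence, []).append(call)
    gff_path = outdir / "novel_calls.gff3"
    hairpin_miner.write_calls_gff3(calls, gff_path)
    trace_path = outdir / "novel_rule_trace.tsv"
    hairpin_miner.write_rule_trace_tsv(calls, trace_path)
    struct_path = outdir / "novel_structures.txt"
    hairpin_miner.write_structures(
        [c[0] for c in accepted.values()], struct_path
    )
    table2 = hairpin_miner.tabulate_5prime_by_length(
        [calls_[0] for calls_ in accepted.values()]
    )
    table2_path = outdir / "novel_5prime_by_length.tsv"
    table2.to_csv(table2_path, sep="\t")
    finish_stage("discover", t0, gff_path, trace_path, struct_path, table2_path)

    # --- stage 6: tasiRNA phasing ------------------------------------------
    t0 = time.time()
    tas_reports: list[phasing_detector.PhasedLocusReport] = []
    phase_paths: list[Path] = []
    if config.transcripts:
        transcripts = sequence_io.read_fasta_dict(config.transcripts)
        trigger = _trigger_sequence(
            config.trigger_family, family_records, known_refset, libraries
        )
        if trigger is not None:
            for tid, tseq in sorted(transcripts.items()):
                report = phasing_detector.call_tas_locus(
                    tseq,
                    trigger,
                    collapsed,
                    transcript_id=tid,
                    period=config.phase_period,
                    tolerance=config.phase_tolerance,
                    min_fraction=config.min_phase_fraction,
                    min_positions=config.min_phase_positions,
                )
                if report is not None:
                    tas_reports.append(report)
                    p = outdir / f"phasing_{tid}.tsv"
                    phasing_detector.write_phase_profile_tsv(report, libraries, p)
                    phase_paths.append(p)
    finish_stage("phase", t0, *phase_paths)

    # --- stage 7: differential expression ----------------------------------
    t0 = time.time()
    expr_counts: dict[str, dict[str, int]] = {}
    for fam, rec in family_records.items():
        expr_counts[fam] = {lib: rec.member_count(lib) for lib in libraries}
    seq_by_collapsed = {r.sequence: r for r in collapsed}
    for mature in accepted:
        rec = seq_by_collapsed.get(mature)
        if rec is None:
            continue
        expr_counts[f"novel|{to_rna(mature)}"] = {
            lib: rec.count_in(lib) for lib in libraries
        }
    matrix = None
    de_results: list[expression_analyzer.DEResult] = []
    cluster = None
    de_paths: list[Path] = []
    if expr_counts:
        matrix = expression_analyzer.build_matrix_and_filter(
            expr_counts, clean_totals, libraries, min_rptm=config.de_min_rptm
        )
        de_results = expression_analyzer.differential_expression(
            matrix, alpha=config.de_alpha
        )
        de_path = outdir / "de_table.tsv"
        expression_analyzer.write_de_table(de_results, matrix, de_path)
        de_paths.append(de_path)
        significant = [r.family for r in de_results if r.significant]
        if len(significant) >= 2:
            cluster = expression_analyzer.cluster_profiles(matrix, significant)
            heat_path = outdir / "heatmap_log2ratio.tsv"
            cluster.values.to_csv(heat_path, sep="\t")
            nwk_path = outdir / "dendrograms.nwk"
            with open(nwk_path, "w") as out:
                out.write(
                    expression_analyzer.linkage_to_newick(
                        cluster.row_linkage, list(cluster.values.index)
                    )
                    + "\n"
                )
                out.write(
                    expression_analyzer.linkage_to_newick(
                        cluster.col_linkage, list(cluster.values.columns)
                    )
                    + "\n"
                )
            de_paths.extend([heat_path, nwk_path])
    finish_stage("express", t0, *de_paths)

    # --- manifest -----------------------------------------------------------
    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(manifest)), fh, sort_keys=True)

    return PipelineResult(
        config=config,
        libraries=libraries,
        collapsed=collapsed,
        clean_totals=clean_totals,
        class_table=class_table,
        labels=labels,
        length_distributions=length_dists,
        family_records=family_records,
        novel_calls=calls,
        accepted_novel=accepted,
        tas_reports=tas_reports,
        matrix=matrix,
        de_results=de_results,
        cluster=cluster,
        manifest=manifest,
    )


def _trigger_sequence(
    family: str,
    records: Mapping[str, known_profiler.MiRNAFamilyRecord],
    refset: known_profiler.FamilyReference,
    libraries: Sequence[str],
) -> str | None:
    """Most abundant member of the trigger family, else its reference."""
    rec = records.get(family)
    if rec is not None and rec.members:
        totals = {seq: sum(c.values()) for seq, c in rec.members.items()}
        return max(sorted(totals), key=lambda s: totals[s])
    for rid, seq in refset.sequences:
        if known_profiler.FamilyReference.family_of(rid) == family:
            return seq
    return None
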