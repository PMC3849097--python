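"""Scoring a pipeline run against a synthetic truth ledger.

Used by the recovery tests: novel-call precision/recall against the
planted matures, decoy rejection with the correct violated-rule label,
TAS detection (dominant D-position and in-phase fraction), temporal-type
accuracy and the column-clustering structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import to_rna
from .pipeline import PipelineResult
from .synthetic_data import DECOY_TRACE_KEY, TruthSet


@dataclass
class DecoyOutcome:
    name: str
    rule: str
    n_calls: int
    rejected: bool  # every overlapping call was rejected
    correct_label: bool  # every overlapping call failed the planted rule


@dataclass
class RecoveryReport:
    accepted_matures: set[str]
    expected_matures: set[str]
    precision: float
    recall: float
    decoys: list[DecoyOutcome] = field(default_factory=list)
    tas_detected: bool = False
    tas_dominant_position: int | None = None
    tas_in_phase_fraction: float | None = None
    tas_length_mode: int | None = None
    type_expected: dict[str, str] = field(default_factory=dict)
    type_assigned: dict[str, str | None] = field(default_factory=dict)
    type_accuracy: float = 0.0
    mid_libraries_join_first: bool | None = None

    @property
    def all_decoys_rejected(self) -> bool:
        return all(d.rejected for d in self.decoys)

    @property
    def all_decoy_labels_correct(self) -> bool:
        return all(d.correct_label and d.n_calls > 0 for d in self.decoys)


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def score_against_truth(result: PipelineResult, truth: TruthSet) -> RecoveryReport:
    expected = truth.expected_accepted_matures()
    accepted = set(result.accepted_novel)
    tp = len(accepted & expected)
    precision = tp / len(accepted) if accepted else 0.0
    recall = tp / len(expected) if expected else 1.0

    decoys = []
    for name, rule in truth.decoy_rules.items():
        planted = truth.hairpin(name)
        overlapping = [
            c
            for c in result.novel_calls
            if c.chrom == planted.chrom
            and _overlaps(
                c.precursor_interval[0],
                c.precursor_interval[1],
                planted.region_start,
                planted.region_end,
            )
        ]
        key = DECOY_TRACE_KEY[rule]
        decoys.append(
            DecoyOutcome(
                name=name,
                rule=rule,
                n_calls=len(overlapping),
                rejected=bool(overlapping)
                and all(not c.decision for c in overlapping),
                correct_label=bool(overlapping)
                and all(c.rule_trace.get(key) is False for c in overlapping),
            )
        )

    tas_detected = False
    tas_dom = None
    tas_frac = None
    tas_mode = None
    for report in result.tas_reports:
        if report.transcript_id == truth.tas.transcript_id:
            tas_detected = True
            tas_dom = report.dominant_position
            tas_frac = report.in_phase_fraction
            break
    if tas_detected:
        # size mode of the planted in-phase reads (from the truth entities)
        lengths: dict[int, int] = {}
        for ent in truth.entities:
            if ent.category == "phased":
                n = sum(ent.mean_counts.values())
                lengths[len(ent.sequence)] = lengths.get(len(ent.sequence), 0) + int(n)
        tas_mode = max(sorted(lengths), key=lambda k: lengths[k]) if lengths else None

    assigned = result.de_types()
    expected_types = truth.planted_type_by_family()
    type_assigned: dict[str, str | None] = {}
    hits = 0
    for name, planted_type in expected_types.items():
        if name in truth.novel_matures:
            fid = f"novel|{to_rna(truth.novel_matures[name])}"
        else:
            fid = name
        got = assigned.get(fid)
        type_assigned[name] = got
        if got == planted_type:
            hits += 1
    type_accuracy = hits / len(expected_types) if expected_types else 1.0

    mid_first = None
    if result.cluster is not None:
        merges = result.cluster.col_merge_order()
        if merges:
            first = merges[0][0] | merges[0][1]
            mid_first = first == {"dpa10", "dpa15"}

    return RecoveryReport(
        accepted_matures=accepted,
        expected_matures=expected,
        precision=precision,
        recall=recall,
        decoys=decoys,
        tas_detected=tas_detected,
        tas_dominant_position=tas_dom,
        tas_in_phase_fraction=tas_frac,
        tas_length_mode=tas_mode,
        type_expected=expected_types,
        type_assigned=type_assigned,
        type_accuracy=type_accuracy,
        mid_libraries_join_first=mid_first,
    )
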