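"""Differential expression of miRNA families across a library time course.

Families are screened on RPTM abundance (max over libraries strictly above
100 by default), tested with Fisher's exact test on the raw counts of the
highest- vs lowest-abundance library against the library clean totals, and
the significant families are clustered (complete linkage, Euclidean
distance on log2 ratios to the row mean) and assigned a temporal type:

    A  rising toward the last time point (argmax in the final library),
    B  peaking at an interior time point,
    C  declining from the first time point (argmax in the first library).

Ties in the argmax break toward the earlier library, so a flat profile is
type C (flagged "flat").  Counts lack replicates, so the exact test on the
two extreme libraries is used rather than a variance-based test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import fisher_exact

from .read_classifier import RPTM_FACTOR

DEFAULT_MIN_RPTM = 100.0
DEFAULT_ALPHA = 0.01
PSEUDO_RPTM = 0.1


@dataclass
class ExpressionMatrix:
    """Family x library RPTM values with the parallel raw-count matrix."""

    rptm: pd.DataFrame  # rows: families, cols: ordered libraries
    counts: pd.DataFrame
    clean_totals: dict[str, int]

    def __post_init__(self) -> None:
        if list(self.rptm.columns) != list(self.counts.columns):
            raise ValueError("rptm and counts must share column order")
        if not self.rptm.index.equals(self.counts.index):
            raise ValueError("rptm and counts must share row index")

    @property
    def libraries(self) -> list[str]:
        return list(self.rptm.columns)


def build_matrix_and_filter(
    counts: Mapping[str, Mapping[str, int]],
    clean_totals: Mapping[str, int],
    libraries: Sequence[str],
    min_rptm: float = DEFAULT_MIN_RPTM,
) -> ExpressionMatrix:
    """Assemble the RPTM matrix and drop low-abundance families.

    A family is retained iff its maximum RPTM over the libraries is
    strictly greater than ``min_rptm``.
    """
    if len(libraries) < 2:
        raise ValueError("at least two libraries required")
    count_df = pd.DataFrame(
        {lib: {fam: counts[fam].get(lib, 0) for fam in counts} for lib in libraries}
    ).fillna(0).astype(int)
    totals = pd.Series({lib: clean_totals[lib] for lib in libraries})
    if (totals <= 0).any():
        raise ValueError("library clean totals must be positive")
    rptm = count_df.div(totals, axis=1) * RPTM_FACTOR
    # strict > with a relative guard so a value that is exactly the
    # threshold up to float rounding is still excluded
    keep = rptm.max(axis=1) > min_rptm * (1 + 1e-9)
    rptm, count_df = rptm.loc[keep].sort_index(), count_df.loc[keep].sort_index()
    return ExpressionMatrix(
        rptm=rptm, counts=count_df, clean_totals=dict(clean_totals)
    )


def fisher_de_test(
    raw_count_max: int,
    total_max: int,
    raw_count_min: int,
    total_min: int,
) -> float:
    """Two-sided Fisher exact p for a count difference between two libraries.

    The 2x2 table is [[count, total-count]] for each library; the two-sided
    p sums hypergeometric probabilities no larger than the observed
    table's.
    """
    if total_max <= 0 or total_min <= 0:
        raise ValueError("library totals must be positive")
    if raw_count_max > total_max or raw_count_min > total_min:
        raise ValueError("counts cannot exceed totals")
    table = [
        [raw_count_max, total_max - raw_count_max],
        [raw_count_min, total_min - raw_count_min],
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])


@dataclass
class DEResult:
    family: str
    p_value: float
    max_library: str
    min_library: str
    log2_ratios: dict[str, float]
    significant: bool
    temporal_type: str | None  # 'A' / 'B' / 'C', significant families only
    flat: bool = False
    cluster_id: int | None = None


def assign_type(profile: Sequence[float], flag_flat: bool = True) -> tuple[str, bool]:
    """Temporal class of a 4-point RPTM profile by peak position.

    Returns (type, flat_flag).  argmax ties break toward the earlier
    library; a constant profile is type C with the flat flag set.
    """
    if len(profile) != 4:
        raise ValueError("expected a profile over 4 ordered libraries")
    arr = np.asarray(profile, dtype=float)
    peak = int(np.argmax(arr))  # first occurrence = earlier library
    flat = bool(np.all(arr == arr[0]))
    if peak == len(arr) - 1:
        return "A", False
    if peak == 0:
        return "C", flat and flag_flat
    return "B", False


def log2_ratio_matrix(rptm: pd.DataFrame, pseudo: float = PSEUDO_RPTM) -> pd.DataFrame:
    """log2(RPTM / row mean) with a pseudo-RPTM floor against zeros."""
    floored = rptm.clip(lower=pseudo)
    return np.log2(floored.div(floored.mean(axis=1), axis=0))


def differential_expression(
    matrix: ExpressionMatrix, alpha: float = DEFAULT_ALPHA
) -> list[DEResult]:
    """Fisher screen of every family between its extreme libraries.

    Max/min libraries are chosen by RPTM with ties broken toward the
    earlier library; significance is plain p < alpha (no multiplicity
    correction is applied on top of the stringent threshold).
    """
    results = []
    ratios = log2_ratio_matrix(matrix.rptm)
    for family in matrix.rptm.index:
        row = matrix.rptm.loc[family]
        libs = matrix.libraries
        max_lib = libs[int(np.argmax(row.to_numpy()))]
        min_lib = libs[int(np.argmin(row.to_numpy()))]
        p = fisher_de_test(
            int(matrix.counts.loc[family, max_lib]),
            matrix.clean_totals[max_lib],
            int(matrix.counts.loc[family, min_lib]),
            matrix.clean_totals[min_lib],
        )
        significant = p < alpha
        ttype, flat = (None, False)
        if significant:
            ttype, flat = assign_type(row.to_numpy())
        results.append(
            DEResult(
                family=str(family),
                p_value=p,
                max_library=max_lib,
                min_library=min_lib,
                log2_ratios=ratios.loc[family].to_dict(),
                significant=significant,
                temporal_type=ttype,
                flat=flat,
            )
        )
    return results


@dataclass
class ClusterResult:
    values: pd.DataFrame  # log2-ratio matrix, rows/cols in dendrogram order
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]

    def col_merge_order(self) -> list[tuple[set[str], set[str]]]:
        """Column-label sets joined at each agglomeration step."""
        cols = list(self.values.columns)
        clusters: dict[int, set[str]] = {i: {c} for i, c in enumerate(cols)}
        merges = []
        nxt = len(cols)
        for a, b, _, _ in self.col_linkage:
            sa, sb = clusters[int(a)], clusters[int(b)]
            merges.append((sa, sb))
            clusters[nxt] = sa | sb
            nxt += 1
        return merges


def cluster_profiles(
    matrix: ExpressionMatrix,
    families: Sequence[str] | None = None,
    metric: str = "euclidean",
) -> ClusterResult:
    """Complete-linkage clustering of log2-ratio profiles, both axes.

    Rows with all-zero RPTM are excluded (their ratio is undefined).
    Deterministic for fixed input; row order of the input does not change
    the tree beyond leaf relabelling.
    """
    rptm = matrix.rptm if families is None else matrix.rptm.loc[list(families)]
    nonzero = rptm.sum(axis=1) > 0
    rptm = rptm.loc[nonzero].sort_index()
    if len(rptm) < 2:
        raise ValueError("need at least two families to cluster")
    values = log2_ratio_matrix(rptm)
    row_link = hierarchy.linkage(values.to_numpy(), method="complete", metric=metric)
    col_link = hierarchy.linkage(values.to_numpy().T, method="complete", metric=metric)
    row_order = [values.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [values.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(
        values=values,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[str(r) for r in row_order],
        col_order=[str(c) for c in col_order],
    )


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        return f"({left}:{node.dist / 2:.4f},{right}:{node.dist / 2:.4f})"

    return walk(tree) + ";"


def write_de_table(
    results: Sequence[DEResult],
    matrix: ExpressionMatrix,
    path: str | Path,
) -> None:
    with open(path, "w") as out:
        libs = matrix.libraries
        header = ["family"] + [f"rptm_{lib}" for lib in libs] + [
            "p_value",
            "max_library",
            "min_library",
            "significant",
            "type",
            "flat",
        ]
        out.write("\t".join(header) + "\n")
        for res in results:
            rptms = [f"{matrix.rptm.loc[res.family, lib]:.1f}" for lib in libs]
            out.write(
                "\t".join(
                    [res.family]
                    + rptms
                    + [
                        f"{res.p_value:.3e}",
                        res.max_library,
                        res.min_library,
                        str(res.significant),
                        res.temporal_type or "",
                        str(res.flat),
                    ]
                )
                + "\n"
            )
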