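"""RPTM filtering, the exact count test, clustering and temporal typing."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from srnapipe.expression_analyzer import (
    assign_type,
    build_matrix_and_filter,
    cluster_profiles,
    differential_expression,
    fisher_de_test,
    linkage_to_newick,
    log2_ratio_matrix,
)

LIBS = ["d05", "d10", "d15", "d20"]


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-integer hypergeometric enumeration of the two-sided p."""
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    weights = [comb(r1, k) * comb(r2, m - k) for k in range(lo, hi + 1)]
    obs = comb(r1, a) * comb(r2, c)
    cut = obs + obs // 10**7  # relative tie guard on exact integers
    return sum(w for w in weights if w <= cut) / comb(r1 + r2, m)


def _matrix(rows: dict[str, tuple], totals: int = 1_000_000):
    counts = {fam: dict(zip(LIBS, vals)) for fam, vals in rows.items()}
    clean = {lib: totals for lib in LIBS}
    return build_matrix_and_filter(counts, clean, LIBS, min_rptm=100.0)


class TestFilter:
    # with clean totals of 1e7, raw counts equal RPTM values exactly

    def test_family_below_threshold_excluded(self):
        assert len(_matrix({"f": (99, 80, 70, 60)}, totals=10_000_000).rptm) == 0

    def test_exactly_100_rptm_excluded_strictly(self):
        assert len(_matrix({"f": (100, 80, 70, 60)}, totals=10_000_000).rptm) == 0

    def test_single_library_above_threshold_retained(self):
        mat = _matrix({"f": (101, 0, 0, 0)}, totals=10_000_000)
        assert list(mat.rptm.index) == ["f"]

    def test_raising_min_rptm_is_monotone(self):
        rng = np.random.default_rng(5)
        counts = {
            f"f{i}": {lib: int(rng.integers(0, 40)) for lib in LIBS}
            for i in range(30)
        }
        clean = {lib: 1_000_000 for lib in LIBS}
        kept_prev = None
        for min_rptm in (50, 100, 150, 200, 300):
            kept = set(
                build_matrix_and_filter(counts, clean, LIBS, min_rptm).rptm.index
            )
            if kept_prev is not None:
                assert kept <= kept_prev
            kept_prev = kept


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_de_test(5, 100, 5, 100) == pytest.approx(1.0)

    def test_five_versus_zero_in_hundreds_not_significant(self):
        p = fisher_de_test(5, 100, 0, 100)
        assert p == pytest.approx(0.0594, abs=5e-4)
        assert p > 0.01

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            fisher_de_test(101, 100, 0, 100)

    def test_zero_total_is_fatal(self):
        with pytest.raises(ValueError):
            fisher_de_test(0, 0, 1, 10)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            t1, t2 = int(rng.integers(1, 31)), int(rng.integers(1, 31))
            a, c = int(rng.integers(0, t1 + 1)), int(rng.integers(0, t2 + 1))
            assert fisher_de_test(a, t1, c, t2) == pytest.approx(
                fisher_oracle(a, t1 - a, c, t2 - c), abs=1e-9
            )


class TestAssignType:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((10, 20, 30, 100), "A"),
            ((10, 100, 80, 20), "B"),
            ((10, 80, 100, 20), "B"),
            ((100, 50, 20, 10), "C"),
        ],
    )
    def test_peak_position_rules(self, profile, expected):
        ttype, flat = assign_type(profile)
        assert ttype == expected and not flat

    def test_tie_breaks_toward_earlier_library(self):
        assert assign_type((50, 100, 100, 50))[0] == "B"
        assert assign_type((100, 50, 50, 100))[0] == "C"

    def test_constant_profile_is_flat_type_c(self):
        ttype, flat = assign_type((5, 5, 5, 5))
        assert ttype == "C" and flat


class TestLog2Transform:
    def test_row_equal_to_mean_transforms_to_zero(self):
        rptm = pd.DataFrame({lib: [50.0] for lib in LIBS}, index=["f"])
        assert (log2_ratio_matrix(rptm).to_numpy() == 0).all()

    def test_pseudo_floor_handles_zeros(self):
        rptm = pd.DataFrame([[0.0, 100.0, 100.0, 100.0]], columns=LIBS, index=["f"])
        vals = log2_ratio_matrix(rptm)
        assert np.isfinite(vals.to_numpy()).all()


class TestCluster:
    def test_identical_rows_merge_first_at_distance_zero(self):
        mat = _matrix(
            {
                "a": (100, 200, 300, 400),
                "b": (100, 200, 300, 400),
                "c": (400, 300, 200, 100),
            }
        )
        result = cluster_profiles(mat)
        first = result.row_linkage[0]
        labels = {result.values.index[int(first[0])], result.values.index[int(first[1])]}
        assert labels == {"a", "b"} and first[2] == 0.0

    def test_archetype_matrix_joins_mid_libraries_first(self):
        rows = {}
        archetypes = {
            "A": (10, 20, 40, 100),
            "B1": (15, 100, 70, 10),
            "B2": (15, 70, 100, 10),
            "C": (100, 50, 20, 10),
        }
        for name, base in archetypes.items():
            for i in range(3):
                rows[f"{name}_{i}"] = tuple(v * (i + 1) for v in base)
        result = cluster_profiles(_matrix(rows))
        first_join = result.col_merge_order()[0]
        assert first_join[0] | first_join[1] == {"d10", "d15"}

    def test_row_permutation_invariance(self):
        rows = {
            "a": (100, 200, 300, 400),
            "b": (90, 210, 310, 390),
            "c": (400, 300, 200, 100),
            "d": (50, 400, 300, 20),
        }
        r1 = cluster_profiles(_matrix(rows))
        reordered = dict(reversed(list(rows.items())))
        r2 = cluster_profiles(_matrix(reordered))
        assert r1.values.equals(r2.values)  # both sorted by family id
        assert np.allclose(r1.row_linkage[:, 2], r2.row_linkage[:, 2])
        assert r1.col_merge_order() == r2.col_merge_order()

    def test_newick_serialisation_contains_all_leaves(self):
        mat = _matrix({"a": (1000, 0, 0, 0), "b": (0, 1000, 0, 0), "c": (0, 0, 1000, 0)})
        res = cluster_profiles(mat)
        nwk = linkage_to_newick(res.row_linkage, list(res.values.index))
        assert nwk.endswith(";")
        for leaf in ("a", "b", "c"):
            assert leaf in nwk


class TestDifferentialExpression:
    def test_extreme_difference_is_significant_and_typed(self):
        mat = _matrix({"up": (100, 300, 900, 4000), "flat": (500, 500, 500, 500)})
        results = {r.family: r for r in differential_expression(mat)}
        assert results["up"].significant and results["up"].temporal_type == "A"
        assert not results["flat"].significant
        assert results["flat"].temporal_type is None

    def test_max_min_libraries_reported(self):
        mat = _matrix({"f": (10_000, 300, 900, 4000)})
        res = differential_expression(mat)[0]
        assert res.max_library == "d05" and res.min_library == "d10"
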