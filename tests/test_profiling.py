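"""Profile building, flagging arithmetic, correlation, OG ranking and
average-linkage clustering vs a brute-force oracle."""
from __future__ import annotations

import io
import math
import random

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from secretome_profiler import (
    AbundanceRecord,
    Location,
    OrthogroupMembership,
    PipelineConfig,
    UsageError,
    build_mag_profile,
    cluster_og_matrix,
    correlate_categories,
    flag_high_counts,
    og_count_matrix,
    rank_ogs,
    summarize_cohort,
)
from secretome_profiler.records import CompartmentAssignment
from conftest import upgma_heights


def _assignment(pid, category, unk_sp=False, mag="m1"):
    return CompartmentAssignment(pid, mag, category, unk_sp, int(unk_sp))


class TestBuildMagProfile:
    def test_counts_and_abundance_label(self):
        assignments = [
            _assignment("a", Location.EXTRACELLULAR),
            _assignment("b", Location.EXTRACELLULAR),
            _assignment("c", Location.UNKNOWN, unk_sp=True),
        ]
        prof = build_mag_profile("m1", assignments, [], {}, AbundanceRecord("m1", 0.25))
        assert prof.counts["EC"] == 2 and prof.counts["UNK_SP"] == 1
        assert prof.counts["EXTRA_CYTOPLASMIC"] == 2
        assert prof.abundant

    def test_abundance_boundary_is_strict(self):
        prof = build_mag_profile("m1", [], [], {}, AbundanceRecord("m1", 0.1))
        assert not prof.abundant

    def test_missing_abundance_is_not_abundant(self):
        prof = build_mag_profile("m1", [], [], {}, None)
        assert not prof.abundant and prof.mean_relative_abundance is None

    def test_counts_match_catalog_recount(self, small_result):
        catalog, profiles = small_result.catalog, small_result.profiles
        for _, row in profiles.iterrows():
            sub = catalog[catalog["mag_id"] == row["mag_id"]]
            assert row["EC"] == (sub["category"] == "EXTRACELLULAR").sum()
            assert row["UNK_SP"] == sub["unk_sp"].sum()
            assert row["nuclease"] == sub["nuclease"].sum()
            assert row["multiheme_unk_sp"] == (sub["is_multiheme"] & sub["unk_sp"]).sum()


class TestFlagging:
    def test_all_equal_counts_flag_nothing(self):
        res = flag_high_counts({f"m{i}": 5 for i in range(6)})
        assert res.flagged == frozenset() and res.sd == 0.0

    def test_single_outlier_flagged(self):
        values = {f"m{i}": 0 for i in range(9)}
        values["m9"] = 10
        res = flag_high_counts(values)
        assert res.mean == 1.0
        assert res.sd == pytest.approx(math.sqrt(10.0), abs=1e-12)
        assert res.threshold == pytest.approx(1 + 2 * math.sqrt(10.0), abs=1e-4)
        assert res.flagged == frozenset({"m9"})

    def test_moderate_outlier_below_threshold(self):
        res = flag_high_counts({"a": 1, "b": 1, "c": 1, "d": 1, "e": 10})
        assert res.threshold == pytest.approx(2.8 + 2 * 4.0249223595, abs=1e-4)
        assert res.flagged == frozenset()

    def test_needs_two_mags(self):
        with pytest.raises(UsageError):
            flag_high_counts({"a": 1})


class TestCorrelation:
    def test_identity_and_anticorrelation(self):
        df = pd.DataFrame({"UNK_SP": [1.0, 2, 3, 4], "EXTRA_CYTOPLASMIC": [1.0, 2, 3, 4]})
        assert correlate_categories(df)[0] == pytest.approx(1.0)
        df["EXTRA_CYTOPLASMIC"] = -df["UNK_SP"] + 10
        assert correlate_categories(df)[0] == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        rng = random.Random(31)
        x = [rng.uniform(0, 50) for _ in range(20)]
        y = [xi * 0.7 + rng.uniform(0, 10) for xi in x]
        df = pd.DataFrame({"UNK_SP": x, "EXTRA_CYTOPLASMIC": y})
        r, p = correlate_categories(df)
        mx, my = sum(x) / len(x), sum(y) / len(y)
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
        assert r == pytest.approx(num / den, abs=1e-12)
        assert 0 <= p <= 1

    def test_zero_variance_is_an_error(self):
        df = pd.DataFrame({"UNK_SP": [2.0, 2, 2], "EXTRA_CYTOPLASMIC": [1.0, 2, 3]})
        with pytest.raises(UsageError, match="zero variance"):
            correlate_categories(df)


class TestSummarize:
    def test_sp_percentage(self, small_result):
        catalog = small_result.catalog
        summary = summarize_cohort(catalog, small_result.profiles)
        ec = catalog[catalog["category"] == "EXTRACELLULAR"]
        assert summary.pct_with_sp["EC"] == pytest.approx(
            100.0 * (ec["sp_support"] >= 1).mean()
        )
        assert summary.totals["EC"] == len(ec)

    def test_totals_conserve_catalog_size(self, small_result):
        summary = summarize_cohort(small_result.catalog, small_result.profiles)
        compartment_total = sum(
            summary.totals[k] for k in ("EC", "OM", "CW", "PP", "CM", "CY", "UNK")
        )
        assert compartment_total == len(small_result.catalog)

    def test_empty_cohort(self):
        summary = summarize_cohort(pd.DataFrame(), pd.DataFrame())
        assert summary.totals["EC"] == 0 and summary.pct_with_sp["EC"] is None
        assert summary.pearson_r is None


class TestRankOgs:
    MATRIX = pd.DataFrame(
        {"m1": [3, 1, 2], "m2": [1, 1, 2]}, index=["og1", "og2", "og0"]
    )

    def test_descending_sums(self):
        # og1 and og0 tie at 4; the tie breaks lexicographically
        assert rank_ogs(self.MATRIX, ["m1", "m2"]) == ["og0", "og1", "og2"]

    def test_ties_break_lexicographically(self):
        matrix = pd.DataFrame({"m1": [2, 2]}, index=["og_b", "og_a"])
        assert rank_ogs(matrix, ["m1"]) == ["og_a", "og_b"]

    def test_truncates_to_top_n(self):
        cfg = PipelineConfig(top_og_n=1)
        assert rank_ogs(self.MATRIX, ["m1"], cfg) == ["og1"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        matrix = pd.DataFrame(
            rng.integers(0, 9, size=(30, 4)),
            index=[f"og{i:02d}" for i in range(30)],
            columns=[f"m{i}" for i in range(4)],
        )
        subset = ["m0", "m2"]
        got = rank_ogs(matrix, subset)
        expected = sorted(matrix.index, key=lambda og: (-matrix.loc[og, subset].sum(), og))
        assert got == expected[: PipelineConfig().top_og_n]

    def test_empty_subset_rejected(self):
        with pytest.raises(UsageError):
            rank_ogs(self.MATRIX, [])


class TestClustering:
    def test_og_count_matrix(self):
        rows = [OrthogroupMembership("og1", "p1"), OrthogroupMembership("og1", "p2"),
                OrthogroupMembership("og2", "p3")]
        mat = og_count_matrix(rows, {"p1": "m1", "p2": "m2", "p3": "m1"})
        assert mat.loc["og1", "m1"] == 1 and mat.loc["og2", "m2"] == 0

    def test_anticorrelated_rows_merge_at_distance_two(self):
        matrix = pd.DataFrame([[1.0, 2], [2.0, 1]], index=["r1", "r2"],
                              columns=["m1", "m2"])
        res = cluster_og_matrix(matrix)
        assert res.row_linkage[0, 2] == pytest.approx(2.0)  # d = 1 - (-1)

    def test_identical_rows_merge_at_distance_zero(self):
        matrix = pd.DataFrame([[1.0, 2, 3], [2.0, 4, 6], [5.0, 1, 2]],
                              index=list("abc"), columns=["m1", "m2", "m3"])
        res = cluster_og_matrix(matrix)
        assert res.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_heights_match_bruteforce_average_linkage(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            matrix = pd.DataFrame(rng.normal(size=(5, 4)),
                                  index=[f"og{i}" for i in range(5)],
                                  columns=[f"m{i}" for i in range(4)])
            res = cluster_og_matrix(matrix)
            x = res.scaled.to_numpy()
            dist = 1 - np.corrcoef(x)
            np.fill_diagonal(dist, 0.0)
            expected = upgma_heights(dist)
            assert np.allclose(sorted(res.row_linkage[:, 2]), sorted(expected), atol=1e-12)

    def test_heights_non_decreasing(self, small_result):
        mat = small_result.og_matrix
        mat = mat[mat.std(axis=1, ddof=1) > 0]
        res = cluster_og_matrix(mat)
        heights = res.row_linkage[:, 2]
        assert all(heights[i] <= heights[i + 1] + 1e-12 for i in range(len(heights) - 1))

    def test_newick_parses_and_preserves_leaves(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"),
                              columns=["m1", "m2", "m3"])
        res = cluster_og_matrix(matrix)
        tree = Phylo.read(io.StringIO(res.row_newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcd")

    def test_constant_row_named_in_error(self):
        matrix = pd.DataFrame([[1.0, 1, 1], [1.0, 2, 3]], index=["flat", "ok"],
                              columns=["m1", "m2", "m3"])
        with pytest.raises(UsageError, match="flat"):
            cluster_og_matrix(matrix)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(UsageError):
            cluster_og_matrix(pd.DataFrame([[1.0, 2]], index=["a"], columns=["m1", "m2"]))
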