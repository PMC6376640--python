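"""Term matrix assembly, level summarisation, sign display, filtering."""

import numpy as np
import pytest

from enrichgrid import (
    EnrichmentResult,
    TermMatrix,
    apply_sign_mode,
    build_term_matrix,
    filter_view,
    summarize_to_level,
    term_sets,
)
from enrichgrid.enrichment import SUMMARY_STATS, EnrichmentRecord
from enrichgrid.errors import DomainError, InputError, UnsupportedModeError

import pandas as pd


def result(cond, **term_ps):
    return EnrichmentResult(
        condition_id=cond,
        records=[
            EnrichmentRecord(term=t, raw_p=p, adj_p=p, overlap=1)
            for t, p in term_ps.items()
        ],
    )


def matrix_from(values: dict[str, dict[str, float]], mode="enrichment_p") -> TermMatrix:
    df = pd.DataFrame(values).T  # rows: conditions
    return TermMatrix(data=df, mode=mode)


class TestBuildTermMatrix:
    def test_disjoint_terms_give_two_defined_two_undefined(self):
        tm = build_term_matrix([result("c1", A=0.01), result("c2", B=0.02)])
        assert tm.data.shape == (2, 2)
        assert int(tm.data.notna().sum().sum()) == 2
        assert tm.data.loc["c1", "A"] == 0.01
        assert np.isnan(tm.data.loc["c1", "B"])

    def test_identical_results_identical_rows(self):
        tm = build_term_matrix([result("c1", A=0.01, B=0.2), result("c2", A=0.01, B=0.2)])
        assert tm.data.loc["c1"].equals(tm.data.loc["c2"])

    def test_empty_results_warn_and_zero_columns(self):
        with pytest.warns(UserWarning, match="no enriched terms"):
            tm = build_term_matrix([result("c1"), result("c2")])
        assert tm.data.shape == (2, 0)

    def test_duplicate_condition_ids_rejected(self):
        with pytest.raises(InputError):
            build_term_matrix([result("c1", A=0.1), result("c1", B=0.2)])


class TestSummarizeToLevel:
    def test_median_of_two_terms_in_category(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.01, "t2": 0.03}})
        lm = summarize_to_level(tm, small_hierarchy, level=2, stat="median")
        assert lm.data.loc["c1", "A1"] == pytest.approx(0.02)

    @pytest.mark.parametrize("stat", ["min", "median", "mean", "max"])
    def test_single_descendant_identity(self, small_hierarchy, stat):
        tm = matrix_from({"c1": {"t4": 0.007}})
        lm = summarize_to_level(tm, small_hierarchy, level=2, stat=stat)
        assert lm.data.loc["c1", "B1"] == 0.007

    def test_multi_membership_term_contributes_to_both_categories(self, small_hierarchy):
        small_hierarchy.memberships["t1"] = {("A", "A1"), ("A", "A2")}
        tm = matrix_from({"c1": {"t1": 0.04}})
        lm = summarize_to_level(tm, small_hierarchy, level=2, stat="median")
        assert lm.data.loc["c1", "A1"] == 0.04
        assert lm.data.loc["c1", "A2"] == 0.04

    def test_undefined_cells_excluded_from_statistic(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.01, "t2": np.nan}, "c2": {"t1": np.nan, "t2": np.nan}})
        lm = summarize_to_level(tm, small_hierarchy, level=2, stat="mean")
        assert lm.data.loc["c1", "A1"] == pytest.approx(0.01)
        assert np.isnan(lm.data.loc["c2", "A1"])

    def test_unmapped_terms_collected_with_warning(self, small_hierarchy):
        tm = matrix_from({"c1": {"mystery": 0.02}})
        with pytest.warns(UserWarning, match="unmapped"):
            lm = summarize_to_level(tm, small_hierarchy, level=1, stat="min")
        assert lm.data.loc["c1", "unmapped"] == 0.02

    def test_invalid_level_raises(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.01}})
        with pytest.raises(DomainError):
            summarize_to_level(tm, small_hierarchy, level=3)

    def test_level2_columns_grouped_under_level1_parent(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.01, "t3": 0.02, "t4": 0.03}})
        lm = summarize_to_level(tm, small_hierarchy, level=2, stat="min")
        assert lm.categories == ["A1", "A2", "B1"]
        assert lm.parents == {"A1": "A", "A2": "A", "B1": "B"}

    @pytest.mark.parametrize("stat", ["min", "median", "mean", "max"])
    @pytest.mark.parametrize("level", [1, 2])
    def test_random_matrices_match_direct_from_terms_oracle(self, small_hierarchy, stat, level):
        rng = np.random.default_rng(hash((stat, level)) % 2**31)
        terms = ["t1", "t2", "t3", "t4"]
        for _ in range(20):
            vals = rng.uniform(0, 1, (3, 4))
            vals[rng.uniform(size=vals.shape) < 0.4] = np.nan
            tm = TermMatrix(
                data=pd.DataFrame(vals, index=["c1", "c2", "c3"], columns=terms),
                mode="enrichment_p",
            )
            lm = summarize_to_level(tm, small_hierarchy, level=level, stat=stat)
            # oracle: group terms by category straight from the memberships
            for cond in tm.conditions:
                for cat in lm.categories:
                    member_vals = [
                        tm.data.loc[cond, t]
                        for t in terms
                        if any((cat in pair) for pair in small_hierarchy.memberships[t])
                        and not np.isnan(tm.data.loc[cond, t])
                    ]
                    got = lm.data.loc[cond, cat]
                    if member_vals:
                        assert got == pytest.approx(SUMMARY_STATS[stat](member_vals))
                    else:
                        assert np.isnan(got)

    @pytest.mark.parametrize("stat", ["min", "max"])
    def test_min_max_associative_over_levels(self, small_hierarchy, stat):
        """For min/max, summarising the level-2 matrix again equals level 1."""
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (3, 4))
        vals[rng.uniform(size=vals.shape) < 0.3] = np.nan
        tm = TermMatrix(
            data=pd.DataFrame(vals, index=["c1", "c2", "c3"],
                              columns=["t1", "t2", "t3", "t4"]),
            mode="enrichment_p",
        )
        lvl1 = summarize_to_level(tm, small_hierarchy, level=1, stat=stat)
        lvl2 = summarize_to_level(tm, small_hierarchy, level=2, stat=stat)
        chained = {}
        for cond in tm.conditions:
            for cat in lvl2.categories:
                parent = lvl2.parents[cat]
                v = lvl2.data.loc[cond, cat]
                if not np.isnan(v):
                    chained.setdefault((cond, parent), []).append(v)
        for (cond, parent), vs in chained.items():
            assert lvl1.data.loc[cond, parent] == pytest.approx(SUMMARY_STATS[stat](vs))

    def test_defined_cells_never_increase(self, small_hierarchy):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 1, (3, 4))
        vals[rng.uniform(size=vals.shape) < 0.5] = np.nan
        tm = TermMatrix(
            data=pd.DataFrame(vals, index=["c1", "c2", "c3"],
                              columns=["t1", "t2", "t3", "t4"]),
            mode="enrichment_p",
        )
        for level in (1, 2):
            lm = summarize_to_level(tm, small_hierarchy, level=level)
            assert int(lm.data.notna().sum().sum()) <= int(tm.data.notna().sum().sum())


class TestSignMode:
    def test_sign_values(self):
        tm = matrix_from({"c1": {"t1": -2.3, "t2": 0.0, "t3": 4.0}}, mode="modification")
        signed = apply_sign_mode(tm)
        assert list(signed.data.loc["c1"]) == [-1.0, 0.0, 1.0]
        assert signed.mode == "sign"

    def test_undefined_row_unchanged(self):
        tm = matrix_from({"c1": {"t1": np.nan, "t2": np.nan}}, mode="modification")
        signed = apply_sign_mode(tm)
        assert signed.data.isna().all().all()

    def test_idempotent(self):
        tm = matrix_from({"c1": {"t1": -7.0, "t2": 3.0}}, mode="modification")
        once = apply_sign_mode(tm)
        twice = apply_sign_mode(once)
        assert once.data.equals(twice.data)

    def test_pvalue_mode_rejected(self):
        tm = matrix_from({"c1": {"t1": 0.01}}, mode="enrichment_p")
        with pytest.raises(UnsupportedModeError):
            apply_sign_mode(tm)


class TestFilterView:
    def test_keep_all_conditions_is_identity(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.1}, "c2": {"t1": 0.2}})
        out = filter_view(tm, small_hierarchy, keep_conditions=["c1", "c2"])
        assert out.data.equals(tm.data)

    def test_keep_level1_category_keeps_its_descendants(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.1, "t3": 0.2, "t4": 0.3}})
        out = filter_view(tm, small_hierarchy, keep_categories={1: {"A"}})
        assert out.terms == ["t1", "t3"]

    def test_empty_keep_set_warns(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.1}})
        with pytest.warns(UserWarning, match="empty"):
            out = filter_view(tm, small_hierarchy, keep_conditions=[])
        assert out.data.shape[0] == 0

    def test_unknown_ids_listed_in_error(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.1}})
        with pytest.raises(InputError, match="cX"):
            filter_view(tm, small_hierarchy, keep_conditions=["cX"])
        with pytest.raises(InputError, match="Zed"):
            filter_view(tm, small_hierarchy, keep_categories={1: {"Zed"}})

    def test_filter_then_summarize_commutes_with_summarize_then_filter(self, small_hierarchy):
        tm = matrix_from({"c1": {"t1": 0.1, "t2": 0.5, "t4": 0.2},
                          "c2": {"t1": 0.3, "t2": 0.7, "t4": 0.9}})
        keep = {1: {"A"}}
        a = summarize_to_level(
            filter_view(tm, small_hierarchy, keep_categories=keep),
            small_hierarchy, level=1, stat="median",
        )
        b = filter_view(
            summarize_to_level(tm, small_hierarchy, level=1, stat="median"),
            small_hierarchy, keep_categories=keep,
        )
        assert a.data.equals(b.data)


def test_term_sets_reads_defined_cells(small_hierarchy):
    tm = matrix_from({"c1": {"t1": 0.1, "t2": np.nan}, "c2": {"t1": np.nan, "t2": 0.2}})
    assert term_sets(tm) == {"c1": {"t1"}, "c2": {"t2"}}
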