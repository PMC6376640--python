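"""Over-representation statistics, correction, and value modes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enrichgrid import (
    Condition,
    GeneAnnotation,
    adjust_pvalues,
    cell_value,
    enrich,
    hypergeometric_pvalue,
    modification_summary,
)
from enrichgrid.enrichment import EnrichmentRecord, read_enrichment_tsv, write_enrichment_tsv
from enrichgrid.errors import DomainError, UnsupportedModeError

from oracles import bh_stepup, hypergeom_tail


class TestHypergeometricPvalue:
    def test_matches_exhaustive_draw_enumeration(self):
        """P(X >= 3) for term of 4 in universe 10, query 5 = 11/42.

        Verified by enumerating all C(10,5) draws and counting those with
        at least 3 term genes.
        """
        universe = list(range(10))
        term = set(range(4))
        hits = sum(
            1 for draw in itertools.combinations(universe, 5) if len(term & set(draw)) >= 3
        )
        expected = hits / math.comb(10, 5)
        assert expected == pytest.approx(11 / 42)
        assert hypergeometric_pvalue(3, 4, 5, 10) == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeometric_pvalue(0, 4, 5, 10) == 1.0

    def test_term_equals_universe_is_one(self):
        assert hypergeometric_pvalue(5, 10, 5, 10) == 1.0

    @pytest.mark.parametrize(
        "overlap,term,query,universe",
        [(-1, 4, 5, 10), (6, 4, 5, 10), (3, 11, 5, 10), (3, 4, 11, 10)],
    )
    def test_bounds_violations_raise(self, overlap, term, query, universe):
        with pytest.raises(DomainError):
            hypergeometric_pvalue(overlap, term, query, universe)

    def test_small_universe_sweep_against_sum_oracle(self):
        for u in range(1, 9):
            for k in range(u + 1):
                for q in range(u + 1):
                    for o in range(min(k, q) + 1):
                        assert hypergeometric_pvalue(o, k, q, u) == pytest.approx(
                            hypergeom_tail(o, k, q, u), abs=1e-12
                        )


class TestAdjustPvalues:
    def test_bonferroni_hand_example(self):
        assert adjust_pvalues([0.01, 0.04], "bonferroni") == pytest.approx([0.02, 0.08])

    def test_bh_hand_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.9], "fdr") == pytest.approx([0.03, 0.03, 0.9])

    def test_single_value_unchanged(self):
        for method in ("bonferroni", "fdr"):
            assert adjust_pvalues([0.5], method) == pytest.approx([0.5])

    def test_empty_list(self):
        assert adjust_pvalues([], "fdr") == []

    def test_out_of_range_raises(self):
        with pytest.raises(DomainError):
            adjust_pvalues([0.0, 0.5], "fdr")
        with pytest.raises(DomainError):
            adjust_pvalues([0.5], "nonsense")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_bh_matches_stepup_oracle_and_bonferroni_dominates_raw(self, raw):
        bh = adjust_pvalues(raw, "fdr")
        assert bh == pytest.approx(bh_stepup(raw), abs=1e-12)
        bonf = adjust_pvalues(raw, "bonferroni")
        assert all(b >= r - 1e-15 for b, r in zip(bonf, raw))

    def test_bh_monotone_on_sorted_input(self):
        rng = np.random.default_rng(0)
        raw = np.sort(rng.uniform(1e-6, 1, 50))
        bh = adjust_pvalues(list(raw), "fdr")
        assert all(a <= b + 1e-15 for a, b in zip(bh, bh[1:]))


class TestEnrich:
    def test_exact_term_match_is_enriched(self, two_term_annotation):
        """A query equal to one of two disjoint terms enriches that term.

        Closed form: overlap 5 of term 5, query 5, universe 10 gives raw
        p = 1/C(10,5) = 1/252; only one term is tested, so it survives any
        correction at alpha 0.05.
        """
        cond = Condition(id="c", group="g", genes=[f"a{i}" for i in range(5)])
        res = enrich(cond, two_term_annotation, alpha=0.05, method="bonferroni")
        assert [r.term for r in res.records] == ["TA"]
        assert res.records[0].raw_p == pytest.approx(1 / 252)
        assert res.records[0].adj_p == pytest.approx(1 / 252)

    def test_alpha_zero_gives_empty_result(self, two_term_annotation):
        cond = Condition(id="c", group="g", genes=["a0", "a1"])
        assert enrich(cond, two_term_annotation, alpha=0.0).records == []

    def test_planted_terms_recovered(self, planted_setup):
        spec, _, ann, cs, truth = planted_setup
        for cond in cs:
            res = enrich(cond, ann, alpha=0.05, method="fdr")
            planted = set(truth["planted_terms"][cond.group])
            assert planted <= res.terms

    def test_permutation_invariant_in_gene_order(self, two_term_annotation):
        genes = ["a0", "a1", "a2", "b0"]
        c1 = Condition(id="c", group="g", genes=genes)
        c2 = Condition(id="c", group="g", genes=list(reversed(genes)))
        r1 = enrich(c1, two_term_annotation, alpha=1.0)
        r2 = enrich(c2, two_term_annotation, alpha=1.0)
        assert [(r.term, r.raw_p, r.adj_p) for r in r1.records] == [
            (r.term, r.raw_p, r.adj_p) for r in r2.records
        ]

    def test_genes_outside_universe_dropped(self, two_term_annotation):
        cond = Condition(id="c", group="g", genes=["a0", "a1", "zz"])
        res = enrich(cond, two_term_annotation, alpha=1.0)
        assert all(r.overlap <= 2 for r in res.records)

    def test_no_overlap_with_universe_warns_and_is_empty(self, two_term_annotation):
        cond = Condition(id="c", group="g", genes=["x", "y"])
        with pytest.warns(UserWarning, match="no genes"):
            res = enrich(cond, two_term_annotation)
        assert res.records == []

    def test_adjusted_never_below_raw_for_bonferroni(self, planted_setup):
        _, _, ann, cs, _ = planted_setup
        res = enrich(cs.conditions[0], ann, alpha=1.0, method="bonferroni")
        assert all(r.adj_p >= r.raw_p for r in res.records)


class TestModificationSummary:
    def test_median_of_two(self):
        cond = Condition(id="c", group="g", genes=["g1", "g2"],
                         modifications={"g1": 2.0, "g2": 4.0})
        assert modification_summary(cond, {"g1", "g2"}, "median") == 3.0

    @pytest.mark.parametrize("stat", ["min", "median", "mean", "max"])
    def test_singleton_term_any_stat(self, stat, mod_condition):
        assert modification_summary(mod_condition, {"g1"}, stat) == -1.0

    def test_max_over_intersection_only(self, mod_condition):
        assert modification_summary(mod_condition, {"g1", "g3"}, "max") == 2.0

    def test_empty_intersection_is_undefined(self, mod_condition):
        assert modification_summary(mod_condition, {"nope"}, "median") is None

    def test_missing_modifications_unsupported(self):
        cond = Condition(id="c", group="g", genes=["g1"])
        with pytest.raises(UnsupportedModeError):
            modification_summary(cond, {"g1"}, "median")


class TestCellValue:
    REC = EnrichmentRecord(term="t", raw_p=0.0005, adj_p=0.001, overlap=3, mv_summary=1.5)

    def test_combined_is_mv_times_neglog10(self):
        assert cell_value(self.REC, "combined") == pytest.approx(4.5)

    def test_enrichment_p_passthrough(self):
        assert cell_value(self.REC, "enrichment_p") == 0.001

    def test_zero_mv_combined_is_zero(self):
        rec = EnrichmentRecord(term="t", raw_p=0.0005, adj_p=0.001, overlap=3, mv_summary=0.0)
        assert cell_value(rec, "combined") == 0.0

    def test_missing_mv_raises_in_mv_modes(self):
        rec = EnrichmentRecord(term="t", raw_p=0.1, adj_p=0.2, overlap=1)
        for mode in ("modification", "combined"):
            with pytest.raises(UnsupportedModeError):
                cell_value(rec, mode)


def test_enrichment_tsv_round_trip(planted_setup, tmp_path):
    _, _, ann, cs, _ = planted_setup
    results = [enrich(c, ann, alpha=0.05) for c in cs]
    p = tmp_path / "enrichment.tsv"
    with open(p, "w") as fh:
        write_enrichment_tsv(results, fh)
    with open(p) as fh:
        back = read_enrichment_tsv(fh)
    orig = {r.condition_id: r.records for r in results if r.records}
    redo = {r.condition_id: r.records for r in back}
    assert set(orig) == set(redo)
    for cond in orig:
        for a, b in zip(orig[cond], redo[cond]):
            assert a.term == b.term and a.overlap == b.overlap
            assert a.raw_p == pytest.approx(b.raw_p, rel=1e-9)
            assert (a.mv_summary is None) == (b.mv_summary is None)
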