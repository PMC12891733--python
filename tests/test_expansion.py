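from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from tcrvax.expansion import (
    ExpansionCall,
    ExpansionConfig,
    antigen_set_distribution,
    by_adjust,
    call_expanded,
    classify_cross_reactive,
    filter_baseline,
    find_public,
    fisher_one_sided,
    odds_ratio,
    shannon_equitability,
    tumor_overlap,
)
from tcrvax.expansion import test_expansion as compute_expansion
from tcrvax.repertoire_io import Clonotype, Condition, Repertoire


def _rep(counts, condition=Condition.G12V, subject="P1", sample="s"):
    cts = {Clonotype("TRBV1", f"CASS{chr(65 + i)}F"): n for i, n in enumerate(counts)}
    return Repertoire(sample, subject, condition, cts)


class TestShannonEquitability:
    def test_uniform_is_exactly_zero(self):
        assert shannon_equitability(_rep([5] * 100)) == 0.0

    def test_hand_computed_value(self):
        # counts {2,1,1}: H = -(1/2 ln 1/2 + 2 * 1/4 ln 1/4) = 1.03972...
        expected = 1 - (0.5 * math.log(2) + 0.5 * math.log(4)) / math.log(3)
        assert shannon_equitability(_rep([2, 1, 1])) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.053605, abs=1e-5)

    def test_near_monoclonal_approaches_one(self):
        value = shannon_equitability(_rep([999_999, 1]))
        assert 0.9999 < value < 1

    def test_single_clonotype_raises(self):
        with pytest.raises(ValueError, match="n=1"):
            shannon_equitability(_rep([10]))

    def test_bounded_on_random_repertoires(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = rng.integers(1, 1000, size=rng.integers(2, 50))
            v = shannon_equitability(_rep(list(counts)))
            assert 0 <= v <= 1


class TestOddsRatio:
    @pytest.mark.parametrize(
        "a,c,expected", [(50, 10, 5.0), (7, 7, 1.0), (12, 0, math.inf)]
    )
    def test_values(self, a, c, expected):
        assert odds_ratio(a, c) == expected

    def test_both_zero_raises(self):
        with pytest.raises(ValueError, match="absent from both"):
            odds_ratio(0, 0)


def _fisher_enumeration(a: int, da: int, c: int, dc: int) -> float:
    """Independent oracle: exact hypergeometric tail via integer binomials."""
    n, big_n, k = da, da + dc, a + c
    denom = math.comb(big_n, k)
    num = sum(
        math.comb(n, x) * math.comb(big_n - n, k - x)
        for x in range(a, min(n, k) + 1)
    )
    return float(Fraction(num, denom))


class TestFisherOneSided:
    def test_no_enrichment_has_large_p(self):
        assert fisher_one_sided(5, 100, 5, 100) >= 0.5

    def test_small_table_matches_enumeration(self):
        # table [[3,7],[0,10]]
        p = fisher_one_sided(3, 10, 0, 10)
        assert p == pytest.approx(_fisher_enumeration(3, 10, 0, 10), abs=1e-14)

    def test_zero_condition_count_gives_p_one(self):
        assert fisher_one_sided(0, 50, 3, 50) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_condition_count(self):
        # at fixed margins, moving reads into the condition never raises p
        for da, dc, k in [(20, 30, 8), (50, 50, 12), (10, 40, 5)]:
            ps = [
                fisher_one_sided(a, da, k - a, dc)
                for a in range(max(0, k - dc), min(da, k) + 1)
            ]
            assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_agrees_with_scipy_fisher_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            da, dc = rng.integers(5, 200, size=2)
            a, c = rng.integers(0, da + 1), rng.integers(0, dc + 1)
            expected = fisher_exact(
                [[a, da - a], [c, dc - c]], alternative="greater"
            ).pvalue
            assert fisher_one_sided(a, da, c, dc) == pytest.approx(expected, rel=1e-9)

    def test_invalid_margins_raise(self):
        with pytest.raises(ValueError, match="invalid 2x2"):
            fisher_one_sided(5, 3, 0, 10)


def _by_stepup_oracle(p):
    """Direct BY step-up formula, independent of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, m * c_m * p[order] / np.arange(1, m + 1))
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj
    return out


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        assert by_adjust([0.02]) == pytest.approx([0.02])

    def test_hand_computed_triple(self):
        # m=3, c(3)=11/6: all three step up to 0.055
        assert by_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.055, 0.055, 0.055])

    def test_all_ones(self):
        assert by_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_direct_stepup_and_dominates_p(self, pvals):
        q = by_adjust(pvals)
        assert q == pytest.approx(_by_stepup_oracle(pvals), abs=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1 + 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-15)


def _tests_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["v_gene", "cdr3_aa", "odds_ratio", "freq_cond", "q_value"],
    )


class TestCallExpanded:
    def test_inclusive_boundaries(self):
        df = _tests_frame([("V", "CASSF", 5.0, 0.001, 0.01)])
        assert call_expanded(df)["expanded"].item() is True

    def test_below_or_threshold(self):
        df = _tests_frame([("V", "CASSF", 4.9, 0.01, 0.001)])
        assert not call_expanded(df)["expanded"].item()

    def test_frequency_cutoff_optional(self):
        df = _tests_frame([("V", "CASSF", 6.0, 0.0001, 0.01)])
        assert not call_expanded(df)["expanded"].item()
        relaxed = ExpansionConfig(apply_freq_cutoff=False)
        assert call_expanded(df, relaxed)["expanded"].item() is True

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(2)
        df = _tests_frame(
            [
                ("V", f"C{i}F", rng.uniform(0, 20), rng.uniform(0, 0.01), rng.uniform(0, 1))
                for i in range(200)
            ]
        )
        strict = call_expanded(df, ExpansionConfig())["expanded"]
        loose = call_expanded(
            df, ExpansionConfig(or_min=2.0, freq_min=0.0005, q_max=0.2)
        )["expanded"]
        assert (strict <= loose).all()


class TestEndToEndStatistics:
    def test_test_expansion_consistency(self):
        cond = _rep([50, 30, 20], condition=Condition.G12V)
        ref = _rep([10, 30, 60], condition=Condition.VEHICLE_ONLY)
        table = compute_expansion(cond, ref)
        assert len(table) == 3
        row = table.set_index("cdr3_aa").loc["CASSAF"]
        assert row["odds_ratio"] == 5.0
        assert row["freq_cond"] == 0.5
        assert row["p_value"] == pytest.approx(
            fisher_one_sided(50, 100, 10, 100), abs=1e-15
        )
        assert (table["q_value"] >= table["p_value"] - 1e-15).all()

    def test_subject_mismatch_raises(self):
        cond = _rep([5, 5], subject="P1")
        ref = _rep([5, 5], subject="P2", condition=Condition.VEHICLE_ONLY)
        with pytest.raises(ValueError, match="subject mismatch"):
            compute_expansion(cond, ref)


def _call(subject, v, cdr3, antigens):
    return ExpansionCall(Clonotype(v, cdr3), subject, frozenset(antigens))


class TestBaselineFilter:
    def test_present_at_baseline_excluded(self):
        calls = [_call("P1", "TRBV1", "CASSAF", {"G12V"})]
        baseline = _rep([2], condition=Condition.BASELINE)  # contains CASSAF
        flagged, n = filter_baseline(calls, baseline)
        assert n == 1 and flagged[0].filtered_by_baseline

    def test_absent_retained_and_empty_baseline(self):
        calls = [_call("P1", "TRBV9", "CAWXF".replace("X", "S"), {"G12V"})]
        baseline = _rep([2, 3], condition=Condition.BASELINE)
        flagged, n = filter_baseline(calls, baseline)
        assert n == 0 and not flagged[0].filtered_by_baseline

    def test_subject_mismatch(self):
        calls = [_call("P2", "TRBV1", "CASSAF", {"G12V"})]
        baseline = _rep([2], condition=Condition.BASELINE, subject="P1")
        with pytest.raises(ValueError, match="does not"):
            filter_baseline(calls, baseline)


class TestCrossReactiveAndPublic:
    def test_multi_antigen_is_cross_reactive(self):
        ct = Clonotype("TRBV1", "CASSAF")
        calls = classify_cross_reactive(
            [("P1", ct, Condition.G12V), ("P1", ct, Condition.G12A)]
        )
        assert calls[0].cross_reactive and calls[0].antigens == {"G12V", "G12A"}

    def test_single_antigen_is_not(self):
        calls = classify_cross_reactive([("P1", Clonotype("TRBV1", "CASSAF"), "G12D")])
        assert not calls[0].cross_reactive

    def test_three_antigen_set_and_distribution(self):
        ct = Clonotype("TRBV1", "CASSAF")
        calls = classify_cross_reactive(
            [("P1", ct, a) for a in ("G12V", "G12A", "G12C")]
        )
        assert calls[0].antigens == {"G12V", "G12A", "G12C"}
        dist = antigen_set_distribution(calls)
        assert dist[("G12A", "G12C", "G12V")] == 1

    def test_public_clonotype_shared_antigen(self):
        # the near-identical public pair: same allele-level V and CDR3
        ct = Clonotype("TCRBV28.01.01", "CASRLGNTGELFF")
        pubs = find_public(
            [_call("P1", *ct, {"G13D"}), _call("P2", *ct, {"G13D"})]
        )
        assert len(pubs) == 1
        assert pubs[0].subjects == ("P1", "P2")
        assert pubs[0].shared_antigens == {"G13D"}

    def test_single_subject_clone_not_public(self):
        calls = [
            _call("P1", "TRBV1", "CASSAF", {"G12V"}),
            _call("P2", "TRBV1", "CASTAF", {"G12V"}),
        ]
        assert find_public(calls) == []

    def test_same_cdr3_different_v_not_public(self):
        calls = [
            _call("P1", "TCRBV28.01.01", "CASRLGNTGELFF", {"G13D"}),
            _call("P2", "TCRBV27.01.01", "CASRLGNTGELFF", {"G13D"}),
        ]
        assert find_public(calls) == []

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            find_public([_call("P1", "TRBV1", "CASSAF", {"G12V"})])


class TestTumorOverlap:
    def _tumor(self, counts):
        return _rep(counts, condition=Condition.TUMOR_TISSUE)

    def test_fraction(self):
        specific = {Clonotype("TRBV1", f"CASS{chr(65 + i)}F") for i in range(10)}
        tumor = self._tumor([5, 5])  # contains CASSAF, CASSBF
        ov = tumor_overlap(specific, tumor)
        assert (ov.count, ov.fraction) == (2, 0.2)

    def test_disjoint(self):
        specific = {Clonotype("TRBV9", "CAWSF")}
        ov = tumor_overlap(specific, self._tumor([5, 5]))
        assert (ov.count, ov.fraction) == (0, 0.0)

    def test_empty_specific_set_raises(self):
        with pytest.raises(ValueError, match="empty specific set"):
            tumor_overlap(set(), self._tumor([5, 5]))

    def test_requires_tumor_condition(self):
        with pytest.raises(ValueError, match="tumor_tissue"):
            tumor_overlap({Clonotype("TRBV1", "CASSAF")}, _rep([5, 5]))
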