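"""Cohort meta-analysis: correlation records, concordance, Venn patterns,
axis counts, modality quadrants, and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from emtmet.meta import (
    CorrelationRecord,
    axis_count_fractions,
    classify,
    compare_groups,
    concordance,
    correlate,
    modality_quadrants,
    venn_consistency,
)
from emtmet.tables import ScoreTable

from oracles import pearson_oracle, ttest_oracle


def _table(data: dict, dataset_id="d1", groups=None):
    frame = pd.DataFrame(data)
    frame.index = [f"s{i}" for i in range(len(frame))]
    return ScoreTable(dataset_id, frame, sample_groups=groups)


def _record(dataset_id, r, p, pair=("a", "b")):
    return classify(CorrelationRecord(dataset_id, pair[0], pair[1], r, p, 30))


class TestCorrelate:
    def test_self_correlation(self):
        table = _table({"a": [1.0, 2.0, 3.0, 5.0], "b": [1.0, 2.0, 3.0, 5.0]})
        record = correlate(table, "a", "b")
        assert record.r == pytest.approx(1.0)
        assert record.p < 1e-3
        assert record.klass == "POS"

    def test_anticorrelation(self):
        table = _table({"a": [1.0, 2.0, 3.0, 5.0], "b": [-1.0, -2.0, -3.0, -5.0]})
        record = correlate(table, "a", "b")
        assert record.r == pytest.approx(-1.0)
        assert record.klass == "NEG"

    def test_matches_textbook_formula_oracle(self):
        a = [1.2, 3.4, 2.2, 5.1, 4.0]
        b = [0.7, 2.9, 1.1, 4.2, 4.4]
        table = _table({"a": a, "b": b})
        record = correlate(table, "a", "b")
        r_exp, p_exp = pearson_oracle(a, b)
        assert record.r == pytest.approx(r_exp, abs=1e-9)
        assert record.p == pytest.approx(p_exp, abs=1e-9)

    def test_too_few_pairs_gives_none_with_warning(self):
        table = _table({"a": [1.0, 2.0, np.nan, np.nan], "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="complete"):
            assert correlate(table, "a", "b") is None

    def test_zero_variance_gives_none(self):
        table = _table({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            assert correlate(table, "a", "b") is None

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=20)
        b = 0.6 * a + rng.normal(scale=0.5, size=20)
        t1 = _table({"a": a, "b": b})
        t2 = _table({"a": 3.0 * a + 7.0, "b": 0.1 * b - 2.0})
        r1 = correlate(t1, "a", "b")
        r2 = correlate(t2, "a", "b")
        assert r1.r == pytest.approx(r2.r, abs=1e-12)
        assert r1.klass == r2.klass


class TestClassify:
    @pytest.mark.parametrize(
        "r, p, expected",
        [
            (0.5, 0.01, "POS"),
            (0.5, 0.2, "NS"),
            (0.2, 0.01, "NS"),
            (-0.5, 0.01, "NEG"),
            (-0.2, 0.01, "NS"),
            (0.3, 0.01, "NS"),   # boundary is strict
        ],
    )
    def test_volcano_rule(self, r, p, expected):
        record = CorrelationRecord("d", "a", "b", r, p, 30)
        assert classify(record).klass == expected


class TestConcordance:
    def test_cohort_arithmetic(self):
        """114 positive, 8 negative of 182 -> probability 114/122, weighted 114/182."""
        records = (
            [_record(f"d{i}", 0.6, 0.001) for i in range(114)]
            + [_record(f"e{i}", -0.6, 0.001) for i in range(8)]
            + [_record(f"n{i}", 0.1, 0.5) for i in range(60)]
        )
        summary = concordance(records)
        assert summary.n_total == 182
        assert summary.probability == pytest.approx(114 / 122)
        assert summary.weighted_probability == pytest.approx(114 / 182)
        assert summary.direction == "positive"

    def test_tie_breaks_positive_with_flag(self):
        records = [_record("d1", 0.6, 0.001), _record("d2", -0.6, 0.001)]
        summary = concordance(records)
        assert summary.probability == 0.5
        assert summary.direction == "positive"
        assert summary.tie

    def test_no_significant_datasets_undefined(self):
        records = [_record("d1", 0.1, 0.9), _record("d2", 0.0, 0.8)]
        summary = concordance(records)
        assert summary.probability is None
        assert summary.weighted_probability is None

    def test_probability_at_least_half(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_pos, n_neg = rng.integers(0, 10, 2)
            records = [
                _record(f"p{i}", 0.7, 0.001) for i in range(n_pos)
            ] + [_record(f"n{i}", -0.7, 0.001) for i in range(n_neg)]
            if not records:
                continue
            summary = concordance(records)
            if summary.probability is not None:
                assert 0.5 <= summary.probability <= 1.0

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            concordance([])


class TestCorrelateCohortFdr:
    def test_bh_adjustment_weakens_borderline_significance(self):
        rng = np.random.default_rng(15)
        tables = []
        for i in range(20):
            a = rng.normal(size=10)
            b = 0.62 * a + rng.normal(scale=0.78, size=10)  # borderline p values
            tables.append(_table({"a": a, "b": b}, dataset_id=f"d{i}"))
        from emtmet.meta import correlate_cohort

        with np.errstate(all="ignore"):
            raw = correlate_cohort(tables, [("a", "b")])
            adj = correlate_cohort(tables, [("a", "b")], fdr=True)
        raw_p = {r.dataset_id: r.p for r in raw}
        adj_p = {r.dataset_id: r.p for r in adj}
        assert all(adj_p[d] >= raw_p[d] for d in raw_p)
        n_sig_raw = sum(r.klass != "NS" for r in raw)
        n_sig_adj = sum(r.klass != "NS" for r in adj)
        assert n_sig_adj <= n_sig_raw


class TestVennConsistency:
    PAIRS = {("ks", "hemt"): "+", ("gs76", "ks"): "-"}

    def _cohort(self, n_match, n_flip):
        records = []
        for i in range(n_match + n_flip):
            d = f"d{i}"
            records.append(_record(d, 0.8, 1e-4, ("ks", "hemt")))
            sign = -0.8 if i < n_match else 0.8
            records.append(_record(d, sign, 1e-4, ("gs76", "ks")))
        return records

    def test_full_agreement_all_mass_on_ones(self):
        result = venn_consistency(self._cohort(6, 0), self.PAIRS)
        assert result["patterns"][(1, 1)] == 6
        assert result["n_included"] == 6

    def test_partition_property(self):
        result = venn_consistency(self._cohort(4, 3), self.PAIRS)
        assert sum(result["patterns"].values()) == result["n_included"] == 7
        assert result["patterns"][(1, 1)] == 4
        assert result["patterns"][(1, 0)] == 3

    def test_single_pair_reduces_to_match_mismatch(self):
        records = [_record("d1", 0.8, 1e-4), _record("d2", -0.8, 1e-4)]
        result = venn_consistency(records, {("a", "b"): "+"})
        assert result["patterns"][(1,)] == 1
        assert result["patterns"][(0,)] == 1

    def test_missing_pair_excluded_and_counted(self):
        records = self._cohort(2, 0)
        records.append(_record("lonely", 0.8, 1e-4, ("ks", "hemt")))
        result = venn_consistency(records, self.PAIRS)
        assert result["n_included"] == 2
        assert result["n_excluded"] == 1

    def test_unknown_pair_errors(self):
        with pytest.raises(ValueError, match="expected pair"):
            venn_consistency(self._cohort(2, 0), {("nope", "nada"): "+"})


class TestAxisCountFractions:
    AXES = ["gly", "ox", "fao"]

    def _records(self, dataset_id, significant):
        out = []
        for axis in self.AXES:
            sig = axis in significant
            out.append(_record(dataset_id, 0.8 if sig else 0.05,
                               1e-4 if sig else 0.9, (axis, "hemt")))
        return out

    def test_all_significant(self):
        records = sum((self._records(f"d{i}", self.AXES) for i in range(5)), [])
        result = axis_count_fractions(records, self.AXES, "hemt")
        assert result["fractions"] == [0.0, 0.0, 0.0, 1.0]

    def test_none_significant(self):
        records = sum((self._records(f"d{i}", []) for i in range(5)), [])
        result = axis_count_fractions(records, self.AXES, "hemt")
        assert result["fractions"] == [1.0, 0.0, 0.0, 0.0]

    def test_independent_axes_match_binomial_pmf(self):
        """Per-axis significance probability 0.5 over 1000 datasets."""
        rng = np.random.default_rng(42)
        records = []
        for i in range(1000):
            chosen = [a for a in self.AXES if rng.random() < 0.5]
            records.extend(self._records(f"d{i}", chosen))
        result = axis_count_fractions(records, self.AXES, "hemt")
        for k in range(4):
            expected = binom.pmf(k, 3, 0.5)
            se = np.sqrt(expected * (1 - expected) / 1000)
            assert abs(result["fractions"][k] - expected) <= 3 * se

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(40):
            chosen = [a for a in self.AXES if rng.random() < 0.3]
            records.extend(self._records(f"d{i}", chosen))
        result = axis_count_fractions(records, self.AXES, "hemt")
        assert sum(result["fractions"]) == pytest.approx(1.0)


class TestModalityQuadrants:
    def test_quadrant_assignment(self):
        ra = [_record("d1", 0.8, 1e-4, ("gly", "hemt"))]
        rb = [_record("d1", -0.8, 1e-4, ("ox", "hemt"))]
        result = modality_quadrants(ra, rb, "gly", "ox")
        assert result["assignments"][0].quadrant == "a_pos_b_neg"
        assert result["percentages"]["a_pos_b_neg"] == 100.0

    def test_ns_unassigned(self):
        ra = [_record("d1", 0.8, 1e-4, ("gly", "hemt"))]
        rb = [_record("d1", 0.1, 0.9, ("ox", "hemt"))]
        result = modality_quadrants(ra, rb, "gly", "ox")
        assert result["n_assigned"] == 0
        assert result["n_total"] == 1

    def test_assigned_plus_unassigned_is_total(self):
        rng = np.random.default_rng(7)
        ra, rb = [], []
        for i in range(30):
            d = f"d{i}"
            ra.append(_record(d, rng.uniform(-1, 1), rng.uniform(0, 0.2), ("gly", "hemt")))
            rb.append(_record(d, rng.uniform(-1, 1), rng.uniform(0, 0.2), ("ox", "hemt")))
        result = modality_quadrants(ra, rb, "gly", "ox")
        assert result["n_assigned"] + sum(
            1 for d in range(30)
            if ra[d].klass == "NS" or rb[d].klass == "NS"
        ) == result["n_total"]


class TestCompareGroups:
    def test_identical_groups_no_difference(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        table = _table({"m": values}, groups=groups)
        result = compare_groups(table, "m", "a", "b")
        assert result.difference == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)

    def test_matches_textbook_t_oracle(self):
        a = [2.1, 3.5, 2.9]
        b = [4.0, 5.2, 4.4]
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        table = _table({"m": a + b}, groups=groups)
        result = compare_groups(table, "m", "a", "b")
        t_exp, p_exp = ttest_oracle(a, b)
        assert result.t == pytest.approx(t_exp, abs=1e-9)
        assert result.p == pytest.approx(p_exp, abs=1e-9)

    def test_small_group_errors(self):
        groups = {"s0": "a", "s1": "b", "s2": "b"}
        table = _table({"m": [1.0, 2.0, 3.0]}, groups=groups)
        with pytest.raises(ValueError, match="group 'a'"):
            compare_groups(table, "m", "a", "b")

    def test_welch_flag_changes_unequal_variance_result(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, 10).tolist()
        b = rng.normal(0.5, 3.0, 4).tolist()
        groups = {f"s{i}": ("a" if i < 10 else "b") for i in range(14)}
        table = _table({"m": a + b}, groups=groups)
        student = compare_groups(table, "m", "a", "b")
        welch = compare_groups(table, "m", "a", "b", welch=True)
        assert student.p != pytest.approx(welch.p)
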