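"""Accuracy statistics: proportions, concordance, comparisons, ROC/AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from septcall.calling import CallResult
from septcall.diagnostics import (
    ConcordanceTable,
    auc_ci,
    build_pairs,
    compare_proportions,
    concordance,
    pdr,
    pool_counts,
    proportion_from_counts,
    roc_censored,
    sens_spec,
    welch_t,
)
from oracles import auc_pairwise, fisher_exact_enumeration


def call(positive, valid=True, sample_id="x", mean_cp=40.0):
    return CallResult(
        sample_id=sample_id,
        valid=valid,
        n_detected=3 if positive else 0,
        mean_cp_censored=mean_cp,
        positive=None if not valid else positive,
    )


def calls(n_pos, n_total):
    return [call(i < n_pos, sample_id=f"s{i}") for i in range(n_total)]


class TestProportions:
    def test_pdr_rounds_like_reports(self):
        assert pdr(calls(4, 13)).percent == 30.8

    def test_zero_rate_interval_starts_at_zero(self):
        p = pdr(calls(0, 6))
        assert p.percent == 0.0 and p.ci_low == 0.0

    def test_full_rate_interval_ends_at_one(self):
        p = pdr(calls(10, 10))
        assert p.percent == 100.0 and p.ci_high == 1.0

    def test_invalid_calls_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            pdr([call(True), call(None, valid=False)])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pdr([])

    def test_wilson_interval_contains_point_estimate(self):
        for num, den in [(0, 10), (1, 10), (5, 10), (10, 10), (77, 90), (8, 81)]:
            p = proportion_from_counts(num, den)
            assert p.ci_low <= p.rate <= p.ci_high
            assert 0.0 <= p.ci_low and p.ci_high <= 1.0

    @pytest.mark.parametrize(
        "stage_counts,expected_pct,expected_frac",
        [
            # plasma CRC by stage under 1/3
            ([(14, 18), (23, 27), (24, 26), (8, 10), (8, 9)], 85.6, (77, 90)),
            # stool CRC by stage under the final rule
            ([(13, 15), (17, 18), (18, 23), (7, 9), (5, 7)], 83.3, (60, 72)),
            ([(3, 4)], 75.0, (3, 4)),  # identity pooling
        ],
    )
    def test_pool_counts(self, stage_counts, expected_pct, expected_frac):
        pooled = pool_counts(stage_counts)
        assert (pooled.numerator, pooled.denominator) == expected_frac
        assert pooled.percent == expected_pct

    def test_pool_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            pool_counts([(5, 4)])
        with pytest.raises(ValueError):
            pool_counts([])


class TestSensSpec:
    @pytest.mark.parametrize(
        "controls,expected_spec",
        [((8, 81), 90.1), ((6, 76), 92.1), ((0, 20), 100.0)],
    )
    def test_specificity_is_complement_of_control_pdr(self, controls, expected_spec):
        n_pos, n = controls
        _, spec = sens_spec(calls(5, 10), calls(n_pos, n))
        assert spec.percent == expected_spec

    def test_specificity_identity_exact(self):
        control_calls = calls(8, 81)
        _, spec = sens_spec(calls(5, 10), control_calls)
        p = pdr(control_calls)
        assert spec.rate == 1 - p.rate
        assert spec.ci_low == 1 - p.ci_high and spec.ci_high == 1 - p.ci_low


class TestConcordance:
    def test_published_paired_categories(self):
        table = ConcordanceTable(39, 7, 6, 8)
        assert table.total == 60
        assert round(100 * table.concordance_rate, 1) == 78.3

    def test_crc_subset_categories(self):
        table = ConcordanceTable(39, 6, 6, 1)
        assert round(100 * table.concordance_rate, 1) == 76.9
        assert table.pdr_test1.percent == 86.5
        assert table.pdr_test2.percent == 86.5

    def test_symmetry(self):
        table = ConcordanceTable(39, 7, 6, 8)
        assert table.swapped().concordance_rate == table.concordance_rate

    def test_concordance_from_paired_calls(self):
        pairs = [(call(True), call(True))] * 3 + [(call(False), call(False))] * 2
        table = concordance(pairs)
        assert table.concordance_rate == 1.0

    def test_build_pairs_excludes_unpaired_and_invalid(self, caplog):
        subject_of = {"p1": "u1", "p2": "u2", "p3": "u3", "s1": "u1", "s2": "u2"}
        plasma = [call(True, sample_id="p1"), call(True, sample_id="p2"),
                  call(True, sample_id="p3")]
        stool = [call(True, sample_id="s1"), call(None, valid=False, sample_id="s2")]
        with caplog.at_level("WARNING"):
            pairs = build_pairs(plasma, stool, subject_of)
        assert len(pairs) == 1
        assert "u3" in caplog.text and "u2" in caplog.text


class TestCompareProportions:
    def test_identical_proportions_give_p_one(self):
        assert compare_proportions((5, 10), (5, 10)) == pytest.approx(1.0)

    @pytest.mark.parametrize("a,b", [((8, 10), (2, 10)), ((0, 5), (5, 5)), ((3, 9), (7, 12))])
    def test_fisher_matches_enumeration_oracle(self, a, b):
        expected = fisher_exact_enumeration(a[0], a[1] - a[0], b[0], b[1] - b[0])
        assert compare_proportions(a, b) == pytest.approx(expected, rel=1e-7)

    def test_chi_square_available(self):
        p = compare_proportions((40, 100), (60, 100), method="chi_square")
        assert 0.0 < p < 0.05


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([38.0, 39.0, 40.0], [38.0, 39.0, 40.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_shift(self):
        # groups (1,2,3) and (11,12,13): s1=s2=1, n=3 each, so
        # t = -10 / sqrt(2/3) and Welch-Satterthwaite df = 4 exactly
        res = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.statistic == pytest.approx(-10.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.df == pytest.approx(4.0, rel=1e-12)
        from scipy import stats
        assert res.pvalue == pytest.approx(2 * stats.t.sf(abs(res.statistic), 4), rel=1e-9)

    def test_large_separation_is_overwhelming(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(38.0, 1.0, 50)
        g2 = rng.normal(49.0, 1.0, 50)
        assert welch_t(g1, g2).pvalue < 1e-4

    def test_constant_equal_groups_p_one_convention(self):
        res = welch_t([50.0, 50.0, 50.0], [50.0, 50.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_censored([35.0] * 5, [50.0] * 5)
        assert roc.auc == 1.0
        assert roc.auc_ci_high == 1.0  # truncation at 1

    def test_all_tied_scores_give_half_with_wide_interval(self):
        with pytest.warns(UserWarning, match="tie"):
            roc = roc_censored([50.0] * 4, [50.0] * 6)
        assert roc.auc == 0.5
        assert (roc.auc_ci_low, roc.auc_ci_high) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            assert auc_ci(roc) == (0.0, 1.0)

    def test_toy_case_matches_pairwise_oracle_and_hand_delong(self):
        cases, controls = [36.0, 38.0, 50.0], [44.0, 50.0, 50.0]
        roc = roc_censored(cases, controls)
        assert roc.auc == pytest.approx(auc_pairwise(cases, controls))
        assert roc.auc == pytest.approx(7.0 / 9.0)
        # hand-evaluated DeLong components: V10 = (1, 1, 1/3), V01 = (2/3, 5/6, 5/6)
        # var(V10)=4/27, var(V01)=1/108 -> Var(AUC) = 4/81 + 1/324 = 17/324
        assert roc.auc_se == pytest.approx(math.sqrt(17.0 / 324.0), rel=1e-12)
        low, high = auc_ci(roc, level=0.95)
        z = 1.959963984540054
        assert low == pytest.approx(7.0 / 9.0 - z * roc.auc_se, rel=1e-9)
        assert high == pytest.approx(min(1.0, 7.0 / 9.0 + z * roc.auc_se), rel=1e-9)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(11)
        roc = roc_censored(rng.uniform(30, 50, 40), rng.uniform(35, 50, 30))
        sens = np.array(roc.sensitivities)
        spec = np.array(roc.specificities)
        assert (np.diff(sens) >= 0).all()
        assert (np.diff(spec) <= 0).all()

    score_vec = st.lists(
        st.sampled_from([35.0, 38.0, 40.0, 44.0, 45.5, 50.0]), min_size=1, max_size=8
    )

    @pytest.mark.filterwarnings("ignore:all scores identical")
    @given(cases=score_vec, controls=score_vec)
    def test_auc_equals_pairwise_oracle(self, cases, controls):
        roc = roc_censored(cases, controls)
        assert roc.auc == pytest.approx(auc_pairwise(cases, controls), abs=1e-12)

    @pytest.mark.filterwarnings("ignore:all scores identical")
    @given(cases=score_vec, controls=score_vec)
    def test_auc_antisymmetry(self, cases, controls):
        assert roc_censored(cases, controls).auc == pytest.approx(
            1.0 - roc_censored(controls, cases).auc, abs=1e-12
        )

    def test_coverage_of_delong_interval_under_null(self):
        """Interval from same-distribution samples covers 0.5 most of the time."""
        rng = np.random.default_rng(29)
        covered = 0
        reps = 200
        for _ in range(reps):
            roc = roc_censored(rng.normal(40, 2, 40), rng.normal(40, 2, 40))
            low, high = auc_ci(roc)
            covered += low <= 0.5 <= high
        assert covered / reps >= 0.90

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_censored([], [50.0])
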