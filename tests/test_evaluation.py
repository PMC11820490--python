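"""Agreement statistics: matching, summaries, AP, Bland–Altman, RMSE."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codseg import (
    CODEvent,
    DetectionParams,
    EventPair,
    EventStatus,
    LabelEvent,
    ManualLabels,
    SegmentationResult,
    Side,
    average_precision,
    bland_altman,
    build_report,
    cutting_time_correlation,
    difference_summaries,
    error_stats,
    match_events,
    rmse,
)


def auto_event(k, minimum, if_frame=None, ff_frame=None):
    status = (
        EventStatus.COMPLETE
        if if_frame is not None and ff_frame is not None
        else EventStatus.BOTH_MISSING
    )
    return CODEvent(
        cod_index=k,
        minimum_frame=minimum,
        if_frame=if_frame,
        ff_frame=ff_frame,
        pfc_side=Side.LEFT,
        ffc_side=Side.RIGHT,
        status=status,
    )


def make_result(minima, if_frames=None, ff_frames=None):
    if_frames = if_frames or [m - 15 for m in minima]
    ff_frames = ff_frames or [m + 8 for m in minima]
    events = [
        auto_event(k + 1, m, i, f)
        for k, (m, i, f) in enumerate(zip(minima, if_frames, ff_frames))
    ]
    return SegmentationResult(
        trial_id="t", params_used=DetectionParams(), events=events, frame_rate=60.0
    )


def make_labels(events):
    return ManualLabels(
        trial_id="t", events=[LabelEvent(k + 1, a, b) for k, (a, b) in enumerate(events)]
    )


def pairs_from_diffs(if_diffs, ff_diffs=None, base=100):
    """Fully matched pairs with prescribed signed differences."""
    ff_diffs = ff_diffs if ff_diffs is not None else if_diffs
    out = []
    for k, (di, df) in enumerate(zip(if_diffs, ff_diffs)):
        m_if = base + 200 * k
        m_ff = m_if + 30
        out.append(
            EventPair(
                cod_index=k + 1,
                manual_if=m_if,
                manual_ff=m_ff,
                auto_if=m_if + di,
                auto_ff=m_ff + df,
            )
        )
    return out


class TestMatchEvents:
    def test_equal_counts_pair_in_order(self):
        auto = make_result([100, 300, 500, 700])
        manual = make_labels([(90, 110), (290, 310), (490, 510), (690, 710)])
        pairs = match_events(auto, manual)
        assert [p.matched for p in pairs] == [True] * 4
        assert [p.auto_if for p in pairs] == [85, 285, 485, 685]

    def test_missing_auto_event_leaves_one_unmatched(self):
        auto = make_result([100, 300, 700])
        manual = make_labels([(90, 110), (290, 310), (490, 510), (690, 710)])
        pairs = match_events(auto, manual)
        assert sum(p.matched for p in pairs) == 3
        (um,) = [p for p in pairs if not p.matched]
        assert um.cod_index == 3

    def test_matches_exhaustive_min_distance_assignment(self, rng):
        for _ in range(50):
            n_auto = int(rng.integers(1, 6))
            n_man = int(rng.integers(1, 6))
            if n_auto == n_man:
                n_auto += 1  # exercise the assignment branch
            mins = np.sort(rng.choice(np.arange(50, 2000, 30), n_auto, replace=False))
            man_mid = np.sort(rng.choice(np.arange(50, 2000, 30), n_man, replace=False))
            auto = make_result(list(map(int, mins)))
            manual = make_labels([(int(m) - 10, int(m) + 10) for m in man_mid])
            cap = auto.params_used.region_width
            pairs = match_events(auto, manual)
            got_cost = sum(
                abs((p.auto_if + 15) - (p.manual_if + 10)) for p in pairs if p.matched
            )
            got_matched = sum(p.matched for p in pairs)
            best_cost, best_count = math.inf, -1
            k = min(n_auto, n_man)
            for size in range(k, -1, -1):
                for a_sub in itertools.permutations(range(n_auto), size):
                    for m_sub in itertools.combinations(range(n_man), size):
                        d = [abs(mins[a] - man_mid[m]) for a, m in zip(a_sub, m_sub)]
                        if any(x > cap for x in d):
                            continue
                        if size > best_count or (
                            size == best_count and sum(d) < best_cost
                        ):
                            best_cost, best_count = sum(d), size
                if best_count == size:
                    break
            assert got_matched == best_count
            assert got_cost == best_cost


class TestDifferenceSummaries:
    def test_known_values(self):
        med, mode, iqr = difference_summaries(pairs_from_diffs([-1, -1, 0, -2]), "IF")
        assert med == -1 and mode == -1

    def test_sign_convention_is_auto_minus_manual(self):
        (pair,) = pairs_from_diffs([-1])
        assert pair.auto_if == pair.manual_if - 1
        assert pair.diff("IF") == -1

    def test_mode_ties_break_toward_smallest_absolute_value(self):
        _, mode, _ = difference_summaries(pairs_from_diffs([-3, -3, 1, 1]), "IF")
        assert mode == 1

    def test_matches_sort_based_oracle(self, rng):
        d = rng.integers(-10, 11, size=200)
        med, _, iqr = difference_summaries(pairs_from_diffs(list(d)), "IF")
        s = np.sort(d)
        assert med == float(np.median(s))
        q1, q3 = np.percentile(s, [25, 75])
        assert iqr == pytest.approx(q3 - q1)

    def test_empty_kind_raises(self):
        with pytest.raises(ValueError):
            difference_summaries([], "IF")


class TestErrorStats:
    def test_closed_forms(self):
        assert error_stats(pairs_from_diffs([1, -1]), "IF") == pytest.approx(
            (1.0, math.sqrt(2))
        )
        assert error_stats(pairs_from_diffs([0, 0, 0]), "IF") == (0.0, 0.0)

    def test_matches_two_pass_oracle(self, rng):
        d = rng.integers(-20, 21, size=500).astype(float)
        abs_e, sd = error_stats(pairs_from_diffs(list(d)), "IF")
        assert abs_e == pytest.approx(sum(abs(x) for x in d) / len(d))
        mean = sum(d) / len(d)
        assert sd == pytest.approx(
            math.sqrt(sum((x - mean) ** 2 for x in d) / (len(d) - 1))
        )

    def test_single_pair_raises(self):
        with pytest.raises(ValueError):
            error_stats(pairs_from_diffs([1]), "IF")


class TestAveragePrecision:
    def test_threshold_rule(self):
        pairs = pairs_from_diffs([0, 1, 2, 3, 5])
        assert average_precision(pairs, "IF", 2) == pytest.approx(60.0)

    def test_unmatched_events_count_in_denominator_only(self):
        pairs = pairs_from_diffs([0, 0]) + [
            EventPair(cod_index=9, manual_if=900, manual_ff=930, matched=False),
            EventPair(cod_index=10, manual_if=1900, manual_ff=1930, matched=False),
        ]
        assert average_precision(pairs, "IF", 1) == pytest.approx(50.0)

    @given(st.lists(st.integers(-8, 8), min_size=1, max_size=30))
    def test_monotone_in_threshold(self, diffs):
        pairs = pairs_from_diffs(diffs)
        aps = [average_precision(pairs, "IF", k) for k in (2, 3, 4, 10**9)]
        assert aps == sorted(aps)
        assert aps[-1] == pytest.approx(100.0)  # AP_inf = matched / N here


class TestBlandAltman:
    def test_perfect_agreement(self):
        assert bland_altman(pairs_from_diffs([0, 0, 0]), "IF") == (0.0, 0.0, 0.0)

    def test_constant_offset_gives_zero_width(self):
        bias, lo, hi = bland_altman(pairs_from_diffs([3, 3, 3, 3]), "IF")
        assert (bias, lo, hi) == (3.0, 3.0, 3.0)

    def test_matches_direct_formula(self, rng):
        d = rng.normal(size=100)
        bias, lo, hi = bland_altman(pairs_from_diffs(list(d)), "IF")
        assert bias == pytest.approx(np.mean(d))
        assert hi - lo == pytest.approx(2 * 1.96 * np.std(d, ddof=1))


class TestCuttingTimeCorrelation:
    def test_identical_times(self):
        pairs = []
        for k, dur in enumerate((20, 30, 40, 50)):
            m_if = 100 + 200 * k
            pairs.append(
                EventPair(k + 1, m_if, m_if + dur, auto_if=m_if, auto_ff=m_if + dur)
            )
        r, r2 = cutting_time_correlation(pairs, 60.0)
        assert (r, r2) == pytest.approx((1.0, 1.0))

    def test_constant_offset_keeps_r_one(self):
        pairs = []
        for k, dur in enumerate((20, 30, 40, 50)):
            m_if = 100 + 200 * k
            pairs.append(
                EventPair(k + 1, m_if, m_if + dur, auto_if=m_if + 2, auto_ff=m_if + dur + 5)
            )
        r, _ = cutting_time_correlation(pairs, 60.0)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula_and_r2_identity(self, rng):
        pairs = []
        for k in range(30):
            m_if = 100 + 200 * k
            dur = int(rng.integers(15, 60))
            d_if, d_ff = rng.integers(-4, 5, size=2)
            pairs.append(
                EventPair(
                    k + 1, m_if, m_if + dur,
                    auto_if=m_if + int(d_if), auto_ff=m_if + dur + int(d_ff),
                )
            )
        r, r2 = cutting_time_correlation(pairs, 60.0)
        ms = 1000 / 60.0
        at = np.array([(p.auto_ff - p.auto_if) * ms for p in pairs])
        mt = np.array([(p.manual_ff - p.manual_if) * ms for p in pairs])
        expected = np.cov(at, mt)[0, 1] / (np.std(at, ddof=1) * np.std(mt, ddof=1))
        assert r == pytest.approx(expected)
        assert r2 == pytest.approx(r**2, abs=1e-15)

    def test_zero_variance_flagged_degenerate(self):
        pairs = [
            EventPair(k + 1, 100 + 200 * k, 130 + 200 * k,
                      auto_if=100 + 200 * k, auto_ff=130 + 200 * k)
            for k in range(4)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            cutting_time_correlation(pairs, 60.0)

    def test_identity_line_variant(self):
        pairs = []
        for k, dur in enumerate((20, 30, 40, 50)):
            m_if = 100 + 200 * k
            pairs.append(
                EventPair(k + 1, m_if, m_if + dur, auto_if=m_if, auto_ff=m_if + dur + 3)
            )
        _, r2 = cutting_time_correlation(pairs, 60.0, method="identity_line")
        ms = 1000 / 60.0
        at = np.array([(d + 3) * ms for d in (20, 30, 40, 50)])
        mt = at - 3 * ms
        expected = 1 - np.sum((at - mt) ** 2) / np.sum((at - at.mean()) ** 2)
        assert r2 == pytest.approx(expected)


class TestRmse:
    def test_closed_form(self):
        assert rmse(pairs_from_diffs([3], [-4])) == pytest.approx(math.sqrt(12.5))
        assert rmse(pairs_from_diffs([0, 0], [0, 0])) == 0.0

    def test_matches_direct_computation(self, rng):
        di = rng.integers(-6, 7, size=40)
        df = rng.integers(-6, 7, size=40)
        expected = math.sqrt((np.sum(di**2) + np.sum(df**2)) / 80)
        assert rmse(pairs_from_diffs(list(di), list(df))) == pytest.approx(expected)

    def test_unmatched_event_adds_one_penalty_term(self):
        pairs = pairs_from_diffs([0], [0]) + [
            EventPair(cod_index=2, manual_if=900, manual_ff=930, matched=False)
        ]
        assert rmse(pairs, region_width=65) == pytest.approx(math.sqrt(65**2 / 3))

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            rmse([])


class TestTranslationProperties:
    @given(c=st.integers(-20, 20), seed=st.integers(0, 50))
    def test_shift_equivariance_and_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        diffs = list(rng.integers(-5, 6, size=12))
        base = pairs_from_diffs(diffs)
        shifted = pairs_from_diffs([d + c for d in diffs])
        med0, _, iqr0 = difference_summaries(base, "IF")
        med1, _, iqr1 = difference_summaries(shifted, "IF")
        assert med1 == pytest.approx(med0 + c)
        assert iqr1 == pytest.approx(iqr0)
        (_, sd0), (_, sd1) = error_stats(base, "IF"), error_stats(shifted, "IF")
        assert sd1 == pytest.approx(sd0)
        b0, lo0, hi0 = bland_altman(base, "IF")
        b1, lo1, hi1 = bland_altman(shifted, "IF")
        assert b1 == pytest.approx(b0 + c)
        assert hi1 - lo1 == pytest.approx(hi0 - lo0)


class TestBuildReport:
    def test_report_invariants(self, rng):
        diffs_if = list(rng.integers(-4, 5, size=20))
        diffs_ff = list(rng.integers(-4, 5, size=20))
        pairs = pairs_from_diffs(diffs_if, diffs_ff)
        rep = build_report(pairs, 60.0)
        for summ in (rep.if_summary, rep.ff_summary):
            assert summ.loa_low <= summ.bias <= summ.loa_high
            aps = [summ.ap[k] for k in sorted(summ.ap)]
            assert aps == sorted(aps)
            assert all(0 <= v <= 100 for v in aps)
            assert summ.abs_mean_error >= 0
        if rep.pearson_r is not None:
            assert -1 <= rep.pearson_r <= 1
            assert rep.r_squared == pytest.approx(rep.pearson_r**2)
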