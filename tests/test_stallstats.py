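"""Stallogram statistics, duration filtering, and the exponential model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capstall.errors import ValidationError
from capstall.stallstats import (
    compute_statistics,
    confusion_rates,
    duration_cdf,
    extract_events,
    exponential_model,
    filter_min_duration,
    fit_exponential,
    incidence_vs_time,
)
from capstall.types import Stallogram

FRAME_PERIOD = 1.0 / 0.57


def make_gram(rows, frame_period=FRAME_PERIOD):
    m = np.asarray(rows, dtype=bool)
    return Stallogram(m, list(range(m.shape[0])), frame_period)


def random_stallogram(rng, n_caps=12, n_frames=60):
    """Random stallogram whose true runs all span >= 2 frames."""
    m = np.zeros((n_caps, n_frames), dtype=bool)
    for i in range(n_caps):
        t = 0
        while t < n_frames - 2:
            t += int(rng.integers(1, 15))
            dur = int(rng.integers(2, 8))
            if t + dur > n_frames:
                break
            m[i, t : t + dur] = True
            t += dur + 1
    return make_gram(m)


class TestExtractEvents:
    def test_runs_are_read_off_rows(self):
        gram = make_gram([[0, 1, 1, 0, 1, 1, 1]])
        events = extract_events(gram)
        assert [(e.start_frame, e.end_frame, e.duration_frames) for e in events] == [
            (1, 2, 2),
            (4, 6, 3),
        ]

    def test_all_false_gives_no_events(self):
        assert extract_events(make_gram(np.zeros((3, 10)))) == []

    def test_durations_conserve_true_entries(self):
        rng = np.random.default_rng(0)
        gram = random_stallogram(rng)
        events = extract_events(gram)
        assert sum(e.duration_frames for e in events) == int(gram.matrix.sum())

    def test_single_frame_run_is_an_integrity_error(self):
        with pytest.raises(ValidationError):
            extract_events(make_gram([[0, 1, 0, 0]]))


class TestComputeStatistics:
    def test_one_capillary_stalled_throughout(self):
        m = np.zeros((10, 350), dtype=bool)
        m[0] = True
        s = compute_statistics(make_gram(m))
        assert s.incidence == pytest.approx(10.0)
        assert s.point_prevalence == pytest.approx(10.0)
        assert s.cumulative_stall_duration == pytest.approx(100.0)

    def test_cumulative_averages_over_stalling_capillaries_only(self):
        m = np.zeros((10, 350), dtype=bool)
        m[0, :35] = True
        m[1, :70] = True
        s = compute_statistics(make_gram(m))
        assert s.incidence == pytest.approx(20.0)
        assert s.cumulative_stall_duration == pytest.approx(15.0)  # mean(10%, 20%)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            gram = random_stallogram(rng)
            s = compute_statistics(gram)
            m = gram.matrix
            n, T = m.shape
            # independent per-entry counting
            inc = 100.0 * sum(1 for i in range(n) if m[i].sum() > 0) / n
            prev = 100.0 * np.mean([m[:, t].sum() / n for t in range(T)])
            stalling = [i for i in range(n) if m[i].sum() > 0]
            cum = 100.0 * np.mean([m[i].sum() / T for i in stalling]) if stalling else 0.0
            assert s.incidence == pytest.approx(inc, abs=1e-12)
            assert s.point_prevalence == pytest.approx(prev, abs=1e-12)
            assert s.cumulative_stall_duration == pytest.approx(cum, abs=1e-12)

    def test_prevalence_conservation_identity(self):
        rng = np.random.default_rng(2)
        gram = random_stallogram(rng)
        s = compute_statistics(gram)
        n, T = gram.matrix.shape
        assert s.point_prevalence / 100.0 * n * T == pytest.approx(gram.matrix.sum())

    def test_no_stalls_flagged(self):
        s = compute_statistics(make_gram(np.zeros((4, 20))))
        assert s.cumulative_stall_duration == 0.0
        assert s.no_stalls

    def test_external_denominator(self):
        m = np.zeros((2, 10), dtype=bool)
        m[0, :2] = True
        s = compute_statistics(make_gram(m), n_capillaries_total=20)
        assert s.incidence == pytest.approx(5.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            compute_statistics(make_gram(np.zeros((1, 5))), n_capillaries_total=0)


class TestFilterMinDuration:
    def test_filters_short_events(self):
        m = np.zeros((1, 40), dtype=bool)
        for start, dur in [(0, 2), (5, 3), (12, 5), (20, 7)]:
            m[0, start : start + dur] = True
        out = filter_min_duration(make_gram(m), 5)
        assert len(extract_events(out)) == 2

    def test_min_two_is_identity(self):
        rng = np.random.default_rng(3)
        gram = random_stallogram(rng)
        out = filter_min_duration(gram, 2)
        assert np.array_equal(out.matrix, gram.matrix)

    def test_min_five_keeps_only_long_stall_regime(self):
        # at the default frame period, 5 frames is ~8.8 s: only events at
        # least that long survive
        m = np.zeros((1, 40), dtype=bool)
        m[0, 0:4] = True  # 4 frames ~ 7.0 s
        m[0, 10:15] = True  # 5 frames ~ 8.8 s
        out = filter_min_duration(make_gram(m), 5)
        events = extract_events(out)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(5 / 0.57, rel=1e-9)
        assert events[0].duration_s > 8.0

    def test_rejects_min_below_two(self):
        with pytest.raises(ValidationError):
            filter_min_duration(make_gram(np.zeros((1, 5))), 1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 9))
    def test_statistics_monotone_in_min_frames(self, seed, min_frames):
        """Raising the duration floor never increases incidence, prevalence
        or event count."""
        gram = random_stallogram(np.random.default_rng(seed))
        base = compute_statistics(gram)
        filt = filter_min_duration(gram, min_frames)
        s = compute_statistics(filt)
        assert s.incidence <= base.incidence + 1e-12
        assert s.point_prevalence <= base.point_prevalence + 1e-12
        assert len(extract_events(filt)) <= len(extract_events(gram))


class TestDurationCDF:
    def test_simple_cdf(self):
        m = np.zeros((3, 20), dtype=bool)
        m[0, :2] = True
        m[1, :2] = True
        m[2, :4] = True
        cdf = duration_cdf(extract_events(make_gram(m, frame_period=1.0)))
        assert cdf.durations_s.tolist() == [2.0, 4.0]
        assert cdf.cdf.tolist() == pytest.approx([2 / 3, 1.0])

    def test_single_event_step(self):
        m = np.zeros((1, 10), dtype=bool)
        m[0, 3:6] = True
        cdf = duration_cdf(extract_events(make_gram(m, frame_period=2.0)))
        assert cdf.durations_s.tolist() == [6.0]
        assert cdf.cdf.tolist() == [1.0]

    def test_cdf_ends_at_one_and_is_monotone(self):
        gram = random_stallogram(np.random.default_rng(5))
        cdf = duration_cdf(extract_events(gram))
        assert cdf.cdf[-1] == pytest.approx(1.0)
        assert np.all(np.diff(cdf.cdf) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            duration_cdf([])


class TestIncidenceVsTime:
    def test_full_record_equals_overall_incidence(self):
        gram = random_stallogram(np.random.default_rng(6))
        total_min = gram.n_frames * gram.frame_period / 60.0
        curve = incidence_vs_time(gram, [total_min])
        assert curve[0] == pytest.approx(compute_statistics(gram).incidence)

    def test_zero_time_is_zero(self):
        gram = random_stallogram(np.random.default_rng(7))
        assert incidence_vs_time(gram, [0.0])[0] == 0.0

    def test_non_decreasing_and_matches_prefix_counting(self):
        gram = random_stallogram(np.random.default_rng(8))
        grid = np.linspace(0, gram.n_frames * gram.frame_period / 60.0, 25)
        curve = incidence_vs_time(gram, grid)
        assert np.all(np.diff(curve) >= -1e-12)
        # brute-force prefix counting oracle
        for t, val in zip(grid, curve):
            k = int(np.floor(t * 60.0 / gram.frame_period))
            expected = 100.0 * np.mean(gram.matrix[:, :k].any(axis=1)) if k else 0.0
            assert val == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            incidence_vs_time(random_stallogram(np.random.default_rng(9)), [-1.0])


class TestFitExponential:
    # frame times over 10 minutes at the default rate
    T_MIN = np.arange(350) * FRAME_PERIOD / 60.0

    @pytest.mark.parametrize("params", [(8.4, 6.4, 1.15), (5.4, 6.5, 0.7)])
    def test_noiseless_round_trip(self, params):
        y = exponential_model(self.T_MIN, *params)
        fit = fit_exponential(self.T_MIN, y, init=(1.0, 1.0, 0.0))
        for got, want in zip(fit.params, params):
            assert abs(got - want) / abs(want) < 1e-6
        assert fit.converged

    def test_constant_curve_degenerate_convention(self):
        y = np.full_like(self.T_MIN, 3.2)
        fit = fit_exponential(self.T_MIN, y)
        assert fit.A == pytest.approx(0.0, abs=1e-9)
        assert fit.C == pytest.approx(3.2)
        assert fit.b_unidentifiable

    def test_recovery_under_noise(self):
        """Median relative error of A stays under 5% with 0.5% noise."""
        rng = np.random.default_rng(10)
        A, B, C = 8.4, 6.4, 1.15
        clean = exponential_model(self.T_MIN, A, B, C)
        errs = []
        for _ in range(200):
            y = clean + rng.normal(0.0, 0.5, clean.shape)
            fit = fit_exponential(self.T_MIN, y)
            errs.append(abs(fit.A - A) / A)
        assert np.median(errs) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_exponential(np.arange(3.0), np.arange(3.0))


class TestConfusionRates:
    def test_validation_counts_manual_detection(self):
        rates = confusion_rates(tp=102, fp=37, tn=2074, fn=245)
        assert rates["sensitivity_pct"] == pytest.approx(29.4, abs=0.05)
        assert rates["specificity_pct"] == pytest.approx(98.2, abs=0.05)
        assert rates["false_negative_rate_pct"] == pytest.approx(70.6, abs=0.05)

    def test_validation_counts_correlation_detection(self):
        rates = confusion_rates(tp=317, fp=1150, tn=961, fn=30)
        assert rates["sensitivity_pct"] == pytest.approx(91.4, abs=0.05)
        assert rates["specificity_pct"] == pytest.approx(45.5, abs=0.05)
        assert rates["false_negative_rate_pct"] == pytest.approx(8.6, abs=0.05)

    def test_zero_row_flags_undefined(self):
        rates = confusion_rates(tp=0, fp=2, tn=8, fn=0)
        assert rates["undefined"]
        assert np.isnan(rates["sensitivity_pct"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            confusion_rates(-1, 0, 0, 0)
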