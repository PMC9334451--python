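"""Syncopated schedule construction and learning-rate decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosvpl.design import (
    LearningRates,
    TEST_SESSIONS,
    VIDEOS_BEFORE,
    acuity_change,
    attribute_gains,
    build_schedule,
    decode_from_spans,
    decode_rates,
    exposure_summary,
    extract_spans,
    rates_from_regression,
    Schedule,
    SpanImprovement,
)


class TestBuildSchedule:
    def test_every_subject_six_tests_with_canonical_spans(self, schedule8):
        for subj in schedule8.subjects:
            assert len(schedule8.positions(subj)) == 6
            spans = schedule8.span_lengths(subj)
            assert sorted(spans) == [3, 3, 3, 6, 6]
            assert sum(spans) == 21  # all videos accounted for

    def test_first_and_last_positions_fully_populated(self, schedule8):
        counts = schedule8.position_counts()
        assert counts[0] == 8 and counts[7] == 8

    def test_intermediate_positions_five_or_six_total_48(self, schedule8):
        counts = schedule8.position_counts()
        assert all(c in (5, 6) for c in counts[1:7])
        assert counts.sum() == 48  # 8 subjects x 6 tests

    def test_deterministic_per_seed(self):
        a = build_schedule(8, seed=4)
        b = build_schedule(8, seed=4)
        assert a.assignments == b.assignments

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(1, seed=0)

    def test_frame_round_trip(self, schedule8):
        df = schedule8.to_frame()
        back = Schedule.from_frame(df)
        assert back.assignments == schedule8.assignments

    def test_frame_session_bookkeeping(self, schedule8):
        df = schedule8.to_frame()
        one = df[df["subject"] == schedule8.subjects[0]]
        assert len(one) == 23
        assert one["has_video"].sum() == 21
        assert not one.loc[one["session"] == 1, "has_video"].item()
        assert not one.loc[one["session"] == 23, "has_video"].item()

    def test_packaged_schedule_validates(self, packaged_schedule):
        counts = packaged_schedule.position_counts()
        assert counts[0] == 8 and counts[7] == 8
        assert all(c in (5, 6) for c in counts[1:7])


class TestExtractSpans:
    def _acuities(self, schedule, fn):
        rows = []
        for subj in schedule.subjects:
            for pos in schedule.positions(subj):
                rows.append({"subject": subj, "position": pos, "acuity": fn(subj, pos)})
        return pd.DataFrame(rows)

    def test_constant_series_all_deltas_zero(self, schedule8):
        spans, dropped = extract_spans(self._acuities(schedule8, lambda s, p: 1.2), schedule8)
        assert dropped == 0
        assert all(s.delta == 0.0 for s in spans)

    def test_uniform_per_session_drop_matches_direct_subtraction(self, schedule8):
        # acuity falls 0.01 per video session; short span = 3 videos
        acuities = self._acuities(schedule8, lambda s, p: 1.3 - 0.01 * VIDEOS_BEFORE[p])
        spans, _ = extract_spans(acuities, schedule8)
        for s in spans:
            expected = -0.03 if s.kind == "short" else -0.06
            assert s.delta == pytest.approx(expected)

    def test_span_counts_24_short_16_long(self, schedule8):
        spans, _ = extract_spans(self._acuities(schedule8, lambda s, p: 1.2), schedule8)
        kinds = [s.kind for s in spans]
        assert kinds.count("short") == 24
        assert kinds.count("long") == 16

    def test_censored_tests_drop_adjacent_spans(self, schedule8):
        acuities = self._acuities(schedule8, lambda s, p: 1.2)
        acuities["usable"] = True
        subj = schedule8.subjects[0]
        mid = schedule8.positions(subj)[2]
        acuities.loc[
            (acuities["subject"] == subj) & (acuities["position"] == mid), "usable"
        ] = False
        spans, dropped = extract_spans(acuities, schedule8)
        assert dropped == 2
        assert len(spans) == 38

    def test_missing_acuity_rejected(self, schedule8):
        acuities = self._acuities(schedule8, lambda s, p: 1.2).iloc[:-1]
        with pytest.raises(ValueError):
            extract_spans(acuities, schedule8)


class TestDecodeRates:
    def test_study_population_means(self):
        rates = decode_rates(-0.025, -0.035)
        assert rates.beta_R == pytest.approx(-0.015, abs=5e-4)
        assert rates.beta_V == pytest.approx(-0.00333, abs=5e-5)

    def test_equal_spans_imply_zero_video_rate(self):
        rates = decode_rates(-0.02, -0.02)
        assert rates.beta_V == 0.0
        assert rates.beta_R == pytest.approx(-0.02)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        beta_v=st.floats(-0.1, 0.1, allow_nan=False),
        beta_r=st.floats(-0.1, 0.1, allow_nan=False),
    )
    def test_encode_decode_identity(self, beta_v, beta_r):
        y1 = 3 * beta_v + beta_r
        y2 = 6 * beta_v + beta_r
        rates = decode_rates(y1, y2)
        assert rates.beta_V == pytest.approx(beta_v, abs=1e-12)
        assert rates.beta_R == pytest.approx(beta_r, abs=1e-12)

    def test_decoding_identity_invariant(self):
        rates = decode_rates(-0.0213, -0.0347)
        assert 3 * rates.beta_V + rates.beta_R == pytest.approx(rates.y1_mean, abs=1e-12)
        assert 6 * rates.beta_V + rates.beta_R == pytest.approx(rates.y2_mean, abs=1e-12)

    def test_unbiased_under_zero_mean_noise(self):
        # law of large numbers: noisy span means decode to the generating
        # rates on average
        rng = np.random.default_rng(0)
        n = 10_000
        beta_v, beta_r = -0.004, -0.012
        y1 = 3 * beta_v + beta_r + rng.normal(0, 0.02, n)
        y2 = 6 * beta_v + beta_r + rng.normal(0, 0.02, n)
        decoded = np.array([(decode_rates(a, b).beta_R, decode_rates(a, b).beta_V)
                            for a, b in zip(y1, y2)])
        assert decoded[:, 0].mean() == pytest.approx(beta_r, abs=3 * 0.045 / np.sqrt(n))
        assert decoded[:, 1].mean() == pytest.approx(beta_v, abs=3 * 0.01 / np.sqrt(n))


class TestDecodeFromSpans:
    def test_pools_means_then_decodes(self):
        spans = [
            SpanImprovement("S1", "short", -0.02),
            SpanImprovement("S1", "long", -0.04),
            SpanImprovement("S2", "short", -0.03),
            SpanImprovement("S2", "long", -0.03),
        ]
        rates = decode_from_spans(spans)
        assert rates.y1_mean == pytest.approx(-0.025)
        assert rates.y2_mean == pytest.approx(-0.035)
        assert rates.n_short == 2 and rates.n_long == 2
        assert rates.beta_R == pytest.approx(-0.015)

    def test_per_subject_distribution(self):
        spans = [
            SpanImprovement("S1", "short", -0.02),
            SpanImprovement("S1", "long", -0.05),
            SpanImprovement("S2", "short", -0.01),
            SpanImprovement("S2", "long", -0.01),
        ]
        rates = decode_from_spans(spans, per_subject=True)
        ps = rates.per_subject.set_index("subject")
        assert ps.loc["S1", "beta_V"] == pytest.approx(-0.01)
        assert ps.loc["S2", "beta_V"] == pytest.approx(0.0)

    def test_single_kind_rejected(self):
        with pytest.raises(ValueError):
            decode_from_spans([SpanImprovement("S1", "short", -0.02)])


class TestRatesFromRegression:
    def test_exact_video_only_dependence(self):
        video = np.repeat(np.arange(0, 500, 25.0), 2)
        # reading alternates +/-10 min within each repeated video value, so
        # it is exactly orthogonal to video and carries no acuity signal
        reading = 40.0 + 10.0 * np.tile([1.0, -1.0], len(video) // 2)
        acuity = 1.3 - 0.0002 * video
        df = pd.DataFrame({"acuity": acuity, "reading_min": reading, "video_min": video})
        out = rates_from_regression(df)
        assert out["video"]["r_squared"] == pytest.approx(1.0)
        assert out["video"]["slopes"]["video_min"] == pytest.approx(-0.0002, abs=1e-10)
        lo, hi = out["reading"]["ci"]["reading_min"]
        assert lo <= 0.0 <= hi  # reading slope CI covers zero

    def test_duplicate_rows_leave_slopes_unchanged(self):
        rng = np.random.default_rng(2)
        n = 30
        df = pd.DataFrame(
            {
                "reading_min": rng.uniform(0, 80, n),
                "video_min": rng.uniform(0, 500, n),
            }
        )
        df["acuity"] = 1.3 - 0.001 * df["reading_min"] - 0.0002 * df["video_min"] + rng.normal(0, 0.01, n)
        dup = pd.concat([df, df], ignore_index=True)
        a = rates_from_regression(df)["both"]["slopes"]
        b = rates_from_regression(dup)["both"]["slopes"]
        for k in a:
            assert b[k] == pytest.approx(a[k], rel=1e-9)

    def test_collinear_predictors_rejected(self):
        df = pd.DataFrame(
            {
                "acuity": [1.3, 1.2, 1.1, 1.0],
                "reading_min": [10.0, 20.0, 30.0, 40.0],
                "video_min": [20.0, 40.0, 60.0, 80.0],
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            rates_from_regression(df)

    def test_per_session_conversion_uses_mean_session_lengths(self):
        rng = np.random.default_rng(3)
        n = 48
        df = pd.DataFrame(
            {
                "reading_min": rng.uniform(0, 80, n),
                "video_min": rng.uniform(0, 500, n),
            }
        )
        df["acuity"] = 1.3 - 0.0011 * df["reading_min"] - 0.00013 * df["video_min"]
        out = rates_from_regression(df)
        # per-session rates are the univariate per-minute slopes scaled by
        # the mean session lengths (13.6 min reading, 24.7 min video)
        assert out["per_session"]["beta_R_prime"] == pytest.approx(
            out["reading"]["slopes"]["reading_min"] * 13.6, rel=1e-12
        )
        assert out["per_session"]["beta_V_prime"] == pytest.approx(
            out["video"]["slopes"]["video_min"] * 24.7, rel=1e-12
        )


class TestAttributeGains:
    def test_study_convention_gains(self):
        rates = LearningRates(-0.015, -0.01 / 3.0, -0.025, -0.035)
        out = attribute_gains(rates, n_reading_influences=5, n_video=21)
        assert out["reading_gain"] == pytest.approx(-0.075)
        assert out["video_gain"] == pytest.approx(-0.07)
        assert out["reading_percent"] == pytest.approx(
            100 * 0.075 / 0.145, rel=1e-9
        )
        assert out["split_defined"]

    def test_zero_rates_flag_undefined_split(self):
        out = attribute_gains(LearningRates(0.0, 0.0, 0.0, 0.0))
        assert not out["split_defined"]
        assert np.isnan(out["reading_percent"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            attribute_gains(LearningRates(-0.01, -0.002, 0, 0), n_reading_influences=-1)


class TestSummaries:
    def test_exposure_ratio_and_fraction(self):
        out = exposure_summary(4483.0, 30389.0)
        assert out["ratio_video_to_reading"] == pytest.approx(6.8, abs=0.05)
        assert out["reading_fraction_percent"] == pytest.approx(13.0, abs=0.5)

    def test_acuity_change_sign_convention(self):
        assert acuity_change(1.28, 1.13) == pytest.approx(-0.15)
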