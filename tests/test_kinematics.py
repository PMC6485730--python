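"""Metric extraction oracles, duration families and invariance properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from whiskerkin import Config
from whiskerkin.kinematics import (
    MissingDataError,
    average_traces,
    baseline_angle,
    duration_family,
    extract_metrics,
    fill_missing,
    group_summary,
    percent_of_baseline,
    sensitivity_threshold,
    smooth_and_differentiate,
)
from whiskerkin.synthetic_data import (
    DEFAULT_DURATIONS_MS,
    TwitchParams,
    gaussian_bump,
    gaussian_peak_velocity,
    simulate_twitch,
)
from whiskerkin.traceio import ValidationError

from conftest import make_trace

import pandas as pd


class TestBaseline:
    def test_constant_trace(self, flat_trace):
        assert baseline_angle(flat_trace) == 5.0

    def test_flat_prestim_then_ramp(self):
        t = np.arange(1500) * 2.0
        angle = np.where(t >= 500, (t - 500) * 0.01, 0.0)
        assert baseline_angle(make_trace(angle)) == 0.0

    def test_noisy_baseline_equals_brute_force_mean(self):
        rng = np.random.default_rng(7)
        angle = rng.normal(2.0, 0.5, 1500)
        tr = make_trace(angle)
        # brute force: plain average of the samples in [300, 500) ms
        expected = angle[150:250].mean()
        assert baseline_angle(tr) == pytest.approx(expected, rel=1e-12)

    def test_no_samples_in_window_rejected(self):
        tr = make_trace(np.zeros(1500), onset=0.0)
        with pytest.raises(ValidationError):
            baseline_angle(tr)


class TestSmoothAndDifferentiate:
    def test_linear_ramp_exact_interior(self):
        angle = np.arange(1500) * 1.0  # 1 deg/frame at 2 ms/frame
        v = smooth_and_differentiate(make_trace(angle))
        np.testing.assert_allclose(v[10:-10], 500.0, rtol=1e-9)

    def test_sinusoid_peak_velocity_analytic(self):
        t = np.arange(1500) * 2.0
        angle = 5.0 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
        v = smooth_and_differentiate(make_trace(angle))
        assert np.max(v) == pytest.approx(2 * np.pi * 5.0 * 5.0, rel=0.01)

    def test_constant_trace_gives_zeros(self, flat_trace):
        np.testing.assert_allclose(smooth_and_differentiate(flat_trace), 0.0, atol=1e-9)

    def test_trace_shorter_than_window_rejected(self):
        tr = make_trace(np.zeros(10), onset=0.0, duration=0.0)
        with pytest.raises(ValidationError):
            smooth_and_differentiate(tr, window_samples=11)


class TestExtractMetrics:
    def test_exponential_rise_closed_forms(self):
        """Asymptote 10 deg, tau 20 ms, no fatigue: peak -> 10, PI -> 1.

        The smoothed-derivative peak velocity underestimates the analytic
        A/tau = 500 deg/s because the maximum slope sits at the onset
        discontinuity, which the smoother rounds; it must never exceed it.
        """
        p = TwitchParams(a_max_deg=10.0, d50_ms=1e-3, hill=1.0, tau_rise_ms=20.0,
                         tau_fatigue_ms=100.0, tau_decay_ms=100.0,
                         plateau_fraction=1.0, latency_ms=0.0, noise_sd_deg=0.0)
        m = extract_metrics(simulate_twitch(p, 1000, 500, 3000))
        assert m.peak_amplitude_deg == pytest.approx(10.0, rel=1e-3)
        assert m.persistence_index == pytest.approx(1.0, abs=0.01)
        assert 0.5 * 500.0 < m.peak_velocity_deg_per_s <= 500.0 * 1.001

    def test_gaussian_primitive_metric_truths(self):
        """Smooth calibrated primitive: peak, FWHM and peak velocity match
        the analytic truths within 2% / one sample period."""
        g = gaussian_bump(10.0, 100.0)
        m = extract_metrics(g)
        assert m.peak_amplitude_deg == pytest.approx(10.0, rel=0.02)
        assert m.half_width_ms == pytest.approx(100.0, abs=2.0)
        assert m.peak_velocity_deg_per_s == pytest.approx(
            gaussian_peak_velocity(10.0, 100.0), rel=0.02
        )

    def test_constructed_persistence_index(self):
        """Peak 10 deg settling to 3.012 deg at offset -> PI = 0.3012."""
        t = np.arange(1500) * 2.0
        angle = np.zeros(1500)
        rise = (t >= 500) & (t < 600)
        angle[rise] = (t[rise] - 500) / 100.0 * 10.0
        fall = (t >= 600) & (t < 900)
        angle[fall] = 10.0 + (t[fall] - 600) / 300.0 * (3.012 - 10.0)
        angle[(t >= 900) & (t <= 1500)] = 3.012  # settled well before offset (1500 ms)
        angle[t > 1500] = 0.0
        m = extract_metrics(make_trace(angle))
        assert m.persistence_index == pytest.approx(0.3012, abs=1e-6)

    def test_zero_trace_flags_no_response(self):
        m = extract_metrics(make_trace(np.zeros(1500)))
        assert m.no_response
        assert m.peak_amplitude_deg == 0.0
        assert m.time_to_peak_ms is None and m.half_width_ms is None

    def test_triangular_bump_half_width(self):
        """Symmetric triangle, 40-ms base, 10-deg peak -> half-width 20 ms."""
        t = np.arange(1500) * 2.0
        angle = np.clip(10.0 - np.abs(t - 700.0) / 2.0, 0.0, None)
        m = extract_metrics(make_trace(angle))
        assert m.half_width_ms == pytest.approx(20.0, abs=1e-9)

    def test_unfinished_decay_censors_half_width(self):
        t = np.arange(1500) * 2.0
        angle = np.where(t >= 500, 10.0, 0.0)  # step that never comes down
        m = extract_metrics(make_trace(angle))
        assert m.half_width_censored and m.half_width_ms is None

    def test_retraction_sign_mode(self):
        p = TwitchParams(a_max_deg=10.0, d50_ms=1e-3, hill=1.0, tau_rise_ms=20.0,
                         tau_fatigue_ms=100.0, tau_decay_ms=100.0,
                         plateau_fraction=1.0, latency_ms=0.0, noise_sd_deg=0.0)
        tr = simulate_twitch(p, 1000, 500, 3000)
        flipped = dataclasses.replace(tr, angle_deg=-tr.angle_deg)
        m = extract_metrics(flipped, Config(response_sign=-1))
        assert m.peak_amplitude_deg == pytest.approx(10.0, rel=1e-3)


class TestAverageAndMissing:
    def test_identical_copies_average_to_themselves(self, flat_trace):
        avg = average_traces([flat_trace, flat_trace, flat_trace])
        np.testing.assert_array_equal(avg.angle_deg, flat_trace.angle_deg)

    def test_two_traces_elementwise_mean(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=1500), rng.normal(size=1500)
        avg = average_traces([make_trace(a), make_trace(b)])
        np.testing.assert_allclose(avg.angle_deg, (a + b) / 2.0, rtol=1e-12)

    def test_masked_frame_averages_over_remaining_trials(self):
        a = np.ones(1500)
        b = np.full(1500, 3.0)
        b[10] = np.nan
        avg = average_traces([make_trace(a), make_trace(b)])
        assert avg.angle_deg[10] == 1.0  # only the unmasked trial contributes
        assert avg.angle_deg[11] == 2.0

    def test_shape_mismatch_rejected(self, flat_trace):
        other = make_trace(np.zeros(1000))
        with pytest.raises(ValidationError):
            average_traces([flat_trace, other])

    def test_short_gap_interpolated_long_gap_rejected(self):
        angle = np.zeros(1500)
        angle[100:103] = np.nan
        filled = fill_missing(make_trace(angle))
        assert np.all(np.isfinite(filled))
        angle[200:210] = np.nan
        with pytest.raises(MissingDataError):
            fill_missing(make_trace(angle))


class TestDurationFamily:
    @staticmethod
    def hill_traces(d50=10.0, h=2.0, a_max=10.0):
        p = TwitchParams(a_max_deg=a_max, d50_ms=d50, hill=h, tau_rise_ms=0.05,
                         tau_fatigue_ms=1e5, tau_decay_ms=500.0,
                         plateau_fraction=1.0, latency_ms=10.0, noise_sd_deg=0.0)
        return [
            simulate_twitch(p, d, 500, 3000, subject_id="s1", day=0.0)
            for d in DEFAULT_DURATIONS_MS
        ]

    def test_hill_family_amplitudes_match_closed_form(self):
        fam = duration_family(self.hill_traces())
        for d in DEFAULT_DURATIONS_MS:
            expected = 10.0 * d**2 / (d**2 + 100.0)
            assert fam.amplitude(d) == pytest.approx(expected, rel=0.02)

    def test_single_duration_family(self):
        fam = duration_family([self.hill_traces()[3]])
        assert len(fam.table) == 1

    def test_missing_duration_flagged_absent(self):
        fam = duration_family(self.hill_traces()[:3], durations_ms=[1, 3, 5, 10])
        row = fam.table[fam.table["stim_duration_ms"] == 10]
        assert bool(row["absent"].iloc[0])

    def test_denervation_presets_boost_short_stimuli_most(self):
        """Day-7 vs. baseline presets: the 5-ms amplitude grows by a larger
        factor than the 1000-ms amplitude (increased sensitivity)."""
        from whiskerkin.pipeline import muscle_twitch_params

        ratios = {}
        for dur in (5.0, 1000.0):
            amps = {}
            for day in (-1.0, 7.0):
                p = dataclasses.replace(muscle_twitch_params(day), noise_sd_deg=0.0)
                m = extract_metrics(simulate_twitch(p, dur, 500, 3000))
                amps[day] = m.peak_amplitude_deg
            ratios[dur] = amps[7.0] / amps[-1.0]
        assert ratios[5.0] > ratios[1000.0] > 1.0


class TestSensitivityThreshold:
    def make_family(self, amps, durs):
        rows = [
            {"stim_duration_ms": d, "absent": False, "n_replicates": 1,
             "peak_amplitude_deg": a}
            for d, a in zip(durs, amps)
        ]
        from whiskerkin.kinematics import ResponseDurationFamily
        return ResponseDurationFamily("s", 0.0, pd.DataFrame(rows))

    def test_first_duration_reaching_criterion(self):
        fam = self.make_family([0.1, 0.5, 2.0, 8.0], [1, 3, 5, 10])
        assert sensitivity_threshold(fam, 1.0) == 5.0

    def test_all_below_criterion_censored(self):
        fam = self.make_family([0.1, 0.2], [1, 3])
        assert sensitivity_threshold(fam, 1.0) is None

    def test_matches_analytic_hill_inversion(self):
        """Noiseless Hill family (A=10, d50=10, h=2): criterion 1 deg crosses
        at d = d50 (c/(A-c))^(1/h) = 3.33 ms -> smallest protocol duration 5 ms."""
        fam = duration_family(TestDurationFamily.hill_traces())
        analytic = 10.0 * (1.0 / 9.0) ** 0.5
        protocol = [d for d in DEFAULT_DURATIONS_MS if d >= analytic]
        assert sensitivity_threshold(fam, 1.0) == protocol[0] == 5.0


class TestPercentOfBaseline:
    @pytest.mark.parametrize(
        "post, base, expected",
        [(0.7655, 0.3012, 254.0), (20.32, 13.88, 146.0), (13.90, 2.75, 505.0)],
    )
    def test_published_worked_examples(self, post, base, expected):
        assert percent_of_baseline(post, base) == expected

    def test_identity_is_100(self):
        assert percent_of_baseline(3.7, 3.7) == 100.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            percent_of_baseline(1.0, 0.0)


class TestGroupSummary:
    def test_three_subject_brute_force(self):
        df = pd.DataFrame({
            "subject": ["a", "b", "c"], "day": [7.0] * 3,
            "peak_amplitude_deg": [10.0, 12.0, 17.0],
        })
        gs = group_summary(df)
        row = gs.summary.iloc[0]
        vals = np.array([10.0, 12.0, 17.0])
        assert row["peak_amplitude_deg_mean"] == pytest.approx(vals.mean())
        assert row["peak_amplitude_deg_se"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(3)
        )

    def test_single_subject_warns_and_reports_zero_se(self):
        df = pd.DataFrame({"subject": ["a"], "day": [0.0], "peak_amplitude_deg": [1.0]})
        with pytest.warns(UserWarning, match="SE undefined"):
            gs = group_summary(df)
        assert gs.summary.iloc[0]["peak_amplitude_deg_se"] == 0.0

    def test_direction_counts_eight_of_nine(self):
        rows = []
        for i in range(9):
            rows.append({"subject": f"m{i}", "day": -1.0, "peak_amplitude_deg": 10.0})
            post = 15.0 if i < 8 else 5.0
            rows.append({"subject": f"m{i}", "day": 7.0, "peak_amplitude_deg": post})
        gs = group_summary(pd.DataFrame(rows), baseline_day=-1.0)
        day7 = gs.summary[gs.summary["day"] == 7.0].iloc[0]
        assert day7["peak_amplitude_deg_increased"] == "8/9"


class TestInvariances:
    @staticmethod
    def noiseless_twitch():
        p = TwitchParams(a_max_deg=8.0, d50_ms=5.0, hill=2.0, tau_rise_ms=10.0,
                         tau_fatigue_ms=200.0, tau_decay_ms=80.0,
                         plateau_fraction=0.4, latency_ms=10.0, noise_sd_deg=0.0)
        return simulate_twitch(p, 1000, 500, 3000)

    @given(k=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    def test_homogeneity_under_amplitude_scaling(self, k):
        tr = self.noiseless_twitch()
        m0 = extract_metrics(tr)
        scaled = dataclasses.replace(tr, angle_deg=tr.angle_deg * k)
        m1 = extract_metrics(scaled)
        assert m1.peak_amplitude_deg == pytest.approx(k * m0.peak_amplitude_deg, rel=1e-9)
        assert m1.peak_velocity_deg_per_s == pytest.approx(
            k * m0.peak_velocity_deg_per_s, rel=1e-9
        )
        assert m1.time_to_peak_ms == m0.time_to_peak_ms
        assert m1.half_width_ms == pytest.approx(m0.half_width_ms, rel=1e-9)
        assert m1.persistence_index == pytest.approx(m0.persistence_index, rel=1e-9)

    @given(shift=st.integers(min_value=-100, max_value=100))
    def test_time_shift_invariance(self, shift):
        tr = self.noiseless_twitch()
        m0 = extract_metrics(tr)
        shifted = dataclasses.replace(
            tr,
            angle_deg=np.roll(tr.angle_deg, shift),
            stim_onset_ms=tr.stim_onset_ms + shift * tr.sample_period_ms,
        )
        # rolled-in samples are zeros anyway for this waveform
        m1 = extract_metrics(shifted)
        assert m1.peak_amplitude_deg == pytest.approx(m0.peak_amplitude_deg, rel=1e-6)
        assert m1.time_to_peak_ms == pytest.approx(m0.time_to_peak_ms, abs=1e-9)
        assert m1.half_width_ms == pytest.approx(m0.half_width_ms, rel=1e-6)
        assert m1.persistence_index == pytest.approx(m0.persistence_index, abs=1e-6)

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        noise=st.floats(min_value=0.0, max_value=0.2),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_persistence_index_always_in_unit_interval(self, p, noise, seed):
        par = TwitchParams(a_max_deg=10.0, d50_ms=5.0, hill=2.0, tau_rise_ms=5.0,
                           tau_fatigue_ms=150.0, tau_decay_ms=80.0,
                           plateau_fraction=p, latency_ms=10.0, noise_sd_deg=noise)
        m = extract_metrics(simulate_twitch(par, 1000, 500, 3000, seed=seed))
        if m.persistence_index is not None:
            assert 0.0 <= m.persistence_index <= 1.0
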