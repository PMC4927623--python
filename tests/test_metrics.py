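"""Activity-profile metrics: RMS envelope, APDF, %MR, exposure flags."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import emgprofile as ep
from emgprofile.errors import InsufficientDurationError, ResolutionError, ValidationError


def _rec(samples, fs=1000.0):
    return ep.EmgRecording(samples=np.asarray(samples, float), sampling_rate=fs)


def _env(values, window=0.1, step=0.05):
    return ep.NormalizedEnvelope(values=np.asarray(values, float), window_duration=window, step_duration=step)


def brute_force_envelope(x, fs, window, step):
    """Independent oracle: explicit loop over windows."""
    w, s = int(round(window * fs)), int(round(step * fs))
    out = []
    k = 0
    while k * s + w <= len(x):
        chunk = x[k * s : k * s + w]
        out.append(np.sqrt(np.mean(chunk**2)))
        k += 1
    return np.array(out)


def brute_force_quantile(values, p):
    """Independent oracle: full sort + manual linear interpolation."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_force_percent_rest(values, step, threshold, min_gap):
    """Independent oracle: enumerate runs one value at a time."""
    runs, current = [], 0
    for v in values:
        if v <= threshold:
            current += 1
        else:
            if current:
                runs.append(current)
            current = 0
    if current:
        runs.append(current)
    rest = sum(n * step for n in runs if n * step >= min_gap - 1e-12)
    return 100.0 * rest / (len(values) * step)


class TestRmsEnvelope:
    def test_constant_signal(self):
        env = ep.compute_rms_envelope(_rec(np.full(1000, 2.0)))
        np.testing.assert_allclose(env.values, 2.0)

    def test_value_count_invariant(self):
        env = ep.compute_rms_envelope(_rec(np.ones(1234)), 0.1, 0.05)
        assert env.values.size == (1234 - 100) // 50 + 1

    def test_sinusoid(self):
        t = np.arange(2000) / 1000.0
        a = 3.0
        env = ep.compute_rms_envelope(_rec(a * np.sin(2 * np.pi * 50 * t)), 0.1, 0.05)
        # 0.1-s window = 5 full periods of 50 Hz
        assert np.max(np.abs(env.values - a / np.sqrt(2))) < 1e-3 * a

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal(1000)
        env = ep.compute_rms_envelope(_rec(x), 0.1, 0.05)
        np.testing.assert_allclose(env.values, brute_force_envelope(x, 1000.0, 0.1, 0.05), rtol=1e-12)

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal(600)
        a = ep.compute_rms_envelope(_rec(x)).values
        b = ep.compute_rms_envelope(_rec(-x)).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(InsufficientDurationError):
            ep.compute_rms_envelope(_rec(np.ones(50)), 0.1, 0.05)

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValidationError):
            ep.compute_rms_envelope(_rec(np.ones(1000)), 0.1, 0.2)


class TestMeanRms:
    def test_constant(self):
        assert ep.mean_rms(_env(np.full(7, 7.0))) == pytest.approx(7.0)

    def test_two_level(self):
        assert ep.mean_rms(_env([0.0] * 10 + [10.0] * 10)) == pytest.approx(5.0)

    def test_simulated_schedule_mean(self, sim_config):
        sched = ep.rest_work_schedule(600.0, 0.3, 1.5, 20.0)
        rec, truth = ep.simulate_recording(sim_config, sched)
        env = ep.compute_rms_envelope(rec)
        got = 100.0 * ep.mean_rms(env) / sim_config.mvc_reference_amplitude
        assert got == pytest.approx(truth.mean_envelope_pct, rel=0.03)


class TestApdf:
    def test_constant_envelope(self):
        apdf = ep.compute_apdf(_env(np.full(50, 4.2)))
        assert all(v == pytest.approx(4.2) for v in apdf.values())

    def test_symmetric_ladder_median(self):
        apdf = ep.compute_apdf(_env(np.arange(1.0, 100.0)), percentiles=(0.5,))
        assert apdf[0.5] == pytest.approx(50.0)

    def test_matches_sort_oracle(self, rng):
        values = rng.gamma(2.0, 5.0, size=10_000)
        apdf = ep.compute_apdf(_env(values))
        for p, got in apdf.items():
            assert got == pytest.approx(brute_force_quantile(values, p), rel=1e-12)

    def test_monotone_in_probability(self, rng):
        apdf = ep.compute_apdf(_env(rng.exponential(size=500)))
        vals = [apdf[p] for p in sorted(apdf)]
        assert vals == sorted(vals)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_probability_bounds(self, bad):
        with pytest.raises(ValidationError):
            ep.compute_apdf(_env([1.0, 2.0]), percentiles=(bad,))


class TestPercentMuscularRest:
    def test_all_zero_envelope(self):
        assert ep.percent_muscular_rest(_env(np.zeros(100))) == pytest.approx(100.0)

    def test_constant_active_envelope(self):
        assert ep.percent_muscular_rest(_env(np.full(100, 10.0))) == pytest.approx(0.0)

    def test_gap_shorter_than_minimum_ignored(self):
        # 4 sub-threshold values at step 0.05 s span 0.20 s < 0.25 s
        values = np.full(100, 10.0)
        values[50:54] = 0.0
        assert ep.percent_muscular_rest(_env(values)) == pytest.approx(0.0)

    def test_gap_exactly_at_minimum_counts(self):
        values = np.full(100, 10.0)
        values[50:55] = 0.0  # 5 × 0.05 s = 0.25 s
        assert ep.percent_muscular_rest(_env(values)) == pytest.approx(100.0 * 5 / 100)

    def test_threshold_is_inclusive(self):
        values = np.full(20, 0.5)  # exactly at the 0.5 %fMVC maximum threshold
        assert ep.percent_muscular_rest(_env(values)) == pytest.approx(100.0)

    def test_min_gap_below_step_resolution_rejected(self):
        with pytest.raises(ResolutionError, match="smaller step"):
            ep.percent_muscular_rest(_env(np.zeros(10)), min_gap_duration=0.01)

    @given(
        values=hnp.arrays(
            float,
            st.integers(min_value=1, max_value=1000),
            elements=st.floats(min_value=0.0, max_value=2.0),
        )
    )
    def test_matches_run_enumeration_oracle(self, values):
        env = _env(values)
        got = ep.percent_muscular_rest(env)
        want = brute_force_percent_rest(values, 0.05, 0.5, 0.25)
        assert got == pytest.approx(want, abs=1e-12)

    @given(
        values=hnp.arrays(
            float, 200, elements=st.floats(min_value=0.0, max_value=2.0)
        ),
        thresholds=st.tuples(
            st.floats(min_value=0.1, max_value=1.0), st.floats(min_value=0.1, max_value=1.0)
        ),
    )
    def test_monotone_in_amplitude_threshold(self, values, thresholds):
        lo, hi = sorted(thresholds)
        env = _env(values)
        assert ep.percent_muscular_rest(env, hi) >= ep.percent_muscular_rest(env, lo)

    @given(
        values=hnp.arrays(
            float, 200, elements=st.floats(min_value=0.0, max_value=2.0)
        ),
        gaps=st.tuples(
            st.floats(min_value=0.05, max_value=2.0), st.floats(min_value=0.05, max_value=2.0)
        ),
    )
    def test_antimonotone_in_min_gap(self, values, gaps):
        lo, hi = sorted(gaps)
        env = _env(values)
        assert ep.percent_muscular_rest(env, min_gap_duration=hi) <= ep.percent_muscular_rest(
            env, min_gap_duration=lo
        )

    def test_simulated_rest_recovery(self, sim_config):
        sched = ep.rest_work_schedule(600.0, 0.3, 1.5, 20.0)
        rec, truth = ep.simulate_recording(sim_config, sched)
        env = ep.compute_rms_envelope(rec)
        norm = ep.NormalizedEnvelope(
            values=100.0 * env.values / sim_config.mvc_reference_amplitude,
            window_duration=env.window_duration,
            step_duration=env.step_duration,
        )
        got = ep.percent_muscular_rest(norm)
        assert got == pytest.approx(truth.rest_fraction_pct, abs=2.0)


class TestBuildProfile:
    def _cal(self, fmvc=1.0):
        return ep.CalibrationResult(fmvc_value=fmvc, per_trial_values=(fmvc,), baseline_rms=0.0, trial_count=3)

    def test_recording_at_fmvc_level(self):
        profile = ep.build_profile(_rec(np.full(2000, 2.0)), self._cal(fmvc=2.0))
        assert profile.mean_rms == pytest.approx(100.0)
        assert profile.apdf_p10 == profile.apdf_p50 == profile.apdf_p90 == pytest.approx(100.0)
        assert profile.percent_rest == pytest.approx(0.0)

    def test_all_zero_work_recording(self):
        profile = ep.build_profile(_rec(np.zeros(2000)), self._cal())
        assert profile.mean_rms == pytest.approx(0.0)
        assert profile.apdf_p90 == pytest.approx(0.0)
        assert profile.percent_rest == pytest.approx(100.0)

    def test_simulated_schedule_full_profile(self, sim_config):
        # two active levels so the median falls inside a level, not on a
        # cluster edge where window-RMS sampling spread would dominate
        rng = np.random.default_rng(11)
        cycle = (
            ep.Segment("light", 3.5, 15.0),
            ep.Segment("rest", 1.5, 0.0),
            ep.Segment("firm", 3.5, 25.0),
            ep.Segment("rest", 1.5, 0.0),
        )
        sched = ep.TaskSchedule(cycle * 60)  # 600 s, 30 % scheduled rest
        rec, truth = ep.simulate_recording(sim_config, sched, rng)
        cal = ep.calibrate(ep.simulate_calibration(sim_config, rng, subject_id="s", muscle="m"))
        profile = ep.build_profile(rec, cal)
        assert profile.mean_rms == pytest.approx(truth.mean_envelope_pct, rel=0.05)
        assert profile.apdf_p50 == pytest.approx(truth.apdf_pct[0.50], rel=0.05)
        assert profile.percent_rest == pytest.approx(truth.rest_fraction_pct, abs=2.0)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ep.MuscleActivityProfile(
                mean_rms=1.0, apdf_p10=5.0, apdf_p50=1.0, apdf_p90=9.0,
                percent_rest=0.0, recording_duration=1.0,
            )


class TestClassifyExposure:
    def _profile(self, p10=0.0, p50=0.0, p90=0.0):
        return ep.MuscleActivityProfile(
            mean_rms=max(p50, 0.0), apdf_p10=p10, apdf_p50=p50, apdf_p90=p90,
            percent_rest=0.0, recording_duration=3600.0,
        )

    def test_published_median_load_exceeds_both_limits(self):
        # reported large-herd biceps brachii p50 of 14.58 %fMVC
        flags = ep.classify_exposure(self._profile(p50=14.58, p90=14.58))
        assert flags.median == "exceeds_must_not"

    def test_published_peak_load_exceeds_only_should_not(self):
        # reported large-herd biceps brachii p90 of 51.22 %fMVC
        flags = ep.classify_exposure(self._profile(p90=51.22))
        assert flags.peak == "exceeds_should_not"

    def test_zero_static_load_within_limits(self):
        assert ep.classify_exposure(self._profile()).static == "within"

    @pytest.mark.parametrize("p10,expected", [(2.0, "within"), (2.01, "exceeds_should_not"),
                                              (5.0, "exceeds_should_not"), (5.01, "exceeds_must_not")])
    def test_limits_are_strict(self, p10, expected):
        flags = ep.classify_exposure(self._profile(p10=p10, p50=p10, p90=p10))
        assert flags.static == expected
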