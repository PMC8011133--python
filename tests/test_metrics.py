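"""Walking-stability metrics: analytic cases, brute-force oracles, and the
full 41-feature contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstab.events import NoGaitError, detect_steps
from gaitstab.metrics import (
    FEATURE_NAMES,
    DegenerateHarmonicsError,
    autocorr_regularity,
    compute_all,
    estimate_stride_frequency,
    gait_symmetry,
    gait_variability,
    harmonic_amplitudes,
    harmonic_ratio,
    rms,
    unbiased_autocorr,
)
from gaitstab.preprocess import preprocess_trial
from gaitstab.synthetic import simulate_trial
from gaitstab.trial import CleanTrial

from conftest import make_config

FS = 148.0


def brute_force_autocorr(x, max_lag):
    """O(n^2) unbiased autocorrelation oracle: r(tau) =
    sum_t x_t x_{t+tau} / ((n - tau) * var), var = sum x^2 / n."""
    x = np.asarray(x, dtype=float)
    n = x.size
    var = np.sum(x * x) / n
    out = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        s = sum(x[t] * x[t + tau] for t in range(n - tau))
        out[tau] = s / ((n - tau) * var)
    return out


class TestRMS:
    def test_zeros(self):
        assert rms(np.zeros(100)) == 0.0

    def test_sinusoid_amp_over_sqrt2(self):
        t = np.arange(0, 10, 1 / FS)
        x = 0.2 * np.sin(2 * np.pi * 2.0 * t)
        assert rms(x) == pytest.approx(0.2 / np.sqrt(2), abs=1e-4)

    def test_hand_computed(self):
        assert rms([0.1, -0.2, 0.3, 0.0]) == pytest.approx(np.sqrt(0.14 / 4), abs=1e-12)

    def test_zero_mean_rms_equals_population_sd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        x -= x.mean()
        assert rms(x) == pytest.approx(np.std(x), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms([])


class TestUnbiasedAutocorr:
    def test_matches_brute_force_on_printed_series(self):
        x = [1, -1, 1, -1, 1, -1, 1, -1]
        r = unbiased_autocorr(x, 4)
        np.testing.assert_allclose(r, brute_force_autocorr(x, 4), atol=1e-12)
        assert r[2] == pytest.approx(1.0) and r[4] == pytest.approx(1.0)

    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=8,
            max_size=64,
        ).filter(lambda v: np.std(v) > 1e-6)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force_exactly(self, values):
        max_lag = len(values) // 2
        r = unbiased_autocorr(values, max_lag)
        np.testing.assert_allclose(r, brute_force_autocorr(values, max_lag), atol=1e-9)

    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(2)
        r = unbiased_autocorr(rng.normal(size=100), 10)
        assert r[0] == pytest.approx(1.0)


class TestStrideFrequency:
    def test_from_events_exact(self):
        from gaitstab.events import GaitEvents

        idx = np.arange(20) * int(FS * 0.5)  # steps every 0.5 s, strides 1.0 s
        ev = GaitEvents(idx, FS)
        assert estimate_stride_frequency(None, events=ev) == pytest.approx(1.0)

    def test_autocorr_estimate_matches_configured(self):
        cfg = make_config(stride_time_mean=1.1, seed=3)
        trial = preprocess_trial(simulate_trial(cfg))
        f = estimate_stride_frequency(trial.axis("vt"), FS)
        assert f == pytest.approx(1.0 / 1.1, rel=0.02)

    def test_white_noise_no_periodicity(self):
        rng = np.random.default_rng(3)
        with pytest.raises(NoGaitError):
            estimate_stride_frequency(rng.normal(size=int(30 * FS)), FS)


class TestHarmonicRatio:
    def test_amplitudes_match_least_squares_fit(self, clean_trial):
        """Oracle: least-squares fit of sin/cos pairs at the harmonic
        frequencies agrees with the DFT-at-harmonics evaluator within 1 %."""
        x = clean_trial.axis("vt")
        f_stride = 1.0
        n_h = 6
        amps = harmonic_amplitudes(x, FS, f_stride, n_h)
        stride_samples = FS / f_stride
        n = int(np.floor(x.size / stride_samples) * stride_samples)
        t = np.arange(n) / FS
        design = np.column_stack(
            [fn(2 * np.pi * k * f_stride * t) for k in range(1, n_h + 1) for fn in (np.cos, np.sin)]
        )
        coef, *_ = np.linalg.lstsq(design, x[:n], rcond=None)
        ls_amps = np.hypot(coef[0::2], coef[1::2])
        mask = ls_amps > 1e-6
        np.testing.assert_allclose(amps[mask], ls_amps[mask], rtol=0.01)

    def test_constructed_even_over_odd(self):
        t = np.arange(0, 20, 1 / FS)
        f = 1.0
        # even-harmonic amplitude sum 2.0 (1.5 + 0.5), odd sum 1.0 (0.6 + 0.4)
        x = (
            1.5 * np.cos(2 * np.pi * 2 * f * t)
            + 0.5 * np.cos(2 * np.pi * 4 * f * t)
            + 0.6 * np.cos(2 * np.pi * 1 * f * t)
            + 0.4 * np.cos(2 * np.pi * 3 * f * t)
        )
        assert harmonic_ratio(x, FS, f, axis="vt") == pytest.approx(2.0, rel=1e-3)

    def test_ml_pure_stride_sinusoid_degenerate(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.cos(2 * np.pi * 1.0 * t)  # stride-frequency fundamental only
        with pytest.raises(DegenerateHarmonicsError):
            harmonic_ratio(x, FS, 1.0, axis="ml")

    def test_ml_convention_inverts(self, clean_trial):
        x = clean_trial.axis("ml")
        inv = harmonic_ratio(x, FS, 1.0, axis="ml", ml_inverted=True)
        literal = harmonic_ratio(x, FS, 1.0, axis="ml", ml_inverted=False)
        assert inv == pytest.approx(1.0 / literal, rel=1e-9)
        assert inv > 1.0  # odd harmonics dominate ML

    def test_asymmetric_gait_has_lower_vt_hr(self):
        sym = preprocess_trial(simulate_trial(make_config(seed=6)))
        asym = preprocess_trial(simulate_trial(make_config(seed=6, asymmetry=0.3)))
        assert harmonic_ratio(asym.axis("vt"), FS, 1.0, axis="vt") < harmonic_ratio(
            sym.axis("vt"), FS, 1.0, axis="vt"
        )


class TestRegularityAndSymmetry:
    def test_periodic_symmetric_signal_near_one(self, symmetric_clean_trial):
        sr1, sr2 = autocorr_regularity(symmetric_clean_trial.axis("vt"), FS, 1.0)
        assert sr1 >= 0.99 and sr2 >= 0.99
        assert gait_symmetry(sr1, sr2) >= 0.99

    def test_alternate_step_scaling_lowers_sr1_not_sr2(self):
        # steps alternate x1.5 / x0.5: stride-periodic but step-asymmetric
        t = np.arange(0, 30, 1 / FS)
        phase = 2 * np.pi * 1.0 * t
        base = np.cos(2 * phase)
        scale = np.where(np.mod(phase, 2 * np.pi) < np.pi, 1.5, 0.5)
        x = base * scale
        sr1, sr2 = autocorr_regularity(x, FS, 1.0)
        assert sr2 >= 0.99
        assert sr1 < sr2

    @pytest.mark.parametrize(
        "sr1, sr2, expected",
        [(0.8, 0.8, 1.0), (0.6, 0.9, 0.6 / 0.9), (0.9, 0.6, 0.6 / 0.9), (-0.6, 0.9, 0.6 / 0.9)],
    )
    def test_symmetry_values(self, sr1, sr2, expected):
        assert gait_symmetry(sr1, sr2) == pytest.approx(expected)

    def test_symmetry_degenerate(self):
        with pytest.raises(ValueError):
            gait_symmetry(0.0, 0.0)

    def test_window_beyond_signal_rejected(self):
        with pytest.raises(ValueError):
            autocorr_regularity(np.ones(100), FS, 0.5)


class TestGaitVariability:
    def test_jitter_free_width_at_resolution_limit(self, clean_trial):
        gv = gait_variability(clean_trial.axis("vt"), FS, 1.0)
        resolution = FS / (4 * FS / 1.0)  # Welch window = 4 stride periods
        assert gv.width_hz <= 2 * resolution

    def test_jitter_broadens_peak(self):
        widths = {j: [] for j in (0.01, 0.05)}
        for seed in range(8):
            for j in widths:
                cfg = make_config(stride_time_jitter_sd=j, seed=seed)
                trial = preprocess_trial(simulate_trial(cfg))
                widths[j].append(gait_variability(trial.axis("vt"), FS, 1.0).width_hz)
        assert np.mean(widths[0.05]) > np.mean(widths[0.01])

    def test_white_noise_no_dominant_peak(self):
        rng = np.random.default_rng(5)
        with pytest.raises(NoGaitError):
            gait_variability(rng.normal(size=int(30 * FS)), FS, 1.0)

    def test_normalized_width(self, clean_trial):
        gv = gait_variability(clean_trial.axis("vt"), FS, 1.0)
        assert gv.normalized == pytest.approx(gv.width_hz / gv.peak_frequency_hz)


class TestComputeAll:
    def test_contract_41_values(self, realistic_trial_pair):
        head, trunk = realistic_trial_pair
        ev = detect_steps(trunk)
        fs = compute_all(head, trunk, ev)
        assert set(fs.values) == set(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 41
        arr = fs.as_array()
        assert np.all(np.isfinite(arr))
        for site in ("trunk", "head"):
            for axis in ("vt", "ml", "ap"):
                assert -1 <= fs.values[f"{site}_{axis}_sr1"] <= 1
                assert -1 <= fs.values[f"{site}_{axis}_sr2"] <= 1
                assert 0 <= fs.values[f"{site}_{axis}_symmetry"] <= 1

    def test_constant_head_flagged_trunk_computed(self, realistic_trial_pair):
        head, trunk = realistic_trial_pair
        dead = CleanTrial(
            subject_id=head.subject_id, sensor_site="head",
            sampling_rate=head.sampling_rate, acc=np.zeros_like(head.acc),
            timed_duration=head.timed_duration,
            gravity_removed=True, filtered=True,
        )
        ev = detect_steps(trunk)
        fs = compute_all(dead, trunk, ev)
        assert np.isnan(fs.values["head_vt_sr1"]) and "head_vt_sr1" in fs.flags
        assert np.isfinite(fs.values["trunk_vt_sr1"])
        assert fs.values["head_vt_rms"] == 0.0  # rms of zeros is defined

    def test_deterministic(self, realistic_trial_pair):
        head, trunk = realistic_trial_pair
        ev = detect_steps(trunk)
        a = compute_all(head, trunk, ev).as_array()
        b = compute_all(head, trunk, ev).as_array()
        np.testing.assert_array_equal(a, b)
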