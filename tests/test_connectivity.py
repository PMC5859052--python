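import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restcompare import (
    BANDS,
    EEGRecording,
    instantaneous_phase,
    phase_difference,
    pli_from_phase_difference,
    pli_matrix,
)
from tests.conftest import sinusoid_recording


class TestInstantaneousPhase:
    def test_phase_advances_at_signal_frequency(self):
        rec = sinusoid_recording([10.0], duration=10.0)
        ph = instantaneous_phase(rec).phase[0]
        n = len(ph)
        sl = slice(n // 10, -n // 10)  # central 80%
        slope = np.polyfit(rec.times[sl], np.unwrap(ph[sl]), 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_quadrature_pair_has_constant_half_pi_difference(self):
        # sin(x) = cos(x - pi/2): sin lags cos by pi/2
        t = np.arange(10_000) / 1000.0
        rec = EEGRecording(
            np.vstack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)]),
            1000.0, ["sin", "cos"], reference="infinity",
        )
        ph = instantaneous_phase(rec).phase
        d = phase_difference(ph[0], ph[1])
        central = d[1000:-1000]
        assert np.allclose(central, -np.pi / 2, atol=0.01)

    def test_amplitude_invariance(self):
        rec = sinusoid_recording([10.0], duration=4.0)
        scaled = rec.copy_with(data=7.0 * rec.data)
        a = instantaneous_phase(rec).phase
        b = instantaneous_phase(scaled).phase
        # compare as wrapped differences: rounding can flip samples sitting
        # exactly on the +/-pi branch cut
        assert np.abs(phase_difference(a[0], b[0])).max() < 1e-9

    def test_all_zero_channel_errors(self):
        rec = EEGRecording(np.zeros((2, 1000)), 250.0, ["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            instantaneous_phase(rec)


class TestPhaseDifference:
    def test_identical_channels_give_zero(self):
        x = np.linspace(-3, 3, 500)
        assert np.all(phase_difference(x, x) == 0)

    def test_wrap_rule(self):
        d = phase_difference(np.array([3.0]), np.array([-3.0]))
        assert d[0] == pytest.approx(6 - 2 * np.pi, abs=1e-12)
        assert -np.pi < d[0] <= np.pi

    def test_result_always_in_half_open_interval(self, rng):
        a = rng.uniform(-np.pi, np.pi, 10_000)
        b = rng.uniform(-np.pi, np.pi, 10_000)
        d = phase_difference(a, b)
        assert np.all(d > -np.pi)
        assert np.all(d <= np.pi)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            phase_difference(np.zeros(5), np.zeros(6))


class TestPLI:
    def test_constant_nonzero_lag_gives_one(self):
        rec = sinusoid_recording([10.0, 10.0], duration=10.0, phases=[0.0, -np.pi / 2])
        mat = pli_matrix(rec, BANDS["alpha"])
        assert mat.values[0, 1] == 1.0

    def test_duplicated_channel_gives_zero(self):
        t = np.arange(10_000) / 1000.0
        x = np.cos(2 * np.pi * 10 * t)
        rec = EEGRecording(np.vstack([x, x]), 1000.0, ["a", "b"], reference="infinity")
        mat = pli_matrix(rec, band=None)  # identical data: differences exactly 0
        assert mat.values[0, 1] == 0.0

    def test_alternating_lag_signs_cancel(self):
        d = np.tile([0.3, -0.3], 500)
        assert pli_from_phase_difference(d) == 0.0

    def test_matches_brute_force_loop(self, rng):
        # 5 channels, 1000 samples of band-limited noise
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [8, 12], btype="bandpass", fs=250.0, output="sos")
        data = sosfiltfilt(sos, rng.standard_normal((5, 1000)), axis=-1)
        rec = EEGRecording(data, 250.0, [f"c{i}" for i in range(5)], reference="infinity")
        mat = pli_matrix(rec, band=None, edge_trim_fraction=0.05)

        ph = instantaneous_phase(rec).phase
        trim = int(round(0.05 * 1000))
        kept = ph[:, trim:-trim]
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                total = 0.0
                for n in range(kept.shape[1]):
                    d = kept[i, n] - kept[j, n]
                    while d <= -np.pi:
                        d += 2 * np.pi
                    while d > np.pi:
                        d -= 2 * np.pi
                    total += np.sign(d)
                expected = abs(total / kept.shape[1])
                assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_scaling_and_common_offset(self, rng):
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [8, 12], btype="bandpass", fs=250.0, output="sos")
        data = sosfiltfilt(sos, rng.standard_normal((4, 2000)), axis=-1)
        rec = EEGRecording(data, 250.0, list("abcd"), reference="infinity")
        mod = rec.copy_with(data=data * np.array([[2.0], [5.0], [0.5], [11.0]]) + 40.0)
        a = pli_matrix(rec, BANDS["alpha"])
        b = pli_matrix(mod, BANDS["alpha"])
        assert np.allclose(a.values, b.values, atol=0.02)

    def test_null_mean_matches_folded_normal_law(self, rng):
        # iid uniform phase differences of length N: E|mean sign| = sqrt(2/(pi N))
        N, reps = 4000, 200
        vals = [
            pli_from_phase_difference(rng.uniform(-np.pi, np.pi, N))
            for _ in range(reps)
        ]
        expected = np.sqrt(2 / (np.pi * N))
        assert np.mean(vals) == pytest.approx(expected, rel=0.20)

    def test_epoch_averaged_mode_close_to_whole_segment_on_locked_pair(self):
        rec = sinusoid_recording([10.0, 10.0], duration=10.0, phases=[0.0, -1.0])
        whole = pli_matrix(rec, BANDS["alpha"])
        epochs = pli_matrix(rec, BANDS["alpha"], epoch_s=2.0)
        assert epochs.values[0, 1] == pytest.approx(whole.values[0, 1], abs=0.01)

    def test_too_few_retained_samples_error(self):
        rec = sinusoid_recording([10.0, 10.0], duration=0.1)
        with pytest.raises(ValueError, match="retained"):
            pli_matrix(rec, band=None)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_and_symmetry_on_arbitrary_input(self, seed):
        rng = np.random.default_rng(seed)
        n_ch = rng.integers(2, 6)
        data = rng.standard_normal((n_ch, 400)) * 10 ** rng.uniform(-2, 2)
        rec = EEGRecording(data, 100.0, [f"c{i}" for i in range(n_ch)], reference="infinity")
        mat = pli_matrix(rec, band=None, edge_trim_fraction=0.05)
        v = mat.values
        assert np.all(v >= 0) and np.all(v <= 1)
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0)
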