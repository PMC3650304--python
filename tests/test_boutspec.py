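"""Spectral-analysis tests: detection, filtering, DFT oracle, DI, metrics."""

import numpy as np
import pytest

from preycap import boutspec, synthgen
from preycap.boutspec import SpectrumConfig
from preycap.synthgen import GeneratorParams


def dft_rms_oracle(x):
    """Direct O(N^2) evaluation of the printed spectrum equations:
    X_k = sum_n x_n e^{-i 2 pi n k / N}; A_k = X_k / N; B_0 = A_0,
    B_k = 2 A_k for k = 1..N/2-1; B_mag = |B_k|."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ks = np.arange(n // 2)
    bmag = np.empty(len(ks))
    for k in ks:
        xk = sum(x[m] * np.exp(-2j * np.pi * m * k / n) for m in range(n))
        ak = xk / n
        bk = ak if k == 0 else 2.0 * ak
        bmag[k] = abs(bk)
    return bmag


def _bout_window(gamma, truth, cfg):
    idx = boutspec._window_indices(truth.t_ms, truth.onset_ms,
                                   truth.offset_ms, cfg)
    return gamma[idx]


class TestSpectrumConfig:
    def test_n_samples_rounding(self):
        assert SpectrumConfig(window_ms=150.0, fs=500.0).n_samples == 75
        # 150 ms at 250 frames/s is 37.5 samples; rounds to 38
        assert SpectrumConfig(window_ms=150.0, fs=250.0).n_samples == 38

    def test_mode_windows(self):
        assert SpectrumConfig.for_mode("free").window_ms == 150.0
        assert SpectrumConfig.for_mode("restrained").window_ms == 300.0

    def test_band_validation(self):
        with pytest.raises(ValueError):
            SpectrumConfig(fs=150.0)        # 100 Hz cutoff at Nyquist


class TestDetectBouts:
    def test_zero_trace_gives_empty_list(self):
        assert boutspec.detect_bouts(np.zeros(1000), 500.0, 1.0) == []

    def test_single_burst_onset_within_4_ms(self):
        p = GeneratorParams(delta_theta_true=15.0, seed=2, pre_ms=100.0,
                            post_ms=100.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        events = boutspec.detect_bouts(np.abs(gamma).mean(axis=1), 500.0,
                                       threshold=1.0)
        assert len(events) == 1
        assert events[0][0] == pytest.approx(truth.onset_ms, abs=4.0)

    def test_two_bursts_with_quiet_gap(self):
        fs = 500.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.where((t >= 0.1) & (t < 0.2), 10.0, 0.0) * np.sin(2 * np.pi * 30 * t)
        x += np.where((t >= 0.5) & (t < 0.6), 10.0, 0.0) * np.sin(2 * np.pi * 30 * t)
        events = boutspec.detect_bouts(x, fs, threshold=1.0)
        assert len(events) == 2
        gap = events[1][0] - events[0][1]
        assert gap == pytest.approx(300.0, abs=4.0)

    def test_short_events_discarded(self):
        x = np.zeros(500)
        x[100:105] = 10.0
        assert boutspec.detect_bouts(x, 500.0, 1.0, min_duration_ms=40.0) == []


class TestBandpass:
    def test_dc_suppressed(self):
        cfg = SpectrumConfig()
        y = boutspec.bandpass(np.full(400, 7.0), cfg)
        assert np.abs(y[50:-50]).max() < 0.01 * 7.0

    def test_passband_gain_at_30_hz(self):
        cfg = SpectrumConfig()
        t = np.arange(3000) / cfg.fs
        y = boutspec.bandpass(np.sin(2 * np.pi * 30 * t), cfg)
        assert np.abs(y[500:-500]).max() >= 0.9

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        cfg = SpectrumConfig()
        np.testing.assert_allclose(boutspec.bandpass(3.5 * x, cfg),
                                   3.5 * boutspec.bandpass(x, cfg),
                                   atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            boutspec.bandpass(np.zeros(100), SpectrumConfig(fs=150.0))


class TestRmsSpectrum:
    def test_unit_cosine_at_exact_bin(self):
        n, k0 = 64, 5
        x = np.cos(2 * np.pi * k0 * np.arange(n) / n)
        freqs, bmag = boutspec.rms_spectrum(x, fs=500.0)
        assert bmag[k0] == pytest.approx(1.0, abs=1e-12)
        others = np.delete(bmag, k0)
        assert others.max() < 1e-9

    def test_constant_trace_dc_bin_undoubled(self):
        x = np.full(40, 2.5)
        _, bmag = boutspec.rms_spectrum(x, fs=500.0)
        assert bmag[0] == pytest.approx(2.5, abs=1e-12)
        assert bmag[1:].max() < 1e-9

    @pytest.mark.parametrize("n", [38, 75, 150])
    def test_matches_direct_summation_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.normal(size=n)
            _, bmag = boutspec.rms_spectrum(x, fs=500.0)
            np.testing.assert_allclose(bmag, dft_rms_oracle(x), atol=1e-9)

    def test_parseval_consistency(self):
        """Two-sided spectrum energy: sum |A_k|^2 = (1/N) sum |x_n|^2 / N."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=75)
        a = np.fft.fft(x) / len(x)
        assert np.sum(np.abs(a) ** 2) == pytest.approx(
            np.sum(x ** 2) / len(x) ** 2 * len(x), abs=1e-9)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="N >= 8"):
            boutspec.rms_spectrum(np.zeros(4), 500.0)


class TestSummedSpectrum:
    def test_five_identical_traces_sum_to_five_times_single(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=75)
        cfg = SpectrumConfig()
        spec = boutspec.summed_spectrum(np.tile(x[:, None], (1, 5)), cfg,
                                        apply_bandpass=False)
        _, single = boutspec.rms_spectrum(x, cfg.fs)
        np.testing.assert_allclose(spec.summed, 5.0 * single, atol=1e-9)

    def test_hf_peak_near_generator_frequency(self):
        cfg = SpectrumConfig()
        p = GeneratorParams(delta_theta_true=15.0, f_osc=28.0, seed=2,
                            pre_ms=30.0, post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        spec = boutspec.summed_spectrum(_bout_window(gamma, truth, cfg), cfg)
        assert spec.hf_peak[0] == pytest.approx(28.0, abs=1.5)

    def test_lf_amplitude_linear_in_turn_amplitude(self):
        """Doubling the turn amplitude doubles the LF peak within 2%
        (checked on the isolated turn component)."""
        cfg = SpectrumConfig()

        def lf(amp):
            p = GeneratorParams(delta_theta_true=amp, osc_amp=0.0, seed=3,
                                pre_ms=30.0, post_ms=30.0)
            gamma, truth = synthgen.gen_bout_kinematics(p)
            return boutspec.summed_spectrum(
                _bout_window(gamma, truth, cfg), cfg).lf_peak[1]

        assert lf(40.0) / lf(20.0) == pytest.approx(2.0, rel=0.02)

    def test_all_zero_traces_flag_undefined_peaks(self):
        cfg = SpectrumConfig()
        spec = boutspec.summed_spectrum(np.zeros((75, 5)), cfg)
        assert spec.lf_peak is None and spec.hf_peak is None

    def test_peaks_inside_search_bands(self):
        cfg = SpectrumConfig()
        rng = np.random.default_rng(4)
        for _ in range(10):
            spec = boutspec.summed_spectrum(rng.normal(size=(75, 5)), cfg)
            assert cfg.lf_band[0] <= spec.lf_peak[0] <= cfg.lf_band[1]
            assert cfg.hf_band[0] <= spec.hf_peak[0] <= cfg.hf_band[1]


class TestDirectionIndex:
    def test_formula_application(self):
        """A rightward turn (positive mean integral) yields DI equal to the
        3-5 Hz average of the summed spectrum, with positive sign."""
        cfg = SpectrumConfig()
        p = GeneratorParams(delta_theta_true=30.0, seed=5, pre_ms=30.0,
                            post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        win = _bout_window(gamma, truth, cfg)
        spec = boutspec.summed_spectrum(win, cfg)
        di = boutspec.direction_index(win, spec, cfg)
        from scipy.interpolate import CubicSpline

        expected = np.mean(np.clip(
            CubicSpline(spec.freq_hz, spec.summed)([3.0, 4.0, 5.0]), 0, None))
        assert di == pytest.approx(expected)
        assert di > 0

    def test_pure_oscillation_gives_zero(self):
        cfg = SpectrumConfig()
        p = GeneratorParams(delta_theta_true=0.0, seed=1, pre_ms=30.0,
                            post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        win = _bout_window(gamma, truth, cfg)
        spec = boutspec.summed_spectrum(win, cfg)
        di = boutspec.direction_index(win, spec, cfg)
        assert abs(di) < 0.01 * p.osc_amp

    def test_odd_under_trace_negation(self):
        cfg = SpectrumConfig()
        p = GeneratorParams(delta_theta_true=25.0, seed=9, pre_ms=30.0,
                            post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        win = _bout_window(gamma, truth, cfg)
        di_pos = boutspec.direction_index(
            win, boutspec.summed_spectrum(win, cfg), cfg)
        di_neg = boutspec.direction_index(
            -win, boutspec.summed_spectrum(-win, cfg), cfg)
        assert di_neg == pytest.approx(-di_pos, abs=1e-9)


class TestBoutMetrics:
    def test_synthetic_turn_bout_metrics(self):
        cfg = SpectrumConfig()
        p = GeneratorParams(delta_theta_true=30.0, f_osc=30.0, n_cycles=3,
                            seed=2, pre_ms=30.0, post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        bout = boutspec.bout_metrics(truth.t_ms, truth.theta_deg, gamma,
                                     (truth.onset_ms, truth.offset_ms), cfg)
        assert bout.dtheta_deg == pytest.approx(30.0, abs=1e-9)
        assert bout.n_cycles == 3

    def test_stationary_no_turn(self):
        cfg = SpectrumConfig()
        p = GeneratorParams(delta_theta_true=0.0, seed=0, pre_ms=30.0,
                            post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        bout = boutspec.bout_metrics(truth.t_ms, truth.theta_deg, gamma,
                                     (truth.onset_ms, truth.offset_ms), cfg)
        assert bout.dtheta_deg == pytest.approx(0.0, abs=1.0)

    def test_bout_at_series_edge_raises(self):
        cfg = SpectrumConfig()
        p = GeneratorParams(seed=0, pre_ms=0.0, post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        with pytest.raises(ValueError, match="edge"):
            boutspec.bout_metrics(truth.t_ms, truth.theta_deg, gamma,
                                  (truth.onset_ms, truth.offset_ms), cfg)

    def test_phi_and_distance_deltas(self):
        cfg = SpectrumConfig()
        p = GeneratorParams(delta_theta_true=20.0, seed=3, pre_ms=30.0,
                            post_ms=30.0)
        gamma, truth = synthgen.gen_bout_kinematics(p)
        phi = 40.0 - truth.theta_deg            # prey fixed at bearing 40
        d = np.linspace(3.0, 2.5, truth.n_frames)
        bout = boutspec.bout_metrics(truth.t_ms, truth.theta_deg, gamma,
                                     (truth.onset_ms, truth.offset_ms), cfg,
                                     phi_deg=phi, d_mm=d)
        i_pre = np.flatnonzero(truth.t_ms < truth.onset_ms)[-1]
        i_post = np.flatnonzero(truth.t_ms > truth.offset_ms)[0]
        assert bout.phi_pre_deg == pytest.approx(40.0, abs=1e-9)
        assert bout.phi_post_deg == pytest.approx(20.0, abs=1e-9)
        assert bout.dd_mm == pytest.approx(d[i_pre] - d[i_post], abs=1e-9)


def test_analyze_series_and_table():
    import pandas as pd

    truth = synthgen.gen_capture_sequence(3, [300.0, 200.0], seed=8,
                                          prey_mm=(7.0, 6.0))
    cfg = SpectrumConfig()
    bouts = boutspec.analyze_series(truth.t_ms, truth.theta_deg,
                                    truth.gamma_deg, cfg, threshold=1.0)
    assert len(bouts) == 3
    df = boutspec.bouts_to_dataframe(bouts)
    assert isinstance(df, pd.DataFrame)
    assert {"onset_ms", "dtheta_deg", "DI", "lf_hz", "hf_hz",
            "n_cycles"} <= set(df.columns)
    # turns recovered against the generator schedule
    trues = [p.delta_theta_true for p in truth.params]
    np.testing.assert_allclose(df["dtheta_deg"], trues, atol=1.0)
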