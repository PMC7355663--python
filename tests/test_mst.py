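"""MST trace processing and Kd fitting tests, driven by the synthetic generator."""

import numpy as np
import pytest

from melbind import synth
from melbind.mst import (
    MstMode,
    MstTrace,
    compute_fnorm,
    detect_mode,
    fit_kd,
    read_traces_csv,
    select_hot_region,
)


def flat_trace(value=1000.0, conc=1.0):
    t = np.arange(0.0, 30.01, 0.25)
    return MstTrace(t, np.full_like(t, value), conc, laser_on_time=5.0)


class TestFnorm:
    def test_flat_trace_gives_unity(self):
        assert compute_fnorm(flat_trace(), (0.0, 4.0), (20.0, 25.0)) == pytest.approx(1.0)

    def test_ratio_of_window_means(self):
        t = np.arange(0.0, 30.01, 0.25)
        f = np.where(t < 5.0, 1000.0, 950.0)
        tr = MstTrace(t, f, 1.0, laser_on_time=5.0)
        assert compute_fnorm(tr, (0.0, 4.9), (10.0, 20.0)) == pytest.approx(0.95)

    def test_matches_generator_programmed_depletion(self):
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.0, seed=0, n_replicates=1)
        series, truth = synth.generate_mst_series(cfg)
        tr = max(series.traces, key=lambda t: t.ligand_conc)
        fb = truth["fraction_bound"][tr.ligand_conc]
        # late window: exponential fully developed
        fn = compute_fnorm(tr, (0.0, 5.0), (28.0, 30.0))
        expected = 1.0 - cfg.depletion_amplitude * fb * (1 - np.exp(-24.0 / cfg.tau_s))
        assert fn == pytest.approx(expected, rel=1e-3)

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            compute_fnorm(flat_trace(), (0.0, 10.0), (20.0, 25.0))  # cold crosses laser


class TestHotRegionSelection:
    def test_identical_traces_flagged_zero_snr(self):
        series_traces = [flat_trace(conc=c) for c in (1.0, 10.0, 100.0)]
        from melbind.mst import MstSeries

        series = MstSeries(tuple(series_traces), target_conc=12.5)
        result = select_hot_region(series)
        assert result.snr == 0.0 and not result.passed

    def test_programmed_separation_passes_threshold(self):
        # 3% trace noise against a 30% full-occupancy amplitude: well over 5 sigma
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.03, seed=1)
        series, _ = synth.generate_mst_series(cfg)
        result = select_hot_region(series)
        assert result.passed and result.snr >= 5.0
        assert result.region[0] >= cfg.laser_on_s

    def test_selected_snr_scales_with_programmed_noise(self):
        # halving the injected noise should roughly double the achieved SNR,
        # and the SNR magnitude should sit near programmed amplitude / noise
        snrs = {}
        for cv in (0.01, 0.02):
            cfg = synth.SynthConfig(true_kd=30.0, noise_cv=cv, seed=2)
            series, truth = synth.generate_mst_series(cfg)
            snrs[cv] = select_hot_region(series).snr
        assert snrs[0.01] / snrs[0.02] == pytest.approx(2.0, rel=0.4)
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.01, seed=2)
        _, truth = synth.generate_mst_series(cfg)
        fb = np.array(list(truth["fraction_bound"].values()))
        amplitude = 0.3 * (fb.max() - fb.min())
        assert 0.2 * amplitude / 0.01 < snrs[0.01] < 5 * amplitude / 0.01


class TestModeDetection:
    def test_constant_cold_counts_mean_mst_mode(self):
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.0, seed=3)
        series, _ = synth.generate_mst_series(cfg)
        assert detect_mode(series) is MstMode.MST

    def test_programmed_cold_trend_switches_mode(self):
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.01, cold_trend_amplitude=0.3, seed=4)
        series, _ = synth.generate_mst_series(cfg)
        assert detect_mode(series) is MstMode.INITIAL_FLUORESCENCE

    def test_random_jitter_without_trend_stays_mst(self):
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.05, seed=5)
        series, _ = synth.generate_mst_series(cfg)
        assert detect_mode(series) is MstMode.MST


class TestKdFit:
    def test_noise_free_round_trip_is_exact(self):
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.0, seed=6)
        series, _ = synth.generate_mst_series(cfg)
        res = fit_kd(series)
        assert res.converged and not res.flags
        assert res.kd == pytest.approx(30.0, rel=1e-3)

    def test_initial_fluorescence_round_trip(self):
        cfg = synth.SynthConfig(true_kd=80.0, noise_cv=0.0, cold_trend_amplitude=0.25, seed=7)
        series, _ = synth.generate_mst_series(cfg)
        res = fit_kd(series)
        assert res.mode is MstMode.INITIAL_FLUORESCENCE
        assert res.kd == pytest.approx(80.0, rel=1e-3)

    def test_kd_invariant_to_fluorescence_rescaling(self):
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.02, seed=8)
        series, _ = synth.generate_mst_series(cfg)
        res = fit_kd(series)
        scaled = type(series)(
            tuple(
                MstTrace(tr.times, tr.fluorescence * 7.3, tr.ligand_conc,
                         tr.laser_on_time, tr.capillary_id)
                for tr in series.traces
            ),
            target_conc=series.target_conc,
        )
        res_scaled = fit_kd(scaled)
        assert res_scaled.kd == pytest.approx(res.kd, rel=1e-6)

    def test_flat_response_flagged_no_binding(self):
        cfg = synth.SynthConfig(true_kd=30.0, noise_cv=0.02, depletion_amplitude=0.0, seed=9)
        series, _ = synth.generate_mst_series(cfg)
        res = fit_kd(series)
        assert "no_binding" in res.flags

    def test_kd_far_above_series_reports_honest_wide_ci(self):
        # true Kd 2x the top tested concentration: the Cramer-Rao bound for
        # this design approaches 100% relative SE, so the CI must be wide
        cfg = synth.SynthConfig(true_kd=1000.0, noise_cv=0.03, seed=10)
        series, _ = synth.generate_mst_series(cfg)
        res = fit_kd(series)
        assert res.kd_ci68_halfwidth > 0.3 * res.kd

    @pytest.mark.parametrize("true_kd", [1.0, 10.0, 100.0])
    def test_recovery_within_design_range(self, true_kd):
        errors = []
        for seed in range(25):
            cfg = synth.SynthConfig(true_kd=true_kd, noise_cv=0.03, seed=300 + seed)
            series, _ = synth.generate_mst_series(cfg)
            res = fit_kd(series)
            errors.append(abs(res.kd / true_kd - 1.0))
        assert np.median(errors) < 0.20


class TestCsvRoundTrip:
    def test_written_series_refits_identically(self, tmp_path):
        cfg = synth.SynthConfig(true_kd=50.0, noise_cv=0.02, seed=11)
        series, truth = synth.generate_mst_series(cfg)
        path = tmp_path / "traces.csv"
        synth.write_mst_csv(series, path, truth=truth)
        loaded = read_traces_csv(path, target_conc=12.5, laser_on_time=5.0)
        assert loaded.reference_trace is not None
        assert fit_kd(loaded).kd == pytest.approx(fit_kd(series).kd, rel=1e-6)
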