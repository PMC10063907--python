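"""Signal-chain contracts: OD, motion correction, QC, filtering, MBLL, GSR."""

import numpy as np
import pytest
from scipy import signal

from nirsconn import (
    BlockDesign,
    EffectSpec,
    PhysiologySpec,
    QCParams,
    assess_quality,
    bandpass,
    block_average,
    compute_hbt,
    correct_motion_spline,
    global_signal_regression,
    hb_to_intensity,
    inject_motion,
    intensity_to_od,
    od_to_hb,
    preprocess_scan,
    simulate_hb,
    triage,
)
from nirsconn.mbll import ExtinctionTable, hb_to_od
from nirsconn.scan import HB, OD, Scan

FS = 13.33


def od_scan(probe, data, fs=FS, events=None):
    return Scan(kind=OD, data=data, sampling_rate=fs, probe=probe,
                events=events if events is not None else np.empty((0, 2)))


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self, probe):
        raw = Scan(kind="intensity", data=np.full((100, 20, 3), 3.7),
                   sampling_rate=FS, probe=probe)
        assert np.allclose(intensity_to_od(raw).data, 0.0)

    def test_closed_form_attenuation(self, probe):
        # I = I0 * 10^(-x) with zero-mean x maps to OD = x exactly
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.01, (2000, 20, 3))
        x -= x.mean(axis=0, keepdims=True)
        raw = Scan(kind="intensity", data=2.0 * 10.0 ** (-x),
                   sampling_rate=FS, probe=probe)
        od = intensity_to_od(raw).data
        # mean(I) != I0 only at second order in x, a constant offset per
        # series; the time course itself is recovered exactly
        assert np.abs((od - od.mean(0)) - (x - x.mean(0))).max() < 1e-12
        assert np.abs(od - x).max() < 1e-3

    def test_sinusoidal_modulation_preserved(self, probe):
        t = np.arange(1000) / FS
        x = 0.02 * np.sin(2 * np.pi * 0.3 * t)
        raw = Scan(kind="intensity",
                   data=np.tile((10.0 ** (-x))[:, None, None], (1, 20, 3)),
                   sampling_rate=FS, probe=probe)
        od = intensity_to_od(raw).data[:, 0, 0]
        f, pxx = signal.periodogram(od, fs=FS)
        assert f[np.argmax(pxx[1:]) + 1] == pytest.approx(0.3, abs=0.02)

    def test_non_positive_intensity_names_location(self, probe):
        data = np.ones((50, 20, 3))
        data[7, 3, 1] = 0.0
        raw = Scan(kind="intensity", data=data, sampling_rate=FS, probe=probe)
        with pytest.raises(ValueError, match="sample 7.*channel 3"):
            intensity_to_od(raw)


class TestMotionCorrection:
    def test_artifact_free_scan_passes_through(self, probe):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 0.005, (2000, 20, 3))
        scan = od_scan(probe, data)
        out, intervals = correct_motion_spline(scan)
        assert intervals == []
        assert np.abs(out.data - data).max() < 1e-12

    def test_step_artifact_mostly_removed(self, probe):
        rng = np.random.default_rng(2)
        n = 2000
        data = rng.normal(0, 0.005, (n, 20, 3))
        data[n // 2:] += 1.0  # 1-OD baseline shift on all series
        out, intervals = correct_motion_spline(od_scan(probe, data))
        assert intervals, "step should be detected"
        resid_step = (out.data[-200:].mean(axis=0)
                      - out.data[:200].mean(axis=0))
        assert np.abs(resid_step).max() < 0.1  # <10% of the injected 1 OD

    def test_flagged_interval_overlaps_injected_artifact(self, hb_scan):
        raw = hb_to_intensity(hb_scan, seed=3)
        dirty, log = inject_motion(raw, rate=1.0, magnitude=1.0, seed=4)
        assert log, "expected at least one injected artifact"
        _, intervals = correct_motion_spline(intensity_to_od(dirty))
        times = [ev["time"] for ev in log]
        assert any(t0 - 1.5 <= t <= t1 + 1.5
                   for t in times for t0, t1 in intervals)


class TestQualityControl:
    def test_perfect_cardiac_coupling_scores_one(self, probe):
        t = np.arange(round(60 * FS)) / FS
        card = 0.01 * np.sin(2 * np.pi * 1.2 * t)
        data = np.tile(card[:, None, None], (1, 20, 3))
        rep = assess_quality(od_scan(probe, data))
        assert np.allclose(rep.sci, 1.0)
        assert np.all(rep.cqs == 1.0)
        assert rep.verdict == "keep"

    def test_uncoupled_white_noise_fails_cqs(self, probe):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = rng.normal(0, 0.01, (round(60 * FS), 20, 3))
            rep = assess_quality(od_scan(probe, data))
            assert np.all(rep.cqs < 0.75)

    def test_default_thresholds(self):
        qc = QCParams()
        assert qc.sci_threshold == 0.8
        assert qc.psp_threshold == 0.1
        assert qc.cqs_threshold == 0.75
        assert qc.min_good_channels == 5

    @pytest.mark.parametrize("n_good,verdict", [(4, "drop"), (5, "keep"),
                                                (20, "keep")])
    def test_triage_boundary(self, probe, n_good, verdict, hb_scan):
        bad = range(20 - n_good)
        raw = hb_to_intensity(hb_scan, seed=5, bad_channels=bad)
        rep = assess_quality(intensity_to_od(raw))
        assert rep.n_acceptable == n_good
        assert triage(rep) == verdict

    def test_window_longer_than_scan_rejected(self, probe):
        data = np.zeros((10, 20, 3))
        with pytest.raises(ValueError):
            assess_quality(od_scan(probe, data), QCParams(window_length=5.0))


class TestBandpass:
    @pytest.mark.parametrize("freq,lo,hi", [(0.1, 0.95, 1.05), (1.0, 0.0, 0.1)])
    def test_amplitude_response(self, probe, freq, lo, hi):
        t = np.arange(round(600 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        scan = od_scan(probe, np.tile(x[:, None, None], (1, 20, 3)))
        out = bandpass(scan).data[:, 0, 0]
        core = slice(len(t) // 4, 3 * len(t) // 4)  # avoid filter edges
        ratio = out[core].std() / x[core].std()
        assert lo <= ratio <= hi

    def test_dc_removed(self, probe):
        scan = od_scan(probe, np.full((4000, 20, 3), 5.0)
                       + np.random.default_rng(0).normal(0, 0.01, (4000, 20, 3)))
        out = bandpass(scan)
        assert abs(out.data.mean()) < 1e-3

    def test_invalid_edges_rejected(self, probe):
        scan = od_scan(probe, np.zeros((100, 20, 3)))
        with pytest.raises(ValueError):
            bandpass(scan, 0.2, 0.01)
        with pytest.raises(ValueError):
            bandpass(scan, 0.01, 8.0)


class TestMbllInversion:
    def test_zero_od_gives_zero_hb(self, probe):
        hb = od_to_hb(od_scan(probe, np.zeros((50, 20, 3))))
        assert np.allclose(hb.hb("HbO2"), 0)
        assert np.allclose(hb.hb("HbR"), 0)

    def test_recovers_known_concentrations(self, probe):
        rng = np.random.default_rng(3)
        hbo2 = rng.normal(0, 0.5, (500, 20))
        hbr = rng.normal(0, 0.2, (500, 20))
        table = ExtinctionTable()
        od = hb_to_od(hbo2, hbr, probe.wavelengths, table)
        hb = od_to_hb(od_scan(probe, od), table)
        assert np.abs(hb.hb("HbO2") - hbo2).max() < 1e-9
        assert np.abs(hb.hb("HbR") - hbr).max() < 1e-9

    def test_least_squares_residual_orthogonal_to_columns(self, probe):
        rng = np.random.default_rng(4)
        table = ExtinctionTable()
        E = table.design_matrix(probe.wavelengths)
        od = hb_to_od(rng.normal(0, 0.5, (200, 20)), rng.normal(0, 0.2, (200, 20)),
                      probe.wavelengths, table) + rng.normal(0, 0.01, (200, 20, 3))
        hb = od_to_hb(od_scan(probe, od), table)
        fitted = np.stack([hb.hb("HbO2"), hb.hb("HbR")], axis=-1) @ E.T
        resid = od - fitted
        assert np.abs(resid @ E).max() < 1e-12

    def test_singular_extinction_matrix_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionTable(coefficients={780.0: (1.0, 2.0), 830.0: (2.0, 4.0)}) \
                .design_matrix((780.0, 830.0))


class TestGlobalSignalRegression:
    def _hb(self, probe, data):
        return Scan(kind=HB, data={"HbO2": data, "HbR": -0.4 * data},
                    sampling_rate=FS, probe=probe)

    def test_identical_channels_give_zero_residuals(self, probe):
        x = np.tile(np.random.default_rng(5).normal(0, 1, (500, 1)), (1, 20))
        out = global_signal_regression(self._hb(probe, x))
        assert np.abs(out.hb("HbO2")).max() < 1e-10

    def test_shared_sinusoid_power_removed(self, probe):
        rng = np.random.default_rng(6)
        t = np.arange(2000) / FS
        shared = np.sin(2 * np.pi * 0.12 * t)
        x = rng.normal(0, 0.2, (2000, 20)) + shared[:, None]
        out = global_signal_regression(self._hb(probe, x)).hb("HbO2")
        proj = (out * shared[:, None]).sum(0) / (shared @ shared)
        assert np.abs(proj).max() < 0.1  # >= 99% shared power removed

    def test_residuals_orthogonal_to_global_mean(self, probe):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (800, 20)) + rng.normal(0, 1, (800, 1))
        scan = self._hb(probe, x)
        out = global_signal_regression(scan).hb("HbO2")
        g = x.mean(axis=1)
        gc = g - g.mean()
        corr = gc @ (out - out.mean(0)) / len(g)
        assert np.abs(corr).max() < 1e-10


class TestHbtAndBlockAverage:
    def test_hbt_is_exact_sum(self, probe, hb_scan):
        out = compute_hbt(hb_scan)
        assert np.array_equal(out.hb("HbT"),
                              hb_scan.hb("HbO2") + hb_scan.hb("HbR"))

    def test_hbt_cancellation(self, probe):
        x = np.random.default_rng(8).normal(0, 1, (100, 20))
        scan = Scan(kind=HB, data={"HbO2": x, "HbR": -x}, sampling_rate=FS,
                    probe=probe)
        assert np.allclose(compute_hbt(scan).hb("HbT"), 0.0)

    def test_identical_blocks_average_to_single_response(self, probe, design):
        scan = simulate_hb(design, EffectSpec(latent_sd=1e-12,
                                              hbr_noise_sd=1e-12), probe, seed=0)
        avg, t, skipped = block_average(scan, window=(5.0, 25.0))
        assert skipped == 0
        # baseline-corrected average is ~0 before stimulus onset
        assert np.abs(avg["HbO2"][t < 0]).max() < 0.02
        peak = avg["HbO2"][(t > 8) & (t < 18)]
        m1 = probe.region_indices("M1_S1")
        assert peak[:, m1].mean() > 0.2

    def test_averaging_reduces_noise_variance(self, probe, design):
        eff = EffectSpec(response_amplitude_pfc=0.0, response_amplitude_m1s1=0.0)
        ratios = []
        for seed in range(5):
            scan = simulate_hb(design, eff, probe, seed=seed)
            avg, t, _ = block_average(scan, window=(0.0, 20.0))
            single = scan.hb("HbO2")[:round(20 * FS)]
            ratios.append(avg["HbO2"].var() / single.var())
        # averaging 6 epochs of correlated-channel noise: variance falls well
        # below a single epoch's (exact 1/6 only for white noise)
        assert np.mean(ratios) < 0.5

    def test_out_of_bounds_event_skipped_with_warning(self, probe):
        x = np.random.default_rng(9).normal(0, 1, (300, 20))
        scan = Scan(kind=HB, data={"HbO2": x, "HbR": -x}, sampling_rate=FS,
                    probe=probe, events=[[1.0, 5.0], [400.0, 5.0]])
        with pytest.warns(UserWarning, match="skipped 1"):
            _, _, skipped = block_average(scan, window=(1.0, 5.0))
        assert skipped == 1


class TestRunner:
    def test_pipeline_order_logged(self, hb_scan):
        raw = hb_to_intensity(hb_scan, seed=11)
        hb, report, log = preprocess_scan(raw)
        assert log["stages"] == [
            "intensity_to_od", "correct_motion_spline", "assess_quality",
            "bandpass", "od_to_hb", "global_signal_regression", "compute_hbt"]
        assert hb is not None and "HbT" in hb.data

    def test_dropped_scan_returns_none(self, hb_scan):
        raw = hb_to_intensity(hb_scan, seed=12, bad_channels=range(16))
        hb, report, log = preprocess_scan(raw)
        assert hb is None
        assert log["verdict"] == "drop"
        assert log["n_acceptable"] < 5

    def test_end_to_end_recovery_of_clean_signal(self, probe, design):
        """With physiology and noise off, preprocessing recovers the generated
        hemoglobin up to the band-pass and the global-mean projection."""
        scan = simulate_hb(design, EffectSpec(), probe, seed=13)
        phys = PhysiologySpec(cardiac_amp=0, respiration_amp=0, mayer_amp=0,
                              noise_sd=0)
        raw = hb_to_intensity(scan, phys, seed=0)
        hb, _, log = preprocess_scan(raw, motion_correction=False)
        assert log["verdict"] == "keep"
        # apply the same band-pass + GSR projection to the ground truth
        ref = Scan(kind=HB, data={"HbO2": scan.hb("HbO2"),
                                  "HbR": scan.hb("HbR")},
                   sampling_rate=design.sampling_rate, probe=probe)
        ref = global_signal_regression(bandpass(ref))
        for hb_type in ("HbO2", "HbR"):
            a, b = hb.hb(hb_type), ref.hb(hb_type)
            core = slice(200, -200)
            for c in range(probe.n_channels):
                r = np.corrcoef(a[core, c], b[core, c])[0, 1]
                assert r > 0.99
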