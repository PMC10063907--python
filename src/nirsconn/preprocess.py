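"""Signal chain from raw intensity to analysis-ready hemoglobin.

Stages, in the order the runner enforces: optical density -> spline motion
correction -> SCI/PSP/CQS quality control and scan triage -> band-pass
(0.01-0.2 Hz) -> MBLL hemoglobin conversion -> global signal regression ->
total hemoglobin. Quality control runs before the band-pass because the
scalp-coupling metrics live in the cardiac band the band-pass removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import maximum_filter1d, uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from . import mbll
from .scan import HB, INTENSITY, OD, Scan


# ---------------------------------------------------------------- optical density

def intensity_to_od(scan: Scan) -> Scan:
    """OD(t) = -log10(I(t) / mean(I)) per channel and wavelength."""
    if scan.kind != INTENSITY:
        raise ValueError("expected a raw intensity scan")
    I = scan.data
    if np.any(I <= 0):
        t, ch, wl = np.unravel_index(np.argmin(I), I.shape)
        raise ValueError(
            f"non-positive intensity at sample {t}, channel {ch}, wavelength index {wl}"
        )
    od = -np.log10(I / I.mean(axis=0, keepdims=True))
    return scan.with_data(od, kind=OD)


# ---------------------------------------------------------------- motion correction

def _moving_std(x: np.ndarray, width: int) -> np.ndarray:
    m = uniform_filter1d(x, width, axis=0, mode="nearest")
    m2 = uniform_filter1d(x * x, width, axis=0, mode="nearest")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def _segments(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Split [0, n) into maximal runs of constant mask value: (start, stop, flagged)."""
    n = len(mask)
    out = []
    start = 0
    for i in range(1, n + 1):
        if i == n or mask[i] != mask[start]:
            out.append((start, i, bool(mask[start])))
            start = i
    return out


def correct_motion_spline(scan: Scan, detection_window: float = 1.0,
                          threshold_factor: float = 5.0,
                          smoothing_p: float = 0.99):
    """Spline-based motion artifact correction (moving-std detection).

    Samples whose moving-window standard deviation exceeds
    ``threshold_factor`` x the scan median are flagged; each flagged segment
    is replaced by (segment - smoothing-spline fit), and segments are rejoined
    with constant offsets so junction levels match. Clean-segment content is
    shape-preserved (only a DC offset may be applied after a baseline-shift
    artifact; the downstream band-pass removes DC). Artifact-free input passes
    through unchanged.

    Returns (corrected scan, list of flagged (t_start, t_stop) intervals in s).
    """
    if scan.kind != OD:
        raise ValueError("motion correction operates on optical density")
    fs = scan.sampling_rate
    width = max(3, round(detection_window * fs))
    if scan.n_samples <= width:
        raise ValueError("scan shorter than the detection window")
    lam = (1.0 - smoothing_p) / smoothing_p

    data = scan.data.copy()
    n, nch, nwl = data.shape
    flat = data.reshape(n, nch * nwl)
    mstd = _moving_std(flat, width)
    thresh = threshold_factor * np.median(mstd, axis=0, keepdims=True)
    flagged_any = mstd > np.maximum(thresh, 1e-300)
    # a movement hits all channels: flag a sample if >=25% of series exceed
    mask = flagged_any.mean(axis=1) >= 0.25
    mask = maximum_filter1d(mask, width)  # dilate to cover artifact flanks

    intervals: list[tuple[float, float]] = []
    if not mask.any():
        return scan.with_data(data, motion_intervals=intervals), intervals

    k = max(1, round(fs / 3))
    x_idx = np.arange(n, dtype=float)
    out = np.empty_like(flat)
    prev_stop = 0
    for start, stop, is_art in _segments(mask):
        seg = flat[start:stop].copy()
        if is_art:
            intervals.append((start / fs, stop / fs))
            if stop - start >= 8:
                xs = x_idx[start:stop]
                for j in range(seg.shape[1]):
                    spl = make_smoothing_spline(xs, seg[:, j], lam=lam)
                    seg[:, j] = seg[:, j] - spl(xs)
            else:
                seg = seg - seg.mean(axis=0, keepdims=True)
        if start > 0:
            kk = min(k, stop - start, prev_stop)
            offset = (out[start - kk:start].mean(axis=0)
                      - seg[:kk].mean(axis=0))
            seg = seg + offset
        out[start:stop] = seg
        prev_stop = stop - start

    corrected = out.reshape(n, nch, nwl)
    return scan.with_data(corrected, motion_intervals=intervals), intervals


# ---------------------------------------------------------------- quality control

@dataclass(frozen=True)
class QCParams:
    """Thresholds of the scalp-coupling quality triage."""

    sci_threshold: float = 0.8
    psp_threshold: float = 0.1
    cqs_threshold: float = 0.75
    window_length: float = 5.0            # s
    window_overlap: float = 0.0           # fraction of window
    cardiac_band: tuple[float, float] = (0.5, 2.5)  # Hz
    min_good_channels: int = 5
    sci_wavelength_pair: tuple[int, int] | None = None  # default: spectral extremes

    def __post_init__(self) -> None:
        for name in ("sci_threshold", "cqs_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window_overlap must lie in [0, 1)")
        lo, hi = self.cardiac_band
        if not 0 < lo < hi:
            raise ValueError("cardiac_band must be an increasing positive interval")


@dataclass
class QualityReport:
    """Windowed SCI/PSP traces, per-channel CQS, and the scan verdict."""

    sci: np.ndarray          # (n_windows, n_channels)
    psp: np.ndarray          # (n_windows, n_channels)
    cqs: np.ndarray          # (n_channels,)
    acceptable: np.ndarray   # (n_channels,) bool
    verdict: str             # "keep" | "drop"
    params: QCParams

    @property
    def n_acceptable(self) -> int:
        return int(self.acceptable.sum())


def assess_quality(scan: Scan, params: QCParams | None = None) -> QualityReport:
    """Windowed scalp-coupling quality control.

    Per window and channel, the two wavelength signals (default: the
    spectrally extreme pair) are filtered to the cardiac band; SCI is their
    zero-lag Pearson correlation and PSP the normalized peak of the power
    spectrum of their cross-correlation within the cardiac band. CQS is the
    fraction of windows passing both thresholds; a channel is acceptable when
    CQS >= cqs_threshold and the scan is kept when at least
    ``min_good_channels`` channels are acceptable.
    """
    params = params or QCParams()
    if scan.kind == INTENSITY:
        scan = intensity_to_od(scan)
    if scan.kind != OD:
        raise ValueError("quality control expects raw intensity or optical density")
    fs = scan.sampling_rate
    lo, hi = params.cardiac_band
    if hi >= fs / 2:
        raise ValueError("cardiac band exceeds the Nyquist frequency")
    wlen = round(params.window_length * fs)
    n, nch, _ = scan.data.shape
    if wlen > n:
        raise ValueError("window longer than scan")

    pair = params.sci_wavelength_pair
    if pair is None:
        wls = scan.probe.wavelengths
        pair = (int(np.argmin(wls)), int(np.argmax(wls)))
    sos = butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    a = sosfiltfilt(sos, scan.data[:, :, pair[0]], axis=0)
    b = sosfiltfilt(sos, scan.data[:, :, pair[1]], axis=0)

    step = max(1, round(wlen * (1.0 - params.window_overlap)))
    starts = range(0, n - wlen + 1, step)
    band_lo, band_hi = lo, hi
    sci = np.zeros((len(starts), nch))
    psp = np.zeros((len(starts), nch))
    freqs = np.fft.rfftfreq(2 * wlen - 1, d=1.0 / fs)
    in_band = (freqs >= band_lo) & (freqs <= band_hi)
    for w, s0 in enumerate(starts):
        wa = a[s0:s0 + wlen] - a[s0:s0 + wlen].mean(axis=0)
        wb = b[s0:s0 + wlen] - b[s0:s0 + wlen].mean(axis=0)
        na = np.sqrt((wa * wa).sum(axis=0))
        nb = np.sqrt((wb * wb).sum(axis=0))
        ok = (na > 0) & (nb > 0)
        for c in np.flatnonzero(ok):
            xc = np.correlate(wa[:, c], wb[:, c], mode="full") / (na[c] * nb[c])
            sci[w, c] = xc[wlen - 1]
            spec = np.abs(np.fft.rfft(xc)) / (wlen / 2.0)
            psp[w, c] = spec[in_band].max()

    passed = (sci >= params.sci_threshold) & (psp >= params.psp_threshold)
    cqs = passed.mean(axis=0)
    acceptable = cqs >= params.cqs_threshold
    verdict = "keep" if acceptable.sum() >= params.min_good_channels else "drop"
    return QualityReport(sci=sci, psp=psp, cqs=cqs, acceptable=acceptable,
                         verdict=verdict, params=params)


def triage(report: QualityReport, params: QCParams | None = None) -> str:
    """Scan-level verdict: drop iff fewer than ``min_good_channels`` are acceptable.

    Channels are never pruned individually; a noisy channel is tolerated and
    handled downstream by the robust correlation.
    """
    params = params or report.params
    return "keep" if report.n_acceptable >= params.min_good_channels else "drop"


# ---------------------------------------------------------------- filtering

def bandpass(scan: Scan, low: float = 0.01, high: float = 0.2,
             order: int = 4) -> Scan:
    """Zero-phase Butterworth band-pass applied per channel."""
    fs = scan.sampling_rate
    if not 0 < low < high < fs / 2:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if scan.kind == HB:
        data = {k: sosfiltfilt(sos, v, axis=0) for k, v in scan.data.items()}
    else:
        data = sosfiltfilt(sos, scan.data, axis=0)
    return scan.with_data(data, bandpass=(low, high))


# ---------------------------------------------------------------- hemoglobin

def od_to_hb(scan: Scan, table: mbll.ExtinctionTable | None = None) -> Scan:
    """MBLL inversion: optical density to (HbO2, HbR) in µM, least squares
    over all available wavelengths."""
    if scan.kind != OD:
        raise ValueError("expected an optical-density scan")
    table = table or mbll.ExtinctionTable()
    hbo2, hbr = mbll.od_to_hb(scan.data, scan.probe.wavelengths, table)
    return scan.with_data({"HbO2": hbo2, "HbR": hbr}, kind=HB)


def global_signal_regression(scan: Scan, channels=None) -> Scan:
    """Regress the across-channel mean series out of every channel.

    ``channels`` restricts which channels form the global-mean estimate
    (typically the QC-acceptable set); the regression is applied to all
    channels. Residuals are exactly uncorrelated with the global mean.
    """
    if scan.kind != HB:
        raise ValueError("global signal regression operates on hemoglobin")
    if scan.n_channels < 2:
        raise ValueError("at least two channels required")
    out = {}
    for hb_type, x in scan.data.items():
        g = x.mean(axis=1) if channels is None else x[:, list(channels)].mean(axis=1)
        gc = g - g.mean()
        denom = gc @ gc
        if denom == 0:
            out[hb_type] = x - x.mean(axis=0, keepdims=True)
            continue
        beta = (gc @ (x - x.mean(axis=0, keepdims=True))) / denom
        out[hb_type] = x - x.mean(axis=0, keepdims=True) - gc[:, None] * beta[None, :]
    return scan.with_data(out, gsr=True)


def compute_hbt(scan: Scan) -> Scan:
    """Total hemoglobin: HbT(t) = HbO2(t) + HbR(t)."""
    if scan.kind != HB or "HbO2" not in scan.data or "HbR" not in scan.data:
        raise ValueError("both HbO2 and HbR series are required")
    hbo2, hbr = scan.data["HbO2"], scan.data["HbR"]
    if hbo2.shape != hbr.shape:
        raise ValueError("HbO2/HbR length mismatch")
    return scan.with_data({**scan.data, "HbT": hbo2 + hbr})


# ---------------------------------------------------------------- block averaging

def block_average(scan: Scan, window: tuple[float, float] = (5.0, 30.0),
                  events: np.ndarray | None = None):
    """Epoch around stimulation onsets, baseline-correct, and average.

    ``window = (pre, post)`` in seconds around each onset; each epoch is
    baseline-corrected by its pre-stimulus mean. Events whose epoch falls
    outside the recording are skipped with a warning.

    Returns (averages, epoch_times, n_skipped) where ``averages`` maps
    hemoglobin type to an (epoch_samples, n_channels) array.
    """
    if scan.kind != HB:
        raise ValueError("block averaging operates on hemoglobin")
    events = scan.events if events is None else np.asarray(events, float).reshape(-1, 2)
    fs = scan.sampling_rate
    pre, post = window
    n_pre, n_post = round(pre * fs), round(post * fs)
    n = scan.n_samples
    out = {}
    skipped = 0
    used_onsets = []
    for onset, _ in events:
        i = round(onset * fs)
        if i - n_pre < 0 or i + n_post > n:
            skipped += 1
            continue
        used_onsets.append(i)
    if skipped:
        warnings.warn(f"block_average: skipped {skipped} event(s) outside bounds")
    if not used_onsets:
        raise ValueError("no usable events for block averaging")
    for hb_type, x in scan.data.items():
        epochs = np.stack([x[i - n_pre:i + n_post] for i in used_onsets])
        baseline = epochs[:, :n_pre].mean(axis=1, keepdims=True) if n_pre else 0.0
        out[hb_type] = (epochs - baseline).mean(axis=0)
    epoch_times = (np.arange(-n_pre, n_post)) / fs
    return out, epoch_times, skipped


# ---------------------------------------------------------------- runner

def preprocess_scan(scan: Scan, qc: QCParams | None = None,
                    band: tuple[float, float] = (0.01, 0.2),
                    table: mbll.ExtinctionTable | None = None,
                    motion_correction: bool = True):
    """Run the full chain on one raw scan; returns (hb_scan | None, report, log).

    Order: OD -> motion correction -> QC/triage -> band-pass -> MBLL ->
    global signal regression -> HbT. A dropped scan returns None with the
    quality report; kept scans are never altered by triage.
    """
    qc = qc or QCParams()
    log: dict = {"stages": []}
    od = intensity_to_od(scan) if scan.kind == INTENSITY else scan
    log["stages"].append("intensity_to_od")
    if motion_correction:
        od, intervals = correct_motion_spline(od)
        log["stages"].append("correct_motion_spline")
        log["motion_intervals"] = intervals
    report = assess_quality(od, qc)
    log["stages"].append("assess_quality")
    log["n_acceptable"] = report.n_acceptable
    verdict = triage(report, qc)
    log["verdict"] = verdict
    if verdict == "drop":
        return None, report, log
    od = bandpass(od, *band)
    log["stages"].append("bandpass")
    hb = od_to_hb(od, table)
    log["stages"].append("od_to_hb")
    hb = global_signal_regression(hb, channels=np.flatnonzero(report.acceptable))
    log["stages"].append("global_signal_regression")
    hb = compute_hbt(hb)
    log["stages"].append("compute_hbt")
    return hb, report, log
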