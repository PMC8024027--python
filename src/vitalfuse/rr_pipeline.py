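"""Respiratory rate from PPG: beats -> modulation series -> spectral RR.

Breathing modulates the photoplethysmogram in three ways: the pulse
amplitude (AM), the baseline level (BW) and the instantaneous heart rate
(FM).  This module detects pulse peaks, extracts the three beat-indexed
modulation series, resamples them to a uniform grid, slices them into 32-s
windows with 29 s of overlap, and estimates one RR per window per series
with two spectral methods (periodogram peak and autoregressive spectrum),
giving six RR "annotators" per window.  The resulting W x 6 matrix maps
directly onto an :class:`~vitalfuse.iam_model.AnnotationSet` for fusion.

Estimates are kept only when a clear in-band spectral peak exists (peak to
in-band median power ratio >= 2) and the peak lies in the plausibility band
4-60 breaths/min; anything else becomes a missing label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.regression.linear_model import burg

from .errors import InputError
from .iam_model import AnnotationSet
from .synthetic_data import PPGRecord

__all__ = [
    "PPGRecord",
    "Beats",
    "ModulationSeries",
    "RRWindowEstimates",
    "detect_beats",
    "extract_modulations",
    "window_signal",
    "estimate_rr_fourier",
    "estimate_rr_ar",
    "extract_rr_estimates",
    "build_annotation_set",
]

RR_BAND_HZ = (4.0 / 60.0, 60.0 / 60.0)   # plausibility band, 4-60 breaths/min
QUALITY_RATIO = 2.0                      # min peak-to-median in-band power
SMOOTH_BW_HZ = 0.45                      # spectral smoothing for the quality gate
WINDOW_S = 32.0
OVERLAP_S = 29.0
MIN_BEATS = 8
REFRACTORY_S = 60.0 / 220.0              # no two beats closer than a 220-bpm interval


@dataclass
class Beats:
    """Detected pulse peaks with per-beat amplitude and preceding trough."""

    times_s: np.ndarray
    peak_values: np.ndarray
    trough_values: np.ndarray

    @property
    def n_beats(self) -> int:
        return self.times_s.size


@dataclass
class ModulationSeries:
    """One respiratory modulation series on a uniform time grid."""

    kind: str                  # "AM", "BW" or "FM"
    times_s: np.ndarray
    values: np.ndarray
    resampled_hz: float


@dataclass
class RRWindowEstimates:
    """Per-window RR estimates: W x 6, columns (AM,BW,FM) x (Fourier,AR)."""

    window_start_s: np.ndarray
    estimates: np.ndarray
    mask: np.ndarray           # True where the estimate passed quality gates
    columns: tuple = (
        "AM_fourier", "AM_ar", "BW_fourier", "BW_ar", "FM_fourier", "FM_ar"
    )


def detect_beats(record: PPGRecord) -> Beats:
    """Locate pulse peaks with an adaptive threshold and refractory period.

    Peaks must exceed an amplitude threshold placed between the signal
    median and maximum, be separated by at least a 220-bpm interval, and
    have non-trivial prominence relative to the signal spread.  The trough
    preceding each peak is the minimum since the previous peak.
    """
    if record.fs_hz < 25:
        raise InputError(f"fs_hz must be >= 25, got {record.fs_hz}")
    x = record.samples
    spread = float(np.max(x) - np.min(x)) if x.size else 0.0
    if spread <= 0:
        raise InputError("record rejected: flat signal, no beats detectable")
    height = float(np.median(x)) + 0.25 * (float(np.max(x)) - float(np.median(x)))
    distance = max(1, int(round(REFRACTORY_S * record.fs_hz)))
    peaks, _ = signal.find_peaks(
        x, height=height, distance=distance, prominence=0.1 * spread
    )
    if peaks.size < MIN_BEATS:
        raise InputError(
            f"record rejected: only {peaks.size} beats detected (need {MIN_BEATS})"
        )
    troughs = np.empty(peaks.size)
    prev = 0
    for k, p in enumerate(peaks):
        troughs[k] = x[prev:p].min() if p > prev else x[p]
        prev = p
    return Beats(
        times_s=peaks / record.fs_hz,
        peak_values=x[peaks],
        trough_values=troughs,
    )


def extract_modulations(
    beats: Beats, record: PPGRecord, resample_hz: float = 4.0
) -> dict[str, ModulationSeries]:
    """Beat-indexed AM/BW/FM series, resampled to a uniform grid.

    AM is the per-beat peak-minus-trough amplitude, BW the trough (baseline)
    level and FM the instantaneous rate 60/IBI in beats/min.  Each series is
    linearly interpolated to ``resample_hz`` over the beat span and
    mean-detrended, ready for respiratory-band spectral analysis.
    """
    if beats.n_beats < MIN_BEATS:
        raise InputError(f"need >= {MIN_BEATS} beats, have {beats.n_beats}")
    t = beats.times_s
    am = beats.peak_values - beats.trough_values
    bw = beats.trough_values
    ibi = np.diff(t)
    fm = 60.0 / ibi
    fm_t = 0.5 * (t[:-1] + t[1:])

    def _resample(src_t: np.ndarray, src_v: np.ndarray, kind: str) -> ModulationSeries:
        # grid spans the whole record; np.interp clamps beyond the beat span
        grid = np.arange(0.0, record.duration_s, 1.0 / resample_hz)
        vals = np.interp(grid, src_t, src_v)
        vals = vals - vals.mean()
        return ModulationSeries(kind=kind, times_s=grid, values=vals, resampled_hz=resample_hz)

    return {
        "AM": _resample(t, am, "AM"),
        "BW": _resample(t, bw, "BW"),
        "FM": _resample(fm_t, fm, "FM"),
    }


def window_signal(
    series: ModulationSeries, window_s: float = WINDOW_S, overlap_s: float = OVERLAP_S
) -> list[tuple[float, np.ndarray]]:
    """Slice a uniform series into overlapping windows.

    Stride is window_s - overlap_s (3 s by default); only windows fully
    contained in the record are returned, so a record of length T seconds
    yields floor((T - window_s)/stride) + 1 windows.
    """
    duration = series.values.size / series.resampled_hz
    if duration < window_s:
        raise InputError(
            f"series duration {duration:.1f}s shorter than window {window_s}s"
        )
    stride = window_s - overlap_s
    if stride <= 0:
        raise InputError("overlap_s must be smaller than window_s")
    n_win = int(np.floor((duration - window_s) / stride)) + 1
    w_len = int(round(window_s * series.resampled_hz))
    out = []
    for k in range(n_win):
        start_s = k * stride
        i0 = int(round(start_s * series.resampled_hz))
        out.append((series.times_s[0] + start_s, series.values[i0: i0 + w_len]))
    return out


def _detrend(window: np.ndarray) -> np.ndarray:
    return signal.detrend(window, type="linear")


def _band_peak(
    freqs: np.ndarray, power: np.ndarray, gate_power: np.ndarray | None = None
) -> float | None:
    """Peak frequency in the RR band, or None if the quality gate fails.

    The peak location comes from ``power``; the peak-to-median gate is
    evaluated on ``gate_power`` (a smoothed version for noisy periodograms)
    when given, since raw periodogram bins of pure noise always contain a
    few large outliers.
    """
    lo, hi = RR_BAND_HZ
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        return None
    p = power[in_band]
    g = (gate_power if gate_power is not None else power)[in_band]
    f = freqs[in_band]
    med = np.median(g)
    if med <= 0 or g.max() / med < QUALITY_RATIO:
        return None
    return float(f[int(np.argmax(p))])


def estimate_rr_fourier(window: np.ndarray, fs_hz: float) -> float | None:
    """RR (breaths/min) from the periodogram peak of one window.

    The window is linearly detrended and Hann-tapered; the periodogram is
    zero-padded for fine frequency resolution.  The quality gate compares
    the in-band peak of a moving-average-smoothed spectrum against its
    median: a concentrated respiratory peak survives smoothing, broadband
    noise does not.  Returns None (a missing label) when the gate fails.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 8 or np.ptp(window) == 0:
        return None
    x = _detrend(window) * np.hanning(window.size)
    nfft = max(4096, int(2 ** np.ceil(np.log2(window.size))))
    power = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    width = max(1, int(round(SMOOTH_BW_HZ / (freqs[1] - freqs[0]))))
    kernel = np.ones(width) / width
    smoothed = np.convolve(power, kernel, mode="same")
    f_peak = _band_peak(freqs, power, gate_power=smoothed)
    return None if f_peak is None else 60.0 * f_peak


def estimate_rr_ar(window: np.ndarray, fs_hz: float, order: int = 10) -> float | None:
    """RR (breaths/min) from the spectral peak of a Burg AR fit.

    Fits an autoregressive model of the given order by Burg's
    reflection-coefficient method, evaluates its spectral density on a fine
    in-band grid and returns the peak frequency; the same quality gate and
    plausibility band as the Fourier path apply.
    """
    window = np.asarray(window, dtype=float)
    if window.size <= 3 * order or np.ptp(window) == 0:
        return None
    x = _detrend(window)
    try:
        ar_coefs, _sigma2 = burg(x, order=order, demean=True)
    except (np.linalg.LinAlgError, ValueError):
        return None
    if not np.all(np.isfinite(ar_coefs)):
        return None
    freqs = np.linspace(0.0, fs_hz / 2.0, 2048)
    # PSD shape of an AR(p) model: 1 / |1 - sum_k a_k e^{-i 2 pi f k / fs}|^2;
    # the innovation variance only scales it and cancels in the quality
    # ratio (it can underflow to ~0 on noiseless input), so it is dropped
    zexp = np.exp(-2j * np.pi * np.outer(freqs / fs_hz, np.arange(1, order + 1)))
    denom = np.abs(1.0 - zexp @ ar_coefs) ** 2
    power = 1.0 / np.maximum(denom, 1e-300)
    width = max(1, int(round(SMOOTH_BW_HZ / (freqs[1] - freqs[0]))))
    smoothed = np.convolve(power, np.ones(width) / width, mode="same")
    f_peak = _band_peak(freqs, power, gate_power=smoothed)
    return None if f_peak is None else 60.0 * f_peak


def extract_rr_estimates(
    record: PPGRecord, resample_hz: float = 4.0, ar_order: int = 10
) -> RRWindowEstimates:
    """Full front end: beats -> modulations -> windows -> 6 RR estimates."""
    if record.duration_s < 2 * WINDOW_S:
        raise InputError(
            f"need >= {2 * WINDOW_S:.0f}s of signal, have {record.duration_s:.1f}s"
        )
    beats = detect_beats(record)
    series = extract_modulations(beats, record, resample_hz)
    per_kind_windows = {k: window_signal(s) for k, s in series.items()}
    n_win = min(len(v) for v in per_kind_windows.values())
    estimates = np.full((n_win, 6), np.nan)
    mask = np.zeros((n_win, 6), dtype=bool)
    starts = np.array([per_kind_windows["AM"][k][0] for k in range(n_win)])
    for col, kind in enumerate(("AM", "BW", "FM")):
        for k in range(n_win):
            _, w = per_kind_windows[kind][k]
            rr_f = estimate_rr_fourier(w, resample_hz)
            rr_a = estimate_rr_ar(w, resample_hz, order=ar_order)
            if rr_f is not None:
                estimates[k, 2 * col] = rr_f
                mask[k, 2 * col] = True
            if rr_a is not None:
                estimates[k, 2 * col + 1] = rr_a
                mask[k, 2 * col + 1] = True
    return RRWindowEstimates(window_start_s=starts, estimates=estimates, mask=mask)


def build_annotation_set(
    estimates: RRWindowEstimates, keep_empty_rows: bool = False
) -> AnnotationSet:
    """Windows become samples, the six estimators become annotators.

    All-missing windows are dropped (with their count retained in the
    sample ids that remain) unless ``keep_empty_rows`` is set, which is only
    sensible when per-window features will inform the latent RR.
    """
    if estimates.estimates.shape[0] < 1:
        raise InputError("no windows to convert")
    keep = np.ones(estimates.estimates.shape[0], dtype=bool)
    if not keep_empty_rows:
        keep = estimates.mask.any(axis=1)
    sample_ids = [f"t{estimates.window_start_s[i]:.0f}s" for i in np.flatnonzero(keep)]
    return AnnotationSet(
        labels=estimates.estimates[keep],
        mask=estimates.mask[keep],
        annotator_ids=list(estimates.columns),
        sample_ids=sample_ids,
    )
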