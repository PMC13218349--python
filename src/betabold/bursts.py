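"""Morlet time-frequency analysis and beta-burst detection.

A beta burst is a transient excursion of the band-averaged (13-30 Hz)
time-frequency amplitude above a data-driven threshold, after the
aperiodic (1/f) background level has been subtracted.  The wavelet
convention follows the Brainstorm definition: a mother wavelet with a
central frequency of 1 Hz and a temporal FWHM of 3 s is time-scaled to
each analysis frequency, so the FWHM at frequency ``f`` is ``3 / f``
seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.signal.windows import hann

__all__ = [
    "TFMatrix",
    "morlet_kernel",
    "morlet_tf",
    "beta_series",
    "background_amplitude",
    "subtract_baseline",
    "detect_bursts",
    "flexible_segment",
    "burst_stats",
    "split_rest",
]

BETA_FREQS = np.arange(13.0, 31.0)


@dataclass
class TFMatrix:
    """Time-frequency amplitude, frequencies x samples, non-negative."""

    freqs: np.ndarray
    amplitude: np.ndarray  # (n_freqs, n_samples)
    fs: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.amplitude = np.asarray(self.amplitude, float)
        if self.amplitude.shape[0] != self.freqs.size:
            raise ValueError("amplitude rows must match freqs")
        if np.any(self.amplitude < 0):
            raise ValueError("TF amplitude must be non-negative")


def morlet_kernel(f: float, fs: float, fc: float = 1.0, fwhm_s: float = 3.0,
                  n_sigma: float = 5.0) -> np.ndarray:
    """Complex Morlet kernel at analysis frequency ``f``.

    The kernel is normalized to unit sinusoid gain: convolving it with
    ``A*cos(2*pi*f*t)`` yields a complex series of magnitude ``A``.
    """
    if f <= 0 or fs <= 0:
        raise ValueError("f and fs must be positive")
    sigma_t = fwhm_s * fc / f / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(n_sigma * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    kernel = env * np.exp(2j * np.pi * f * t)
    return kernel * (2.0 / env.sum())


def morlet_tf(series: np.ndarray, fs: float, freqs: np.ndarray | None = None,
              fc: float = 1.0, fwhm_s: float = 3.0) -> TFMatrix:
    """Wavelet amplitude of ``series`` on the beta-band frequency grid."""
    series = np.asarray(series, float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    if freqs is None:
        freqs = BETA_FREQS
    freqs = np.asarray(freqs, float)
    if freqs.max() >= fs / 2.0:
        raise ValueError(
            f"max analysis frequency {freqs.max()} Hz exceeds Nyquist {fs / 2} Hz")
    amp = np.empty((freqs.size, series.size))
    for i, f in enumerate(freqs):
        k = morlet_kernel(f, fs, fc=fc, fwhm_s=fwhm_s)
        amp[i] = np.abs(fftconvolve(series, k, mode="same"))
    return TFMatrix(freqs=freqs, amplitude=amp, fs=fs)


def beta_series(tf: TFMatrix) -> np.ndarray:
    """Average the TF amplitude across frequencies into one series."""
    if tf.amplitude.size == 0:
        raise ValueError("empty TF matrix")
    return tf.amplitude.mean(axis=0)


def background_amplitude(psd_fn, f: float, fs: float,
                         fc: float = 1.0, fwhm_s: float = 3.0) -> float:
    """Expected wavelet amplitude of stationary noise with one-sided PSD.

    For Gaussian background noise the complex wavelet coefficient is
    circularly Gaussian with ``E|W|^2 = 0.5 * int S(nu) |H(nu)|^2 dnu``,
    so the amplitude is Rayleigh with mean ``sqrt(pi/4 * E|W|^2)``.
    ``psd_fn`` maps frequency (Hz) to one-sided PSD (units^2/Hz).
    """
    kernel = morlet_kernel(f, fs, fc=fc, fwhm_s=fwhm_s)
    n_fft = 4 * kernel.size
    H = np.fft.fft(kernel, n_fft)
    nu = np.fft.fftfreq(n_fft, 1.0 / fs)
    pos = nu > 0
    S = psd_fn(nu[pos])
    var = 0.5 * np.trapezoid(S * np.abs(H[pos]) ** 2, nu[pos])
    return float(np.sqrt(np.pi / 4.0 * var))


def _segment_bounds(segmentation: pd.DataFrame, fs: float, n: int):
    i0 = np.round(segmentation["onset_s"].to_numpy() * fs).astype(int)
    i1 = np.round(segmentation["offset_s"].to_numpy() * fs).astype(int)
    return np.clip(i0, 0, n), np.clip(i1, 0, n)


def subtract_baseline(series: np.ndarray, segmentation: pd.DataFrame,
                      baselines, fs: float) -> np.ndarray:
    """Subtract the per-phase aperiodic baseline and clip at zero.

    ``baselines`` is a scalar or a mapping ``phase -> baseline``; values
    must be non-negative and in the same amplitude units as ``series``.
    """
    series = np.asarray(series, float)
    out = series.copy()
    i0s, i1s = _segment_bounds(segmentation, fs, series.size)
    for (_, row), i0, i1 in zip(segmentation.iterrows(), i0s, i1s):
        b = baselines if np.isscalar(baselines) else baselines[row["phase"]]
        if b < 0:
            raise ValueError("baseline must be non-negative")
        out[i0:i1] = series[i0:i1] - b
    return np.maximum(out, 0.0)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs, half-open."""
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def detect_bursts(subtracted: np.ndarray, segmentation: pd.DataFrame,
                  fs: float, min_dur: float = 0.1, thresh_sd: float = 2.0,
                  pool: str = "trial"):
    """Threshold the subtracted amplitude series and extract burst events.

    The threshold is ``thresh_sd`` times the standard deviation of the
    subtracted amplitude over each single trial (``pool='trial'``, the
    default: a trial's burst content keeps the threshold well above the
    background level in its burst-free phases) or per phase-segment
    within each trial (``pool='segment'``).  The
    binarized raster is concatenated across segments before run-length
    extraction, so bursts may span segment boundaries; only runs strictly
    longer than ``min_dur`` seconds are retained.

    A zero-variance segment yields a zero threshold: a zero segment
    produces no burst samples, a constant positive one a full-segment run.
    """
    subtracted = np.asarray(subtracted, float)
    n = subtracted.size
    last = segmentation["offset_s"].max()
    if np.round(last * fs) < n - 1:
        raise ValueError("segmentation does not cover the series")
    raster = np.zeros(n, dtype=bool)
    i0s, i1s = _segment_bounds(segmentation, fs, n)
    if pool == "segment":
        for i0, i1 in zip(i0s, i1s):
            seg = subtracted[i0:i1]
            raster[i0:i1] = seg > thresh_sd * seg.std()
    elif pool == "trial":
        for _, grp in segmentation.groupby("trial", sort=False):
            gi0 = int(np.round(grp["onset_s"].min() * fs))
            gi1 = min(int(np.round(grp["offset_s"].max() * fs)), n)
            seg = subtracted[gi0:gi1]
            raster[gi0:gi1] = seg > thresh_sd * seg.std()
    else:
        raise ValueError(f"unknown pool mode {pool!r}")

    rows = []
    for start, stop in _runs(raster):
        dur = (stop - start) / fs
        if dur > min_dur:
            rows.append({
                "onset_s": start / fs,
                "offset_s": stop / fs,
                "duration_s": dur,
                "amplitude": float(subtracted[start:stop].max()),
            })
        else:
            raster[start:stop] = False
    events = pd.DataFrame(rows, columns=["onset_s", "offset_s", "duration_s",
                                         "amplitude"])
    return raster, events


def flexible_segment(events: pd.DataFrame, segmentation: pd.DataFrame,
                     margin: float = 0.2):
    """Assign each burst event wholly to one phase segment.

    Each segment's working window is shrunk by ``margin`` seconds at both
    ends; an event whose onset falls inside a working window belongs to
    that segment, and if it crosses the segment boundary the boundary is
    extended to the event offset, pushing the next segment's effective
    start past the extension.  Events starting inside a margin strip are
    captured by the extension of the preceding segment.

    Returns the events with ``phase`` and ``trial`` columns plus the
    effective segmentation (boundaries moved by extensions), whose
    durations are the denominators for rate computation.
    """
    seg = segmentation.sort_values("onset_s").reset_index(drop=True)
    ws = seg["onset_s"].to_numpy() + margin
    events = events.sort_values("onset_s").reset_index(drop=True)
    n_seg = len(seg)
    assigned = np.empty(len(events), dtype=int)
    ext_end = -np.inf
    p = 0
    for i, ev in events.iterrows():
        while p < n_seg - 1 and ev["onset_s"] >= max(ws[p + 1], ext_end):
            p += 1
        assigned[i] = p
        ext_end = max(ext_end, ev["offset_s"])
        if p < n_seg - 1 and ev["offset_s"] > seg.loc[p + 1, "offset_s"]:
            warnings.warn(
                f"burst at {ev['onset_s']:.3f}s outlasts the following phase; "
                "assigned to its onset phase", stacklevel=2)

    out = events.copy()
    out["phase"] = seg["phase"].to_numpy()[assigned]
    out["trial"] = seg["trial"].to_numpy()[assigned]

    # effective boundaries: extensions move the next segment's start
    eff = seg.copy()
    bound = seg["offset_s"].to_numpy().copy()
    for i, ev in out.iterrows():
        p = assigned[i]
        if p < n_seg - 1 and ev["offset_s"] > bound[p]:
            bound[p] = ev["offset_s"]
    bound = np.minimum(bound, np.append(seg["offset_s"].to_numpy()[1:], np.inf))
    eff.loc[: n_seg - 2, "offset_s"] = bound[: n_seg - 1]
    eff.loc[1:, "onset_s"] = bound[: n_seg - 1]
    return out, eff


def burst_stats(events: pd.DataFrame, segmentation: pd.DataFrame) -> pd.DataFrame:
    """Per-phase burst rate (events/s), mean amplitude and mean duration.

    Rate uses the total (effective) time spent in each phase; amplitude
    and duration are reported as missing, not zero, for phases without
    events.
    """
    seg = segmentation.copy()
    seg["dur"] = seg["offset_s"] - seg["onset_s"]
    total = seg.groupby("phase")["dur"].sum()
    if (total <= 0).any():
        raise ValueError("phase with zero total time")
    rows = []
    for phase, t in total.items():
        sub = events[events["phase"] == phase] if "phase" in events else events.iloc[0:0]
        rows.append({
            "phase": phase,
            "rate": len(sub) / t,
            "amplitude": sub["amplitude"].mean() if len(sub) else np.nan,
            "duration": sub["duration_s"].mean() if len(sub) else np.nan,
            "n_events": len(sub),
            "time_s": t,
        })
    return pd.DataFrame(rows)


def split_rest(duration_s: float, phase_len: float = 3.0) -> pd.DataFrame:
    """Segment a resting-state run into contiguous pseudo-phases."""
    if duration_s < phase_len:
        raise ValueError("run shorter than one pseudo-phase")
    n = int(duration_s // phase_len)
    onsets = np.arange(n) * phase_len
    return pd.DataFrame({
        "trial": np.arange(n),
        "phase": ["rest"] * n,
        "onset_s": onsets,
        "offset_s": onsets + phase_len,
    })
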