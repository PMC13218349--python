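"""Sliding-window spectral parameterization into aperiodic and peak parts.

Each non-overlapping 1-s window is Hann-tapered and Fourier transformed
to a one-sided power spectral density; log-log spectra are decomposed
into a 1/f aperiodic component, ``log10 P(f) = offset - exponent * log10 f``,
by an iterative robust line fit that excludes narrowband (oscillatory)
peak bins.  The per-phase aperiodic model, evaluated over 13-30 Hz and
converted to the wavelet amplitude convention, is the baseline that the
burst detector subtracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .bursts import background_amplitude

__all__ = [
    "Spectrogram",
    "AperiodicFit",
    "sliding_spectra",
    "segment_spectra",
    "fit_aperiodic",
    "fit_phase",
    "aperiodic_psd",
    "phase_baseline",
]


@dataclass
class Spectrogram:
    windows: np.ndarray   # (n_windows, 2) start/end seconds
    freqs: np.ndarray     # Hz
    power: np.ndarray     # (n_windows, n_freqs), one-sided PSD (units^2/Hz)

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class AperiodicFit:
    offset: float          # log10 power at 1 Hz
    exponent: float        # log-log slope magnitude
    r2: float              # squared correlation, model vs observed log-power
    freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    peaks: list = field(default_factory=list)   # (center Hz, height, width Hz)
    peak_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))


def sliding_spectra(series: np.ndarray, fs: float, win_s: float = 1.0,
                    t0: float = 0.0) -> Spectrogram:
    """One-sided PSD in non-overlapping Hann windows; the trailing
    partial window is dropped."""
    series = np.asarray(series, float)
    m = int(round(win_s * fs))
    n_win = series.size // m
    if n_win == 0:
        raise ValueError("series shorter than one window")
    w = hann(m, sym=False)
    segs = series[: n_win * m].reshape(n_win, m) * w
    X = np.fft.rfft(segs, axis=1)
    scale = 2.0 / (fs * (w ** 2).sum())
    power = (np.abs(X) ** 2) * scale
    power[:, 0] /= 2.0
    if m % 2 == 0:
        power[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(m, 1.0 / fs)
    starts = t0 + np.arange(n_win) * win_s
    windows = np.column_stack([starts, starts + win_s])
    return Spectrogram(windows=windows, freqs=freqs, power=power)


def segment_spectra(series: np.ndarray, segmentation: pd.DataFrame, fs: float,
                    win_s: float = 1.0):
    """Per-segment sliding spectra, labelled by phase.

    Returns ``(freqs, power, labels)`` where ``power`` stacks the windows
    of every segment and ``labels`` is a DataFrame with the phase, trial
    and window start of each row.
    """
    series = np.asarray(series, float)
    rows, labels = [], []
    freqs = None
    for _, seg in segmentation.iterrows():
        i0 = int(round(seg["onset_s"] * fs))
        i1 = min(int(round(seg["offset_s"] * fs)), series.size)
        if i1 - i0 < int(round(win_s * fs)):
            continue
        spg = sliding_spectra(series[i0:i1], fs, win_s, t0=seg["onset_s"])
        freqs = spg.freqs
        rows.append(spg.power)
        for start, _end in spg.windows:
            labels.append({"phase": seg["phase"], "trial": seg["trial"],
                           "window_start_s": start})
    if not rows:
        raise ValueError("no complete windows in any segment")
    return freqs, np.vstack(rows), pd.DataFrame(labels)


def fit_aperiodic(freqs: np.ndarray, power: np.ndarray,
                  fit_range=(3.0, 45.0), peak_sd: float = 2.5,
                  n_iter: int = 3) -> AperiodicFit:
    """Robust log-log line fit with iterative exclusion of peak bins.

    Bins whose residual exceeds ``peak_sd`` standard deviations above the
    current line are flagged as oscillatory peaks and excluded from the
    refit (at most ``n_iter`` passes).  The goodness of fit ``r2`` is the
    squared correlation between model and observed log-power over the
    retained (non-peak) bins — the aperiodic analogue of the full-model
    fit quality, since narrowband peaks are deliberately not modelled.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    f, p = freqs[sel], power[sel]
    if f.size <= 2:
        raise ValueError("need more than 2 points in the fit range")
    if np.any(p <= 0):
        raise ValueError("non-positive power in the fit range")
    x, y = np.log10(f), np.log10(p)
    mask = np.ones(f.size, dtype=bool)
    slope, inter = np.polyfit(x, y, 1)
    for _ in range(n_iter):
        resid = y - (inter + slope * x)
        sd = resid[mask].std()
        new_mask = resid <= peak_sd * sd if sd > 0 else mask
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
        if mask.sum() <= 2:
            break
        slope, inter = np.polyfit(x[mask], y[mask], 1)
    model = inter + slope * x
    resid = y - model
    mfit, yfit = model[mask], y[mask]
    if np.std(mfit) == 0 or np.std(yfit) == 0:
        r2 = 1.0 if np.allclose(mfit, yfit) else 0.0
    else:
        r2 = float(np.corrcoef(mfit, yfit)[0, 1] ** 2)
    peaks = []
    for grp in _contiguous(np.flatnonzero(~mask)):
        heights = resid[grp]
        k = grp[np.argmax(heights)]
        width = f[grp[-1]] - f[grp[0]] if len(grp) > 1 else 0.0
        peaks.append((float(f[k]), float(heights.max()), float(width)))
    return AperiodicFit(offset=float(inter), exponent=float(-slope), r2=r2,
                        freqs=f, peaks=peaks, peak_mask=~mask)


def _contiguous(idx: np.ndarray):
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, breaks)


def fit_phase(freqs: np.ndarray, power: np.ndarray, labels: pd.DataFrame,
              mode: str = "mean-spectrum", **fit_kw) -> dict[str, AperiodicFit]:
    """Phase-level aperiodic fit from labelled window spectra.

    ``mode='mean-spectrum'`` (default) averages the linear power across
    all windows of a phase before fitting, which avoids the downward
    bias of log-transformed single-window periodograms;
    ``mode='per-window'`` fits every window and averages the parameters.
    """
    out = {}
    for phase, grp in labels.groupby("phase", sort=False):
        rows = power[grp.index.to_numpy()]
        if mode == "mean-spectrum":
            out[phase] = fit_aperiodic(freqs, rows.mean(axis=0), **fit_kw)
        elif mode == "per-window":
            fits = [fit_aperiodic(freqs, r, **fit_kw) for r in rows]
            out[phase] = AperiodicFit(
                offset=float(np.mean([f.offset for f in fits])),
                exponent=float(np.mean([f.exponent for f in fits])),
                r2=float(np.mean([f.r2 for f in fits])))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def aperiodic_psd(fit: AperiodicFit, freqs: np.ndarray) -> np.ndarray:
    """Evaluate the fitted aperiodic model (linear PSD units)."""
    freqs = np.asarray(freqs, float)
    return 10.0 ** (fit.offset - fit.exponent * np.log10(freqs))


def phase_baseline(fits: dict[str, AperiodicFit], fs: float,
                   band=(13.0, 30.0), mode: str = "wavelet") -> dict[str, float]:
    """Band-averaged aperiodic baseline per phase, in amplitude units.

    ``mode='wavelet'`` converts the model PSD to the expected Morlet
    amplitude of 1/f background noise (commensurate with the detector's
    TF series); ``mode='sqrt'`` uses the plain square root of the
    band-mean power.
    """
    grid = np.arange(band[0], band[1] + 1.0)
    out = {}
    for phase, fit in fits.items():
        if mode == "sqrt":
            out[phase] = float(np.sqrt(aperiodic_psd(fit, grid).mean()))
        elif mode == "wavelet":
            def psd_fn(nu, fit=fit):
                nu = np.maximum(np.asarray(nu, float), 1e-6)
                return 10.0 ** (fit.offset - fit.exponent * np.log10(nu))
            amps = [background_amplitude(psd_fn, f, fs) for f in grid]
            out[phase] = float(np.mean(amps))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out
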