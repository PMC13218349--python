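"""Burst co-occurrence networks and lagged cross-correlation connectivity.

The co-occurrence rate from region A to region B is the fraction of A's
burst samples that are also burst samples in B (asymmetric by
construction).  Functional connectivity between two beta-band series is
the maximum absolute Pearson correlation over lags of up to +/-100 ms,
Fisher-Z transformed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "co_occurrence",
    "co_occurrence_matrix",
    "lagged_fc",
    "fc_matrix",
    "node_strength",
    "rank_shift",
]

FISHER_CLIP = 1.0 - 1e-7


def co_occurrence(raster_a: np.ndarray, raster_b: np.ndarray) -> float:
    """|A and B| / |A|; missing (NaN) when A has no burst samples."""
    a = np.asarray(raster_a, bool)
    b = np.asarray(raster_b, bool)
    if a.shape != b.shape:
        raise ValueError("rasters must have the same length")
    na = a.sum()
    if na == 0:
        return np.nan
    return float((a & b).sum() / na)


def co_occurrence_matrix(raster: np.ndarray) -> np.ndarray:
    """All-pairs co-occurrence; row = source region A, column = target B."""
    raster = np.asarray(raster, bool)
    counts = raster.sum(axis=1).astype(float)
    joint = (raster.astype(float) @ raster.T.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = joint / counts[:, None]
    out[counts == 0] = np.nan
    return out


def lagged_fc(series_a: np.ndarray, series_b: np.ndarray, fs: float,
              max_lag_s: float = 0.1, envelope: bool = False) -> float:
    """Fisher-Z of the max-|lag| cross-correlation within +/- max_lag_s.

    Pearson correlation at each lag on mean-removed series with the
    biased (full-length) denominator; lag endpoints included.  By
    default the band-limited signal itself is correlated;
    ``envelope=True`` correlates the analytic amplitude envelopes
    instead.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if envelope:
        from scipy.signal import hilbert
        a = np.abs(hilbert(a))
        b = np.abs(hilbert(b))
    if a.size != b.size:
        raise ValueError("series must have the same length")
    max_lag = int(round(max_lag_s * fs))
    if a.size < 2 * max_lag + 2:
        raise ValueError("series too short for the requested lag range")
    a = a - a.mean()
    b = b - b.mean()
    denom = a.size * a.std() * b.std()
    if denom == 0:
        raise ValueError("constant series: correlation undefined")
    full = np.correlate(a, b, mode="full")  # index n-1 is lag 0
    mid = a.size - 1
    r = full[mid - max_lag: mid + max_lag + 1] / denom
    r_star = np.abs(r).max()
    return float(np.arctanh(min(r_star, FISHER_CLIP)))


def fc_matrix(series: np.ndarray, fs: float, max_lag_s: float = 0.1) -> np.ndarray:
    """Symmetric all-pairs lagged-FC matrix (zero diagonal)."""
    series = np.asarray(series, float)
    n = series.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            z = lagged_fc(series[i], series[j], fs, max_lag_s)
            out[i, j] = out[j, i] = z
    return out


def node_strength(fc: np.ndarray) -> np.ndarray:
    """Mean |FC| of each region with all other regions."""
    fc = np.asarray(fc, float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("FC matrix must be square")
    a = np.abs(fc).astype(float)
    np.fill_diagonal(a, np.nan)
    return np.nanmean(a, axis=1)


def rank_shift(map_a: np.ndarray, map_b: np.ndarray):
    """Spearman rank correlation between two parcel maps (two-sided p)."""
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.size != b.size:
        raise ValueError("maps must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 parcels")
    res = sps.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)
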