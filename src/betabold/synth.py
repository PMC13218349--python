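"""Synthetic EEG-fMRI session generator with ground truth.

Emulates the statistical structure the analysis pipeline assumes: a
jittered 50-trial isometric handgrip paradigm (inter-trial 3-5 s, adapt
2 s, low 3 s, ramp 3 s, high 3 s), parcel-level source series made of a
1/f aperiodic background plus Hann-windowed beta-carrier burst packets
with phase-dependent Poisson rates, BOLD series obtained by convolving
the ground-truth burst raster with a known HRF, and unit-sphere parcel
centroids with a spatially autocorrelated scalar map for spin-test
exercises.  Every stochastic draw flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from . import hrf as hrf_mod
from .bursts import split_rest  # noqa: F401  (rest runs are segmented here too)

__all__ = [
    "PHASES",
    "ParadigmSpec",
    "BurstModel",
    "AperiodicModel",
    "GroundTruth",
    "generate_paradigm",
    "generate_sources",
    "generate_bold",
    "make_true_hrf",
    "generate_geometry_and_map",
    "write_series",
    "read_series",
    "write_segmentation",
    "write_events",
    "split_rest",
]

PHASES = ("IT", "adapt", "low", "ramp", "high")


@dataclass
class ParadigmSpec:
    """Handgrip task paradigm: 50 trials of IT + adapt/low/ramp/high."""

    n_trials: int = 50
    phase_durations: dict = field(default_factory=lambda: {
        "adapt": 2.0, "low": 3.0, "ramp": 3.0, "high": 3.0})
    it_jitter: tuple = (3.0, 5.0)
    fs: float = 250.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if any(d <= 0 for d in self.phase_durations.values()):
            raise ValueError("phase durations must be positive")
        if self.it_jitter[0] <= 0 or self.it_jitter[1] < self.it_jitter[0]:
            raise ValueError("invalid inter-trial jitter interval")


@dataclass
class BurstModel:
    """Generative burst phenomenology.

    Rates are per-phase Poisson event rates (events/s); amplitudes are
    envelope peaks in signal units; durations are truncated-normal
    seconds with support above ``dur_min``.  ``coupling`` maps parcel
    index -> probability that a burst in ``motor_parcel`` spawns a
    synchronous burst there.
    """

    rates: dict = field(default_factory=lambda: {
        "IT": 0.6, "adapt": 0.45, "low": 0.25, "ramp": 0.25, "high": 0.25,
        "rest": 0.55})
    amp_mean: float = 2.0
    amp_sd: float = 0.4
    dur_mean: float = 0.35
    dur_sd: float = 0.08
    dur_min: float = 0.15
    carrier_hz: float = 20.0
    motor_parcel: int = 0
    coupling: dict = field(default_factory=dict)

    def validate(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")
        if not (13.0 <= self.carrier_hz <= 30.0):
            raise ValueError("carrier must lie in the beta band")
        if any(not 0 <= c <= 1 for c in self.coupling.values()):
            raise ValueError("coupling probabilities must lie in [0, 1]")


@dataclass
class AperiodicModel:
    """1/f background: one-sided PSD = 10^offset * f^-exponent.

    ``offsets``/``exponents`` override the scalars per phase.
    """

    offset: float = -0.5
    exponent: float = 1.5
    offsets: dict | None = None
    exponents: dict | None = None

    def params(self, phase: str):
        off = self.offsets.get(phase, self.offset) if self.offsets else self.offset
        exp = self.exponents.get(phase, self.exponent) if self.exponents else self.exponent
        if exp < 0:
            raise ValueError("exponent must be non-negative")
        return off, exp

    @property
    def uniform(self) -> bool:
        return not self.offsets and not self.exponents


@dataclass
class GroundTruth:
    raster: np.ndarray            # (n_parcels, n_samples) bool
    events: pd.DataFrame          # parcel, onset_s, offset_s, amplitude
    fs: float
    aperiodic: AperiodicModel
    burst_model: BurstModel
    true_hrf: tuple | None = None        # (t, h)
    centroids: np.ndarray | None = None
    receptor_map: np.ndarray | None = None


def generate_paradigm(spec: ParadigmSpec) -> pd.DataFrame:
    """Ordered, non-overlapping phase intervals covering the session."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    t = 0.0
    for trial in range(spec.n_trials):
        it = rng.uniform(*spec.it_jitter)
        for phase, dur in [("IT", it)] + [(p, spec.phase_durations[p])
                                          for p in PHASES[1:]]:
            rows.append({"trial": trial, "phase": phase,
                         "onset_s": t, "offset_s": t + dur})
            t += dur
    return pd.DataFrame(rows)


def _shaped_noise(n: int, fs: float, offset: float, exponent: float,
                  rng: np.random.Generator) -> np.ndarray:
    """White noise spectrally shaped to a one-sided PSD 10^offset * f^-exp."""
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    S = np.zeros_like(f)
    S[1:] = 10.0 ** offset * f[1:] ** (-exponent)
    # unit-variance white noise has one-sided PSD 2/fs
    X *= np.sqrt(S * fs / 2.0)
    return np.fft.irfft(X, n)


def generate_sources(segmentation: pd.DataFrame, burst_model: BurstModel,
                     aperiodic_model: AperiodicModel, n_parcels: int,
                     fs: float = 250.0, seed: int = 0):
    """Parcel source series = 1/f background + beta burst packets.

    Returns ``(data, truth)`` where ``data`` is (n_parcels, n_samples)
    and ``truth`` carries the merged ground-truth burst raster/events on
    the identical sample grid.
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    if len(segmentation) == 0:
        raise ValueError("empty segmentation")
    burst_model.validate()
    rng = np.random.default_rng(seed)
    duration = float(segmentation["offset_s"].max())
    n = int(round(duration * fs))

    data = np.empty((n_parcels, n))
    for p in range(n_parcels):
        if aperiodic_model.uniform:
            off, exp = aperiodic_model.params("IT")
            data[p] = _shaped_noise(n, fs, off, exp, rng)
        else:
            sig = np.empty(n)
            for _, seg in segmentation.iterrows():
                i0 = int(round(seg["onset_s"] * fs))
                i1 = min(int(round(seg["offset_s"] * fs)), n)
                off, exp = aperiodic_model.params(seg["phase"])
                sig[i0:i1] = _shaped_noise(i1 - i0, fs, off, exp, rng)
            data[p] = sig

    # draw burst events per parcel and phase segment
    events = {p: [] for p in range(n_parcels)}
    for _, seg in segmentation.iterrows():
        rate = burst_model.rates.get(seg["phase"], 0.0)
        seg_dur = seg["offset_s"] - seg["onset_s"]
        for p in range(n_parcels):
            for _ in range(rng.poisson(rate * seg_dur)):
                onset = rng.uniform(seg["onset_s"], seg["offset_s"])
                ev = _draw_event(onset, burst_model, rng, duration)
                if ev is not None:
                    events[p].append(ev)
                    if p == burst_model.motor_parcel:
                        for q, prob in burst_model.coupling.items():
                            if rng.uniform() < prob:
                                amp = _trunc_normal(
                                    burst_model.amp_mean, burst_model.amp_sd,
                                    0.0, rng)
                                events[q].append((ev[0], ev[1], amp))

    raster = np.zeros((n_parcels, n), dtype=bool)
    merged_rows = []
    for p in range(n_parcels):
        for onset, dur, amp in events[p]:
            i0 = int(round(onset * fs))
            i1 = min(int(round((onset + dur) * fs)), n)
            m = i1 - i0
            if m < 2:
                continue
            tt = np.arange(m) / fs
            phase0 = rng.uniform(0, 2 * np.pi)
            data[p, i0:i1] += (amp * hann(m)
                               * np.cos(2 * np.pi * burst_model.carrier_hz * tt
                                        + phase0))
            raster[p, i0:i1] = True
        for (i0, i1), amp in _merge_events(events[p], fs, n):
            merged_rows.append({"parcel": p, "onset_s": i0 / fs,
                                "offset_s": i1 / fs, "amplitude": amp})
    ev_df = pd.DataFrame(merged_rows,
                         columns=["parcel", "onset_s", "offset_s", "amplitude"])
    truth = GroundTruth(raster=raster, events=ev_df, fs=fs,
                        aperiodic=aperiodic_model, burst_model=burst_model)
    return data, truth


def _trunc_normal(mean, sd, lo, rng, max_tries=1000):
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    return max(lo + sd * 1e-3, mean)


def _draw_event(onset, bm: BurstModel, rng, session_dur):
    dur = _trunc_normal(bm.dur_mean, bm.dur_sd, bm.dur_min, rng)
    if onset >= session_dur:
        return None
    dur = min(dur, session_dur - onset)
    if dur <= 0:
        return None
    amp = _trunc_normal(bm.amp_mean, bm.amp_sd, 0.0, rng)
    return (onset, dur, amp)


def _merge_events(evs, fs, n):
    """Merge overlapping events into (sample interval, peak amplitude)."""
    ivals = []
    for onset, dur, amp in evs:
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + dur) * fs)), n)
        if i1 - i0 >= 2:
            ivals.append((i0, i1, amp))
    ivals.sort()
    merged = []
    for i0, i1, amp in ivals:
        if merged and i0 <= merged[-1][0][1]:
            (m0, m1), ma = merged[-1]
            merged[-1] = ((m0, max(m1, i1)), max(ma, amp))
        else:
            merged.append(((i0, i1), amp))
    return merged


def make_true_hrf(fs: float = 250.0, support_s: float = 30.0,
                  alpha: float = 0.75, mu: float = 3.5,
                  coefficients=(1.0, 0.35), peak: float = 1.0):
    """A ground-truth HRF inside the spherical-Laguerre basis span.

    Returns ``(t, h)`` scaled so the signed peak equals ``peak``.
    """
    cfg = hrf_mod.BasisConfig(L=len(coefficients), alpha=alpha, mu=mu,
                              support_s=support_s, fs_model=fs)
    basis = hrf_mod.spherical_basis(cfg)
    h = basis.matrix @ np.asarray(coefficients, float)
    h = h * (peak / h[np.argmax(np.abs(h))])
    return basis.t, h


def generate_bold(raster: np.ndarray, true_hrf: np.ndarray, fs: float,
                  tr: float = 2.12, noise_sd: float = 0.0, seed: int = 0):
    """BOLD = TR-sampled discrete convolution of raster and HRF + noise."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    was_1d = np.asarray(raster).ndim == 1
    raster = np.atleast_2d(np.asarray(raster, float))
    true_hrf = np.asarray(true_hrf, float)
    n = raster.shape[1]
    if true_hrf.size > n:
        raise ValueError("HRF longer than session")
    rng = np.random.default_rng(seed)
    step = tr * fs
    idx = np.round(np.arange(0, n, step)).astype(int)
    idx = idx[idx < n]
    out = np.empty((raster.shape[0], idx.size))
    for p in range(raster.shape[0]):
        conv = np.convolve(raster[p], true_hrf)[:n]
        out[p] = conv[idx] + rng.normal(0.0, noise_sd, idx.size)
    return out[0] if was_1d else out


def generate_geometry_and_map(n_parcels: int, autocorr_scale: float = 0.5,
                              seed: int = 0):
    """Unit-sphere parcel centroids and a spatially autocorrelated map.

    The map is Gaussian-kernel-smoothed white noise on the sphere;
    ``autocorr_scale`` is the kernel width in radians of angular
    distance (scale -> 0 gives spatially independent values).
    """
    if n_parcels < 3:
        raise ValueError("need at least 3 parcels")
    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_parcels, 3))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    dots = np.clip(centroids @ centroids.T, -1.0, 1.0)
    ang = np.arccos(dots)
    if autocorr_scale > 0:
        K = np.exp(-(ang ** 2) / (2.0 * autocorr_scale ** 2))
    else:
        K = np.eye(n_parcels)
    vals = K @ rng.standard_normal(n_parcels)
    vals = (vals - vals.mean()) / vals.std()
    return centroids, vals


# -- plain-text I/O -----------------------------------------------------------

def write_series(path, data: np.ndarray, fs: float, labels=None) -> None:
    """Delimited numeric table (parcels x samples) with a JSON sidecar."""
    path = Path(path)
    data = np.atleast_2d(data)
    if labels is None:
        labels = [f"parcel{i:02d}" for i in range(data.shape[0])]
    pd.DataFrame(data.T, columns=labels).to_csv(path, sep="\t", index=False)
    sidecar = {"fs": fs, "labels": list(labels), "n_samples": int(data.shape[1])}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_series(path):
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return df.to_numpy().T, meta["fs"], meta["labels"]


def write_segmentation(path, segmentation: pd.DataFrame) -> None:
    segmentation.to_csv(path, sep="\t", index=False)


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)
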