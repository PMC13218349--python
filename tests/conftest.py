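"""Shared fixtures: a synthetic task session processed once per run."""

from __future__ import annotations

import numpy as np
import pytest

from betabold import bursts, spectral, synth

SESSION_FS = 250.0
SESSION_SEED = 5
SESSION_PARCELS = 4


@pytest.fixture(scope="session")
def task_session():
    """20-trial default-model session with ground truth."""
    spec = synth.ParadigmSpec(n_trials=20, fs=SESSION_FS, seed=SESSION_SEED)
    seg = synth.generate_paradigm(spec)
    bm = synth.BurstModel()
    am = synth.AperiodicModel()
    data, truth = synth.generate_sources(seg, bm, am, SESSION_PARCELS,
                                         fs=SESSION_FS, seed=SESSION_SEED + 1)
    return {"segmentation": seg, "data": data, "truth": truth,
            "fs": SESSION_FS, "burst_model": bm, "aperiodic_model": am}


@pytest.fixture(scope="session")
def detected_session(task_session):
    """Full detection chain (aperiodic fit -> TF -> subtract -> detect)
    for every parcel of the shared session."""
    fs = task_session["fs"]
    seg = task_session["segmentation"]
    out = []
    for p in range(task_session["data"].shape[0]):
        series = task_session["data"][p]
        freqs, power, labels = spectral.segment_spectra(series, seg, fs)
        fits = spectral.fit_phase(freqs, power, labels)
        base = spectral.phase_baseline(fits, fs)
        tf = bursts.morlet_tf(series, fs)
        sub = bursts.subtract_baseline(bursts.beta_series(tf), seg, base, fs)
        raster, events = bursts.detect_bursts(sub, seg, fs)
        out.append({"fits": fits, "baselines": base, "subtracted": sub,
                    "raster": raster, "events": events})
    return out


def overlap_fraction(events_a, events_b) -> float:
    """Fraction of events in A with a partner in B overlapping by at
    least half of the shorter event's duration."""
    if len(events_a) == 0:
        return 1.0
    if len(events_b) == 0:
        return 0.0
    bv = events_b[["onset_s", "offset_s"]].to_numpy()
    hits = 0
    for _, a in events_a.iterrows():
        da = a["offset_s"] - a["onset_s"]
        ov = (np.minimum(a["offset_s"], bv[:, 1])
              - np.maximum(a["onset_s"], bv[:, 0]))
        db = bv[:, 1] - bv[:, 0]
        if np.any(ov >= 0.5 * np.minimum(da, db)):
            hits += 1
    return hits / len(events_a)
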