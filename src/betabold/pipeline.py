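"""End-to-end orchestration: synth -> spectral -> bursts -> network -> hrf -> stats.

A single nested config drives every stage; all defaults mirror the
analysis conventions used throughout the package (2-SD burst threshold,
100 ms duration filter, 0.2 s flexible-segmentation margin, +/-100 ms FC
lags, L in 1..3, alpha in [0.5, 1], mu in [2.5, 5], tau = 1 s, 3 CV
folds, TR 2.12 s, fs 250 Hz).  Every intermediate table is written as a
delimited file, and a JSON manifest records versions, seeds, parameters
and per-stage runtimes so identical manifests imply identical outputs.
"""

from __future__ import annotations

import copy
import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import __version__, bursts, hrf, network, spectral, stats, synth

__all__ = ["default_config", "run"]


def default_config() -> dict:
    return {
        "seed": 0,
        "out_dir": "betabold_out",
        "stages": {"synth": True, "spectral": True, "bursts": True,
                   "network": True, "hrf": True, "stats": True},
        "synth": {
            "n_parcels": 6,
            "n_trials": 10,
            "fs": 250.0,
            "tr": 2.12,
            "bold_noise_sd": 0.1,
            "coupling": {1: 0.8},
            "autocorr_scale": 0.5,
        },
        "spectral": {"win_s": 1.0, "fit_range": [3.0, 45.0],
                     "baseline_mode": "wavelet"},
        "bursts": {"min_dur": 0.1, "thresh_sd": 2.0, "margin": 0.2,
                   "pool": "trial"},
        "network": {"max_lag_s": 0.1, "band": [13.0, 30.0]},
        "hrf": {"fs_model": 25.0, "n_folds": 3, "n_surrogates": 0,
                "support_s": 30.0},
        "stats": {"n_rotations": 200, "alpha": 0.05},
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _bandpass(data: np.ndarray, fs: float, band) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, data, axis=-1)


def run(config: dict | None = None, out_dir=None) -> dict:
    """Run the configured stages; returns a results bundle.

    Any stage failure aborts with the stage name attached to the raised
    error.  Disabling a stage omits its outputs (and those of stages
    that depend on it) while leaving earlier outputs unchanged.
    """
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "python": platform.python_version(),
                "config": _jsonable(cfg), "stage_runtimes_s": {}, "outputs": []}
    bundle: dict = {"config": cfg}
    stage = "setup"
    try:
        for stage in ["synth", "spectral", "bursts", "network", "hrf", "stats"]:
            if not cfg["stages"].get(stage, False):
                continue
            t0 = time.perf_counter()
            _STAGES[stage](cfg, bundle, out, manifest)
            manifest["stage_runtimes_s"][stage] = round(
                time.perf_counter() - t0, 3)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["outputs"].append(path.name)


def _stage_synth(cfg, bundle, out, manifest):
    sc = cfg["synth"]
    seed = cfg["seed"]
    spec = synth.ParadigmSpec(n_trials=sc["n_trials"], fs=sc["fs"], seed=seed)
    seg = synth.generate_paradigm(spec)
    bm = synth.BurstModel(coupling={int(k): v
                                    for k, v in sc["coupling"].items()})
    am = synth.AperiodicModel()
    data, truth = synth.generate_sources(seg, bm, am, sc["n_parcels"],
                                         fs=sc["fs"], seed=seed + 1)
    t_h, h = synth.make_true_hrf(fs=sc["fs"])
    bold = synth.generate_bold(truth.raster, h, fs=sc["fs"], tr=sc["tr"],
                               noise_sd=sc["bold_noise_sd"], seed=seed + 2)
    centroids, rmap = synth.generate_geometry_and_map(
        sc["n_parcels"], sc["autocorr_scale"], seed=seed + 3)
    truth.true_hrf = (t_h, h)
    truth.centroids = centroids
    truth.receptor_map = rmap
    bundle.update(segmentation=seg, data=data, truth=truth, bold=bold)
    _write(seg, out / "segmentation.tsv", manifest)
    _write(truth.events, out / "true_events.tsv", manifest)
    step = max(1, int(round(sc["fs"] / 5.0)))  # curves are smooth; 5 Hz table
    _write(pd.DataFrame({"t_s": t_h[::step], "h": h[::step]}),
           out / "true_hrf.tsv", manifest)


def _stage_spectral(cfg, bundle, out, manifest):
    sc, fs = cfg["spectral"], cfg["synth"]["fs"]
    fits_rows, baselines = [], {}
    for p in range(bundle["data"].shape[0]):
        freqs, power, labels = spectral.segment_spectra(
            bundle["data"][p], bundle["segmentation"], fs, sc["win_s"])
        fits = spectral.fit_phase(freqs, power, labels,
                                  fit_range=tuple(sc["fit_range"]))
        base = spectral.phase_baseline(fits, fs, mode=sc["baseline_mode"])
        baselines[p] = base
        for phase, fit in fits.items():
            fits_rows.append({"parcel": p, "phase": phase,
                              "offset": fit.offset, "exponent": fit.exponent,
                              "r2": fit.r2, "baseline": base[phase]})
    df = pd.DataFrame(fits_rows)
    bundle["aperiodic"] = df
    bundle["baselines"] = baselines
    _write(df, out / "aperiodic_fits.tsv", manifest)


def _stage_bursts(cfg, bundle, out, manifest):
    bc, fs = cfg["bursts"], cfg["synth"]["fs"]
    seg = bundle["segmentation"]
    all_events, rasters, stats_rows = [], [], []
    for p in range(bundle["data"].shape[0]):
        tf = bursts.morlet_tf(bundle["data"][p], fs)
        series = bursts.beta_series(tf)
        sub = bursts.subtract_baseline(series, seg, bundle["baselines"][p], fs)
        raster, events = bursts.detect_bursts(sub, seg, fs,
                                              min_dur=bc["min_dur"],
                                              thresh_sd=bc["thresh_sd"],
                                              pool=bc["pool"])
        events, eff_seg = bursts.flexible_segment(events, seg, bc["margin"])
        events.insert(0, "parcel", p)
        all_events.append(events)
        rasters.append(raster)
        st = bursts.burst_stats(events, eff_seg)
        st.insert(0, "parcel", p)
        stats_rows.append(st)
    events = pd.concat(all_events, ignore_index=True)
    bundle["events"] = events
    bundle["raster"] = np.vstack(rasters)
    bundle["burst_stats"] = pd.concat(stats_rows, ignore_index=True)
    _write(events, out / "burst_events.tsv", manifest)
    _write(bundle["burst_stats"], out / "burst_stats.tsv", manifest)


def _phase_mask(seg: pd.DataFrame, phase: str, fs: float, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for _, row in seg[seg["phase"] == phase].iterrows():
        i0 = int(round(row["onset_s"] * fs))
        i1 = min(int(round(row["offset_s"] * fs)), n)
        mask[i0:i1] = True
    return mask


def _stage_network(cfg, bundle, out, manifest):
    nc, fs = cfg["network"], cfg["synth"]["fs"]
    seg = bundle["segmentation"]
    n = bundle["raster"].shape[1]
    beta_band = _bandpass(bundle["data"], fs, nc["band"])
    for phase in seg["phase"].unique():
        mask = _phase_mask(seg, phase, fs, n)
        co = network.co_occurrence_matrix(bundle["raster"][:, mask])
        _write(pd.DataFrame(co), out / f"cooccurrence_{phase}.tsv", manifest)
        fc = network.fc_matrix(beta_band[:, mask], fs, nc["max_lag_s"])
        _write(pd.DataFrame(fc), out / f"fc_{phase}.tsv", manifest)
        bundle.setdefault("cooccurrence", {})[phase] = co
        bundle.setdefault("fc", {})[phase] = fc
    strengths = {ph: network.node_strength(m)
                 for ph, m in bundle["fc"].items()}
    _write(pd.DataFrame(strengths), out / "fc_node_strength.tsv", manifest)
    bundle["node_strength"] = strengths


def _stage_hrf(cfg, bundle, out, manifest):
    hc = cfg["hrf"]
    fs, tr = cfg["synth"]["fs"], cfg["synth"]["tr"]
    fs_model = hc["fs_model"]
    grid = hrf.default_grid(support_s=hc["support_s"], fs_model=fs_model)
    rows, estimates = [], {}
    for p in range(bundle["raster"].shape[0]):
        raster_m = hrf.decimate_raster(bundle["raster"][p], fs, fs_model)
        bold_up = hrf.upsample_bold(bundle["bold"][p], tr, fs_model,
                                    n_out=raster_m.size)
        est = hrf.fit_hrf_cv(raster_m, bold_up, grid=grid,
                             n_folds=hc["n_folds"])
        _, r = hrf.predict_bold(est, raster_m, bold_up)
        row = {"parcel": p, "L": est.config.L, "alpha": est.config.alpha,
               "mu": est.config.mu, "cv_r_mean": est.cv_r_mean,
               "pred_r": r, **est.features}
        if hc["n_surrogates"]:
            sur = hrf.surrogate_test(raster_m, bold_up, grid=grid,
                                     n_shuffles=hc["n_surrogates"],
                                     seed=cfg["seed"] + 10 + p)
            row.update(surrogate_p=sur.p,
                       surrogate_null_95=float(np.percentile(sur.null, 95)))
        rows.append(row)
        estimates[p] = est
    df = pd.DataFrame(rows)
    bundle["hrf_estimates"] = estimates
    bundle["hrf_table"] = df
    _write(df, out / "hrf_estimates.tsv", manifest)
    step = max(1, int(round(fs_model / 5.0)))
    curves = pd.DataFrame({"t_s": next(iter(estimates.values())).t[::step]})
    for p, est in estimates.items():
        curves[f"parcel{p}"] = est.curve[::step]
    _write(curves, out / "hrf_curves.tsv", manifest)


def _stage_stats(cfg, bundle, out, manifest):
    st = cfg["stats"]
    rows = []
    bs = bundle.get("burst_stats")
    if bs is not None:
        # paired across parcels: burst amplitude between phase pairs
        wide = bs.pivot(index="parcel", columns="phase", values="amplitude")
        phases = [p for p in ["IT", "adapt", "low", "ramp", "high"]
                  if p in wide.columns]
        for i, a in enumerate(phases):
            for b in phases[i + 1:]:
                pair = wide[[a, b]].dropna()
                if len(pair) < 5 or (pair[a] - pair[b]).ne(0).sum() < 5:
                    continue
                res = stats.wilcoxon_paired(pair[a].to_numpy(),
                                            pair[b].to_numpy())
                rows.append({"comparison": f"amplitude {a} vs {b}",
                             "z": res.z, "p": res.p, "r_effect": res.r_effect,
                             "n": res.n})
    if rows:
        df = pd.DataFrame(rows)
        df["p_fdr"] = stats.fdr_adjust(df["p"])
        _write(df, out / "phase_comparisons.tsv", manifest)
        bundle["comparisons"] = df
    truth = bundle.get("truth")
    hrf_table = bundle.get("hrf_table")
    if truth is not None and truth.receptor_map is not None \
            and hrf_table is not None and len(hrf_table) >= 10:
        spin = stats.spin_correlation(hrf_table["area"].to_numpy(),
                                      truth.receptor_map, truth.centroids,
                                      n_rot=st["n_rotations"],
                                      seed=cfg["seed"] + 100)
        res = {"observed_r": spin.observed, "p_spin": spin.p,
               "n_rotations": spin.n_rotations}
        (out / "spin_test.json").write_text(json.dumps(res, indent=2))
        manifest["outputs"].append("spin_test.json")
        bundle["spin"] = res


_STAGES = {"synth": _stage_synth, "spectral": _stage_spectral,
           "bursts": _stage_bursts, "network": _stage_network,
           "hrf": _stage_hrf, "stats": _stage_stats}
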