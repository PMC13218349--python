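"""Morlet TF, baseline subtraction, burst detection and segmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import hilbert, welch
from scipy.signal.windows import hann

from betabold import bursts, synth
from tests.conftest import overlap_fraction


def make_segmentation(rows):
    return pd.DataFrame(rows, columns=["trial", "phase", "onset_s", "offset_s"])


class TestMorletTF:
    def test_unit_gain_on_stationary_sinusoid(self):
        fs, amp = 250.0, 1.5
        t = np.arange(10 * 250) / fs
        x = amp * np.cos(2 * np.pi * 20.0 * t)
        tf = bursts.morlet_tf(x, fs)
        mid = tf.amplitude[tf.freqs == 20.0, 500:-500]
        np.testing.assert_allclose(mid, amp, rtol=1e-3)
        assert mid.std() < 1e-3 * amp  # flat over time away from edges

    def test_zero_signal_zero_tf(self):
        tf = bursts.morlet_tf(np.zeros(1000), 250.0)
        np.testing.assert_allclose(tf.amplitude, 0.0, atol=1e-12)

    def test_packet_peak_time_matches_analytic_envelope(self):
        # oracle: envelope peak of the analytic signal
        fs = 250.0
        n = int(6 * fs)
        x = np.zeros(n)
        m = int(0.4 * fs)
        i0 = int(3.0 * fs) - m // 2
        tt = np.arange(m) / fs
        x[i0:i0 + m] = hann(m) * np.cos(2 * np.pi * 20.0 * tt)
        oracle_peak = np.argmax(np.abs(hilbert(x))) / fs
        tf = bursts.morlet_tf(x, fs)
        beta = bursts.beta_series(tf)
        assert abs(np.argmax(beta) / fs - oracle_peak) <= 0.02

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            bursts.morlet_tf(np.zeros(100), 50.0)

    def test_matches_mne_morlet_envelope(self):
        """Independent cross-check: amplitude envelope at one frequency
        agrees (up to scale) with MNE's Morlet TF at the matched
        number of cycles."""
        mne = pytest.importorskip("mne")
        fs = 250.0
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(8 * fs))
        f0 = 20.0
        tf = bursts.morlet_tf(x, fs, freqs=np.array([f0]))
        n_cycles = 3.0 * 2 * np.pi / (2 * np.sqrt(2 * np.log(2)))
        out = mne.time_frequency.tfr_array_morlet(
            x[None, None, :], fs, freqs=[f0], n_cycles=n_cycles,
            output="complex", zero_mean=False)
        ours = tf.amplitude[0, 300:-300]
        theirs = np.abs(out[0, 0, 0, 300:-300])
        assert np.corrcoef(ours, theirs)[0, 1] > 0.999


class TestBetaSeries:
    def test_constant_tf(self):
        tf = bursts.TFMatrix(freqs=np.arange(13, 31.0),
                             amplitude=np.full((18, 50), 3.0), fs=250.0)
        np.testing.assert_allclose(bursts.beta_series(tf), 3.0)

    def test_single_nonzero_row(self):
        amp = np.zeros((18, 10))
        amp[4, :] = 9.0
        tf = bursts.TFMatrix(freqs=np.arange(13, 31.0), amplitude=amp, fs=250.0)
        np.testing.assert_allclose(bursts.beta_series(tf), 0.5)

    def test_matches_column_mean_oracle(self):
        rng = np.random.default_rng(3)
        amp = rng.uniform(size=(18, 100))
        tf = bursts.TFMatrix(freqs=np.arange(13, 31.0), amplitude=amp, fs=250.0)
        np.testing.assert_allclose(bursts.beta_series(tf), amp.mean(axis=0))


class TestSubtractBaseline:
    seg = make_segmentation([(0, "low", 0.0, 2.0), (0, "high", 2.0, 4.0)])

    def test_all_below_baseline_zeroed(self):
        x = np.full(1000, 0.3)
        out = bursts.subtract_baseline(x, self.seg, 0.5, 250.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_offset_above_baseline(self):
        x = np.full(1000, 1.5)
        out = bursts.subtract_baseline(x, self.seg, {"low": 0.5, "high": 0.5},
                                       250.0)
        np.testing.assert_allclose(out, 1.0)

    def test_per_phase_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=1000)
        base = {"low": 0.3, "high": 0.7}
        out = bursts.subtract_baseline(x, self.seg, base, 250.0)
        expected = np.maximum(
            x - np.where(np.arange(1000) < 500, 0.3, 0.7), 0.0)
        np.testing.assert_allclose(out, expected)


class TestDetectBursts:
    seg = make_segmentation([(0, "low", 0.0, 3.0)])

    def test_all_zero_series_no_events(self):
        raster, events = bursts.detect_bursts(np.zeros(750), self.seg, 250.0)
        assert len(events) == 0
        assert not raster.any()

    def test_150ms_excursion_accepted(self):
        x = np.zeros(750)
        x[200:238] = 5.0  # 38 samples = 152 ms
        raster, events = bursts.detect_bursts(x, self.seg, 250.0)
        assert len(events) == 1
        assert events.loc[0, "duration_s"] == pytest.approx(0.152)
        assert events.loc[0, "amplitude"] == 5.0

    def test_80ms_excursion_rejected(self):
        x = np.zeros(750)
        x[200:220] = 5.0  # 80 ms, below the 100 ms filter
        raster, events = bursts.detect_bursts(x, self.seg, 250.0)
        assert len(events) == 0
        assert not raster.any()

    def test_threshold_monotonicity(self, detected_session):
        """Raising the threshold multiplier never increases event count."""
        parcel = detected_session[0]
        seg = make_segmentation([(0, "low", 0.0,
                                  len(parcel["subtracted"]) / 250.0)])
        counts = []
        for k in (1.0, 2.0, 3.0, 4.0):
            _, ev = bursts.detect_bursts(parcel["subtracted"], seg, 250.0,
                                         thresh_sd=k)
            counts.append(len(ev))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_run_lengths_match_runlength_oracle(self):
        rng = np.random.default_rng(5)
        x = np.where(rng.uniform(size=750) < 0.3, 2.0, 0.0)
        raster, events = bursts.detect_bursts(x, self.seg, 250.0, min_dur=0.0)
        mask = x > 2 * x.std()
        # independent run-length count
        n_runs = int(np.sum(np.diff(np.r_[0, mask.astype(int), 0]) == 1))
        assert len(events) == n_runs


class TestFlexibleSegment:
    seg = make_segmentation([(0, "A", 0.0, 3.0), (0, "B", 3.0, 6.0),
                             (1, "C", 6.0, 9.0)])

    def make_events(self, intervals):
        return pd.DataFrame([{"onset_s": a, "offset_s": b,
                              "duration_s": b - a, "amplitude": 1.0}
                             for a, b in intervals])

    def test_interior_events_match_naive_lookup(self):
        ev = self.make_events([(1.0, 1.3), (4.0, 4.3), (7.0, 7.2)])
        out, _ = bursts.flexible_segment(ev, self.seg)
        assert list(out["phase"]) == ["A", "B", "C"]

    def test_boundary_event_stays_in_onset_phase_and_count_conserved(self):
        ev = self.make_events([(2.7, 3.4), (4.5, 4.8)])
        out, eff = bursts.flexible_segment(ev, self.seg)
        assert list(out["phase"]) == ["A", "B"]
        assert len(out) == len(ev)
        # the extension moved the A/B boundary to the event offset
        assert eff.loc[0, "offset_s"] == pytest.approx(3.4)
        assert eff.loc[1, "onset_s"] == pytest.approx(3.4)

    def test_margin_strip_event_captured_by_previous_phase(self):
        # onset inside B's leading margin strip [3.0, 3.2)
        ev = self.make_events([(3.05, 3.18)])
        out, _ = bursts.flexible_segment(ev, self.seg)
        assert out.loc[0, "phase"] == "A"

    def test_event_after_extension_follows_extended_boundary(self):
        # first event extends A to 3.4; second event starts at 3.3,
        # inside B's nominal window but before the moved boundary
        ev = self.make_events([(2.7, 3.4), (3.3, 3.5), (3.6, 3.8)])
        out, _ = bursts.flexible_segment(ev, self.seg)
        assert list(out["phase"]) == ["A", "A", "B"]

    def test_overlong_event_warns(self):
        ev = self.make_events([(2.5, 6.5)])
        with pytest.warns(UserWarning):
            out, _ = bursts.flexible_segment(ev, self.seg)
        assert out.loc[0, "phase"] == "A"

    def test_matches_stepthrough_reference(self):
        """Randomized events agree with an independent step-through
        simulation of the margin/extension rule."""
        rng = np.random.default_rng(6)
        onsets = np.sort(rng.uniform(0.0, 8.5, size=40))
        ev = self.make_events([(o, o + rng.uniform(0.05, 0.5)) for o in onsets])
        out, _ = bursts.flexible_segment(ev, self.seg)

        # reference: walk phases with an explicit moving working-start
        margin = 0.2
        starts = self.seg["onset_s"].to_numpy() + margin
        expected = []
        p, barrier = 0, -np.inf
        for _, e in ev.iterrows():
            while p < 2 and e["onset_s"] >= max(starts[p + 1], barrier):
                p += 1
            expected.append(self.seg.loc[p, "phase"])
            barrier = max(barrier, e["offset_s"])
        assert list(out["phase"]) == expected
        assert len(out) == len(ev)


class TestBurstStats:
    def test_rate_normalized_by_time(self):
        seg = make_segmentation([(0, "low", 0.0, 3.0)])
        ev = pd.DataFrame({"onset_s": np.linspace(0.1, 2.5, 6),
                           "offset_s": np.linspace(0.3, 2.7, 6),
                           "duration_s": [0.2] * 6, "amplitude": [1.0] * 6,
                           "phase": ["low"] * 6, "trial": [0] * 6})
        st = bursts.burst_stats(ev, seg)
        assert st.loc[0, "rate"] == pytest.approx(2.0)

    def test_empty_phase_reports_missing_not_zero(self):
        seg = make_segmentation([(0, "low", 0.0, 3.0), (0, "high", 3.0, 6.0)])
        ev = pd.DataFrame({"onset_s": [1.0], "offset_s": [1.2],
                           "duration_s": [0.2], "amplitude": [2.0],
                           "phase": ["low"], "trial": [0]})
        st = bursts.burst_stats(ev, seg).set_index("phase")
        assert st.loc["high", "rate"] == 0.0
        assert np.isnan(st.loc["high", "amplitude"])
        assert np.isnan(st.loc["high", "duration"])

    def test_zero_time_phase_rejected(self):
        seg = make_segmentation([(0, "low", 1.0, 1.0)])
        with pytest.raises(ValueError):
            bursts.burst_stats(pd.DataFrame(columns=["phase"]), seg)

    def test_detected_rates_track_generative_rates(self):
        """Spearman correlation > 0.9 between detected per-phase rates
        and the generative per-phase rates (phases given distinct rates
        so rank recovery is identifiable)."""
        from scipy.stats import spearmanr
        from betabold import spectral
        fs = 250.0
        rates = {"IT": 0.7, "adapt": 0.5, "low": 0.35, "ramp": 0.25,
                 "high": 0.15}
        seg = synth.generate_paradigm(synth.ParadigmSpec(n_trials=30, seed=41))
        bm = synth.BurstModel(rates=rates)
        data, _ = synth.generate_sources(seg, bm, synth.AperiodicModel(),
                                         3, fs=fs, seed=42)
        phases = list(rates)
        det = {ph: [] for ph in phases}
        for p in range(3):
            freqs, power, labels = spectral.segment_spectra(data[p], seg, fs)
            fits = spectral.fit_phase(freqs, power, labels)
            base = spectral.phase_baseline(fits, fs)
            sub = bursts.subtract_baseline(
                bursts.beta_series(bursts.morlet_tf(data[p], fs)), seg, base, fs)
            _, events = bursts.detect_bursts(sub, seg, fs)
            ev, eff = bursts.flexible_segment(events, seg)
            st = bursts.burst_stats(ev, eff).set_index("phase")
            for ph in phases:
                det[ph].append(st.loc[ph, "rate"])
        mean_rates = [np.mean(det[ph]) for ph in phases]
        rho = spearmanr(mean_rates, [rates[ph] for ph in phases]).statistic
        assert rho > 0.9


class TestRestSplit:
    def test_contiguous_three_second_phases(self):
        seg = synth.split_rest(31.0)
        assert len(seg) == 10
        assert (seg["offset_s"] - seg["onset_s"] == 3.0).all()


class TestBurstSpectra:
    def test_raster_and_convolved_spectra_concentrate_below_fmri_nyquist(
            self, task_session):
        """The burst raster carries a pronounced low-frequency peak below
        the fMRI Nyquist (~0.24 Hz), and its HRF-convolved version
        concentrates spectral power well inside the BOLD bandwidth."""
        fs = task_session["fs"]
        raster = task_session["truth"].raster[0].astype(float)
        f, p = welch(raster - raster.mean(), fs=fs, nperseg=2 ** 14)
        assert f[p.argmax()] < 0.24
        _, h = synth.make_true_hrf(fs=fs)
        conv = np.convolve(raster, h)[: raster.size]
        f2, p2 = welch(conv - conv.mean(), fs=fs, nperseg=2 ** 14)
        assert f2[p2.argmax()] < 0.24
        assert p2[f2 <= 0.24].sum() / p2.sum() > 0.9
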