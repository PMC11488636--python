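"""EFP model: notch, energy-uniform bands, features, fit, prediction."""

import numpy as np
import pytest

from efpnf import efp, synthetic as syn

from conftest import NOISE_FREE, flat_bands


def tone_recording(freq=10.0, amp=1.0, duration=60.0, rate=250.0, pad=0):
    n = int(duration * rate) + pad
    t = np.arange(n) / rate
    return syn.EEGRecording(data=amp * np.sin(2 * np.pi * freq * t)[None, :],
                            rate=rate, channel_labels=["Pz"])


class TestNotchFilter:
    def test_50hz_attenuated_at_least_30db(self):
        # steady-state response to a pure 50-Hz tone (edges trimmed:
        # boundary leakage of the finite segment is not filter gain)
        rec = tone_recording(50.0, duration=60.0)
        out = efp.notch_filter(rec.pz, 250.0)[500:-500]
        rms_in = np.sqrt(np.mean(rec.pz**2))
        assert np.sqrt(np.mean(out**2)) <= 0.032 * rms_in

    def test_frequency_response_oracle(self):
        from scipy import signal as sps
        b, a = sps.iirnotch(50.0, 40.0, fs=250.0)
        w, h = sps.freqz(b, a, worN=16384, fs=250.0)
        gain2 = np.abs(h) ** 2  # forward-backward amplitude gain
        assert gain2[np.argmin(np.abs(w - 50.0))] <= 0.032
        outside = (w < 48.0) | (w > 52.0)
        assert 20 * np.log10(gain2[outside].min()) > -1.0

    def test_10hz_passes_within_11_percent(self):
        rec = tone_recording(10.0, duration=12.0)
        out = efp.notch_filter(rec.pz, 250.0)
        rms_in = np.sqrt(np.mean(rec.pz**2))
        assert abs(np.sqrt(np.mean(out**2)) - rms_in) / rms_in < 0.11

    def test_passband_ripple_below_1db_outside_2hz(self):
        # steady-state gain probed on long tones at 48 and 52 Hz
        for f0 in (48.0, 52.0):
            rec = tone_recording(f0, duration=60.0)
            out = efp.notch_filter(rec.pz, 250.0)[2000:-2000]
            gain_db = 20 * np.log10(np.sqrt(np.mean(out**2))
                                    / np.sqrt(0.5))
            assert gain_db > -1.0

    def test_zero_in_zero_out(self):
        assert np.allclose(efp.notch_filter(np.zeros(3000), 250.0), 0.0)

    def test_rate_must_exceed_twice_f0(self):
        with pytest.raises(ValueError):
            efp.notch_filter(np.zeros(100), rate=90.0)


class TestEnergyUniformBands:
    def test_flat_spectrum_gives_equal_width_bands(self):
        rng = np.random.default_rng(0)
        rec = syn.EEGRecording(data=rng.standard_normal(250 * 600)[None, :],
                               rate=250.0, channel_labels=["Pz"])
        bands = efp.band_edges_energy_uniform(rec, f_range=(1.0, 41.0))
        expected = np.linspace(1.0, 41.0, 11)
        assert np.max(np.abs(bands.edges - expected)) / 40.0 < 0.01
        assert bands.uniformity_error() < 0.01

    def test_one_over_f2_spectrum_matches_analytic_quantiles(self):
        # PSD ~ 1/f^2 on [1,41]: k-th edge solves
        # 1/1 - 1/e_k = (k/10) (1/1 - 1/41)
        freqs = np.linspace(0.5, 45.0, 20000)
        psd = np.where(freqs >= 1.0, 1.0 / freqs**2, 0.0)
        bands = efp.edges_from_spectrum(freqs, psd, 10, (1.0, 41.0))
        k = np.arange(11)
        expected = 1.0 / (1.0 - (k / 10.0) * (40.0 / 41.0))
        assert np.max(np.abs(bands.edges - expected) / expected) < 0.01
        assert bands.uniformity_error() < 0.01

    def test_one_over_f2_signal_end_to_end(self):
        # realized random-phase signal through notch + Welch: the edges
        # additionally carry the spectral estimator's variance
        rng = np.random.default_rng(1)
        n = 250 * 600
        freqs = np.fft.rfftfreq(n, 1 / 250.0)
        shape = np.zeros_like(freqs)
        band = (freqs >= 1.0) & (freqs <= 41.0)
        shape[band] = 1.0 / freqs[band]  # amplitude 1/f -> power 1/f^2
        spec = shape * np.exp(2j * np.pi * rng.random(freqs.size))
        x = np.fft.irfft(spec, n)
        rec = syn.EEGRecording(data=x[None, :] / x.std(), rate=250.0,
                               channel_labels=["Pz"])
        bands = efp.band_edges_energy_uniform(rec, f_range=(1.0, 41.0))
        k = np.arange(11)
        expected = 1.0 / (1.0 - (k / 10.0) * (40.0 / 41.0))
        assert np.max(np.abs(bands.edges - expected) / expected) < 0.03

    def test_single_band_spans_range(self):
        rng = np.random.default_rng(2)
        rec = syn.EEGRecording(data=rng.standard_normal(250 * 120)[None, :],
                               rate=250.0, channel_labels=["Pz"])
        bands = efp.band_edges_energy_uniform(rec, n_bands=1, f_range=(2.0, 30.0))
        assert bands.n_bands == 1
        assert bands.edges[0] == 2.0 and bands.edges[-1] == 30.0

    def test_short_calibration_rejected(self):
        rec = tone_recording(10.0, duration=30.0)
        with pytest.raises(ValueError, match="too short"):
            efp.band_edges_energy_uniform(rec)

    def test_band_definition_invariants(self):
        with pytest.raises(ValueError):
            efp.BandDefinition(edges=np.array([1.0, 3.0, 2.0]),
                               calibration_energy=np.ones(2))


class TestFeatureExtraction:
    def test_zero_segment_zero_features(self):
        rec = syn.EEGRecording(data=np.zeros((1, 250 * 20)), rate=250.0,
                               channel_labels=["Pz"])
        fw = efp.extract_features(rec, flat_bands(), end_time=15.0)
        assert fw.values.shape == (10, 48)
        assert np.allclose(fw.values, 0.0)

    def test_in_band_sinusoid_dominates_its_row(self):
        rec = tone_recording(10.0, duration=20.0)
        fw = efp.extract_features(rec, flat_bands(), end_time=16.0)
        # 10 Hz lies in band 2 of equal-width 0.5-40 bands
        assert np.argmax(fw.values.mean(axis=1)) == 2

    def test_insufficient_history_rejected(self):
        rec = tone_recording(10.0, duration=20.0)
        with pytest.raises(ValueError, match="12-s window"):
            efp.extract_features(rec, flat_bands(), end_time=11.0)


class TestFitEFPWeights:
    def test_constant_target_gives_zero_weights(self, noisefree_calibration):
        c = noisefree_calibration
        model = efp.fit_efp_weights(c["windows"][:150], np.full(150, 3.7),
                                    c["bands"])
        assert np.max(np.abs(model.weights)) < 1e-8
        assert model.intercept == pytest.approx(3.7)

    def test_permuted_target_kills_heldout_r(self, noisefree_calibration):
        # fixed lambda so the null r is not inflated by grid selection
        c = noisefree_calibration
        rng = np.random.default_rng(0)
        permuted = rng.permutation(c["target"])
        model = efp.fit_efp_weights(c["windows"], permuted, c["bands"],
                                    lambda_grid=[1.0])
        assert abs(model.fit_report["heldout_r"]) < 0.1

    def test_known_linear_functional_recovered(self, noisefree_calibration):
        c = noisefree_calibration
        rng = np.random.default_rng(3)
        w_true = c["X"].T @ rng.standard_normal(c["X"].shape[0])
        w_true /= np.linalg.norm(w_true)
        y = c["X"] @ w_true
        model = efp.fit_efp_weights(c["windows"], y, c["bands"],
                                    lambda_grid=[1e-8])
        w_fit = model.weights.flatten()
        cosine = w_fit @ w_true / np.linalg.norm(w_fit)
        assert model.fit_report["heldout_r"] >= 0.99
        assert cosine >= 0.95

    def test_weight_signs_match_generator_couplings(self, noisefree_calibration):
        c = noisefree_calibration
        row_sums = c["model"].weights.sum(axis=1)
        for coupling in syn.EEGParams().couplings:
            k = min(int(np.searchsorted(c["bands"].edges, coupling.centre,
                                        side="right")) - 1, 9)
            assert np.sign(row_sums[k]) == np.sign(coupling.slope)

    def test_too_few_windows_rejected(self, noisefree_calibration):
        c = noisefree_calibration
        with pytest.raises(ValueError, match="at least"):
            efp.fit_efp_weights(c["windows"][:50], c["target"][:50], c["bands"])

    def test_model_json_roundtrip(self, noisefree_calibration, tmp_path):
        model = noisefree_calibration["model"]
        path = tmp_path / "model.json"
        model.to_json(path)
        back = efp.EFPModel.from_json(path)
        assert np.array_equal(back.weights, model.weights)
        assert back.intercept == model.intercept
        assert np.array_equal(back.bands.edges, model.bands.edges)
        assert back.fit_report["best_lambda"] == model.fit_report["best_lambda"]


class TestPredictEFP:
    def make_model(self):
        rng = np.random.default_rng(4)
        return efp.EFPModel(bands=flat_bands(),
                            weights=rng.standard_normal((10, 48)) * 0.01,
                            intercept=0.5, ridge_lambda=1.0)

    def test_zero_weights_constant_intercept(self):
        model = efp.EFPModel(bands=flat_bands(), weights=np.zeros((10, 48)),
                             intercept=2.0, ridge_lambda=1.0)
        rec = tone_recording(10.0, duration=40.0)
        series = efp.predict_efp(model, rec, times=[15.0, 18.0, 21.0])
        assert np.allclose(series.values, 2.0)

    def test_causality_future_samples_do_not_matter(self):
        model = self.make_model()
        lat = syn.generate_latent_arousal(syn.OUParams(duration=40.0), seed=8)
        rec = syn.synthesize_eeg(lat, seed=9)
        series = efp.predict_efp(model, rec, times=[15.0, 18.0, 21.0])
        tampered = syn.EEGRecording(data=rec.data.copy(), rate=rec.rate,
                                    channel_labels=list(rec.channel_labels))
        tampered.data[0, int(21.0 * rec.rate):] = 999.0
        series2 = efp.predict_efp(model, tampered, times=[15.0, 18.0, 21.0])
        assert np.array_equal(series.values, series2.values)

    def test_missing_history_flagged_not_silent(self):
        model = self.make_model()
        rec = tone_recording(10.0, duration=30.0)
        series = efp.predict_efp(model, rec, times=[9.0, 12.0, 15.0])
        assert not series.valid[0] and np.isnan(series.values[0])
        assert series.valid[1] and series.valid[2]

    def test_one_sample_jitter_robustness(self):
        # magnitude features of a stationary tone are phase-invariant
        model = self.make_model()
        rec = tone_recording(10.0, duration=40.0, pad=1)
        shifted = syn.EEGRecording(data=rec.data[:, 1:], rate=rec.rate,
                                   channel_labels=["Pz"])
        base = syn.EEGRecording(data=rec.data[:, :-1], rate=rec.rate,
                                channel_labels=["Pz"])
        a = efp.predict_efp(model, base, times=[20.0, 23.0])
        b = efp.predict_efp(model, shifted, times=[20.0, 23.0])
        assert np.max(np.abs(a.values - b.values)) < 1e-6 * np.max(np.abs(a.values))

    def test_heldout_prediction_tracks_lagged_latent(self, default_calibration):
        # fit on the first half of the calibration run, evaluate on the
        # second half of the same recording
        c = default_calibration
        n = len(c["windows"])
        half = n // 2
        model = efp.fit_efp_weights(c["windows"][:half], c["target"][:half],
                                    c["bands"])
        times = c["times"][half:]
        pred = efp.predict_efp(model, c["rec"], times=times)
        r = np.corrcoef(pred.values, c["target"][half:])[0, 1]
        assert r >= 0.6
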