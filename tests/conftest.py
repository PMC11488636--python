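import numpy as np
import pytest
from hypothesis import settings

from efpnf import efp, nf, synthetic as syn

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

NOISE_FREE = syn.EEGParams(pink_amp=0.0, line_amp=0.0, white_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_calibration():
    """Noise-free simultaneous EEG/latent calibration set (25 min).

    Long enough (>480 windows) that the 480-dimensional feature map is
    fully determined, enabling exact weight recovery checks.
    """
    latent = syn.generate_latent_arousal(syn.OUParams(duration=1500.0), seed=21)
    rec = syn.synthesize_eeg(latent, NOISE_FREE, seed=22)
    bands = efp.band_edges_energy_uniform(rec)
    windows = efp.calibration_windows(rec, bands)
    times = np.array([w.end_time for w in windows])
    target = syn.hrf_lagged_latent(latent, times)
    X = np.stack([w.values.flatten() for w in windows])
    model = efp.fit_efp_weights(windows, target, bands)
    return {"latent": latent, "rec": rec, "bands": bands, "windows": windows,
            "times": times, "target": target, "X": X, "model": model}


@pytest.fixture(scope="session")
def default_calibration():
    """Default-SNR calibration set (20 min) with a fitted model."""
    latent = syn.generate_latent_arousal(syn.OUParams(duration=1200.0), seed=31)
    rec = syn.synthesize_eeg(latent, seed=32)
    bands = efp.band_edges_energy_uniform(rec)
    windows = efp.calibration_windows(rec, bands)
    times = np.array([w.end_time for w in windows])
    target = syn.hrf_lagged_latent(latent, times)
    model = efp.fit_efp_weights(windows, target, bands)
    return {"latent": latent, "rec": rec, "bands": bands, "windows": windows,
            "times": times, "target": target, "model": model}


@pytest.fixture(scope="session")
def skilled_session(noisefree_calibration):
    """One closed-loop training session of a skilled noise-free agent."""
    agent = syn.AgentParams(noise_sd=0.0)
    sched = nf.build_schedule("efp_nf")
    record = nf.run_closed_loop_session(
        agent, noisefree_calibration["model"], sched, session_index=1,
        seed=5, eeg_params=NOISE_FREE)
    return record


def flat_bands(n_bands: int = 10, f_lo: float = 0.5, f_hi: float = 40.0):
    """Equal-width band definition, for tests that need fixed bands."""
    edges = np.linspace(f_lo, f_hi, n_bands + 1)
    return efp.BandDefinition(edges=edges, calibration_energy=np.ones(n_bands))
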