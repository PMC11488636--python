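"""Synthetic ground-truth generators for the EFP-NF pipeline.

Everything downstream of this module (feature extraction, model fitting,
closed-loop simulation, trial statistics) is testable without access to
the original recordings.  A latent "arousal" process stands in for
amygdala activity; it drives a BOLD time course through the canonical
HRF and modulates the band-limited amplitude of a synthetic Pz EEG
channel.  A simple regulating agent lowers the latent level during
Regulate blocks and improves over sessions, and a cohort generator draws
clinical score trajectories around configurable group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import canonical_hrf
from . import published

# --------------------------------------------------------------------------
# domain types


@dataclass
class LatentSeries:
    """Latent arousal sampled on a uniform grid (arbitrary zero-mean units)."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.values.size < 1:
            raise ValueError("latent series must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent series contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    def at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the latent path at arbitrary times."""
        return np.interp(times, self.times, self.values)


@dataclass
class EEGRecording:
    """Multichannel EEG (µV) with condition markers.

    ``markers`` is a list of ``(time_s, label)`` pairs sorted by time.
    """

    data: np.ndarray
    rate: float
    channel_labels: list
    markers: list = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if "Pz" not in self.channel_labels:
            raise ValueError("recording must contain a Pz channel")
        dur = self.data.shape[1] / self.rate
        times = [t for t, _ in self.markers]
        if times != sorted(times):
            raise ValueError("markers must be sorted by time")
        if any(t < 0 or t > dur for t in times):
            raise ValueError("marker outside record duration")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    @property
    def pz(self) -> np.ndarray:
        return self.channel("Pz")


@dataclass
class BOLDSeries:
    """Single-ROI BOLD time course (arbitrary units) at repetition time ``tr``."""

    values: np.ndarray
    tr: float
    onset: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD series contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.onset + np.arange(self.values.size) * self.tr


@dataclass
class AgentParams:
    """Behaviour of a simulated down-regulating participant.

    The latent level relaxes toward ``baseline_arousal`` with time
    constant ``relax_tau`` (s); during Regulate an extra downward drift
    of ``regulate_gain`` units/s applies, scaled by
    ``1 + learning_rate * (session_index - 1)`` so regulation deepens
    over the 10-session course.
    """

    baseline_arousal: float = 0.0
    regulate_gain: float = 0.1
    learning_rate: float = 0.2
    noise_sd: float = 0.1
    relax_tau: float = 15.0

    def __post_init__(self):
        if self.regulate_gain < 0:
            raise ValueError("regulate_gain must be >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.relax_tau <= 0:
            raise ValueError("relax_tau must be > 0")

    def session_gain(self, session_index: int) -> float:
        return self.regulate_gain * (1.0 + self.learning_rate * (session_index - 1))


# --------------------------------------------------------------------------
# latent arousal (Ornstein-Uhlenbeck)


@dataclass
class OUParams:
    """Mean-reverting (Ornstein-Uhlenbeck) process specification."""

    theta: float = 0.25
    sigma: float = 0.5
    mean: float = 0.0
    rate: float = 4.0
    duration: float = 300.0


def generate_latent_arousal(params: OUParams, seed=None) -> LatentSeries:
    """Draw a stationary OU path at ``params.rate`` samples/s.

    Uses the exact transition density, so the discretization is unbiased
    at any rate; the initial value is drawn from the stationary law
    N(mean, sigma^2 / (2 theta)).
    """
    if params.theta <= 0:
        raise ValueError("theta must be > 0")
    if params.sigma < 0:
        raise ValueError("sigma must be >= 0")
    if params.duration <= 0 or params.rate <= 0:
        raise ValueError("duration and rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * params.rate))
    dt = 1.0 / params.rate
    a = math.exp(-params.theta * dt)
    stat_sd = params.sigma / math.sqrt(2.0 * params.theta)
    step_sd = stat_sd * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    innov = rng.standard_normal(n)
    x[0] = params.mean + stat_sd * innov[0]
    for i in range(1, n):
        x[i] = params.mean + a * (x[i - 1] - params.mean) + step_sd * innov[i]
    return LatentSeries(values=x, rate=params.rate)


# --------------------------------------------------------------------------
# EEG synthesis


@dataclass
class BandCoupling:
    """One oscillatory component: carrier within (f_lo, f_hi) whose
    instantaneous amplitude is ``base_amp + slope * latent`` (µV)."""

    f_lo: float
    f_hi: float
    base_amp: float
    slope: float

    @property
    def centre(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


@dataclass
class EEGParams:
    """Synthesis parameters for the Pz channel.

    Defaults couple the latent positively to a theta-band (4-8 Hz)
    component and negatively to a beta-band (13-30 Hz) component, on top
    of 1/f background, 50-Hz line interference, and white sensor noise.
    The EFP learner is never told these signs.
    """

    couplings: tuple = (
        BandCoupling(4.0, 8.0, 2.0, 0.8),
        BandCoupling(13.0, 30.0, 1.5, -0.5),
    )
    pink_amp: float = 1.0
    line_amp: float = 1.0
    line_freq: float = 50.0
    white_sd: float = 0.5
    rate: float = 250.0


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f (power) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def synthesize_eeg(
    latent: LatentSeries,
    eeg_params: EEGParams | None = None,
    seed=None,
    markers: list | None = None,
    extra_channels: tuple = (),
) -> EEGRecording:
    """Render a Pz EEG channel driven by the latent arousal path.

    Pz = sum of amplitude-modulated band carriers + pink background +
    line sinusoid + white noise.  Carrier phases are seeded; the true
    couplings are recorded in ``ground_truth``.  ``extra_channels`` adds
    pure-noise channels with standard 10/20 labels.
    """
    p = eeg_params or EEGParams()
    nyq = p.rate / 2.0
    for c in p.couplings:
        if not (0.0 < c.f_lo < c.f_hi < nyq):
            raise ValueError(f"coupling band ({c.f_lo}, {c.f_hi}) outside (0, Nyquist)")
    rng = np.random.default_rng(seed)
    n = int(round(latent.duration * p.rate))
    t = np.arange(n) / p.rate + latent.t0
    lat = latent.at(t)
    sig = np.zeros(n)
    phases = rng.uniform(0, 2 * np.pi, size=len(p.couplings))
    for c, phi in zip(p.couplings, phases):
        amp = np.clip(c.base_amp + c.slope * lat, 0.0, None)
        sig += amp * np.sin(2 * np.pi * c.centre * t + phi)
    if p.pink_amp > 0:
        sig += p.pink_amp * _pink_noise(n, rng)
    if p.line_amp > 0:
        sig += p.line_amp * np.sin(2 * np.pi * p.line_freq * t + rng.uniform(0, 2 * np.pi))
    if p.white_sd > 0:
        sig += p.white_sd * rng.standard_normal(n)
    labels = ["Pz"] + list(extra_channels)
    data = np.zeros((len(labels), n))
    data[0] = sig
    for i in range(1, len(labels)):
        data[i] = rng.standard_normal(n)
    gt = {
        "couplings": [
            {"f_lo": c.f_lo, "f_hi": c.f_hi, "base_amp": c.base_amp, "slope": c.slope}
            for c in p.couplings
        ],
        "carrier_phases": phases.tolist(),
        "pink_amp": p.pink_amp,
        "line_amp": p.line_amp,
        "line_freq": p.line_freq,
        "white_sd": p.white_sd,
    }
    return EEGRecording(
        data=data,
        rate=p.rate,
        channel_labels=labels,
        markers=list(markers or []),
        ground_truth=gt,
    )


# --------------------------------------------------------------------------
# BOLD synthesis


def synthesize_bold(
    latent: LatentSeries,
    tr: float = 3.0,
    noise_sd: float = 0.0,
    seed=None,
    hrf_duration: float = 32.0,
) -> BOLDSeries:
    """Convolve the latent path with the canonical HRF and sample at ``tr``.

    The convolution is discrete at the latent rate with a peak-normalized
    kernel, so a unit-impulse latent reproduces the kernel samples.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    kernel = canonical_hrf(1.0 / latent.rate, hrf_duration)
    conv = np.convolve(latent.values, kernel)[: latent.values.size]
    conv_times = latent.times
    times = np.arange(latent.t0, latent.t0 + latent.duration, tr)
    vals = np.interp(times, conv_times, conv)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + noise_sd * rng.standard_normal(vals.size)
    return BOLDSeries(values=vals, tr=tr, onset=latent.t0)


def hrf_lagged_latent(latent: LatentSeries, times: np.ndarray) -> np.ndarray:
    """HRF-convolved latent evaluated at arbitrary times (the regression
    target used when fitting EFP weights)."""
    bold = synthesize_bold(latent, tr=1.0 / latent.rate, noise_sd=0.0)
    return np.interp(times, bold.times, bold.values)


# --------------------------------------------------------------------------
# regulating agent


class AgentState:
    """Incremental integrator of the agent dynamics (Euler-Maruyama).

    The closed-loop engine advances this state in 3-s chunks and can
    scale the regulate drift by a feedback-derived multiplier.
    """

    def __init__(self, agent: AgentParams, session_index: int, rng: np.random.Generator,
                 rate: float = 4.0):
        if session_index < 1:
            raise ValueError("session_index must be >= 1")
        self.agent = agent
        self.gain = agent.session_gain(session_index)
        self.rng = rng
        self.rate = rate
        self.x = agent.baseline_arousal

    def advance(self, duration: float, regulating: bool, gain_multiplier: float = 1.0
                ) -> np.ndarray:
        """Advance by ``duration`` seconds; returns the new samples."""
        n = int(round(duration * self.rate))
        dt = 1.0 / self.rate
        sqdt = math.sqrt(dt)
        drift_extra = -self.gain * gain_multiplier if regulating else 0.0
        out = np.empty(n)
        noise = (self.agent.noise_sd * sqdt * self.rng.standard_normal(n)
                 if self.agent.noise_sd > 0 else np.zeros(n))
        x = self.x
        base = self.agent.baseline_arousal
        tau = self.agent.relax_tau
        for i in range(n):
            x = x + (-(x - base) / tau + drift_extra) * dt + noise[i]
            out[i] = x
        self.x = x
        return out


def simulate_regulating_agent(
    agent: AgentParams,
    schedule,
    session_index: int,
    seed=None,
    rate: float = 4.0,
) -> LatentSeries:
    """Open-loop latent path for one session under a block schedule.

    ``schedule`` needs only a ``blocks`` attribute of ``(label, onset,
    duration)`` tuples.  The path drifts down during Regulate and relaxes
    to baseline otherwise; with ``noise_sd=0`` it is piecewise
    deterministic.
    """
    blocks = list(schedule.blocks)
    if not any(label == "Regulate" for label, _, _ in blocks):
        raise ValueError("schedule contains no Regulate blocks")
    rng = np.random.default_rng(seed)
    state = AgentState(agent, session_index, rng, rate=rate)
    chunks = []
    for label, onset, duration in blocks:
        chunks.append(state.advance(duration, regulating=(label == "Regulate")))
    return LatentSeries(values=np.concatenate(chunks), rate=rate, t0=blocks[0][1])


# --------------------------------------------------------------------------
# clinical cohort


def _default_deltas() -> dict:
    """Per-timepoint mean changes from pre, per group and instrument.

    CAPS-5 post changes reproduce the printed point reductions; PCL-5
    trajectories interpolate between the printed pre and 6-month group
    means; DES-II follows a similar modest decline in the test group.
    """
    pcl_test_total = published.PCL5_6M["test"] - published.PRE_MEANS["test"]["PCL5"]
    pcl_ctrl_total = published.PCL5_6M["control"] - published.PRE_MEANS["control"]["PCL5"]
    return {
        "test": {
            "CAPS5": {"post": -published.REDUCTION_CAPS5["test"]},
            "PCL5": {
                "post": 0.25 * pcl_test_total,
                "m1": 0.5 * pcl_test_total,
                "m3": 0.75 * pcl_test_total,
                "m6": pcl_test_total,
            },
            "DES2": {"post": -1.5, "m1": -3.0, "m3": -4.5, "m6": -6.0},
        },
        "control": {
            "CAPS5": {"post": -published.REDUCTION_CAPS5["control"]},
            "PCL5": {
                "post": 0.25 * pcl_ctrl_total,
                "m1": 0.5 * pcl_ctrl_total,
                "m3": 0.75 * pcl_ctrl_total,
                "m6": pcl_ctrl_total,
            },
            "DES2": {"post": 0.0, "m1": 0.0, "m3": 0.0, "m6": 0.0},
        },
    }


@dataclass
class CohortParams:
    """Synthetic trial cohort specification, calibrated by default to the
    printed group sizes, baseline means/SDs and outcome trajectories."""

    n_test: int = published.N_TEST
    n_control: int = published.N_CONTROL
    pre_means: dict = field(default_factory=lambda: {
        g: dict(published.PRE_MEANS[g]) for g in published.GROUPS})
    pre_sds: dict = field(default_factory=lambda: {
        g: dict(published.PRE_SDS[g]) for g in published.GROUPS})
    deltas: dict = field(default_factory=_default_deltas)
    diagnosis_loss_probs: dict = field(default_factory=lambda: {"test": 0.40, "control": 0.15})
    dropout_probs: dict = field(default_factory=lambda: {
        "pre": 0.0, "post": 0.025, "m1": 0.30, "m3": 0.35, "m6": 0.50})
    icc: float = 0.6
    seed: int | None = None

    def __post_init__(self):
        if self.n_test <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        for g in self.pre_sds:
            for v in self.pre_sds[g].values():
                if v <= 0:
                    raise ValueError("pre SDs must be positive")
        for p in list(self.diagnosis_loss_probs.values()) + list(self.dropout_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")


def generate_clinical_cohort(params: CohortParams | None = None, seed=None
                             ) -> tuple[pd.DataFrame, dict]:
    """Draw a long-format clinical table over the five assessments.

    Scores are Gaussian around group trajectory means with a subject
    random intercept (variance fraction ``icc`` of the instrument's
    baseline variance), clipped to instrument ranges.  Missingness is
    independent per timepoint (missing at random); the pre assessment is
    never missing.  Returns ``(table, ground_truth)``.
    """
    p = params or CohortParams()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    rows = []
    subjects = [("T%03d" % i, "test") for i in range(p.n_test)] + [
        ("C%03d" % i, "control") for i in range(p.n_control)]
    for sid, group in subjects:
        dropout = {tp: rng.random() < p.dropout_probs.get(tp, 0.0)
                   for tp in published.TIMEPOINTS}
        dropout["pre"] = False
        lost_diag = rng.random() < p.diagnosis_loss_probs[group]
        for instrument in published.INSTRUMENTS:
            sd = p.pre_sds[group][instrument]
            sd_b = sd * math.sqrt(p.icc)
            sd_w = sd * math.sqrt(1.0 - p.icc)
            u = sd_b * rng.standard_normal()
            lo, hi = published.SCORE_RANGES[instrument]
            for tp in published.TIMEPOINTS:
                delta = p.deltas[group][instrument].get(tp, 0.0) if tp != "pre" else 0.0
                mu = p.pre_means[group][instrument] + delta
                score = float(np.clip(mu + u + sd_w * rng.standard_normal(), lo, hi))
                if dropout[tp]:
                    continue
                rows.append({
                    "subject_id": sid,
                    "group": group,
                    "timepoint": tp,
                    "instrument": instrument,
                    "score": round(score, 2),
                    "diagnosis": (True if tp == "pre"
                                  else (not lost_diag) if tp == "post" else None),
                })
    table = pd.DataFrame(rows)
    expected_arr = p.diagnosis_loss_probs["test"] - p.diagnosis_loss_probs["control"]
    truth = {
        "n_test": p.n_test,
        "n_control": p.n_control,
        "pre_means": p.pre_means,
        "pre_sds": p.pre_sds,
        "deltas": p.deltas,
        "diagnosis_loss_probs": p.diagnosis_loss_probs,
        "dropout_probs": p.dropout_probs,
        "icc": p.icc,
        "expected_arr": expected_arr,
        "expected_nnt": (1.0 / expected_arr) if expected_arr > 0 else None,
    }
    return table, truth


__all__ = [
    "LatentSeries", "EEGRecording", "BOLDSeries", "AgentParams", "OUParams",
    "BandCoupling", "EEGParams", "CohortParams", "AgentState",
    "generate_latent_arousal", "synthesize_eeg", "synthesize_bold",
    "hrf_lagged_latent", "simulate_regulating_agent", "generate_clinical_cohort",
]
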