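"""Closed-loop neurofeedback engine.

Implements the two block protocols (10-session EEG-EFP training and the
pre/post rt-fMRI assessment), the online normalization of each Regulate
sample against the preceding Watch block, the 1-10 feedback mapping
driving the audiovisual scene, the closed loop coupling feedback back to
the simulated agent, and the offline regulation success indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .efp import EFPModel, EFPSampleSeries, extract_features, WINDOW_SECONDS
from .synthetic import AgentParams, AgentState, EEGParams, EEGRecording, _pink_noise

SAMPLE_STEP = 3.0  # one EFP sample every 3 s

# Degenerate-baseline floor: a Watch SD this far below the signal scale is
# treated as zero variance (flagged).  When the condition means agree on
# the same scale the success index is exactly 0 (no modulation); a real
# mean shift over a flat baseline keeps its (large) signed ratio.
_DEGENERATE_REL_SD = 1e-5



def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)

# --------------------------------------------------------------------------
# schedules


@dataclass
class Schedule:
    """Ordered block layout of one session."""

    blocks: list  # (label, onset_s, duration_s)
    protocol_name: str

    def __post_init__(self):
        prev_end = None
        for label, onset, duration in self.blocks:
            if duration <= 0:
                raise ValueError(f"non-positive duration for block {label}")
            if prev_end is not None and onset < prev_end - 1e-9:
                raise ValueError("blocks overlap or onsets decrease")
            prev_end = onset + duration

    @property
    def duration(self) -> float:
        label, onset, dur = self.blocks[-1]
        return onset + dur

    def label_at(self, t: float) -> str | None:
        """Block label at time ``t`` (half-open intervals), or None."""
        for label, onset, duration in self.blocks:
            if onset < t <= onset + duration:
                return label
        return None

    def blocks_of(self, label: str) -> list:
        return [b for b in self.blocks if b[0] == label]


def build_schedule(protocol: str) -> Schedule:
    """The exact block sequences of the two NF protocols.

    ``efp_nf``: Rest 180 s then 5 cycles of [Watch 60 s, Regulate 180 s]
    (total 1380 s).  ``fmri_nf``: Rest 54 s then 2 cycles of [Watch 60 s,
    Regulate 60 s, Washout 9 s, Fixation 15 s] (total 342 s).
    """
    blocks = []
    t = 0.0
    if protocol == "efp_nf":
        blocks.append(("Rest", t, 180.0)); t += 180.0
        for _ in range(5):
            blocks.append(("Watch", t, 60.0)); t += 60.0
            blocks.append(("Regulate", t, 180.0)); t += 180.0
    elif protocol == "fmri_nf":
        blocks.append(("Rest", t, 54.0)); t += 54.0
        for _ in range(2):
            blocks.append(("Watch", t, 60.0)); t += 60.0
            blocks.append(("Regulate", t, 60.0)); t += 60.0
            blocks.append(("Washout", t, 9.0)); t += 9.0
            blocks.append(("Fixation", t, 15.0)); t += 15.0
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return Schedule(blocks=blocks, protocol_name=protocol)


# --------------------------------------------------------------------------
# online normalization and feedback mapping


@dataclass
class ZScore:
    """Standardized EFP sample; ``degenerate`` marks a zero-SD baseline."""

    value: float
    degenerate: bool = False


def z_normalize(efp_sample: float, watch_samples) -> ZScore:
    """Z = (sample - mean(Watch)) / sd(Watch), sample (n-1) SD.

    The Watch samples are those of the immediately preceding Watch block.
    """
    watch = np.asarray(watch_samples, dtype=float)
    if watch.size < 2:
        raise ValueError("need at least 2 Watch samples to normalize")
    mu = watch.mean()
    sd = watch.std(ddof=1)
    if sd <= _DEGENERATE_REL_SD * max(1.0, abs(mu)):
        return ZScore(value=float("nan"), degenerate=True)
    return ZScore(value=float((efp_sample - mu) / sd))


@dataclass
class FeedbackLevel:
    """Scene agitation level, 1 (calm; avatars seated) to 10 (maximal)."""

    level: int

    def __post_init__(self):
        if not 1 <= self.level <= 10:
            raise ValueError("feedback level must lie in 1..10")


def map_feedback(z: ZScore) -> FeedbackLevel:
    """Map a Z score onto the 1-10 scene scale.

    level = clamp(round_half_up(5.5 + 2 Z), 1, 10): the mapping is
    monotone in Z, centred at mid-scale, and +-2.25 SD spans the full
    range.  A degenerate Z maps to mid-scale.
    """
    if z.degenerate or not math.isfinite(z.value):
        return FeedbackLevel(level=6)
    raw = 5.5 + 2.0 * z.value
    level = int(math.floor(raw + 0.5))  # round half up
    return FeedbackLevel(level=min(10, max(1, level)))


# --------------------------------------------------------------------------
# success indices


def success_index(regulate_samples, watch_samples, return_flag: bool = False):
    """Regulation success: (mean(Regulate) - mean(Watch)) / sd(Watch).

    Negative values indicate down-regulation.  A (numerically) zero
    Watch SD is flagged degenerate; if the condition means also agree
    the index is 0 (no modulation), otherwise NaN.
    """
    reg = np.asarray(regulate_samples, dtype=float)
    watch = np.asarray(watch_samples, dtype=float)
    if reg.size < 2 or watch.size < 2:
        raise ValueError("need at least 2 samples per condition")
    mu_w = watch.mean()
    sd_w = watch.std(ddof=1)
    scale = max(1.0, abs(mu_w))
    diff = reg.mean() - mu_w
    if sd_w <= _DEGENERATE_REL_SD * scale:
        if abs(diff) <= _DEGENERATE_REL_SD * scale:
            si = 0.0
        elif sd_w == 0.0:
            si = math.copysign(float("inf"), diff)
        else:
            si = float(diff / sd_w)
        return (si, True) if return_flag else si
    si = float(diff / sd_w)
    return (si, False) if return_flag else si


# --------------------------------------------------------------------------
# session record and closed loop


@dataclass
class SessionRecord:
    """One EFP-NF training session at the 3-s sample resolution."""

    session_index: int
    samples: EFPSampleSeries
    z_values: np.ndarray
    feedback: np.ndarray
    block_success: np.ndarray
    strategies: str = ""
    seed: object = None

    def __post_init__(self):
        self.block_success = np.asarray(self.block_success, dtype=float)
        if self.block_success.size != 5:
            raise ValueError("expected 5 block success indices")

    def to_frame(self):
        """Tidy one-row-per-sample table (time, condition, efp, z, feedback)."""
        import pandas as pd

        return pd.DataFrame({
            "time": self.samples.times,
            "condition": self.samples.condition_labels,
            "efp": self.samples.values,
            "z": self.z_values,
            "feedback": self.feedback,
        })


def session_success(record: SessionRecord) -> float:
    """Session-level modulation: mean of the 5 block success indices."""
    bs = np.asarray(record.block_success, dtype=float)
    if bs.size != 5 or np.any(np.isnan(bs)):
        raise ValueError("incomplete session record")
    return float(bs.mean())


def run_closed_loop_session(
    agent: AgentParams,
    model: EFPModel,
    schedule: Schedule,
    session_index: int,
    seed=None,
    eeg_params: EEGParams | None = None,
    return_eeg: bool = False,
):
    """Simulate one full closed-loop EFP-NF training session.

    Every 3 s the agent's latent state advances (the current feedback
    level scales the Regulate drift by ``(11 - level) / 10``, so good
    feedback sustains regulation), the Pz EEG is extended from the new
    latent samples, and the EFP is predicted causally from the 12-s
    window ending at the sample time.  Regulate samples are Z-normalized
    against the preceding Watch block and mapped to 1-10 feedback; Watch
    and Rest produce no feedback.  A fixed seed reproduces the record
    bit-identically.
    """
    if schedule.protocol_name != "efp_nf":
        raise ValueError("closed-loop training requires the efp_nf schedule")
    p = eeg_params or EEGParams()
    ss = _seed_seq(seed)
    agent_rng, eeg_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    total = schedule.duration
    rate = p.rate
    n250 = int(round(total * rate))
    t250 = np.arange(n250) / rate
    # feedback-independent noise components are drawn up front
    background = np.zeros(n250)
    if p.pink_amp > 0:
        background += p.pink_amp * _pink_noise(n250, eeg_rng)
    if p.line_amp > 0:
        background += p.line_amp * np.sin(
            2 * np.pi * p.line_freq * t250 + eeg_rng.uniform(0, 2 * np.pi))
    if p.white_sd > 0:
        background += p.white_sd * eeg_rng.standard_normal(n250)
    phases = eeg_rng.uniform(0, 2 * np.pi, size=len(p.couplings))

    state = AgentState(agent, session_index, agent_rng)
    lat_rate = state.rate
    latent_nodes = [agent.baseline_arousal]  # value at t=0
    eeg = np.zeros(n250)
    eeg_filled = 0  # samples rendered so far

    def render_until(t_end: float):
        nonlocal eeg_filled
        idx_end = int(round(t_end * rate))
        if idx_end <= eeg_filled:
            return
        sl = slice(eeg_filled, idx_end)
        tt = t250[sl]
        node_t = np.arange(len(latent_nodes)) / lat_rate
        lat = np.interp(tt, node_t, latent_nodes)
        chunk = background[sl].copy()
        for c, phi in zip(p.couplings, phases):
            amp = np.clip(c.base_amp + c.slope * lat, 0.0, None)
            chunk += amp * np.sin(2 * np.pi * c.centre * tt + phi)
        eeg[sl] = chunk
        eeg_filled = idx_end

    w_flat = model.weights.flatten()

    def predict_at(t: float) -> float:
        end_idx = int(round(t * rate))
        seg_start = end_idx - int(round(WINDOW_SECONDS * rate))
        if seg_start < 0:
            raise ValueError("insufficient history for EFP sample")
        rec = EEGRecording(data=eeg[None, :end_idx], rate=rate, channel_labels=["Pz"])
        fw = extract_features(rec, model.bands, t)
        return model.intercept + float(fw.values.flatten() @ w_flat)

    sample_times, sample_vals, sample_labels = [], [], []
    sample_z, sample_fb = [], []
    block_success = []
    watch_efps: list = []

    for label, onset, duration in schedule.blocks:
        n_steps = int(round(duration / SAMPLE_STEP))
        if label == "Watch":
            watch_efps = []
        reg_efps = []
        level = 6  # mid-scale before the first feedback of a Regulate block
        for k in range(n_steps):
            t_end = onset + (k + 1) * SAMPLE_STEP
            regulating = label == "Regulate"
            mult = (11 - level) / 10.0 if regulating else 1.0
            latent_nodes.extend(state.advance(SAMPLE_STEP, regulating, mult))
            render_until(t_end)
            if label == "Rest":
                continue
            efp_val = predict_at(t_end)
            sample_times.append(t_end)
            sample_vals.append(efp_val)
            sample_labels.append(label)
            if label == "Watch":
                watch_efps.append(efp_val)
                sample_z.append(np.nan)
                sample_fb.append(np.nan)
            elif label == "Regulate":
                z = z_normalize(efp_val, watch_efps)
                fb = map_feedback(z)
                level = fb.level
                reg_efps.append(efp_val)
                sample_z.append(z.value)
                sample_fb.append(float(fb.level))
        if label == "Regulate":
            block_success.append(success_index(reg_efps, watch_efps))

    samples = EFPSampleSeries(
        values=np.array(sample_vals),
        times=np.array(sample_times),
        condition_labels=sample_labels)
    record = SessionRecord(
        session_index=session_index,
        samples=samples,
        z_values=np.array(sample_z),
        feedback=np.array(sample_fb),
        block_success=np.array(block_success),
        seed=seed)
    if return_eeg:
        rec = EEGRecording(
            data=eeg[None, :], rate=rate, channel_labels=["Pz"],
            markers=[(onset, label) for label, onset, _ in schedule.blocks])
        return record, rec
    return record


def simulate_training_course(
    agent: AgentParams,
    n_sessions: int = 10,
    seed=None,
    rate: float = 4.0,
) -> np.ndarray:
    """Per-session (watch_mean, regulate_mean, success) for one subject.

    Runs the open-loop agent through the training schedule for each
    session and scores the latent samples on the 3-s grid directly; this
    is the light-weight route used for population-scale learning-curve
    analyses, bypassing EEG synthesis and EFP prediction.  Returns an
    (n_sessions, 3) array.
    """
    from .synthetic import simulate_regulating_agent

    schedule = build_schedule("efp_nf")
    ss = _seed_seq(seed)
    out = np.empty((n_sessions, 3))
    for s_idx, sub in enumerate(ss.spawn(n_sessions), start=1):
        lat = simulate_regulating_agent(agent, schedule, s_idx, seed=sub, rate=rate)
        sis, w_means, r_means = [], [], []
        for (_, w_on, w_dur), (_, r_on, r_dur) in zip(
                schedule.blocks_of("Watch"), schedule.blocks_of("Regulate")):
            w_t = w_on + SAMPLE_STEP * np.arange(1, int(w_dur / SAMPLE_STEP) + 1)
            r_t = r_on + SAMPLE_STEP * np.arange(1, int(r_dur / SAMPLE_STEP) + 1)
            w, r = lat.at(w_t), lat.at(r_t)
            w_means.append(w.mean())
            r_means.append(r.mean())
            sis.append(success_index(r, w))
        out[s_idx - 1] = [np.mean(w_means), np.mean(r_means), np.mean(sis)]
    return out


def simulate_session_successes(agent: AgentParams, n_sessions: int = 10,
                               seed=None, rate: float = 4.0) -> np.ndarray:
    """Per-session success indices of one simulated subject (agent level)."""
    return simulate_training_course(agent, n_sessions, seed=seed, rate=rate)[:, 2]


__all__ = [
    "Schedule", "build_schedule", "ZScore", "z_normalize", "FeedbackLevel",
    "map_feedback", "success_index", "SessionRecord", "session_success",
    "run_closed_loop_session", "simulate_session_successes",
    "simulate_training_course", "SAMPLE_STEP",
]
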