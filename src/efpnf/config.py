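"""Trial configuration: a single YAML document describing one synthetic trial.

Strictly schema-validated (unknown keys are rejected) and round-trip
serializable; the SHA-256 of the canonical YAML dump plus the seed is
embedded in every artifact for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields

import yaml

from .synthetic import AgentParams, CohortParams, EEGParams, OUParams


def _from_mapping(cls, mapping: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys under {path!r}: {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class EFPSettings:
    """Calibration and model-fit settings."""

    calibration_duration: float = 900.0
    f_lo: float = 0.5
    f_hi: float = 40.0
    n_bands: int = 10
    bold_noise_sd: float = 0.1

    def __post_init__(self):
        if self.calibration_duration < 60:
            raise ValueError("calibration_duration must be >= 60 s")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")


@dataclass
class NFSettings:
    """How much of the training course `simulate` materializes."""

    n_subjects: int = 20
    n_sessions: int = 10

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("n_subjects and n_sessions must be >= 1")


@dataclass
class TrialConfig:
    seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)
    agent: AgentParams = field(default_factory=AgentParams)
    latent: OUParams = field(default_factory=OUParams)
    eeg_noise: dict = field(default_factory=lambda: {
        "pink_amp": 1.0, "line_amp": 1.0, "white_sd": 0.5})
    efp: EFPSettings = field(default_factory=EFPSettings)
    nf: NFSettings = field(default_factory=NFSettings)

    def eeg_params(self) -> EEGParams:
        return EEGParams(**self.eeg_noise)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "TrialConfig":
        payload = dict(payload or {})
        allowed = {f.name for f in fields(cls)}
        unknown = set(payload) - allowed
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        for name, sub_cls in (("cohort", CohortParams), ("agent", AgentParams),
                              ("latent", OUParams), ("efp", EFPSettings),
                              ("nf", NFSettings)):
            if name in payload:
                kwargs[name] = _from_mapping(sub_cls, payload.pop(name), name)
        if "eeg_noise" in payload:
            noise = payload.pop("eeg_noise")
            unknown = set(noise) - {"pink_amp", "line_amp", "white_sd"}
            if unknown:
                raise ValueError(f"unknown keys under 'eeg_noise': {sorted(unknown)}")
            kwargs["eeg_noise"] = {**{"pink_amp": 1.0, "line_amp": 1.0,
                                      "white_sd": 0.5}, **noise}
        if "seed" in payload:
            kwargs["seed"] = int(payload.pop("seed"))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, source) -> "TrialConfig":
        if isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        else:
            payload = yaml.safe_load(source)
        return cls.from_dict(payload or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def provenance(self, seed=None) -> dict:
        return {"config_sha256": self.config_hash(),
                "seed": int(self.seed if seed is None else seed)}


__all__ = ["TrialConfig", "EFPSettings", "NFSettings"]
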