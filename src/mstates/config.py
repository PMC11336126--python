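"""Pipeline configuration: YAML-backed, strictly validated.

Unknown keys are rejected so typos fail loudly.  The single global ``seed``
expands to stage-specific child seeds through a documented counter scheme
(see :func:`stage_seed`), which keeps every stage reproducible when rerun
in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidArgumentError

#: Fixed stage order; the index is the stage's seed counter.
STAGES = ("synth", "preproc", "microstates", "stats", "classify")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: SeedSequence([global_seed, index])."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


def _from_dict(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InvalidArgumentError(f"unknown config keys under {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SynthConfig:
    n_channels: int = 60
    n_ad: int = 56
    n_hc: int = 38
    duration_s: float = 60.0
    sfreq: float = 500.0
    snr: float = 5.0
    osc_freq: float = 10.0
    k: int = 4
    mean_dwell: float = 0.066
    dwell_dispersion: float = 0.3
    group_dwell_shift_class: str = "C"
    group_dwell_shift_s: float = 0.006

    def validate(self) -> None:
        if min(self.duration_s, self.sfreq, self.snr, self.osc_freq,
               self.mean_dwell, self.dwell_dispersion) <= 0:
            raise InvalidArgumentError("synth: all rates/durations must be positive")


@dataclass
class PreprocConfig:
    band: tuple[float, float] = (0.1, 40.0)
    notch: tuple[float, float] = (48.0, 52.0)
    target_sfreq: float = 500.0
    epoch_s: float = 2.0
    amp_thresh: float = 100.0
    flat_thresh: float = 0.1
    neighbor_z: float = 4.0

    def validate(self) -> None:
        if min(self.amp_thresh, self.flat_thresh, self.neighbor_z,
               self.epoch_s, self.target_sfreq) <= 0:
            raise InvalidArgumentError("preproc: thresholds must be positive")
        for name in ("band", "notch"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidArgumentError(f"preproc: {name} must be ordered (low, high)")


@dataclass
class MicrostatesConfig:
    band: tuple[float, float] = (2.0, 20.0)
    k_min: int = 2
    k_max: int = 8
    gev_gain_threshold: float = 0.01
    force_k: int | None = None
    min_segment_ms: float = 0.0
    min_peak_separation: int = 0

    def validate(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise InvalidArgumentError("microstates: band must be ordered positive")
        if not 2 <= self.k_min <= self.k_max:
            raise InvalidArgumentError("microstates: need 2 <= k_min <= k_max")
        if self.gev_gain_threshold <= 0:
            raise InvalidArgumentError("microstates: gev_gain_threshold must be positive")


@dataclass
class StatsConfig:
    covariates: tuple[str, ...] = ("sex", "age", "education")
    p_enter: float = 0.05
    p_remove: float = 0.10
    correlation_metrics: tuple[str, ...] = (
        "duration_C", "duration_D", "mean_duration",
        "occurrence_B", "mean_occurrence", "tp_C_A")
    correlation_targets: tuple[str, ...] = (
        "mmse", "moca", "adl", "scwt_d", "scwt_w", "scwt_cw", "vft_s",
        "abeta42", "abeta40", "ptau181", "ttau", "nfl")
    regression_outcome: str = "abeta42"

    def validate(self) -> None:
        if not 0 < self.p_enter <= self.p_remove:
            raise InvalidArgumentError("stats: need 0 < p_enter <= p_remove")


@dataclass
class ClassifyConfig:
    test_fraction: float = 0.2
    folds: int = 5

    def validate(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise InvalidArgumentError("classify: test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise InvalidArgumentError("classify: need >= 2 folds")


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "mstates_out"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    microstates: MicrostatesConfig = field(default_factory=MicrostatesConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def validate(self) -> None:
        for section in (self.synth, self.preproc, self.microstates,
                        self.stats, self.classify):
            section.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {}
        for name, sub_cls in (("synth", SynthConfig), ("preproc", PreprocConfig),
                              ("microstates", MicrostatesConfig),
                              ("stats", StatsConfig), ("classify", ClassifyConfig)):
            sub = dict(data.pop(name, {}))
            for key, val in sub.items():
                if isinstance(val, list):
                    sub[key] = tuple(val)
            sections[name] = _from_dict(sub_cls, sub, name)
        known = {"seed", "out_dir"}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown top-level config keys: {sorted(unknown)}")
        cfg = cls(seed=data.get("seed", 1), out_dir=data.get("out_dir", "mstates_out"),
                  **sections)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)
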