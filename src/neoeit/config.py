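"""Pipeline configuration: YAML/JSON file -> validated dataclasses."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ParameterError
from .metrics import MetricsConfig
from .simulate import CohortScenario, RecordingScenario


@dataclass
class SegmentConfig:
    t_start_s: float = 3.0
    duration_s: float = 30.0
    z_limit: float = 6.0
    min_frac_within: float = 0.99
    artefact_hard_fail: bool = False
    lowpass_hz: float = 2.0
    lowpass_order: int = 8
    prominence_frac: float = 0.25


@dataclass
class SimulateConfig:
    n_subjects: int = 32
    cohort_seed_stream: int = 0
    recording: dict = field(default_factory=dict)  # RecordingScenario overrides
    cohort: dict = field(default_factory=dict)     # CohortScenario overrides


@dataclass
class ModelsConfig:
    alpha: float = 0.05
    min_events_comparison: int = 5
    min_events_screen: int = 2
    standardize: bool = False
    cross_validate: bool = False


@dataclass
class PipelineConfig:
    output_dir: str = "neoeit_out"
    input_dir: str | None = None  # recordings live here for `extract`
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    models: ModelsConfig = field(default_factory=ModelsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        try:
            sim = SimulateConfig(**d.pop("simulate", {}))
            seg = SegmentConfig(**d.pop("segment", {}))
            met = MetricsConfig(**d.pop("metrics", {}))
            mod = ModelsConfig(**d.pop("models", {}))
            return cls(simulate=sim, segment=seg, metrics=met, models=mod, **d)
        except TypeError as exc:
            raise ParameterError(f"invalid config: {exc}") from exc

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = self.metrics.as_dict()
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Filesystem locations are excluded so the same analysis written to a
        different directory stays byte-identical.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("input_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "neoeit_version": __version__,
        }

    def recording_scenario(self, **overrides) -> RecordingScenario:
        kwargs = {**self.simulate.recording, **overrides}
        return RecordingScenario(**kwargs)

    def cohort_scenario(self) -> CohortScenario:
        kwargs = dict(self.simulate.cohort)
        kwargs.setdefault("n_subjects", self.simulate.n_subjects)
        kwargs.setdefault("seed", self.seed)
        return CohortScenario(**kwargs)
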