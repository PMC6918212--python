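"""Run configuration: serializable bundle of pipeline and analysis options."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .signal import InputError, PipelineConfig


@dataclass
class RunConfig:
    """Everything a run needs: pipeline parameters, analysis options, seed.

    Round-trips losslessly through YAML (load -> save -> load identical).
    """

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    icc_model: str = "2,1"
    kappa_weights: str = "linear"
    alpha: float = 0.05
    bonferroni_m: int | None = None
    min_valid_days: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pipe = d.pop("pipeline", {})
        if isinstance(pipe, PipelineConfig):
            pipeline = pipe
        else:
            pipeline = PipelineConfig(**pipe)
        return cls(pipeline=pipeline, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def hash(self) -> str:
        """Short content hash stamped into output-file header comments."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
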