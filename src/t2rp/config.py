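"""Pipeline configuration: every fixed analysis constant in one place.

The configuration round-trips through YAML unchanged, so a saved config
fully determines a pipeline run together with its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Analysis constants of the RP T2-mapping pipeline.

    ``phantom`` configures the synthetic cohort (grid, echo times, noise,
    prevalence); the remaining fields are the analysis constants: the
    alpha/beta ratio of the EQD2 conversion, the V20 dose threshold, the
    bootstrap size, the Mann-Whitney significance level, the CT-MRI gap
    limit for segmentation eligibility and the morphology kernel sizes.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    alpha_beta_gy: float = 3.0
    v20_threshold_gy: float = 20.0
    t2_cap_ms: float = 2000.0
    min_signal: float | None = None
    n_boot: int = 5000
    alpha_stats: float = 0.05
    max_gap_days: int = 28
    dilation_px: int = 6
    erosion_px: int = 3
    seed: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        if self.v20_threshold_gy <= 0 or self.t2_cap_ms <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0 < self.alpha_stats < 1):
            raise ValueError("alpha_stats must be in (0, 1)")
        if self.dilation_px < 1 or self.erosion_px < 1:
            raise ValueError("morphology kernels must be >= 1 px")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ph = d.pop("phantom", {})
        if not isinstance(ph, PhantomConfig):
            ph = dict(ph)
            # YAML has no tuple type: restore tuple-valued fields from lists
            for f in dataclasses.fields(PhantomConfig):
                if isinstance(ph.get(f.name), list):
                    ph[f.name] = tuple(ph[f.name])
            ph = PhantomConfig(**ph)
        return cls(phantom=ph, **d)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(Path(path)) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))
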