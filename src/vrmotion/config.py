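"""Pipeline configuration with JSON round-tripping.

Defaults are the protocol's operating values: 89 Hz sampling, the
0.077 m/s speed threshold sustained for more than 0.2 s, cursor
thresholds at 25% of the calibrated excursion, 13-step feature windows
and 5-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .features import FeatureSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sample_rate_hz: float = 89.0
    convention: str = "ZXY"
    fd_scheme: str = "forward"
    omega_rule: str = "mean"
    speed_threshold: float = 0.077
    min_duration: float = 0.2
    calibration_fraction: float = 0.25
    reps_per_gesture: int = 5
    window_steps: int = 13
    n_trees: int = 100
    k_folds: int = 5
    seed: int = 0
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)

    def to_json(self) -> str:
        obj = asdict(self)
        obj["feature_spec"] = json.loads(self.feature_spec.to_json())
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        obj = json.loads(text)
        spec = obj.pop("feature_spec", None)
        config = cls(**obj)
        if spec is not None:
            config.feature_spec = FeatureSpec(
                mean_vars=tuple(spec["mean_vars"]),
                sd_vars=tuple(spec["sd_vars"]),
                corr_pairs=tuple(tuple(p) for p in spec["corr_pairs"]),
                window_steps=int(spec["window_steps"]),
            )
        return config
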