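"""Run configuration: analysis defaults in one overridable record."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .strand_coverage import DEFAULT_RC_THRESHOLDS


@dataclass
class RunConfig:
    """Defaults for the end-to-end analysis.

    bin_size : width (nt) of composition/coverage bins.
    downsample_to : target mean depth for cross-dataset comparability.
    rc_thresholds : descending relative-coverage cutoffs for the fraction table.
    threshold_multiplier / threshold_floor : detection-threshold policy
        (threshold = smallest whole percent strictly above multiplier x mean
        error, never below the floor).
    band_width : content-band width (percentage points) for bias curves.
    seed : master seed for all randomized steps.
    """

    bin_size: int = 150
    downsample_to: float = 3000.0
    rc_thresholds: tuple[float, ...] = DEFAULT_RC_THRESHOLDS
    threshold_multiplier: float = 5.0
    threshold_floor: float = 0.01
    band_width: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.rc_thresholds = tuple(float(t) for t in self.rc_thresholds)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.downsample_to <= 0:
            raise ValueError("downsample_to must be positive")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["rc_thresholds"] = list(self.rc_thresholds)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
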