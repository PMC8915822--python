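"""Study-level configuration: thresholds, scales and policies in one place.

Defaults reproduce the guideline decision rules exactly: CD86 positivity at
RFI >= 150%, CD54 at >= 200%, viability gate at CV >= 50%, DNCB control
checks strict (> 150 / > 200), 2-of-3 final prediction with optional 2-run
early stop for concordant runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .prediction_engine import AcceptanceConfig


@dataclass(frozen=True)
class StudyConfig:
    cd86_threshold: float = 150.0   # % RFI
    cd54_threshold: float = 200.0   # % RFI
    cv_gate: float = 50.0           # % viability for eligibility
    cv75_target: float = 75.0       # % viability defining CV75
    acceptance: AcceptanceConfig = field(default_factory=AcceptanceConfig)
    cv75_interp: str = "log"        # CV75 interpolation scale
    ec_interp: str = "linear"       # EC interpolation scale
    mfi_method: str = "geometric"
    dose_dilution: float = 2.0
    main_dilution: float = 1.2
    n_series_points: int = 8
    allow_early_stop: bool = False
    interference_ratio: float = 1.5
    report_ec_decimals: int = 0     # display rounding only; never fed back
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cd86_threshold", "cd54_threshold", "cv_gate",
                     "cv75_target", "interference_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cv75_interp not in ("log", "linear"):
            raise ValueError("cv75_interp must be 'log' or 'linear'")
        if self.ec_interp not in ("log", "linear"):
            raise ValueError("ec_interp must be 'log' or 'linear'")
        if self.mfi_method not in ("geometric", "arithmetic"):
            raise ValueError("mfi_method must be 'geometric' or 'arithmetic'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "acceptance" in data and isinstance(data["acceptance"], dict):
            data["acceptance"] = AcceptanceConfig(**data["acceptance"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable digest of the full configuration, carried on all outputs."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, seed=seed)
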