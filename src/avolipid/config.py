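"""Pipeline configuration with defaults matching the published parameters."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

from .synthetic import AcquisitionSettings

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; every default is the printed method value."""

    # simulation
    tissue: str = "mesocarp"
    stages: list = field(default_factory=lambda: ["unripe", "ripe"])
    replicates: int = 3
    seed: int = 1
    noise_cv: float = 0.08
    share_cv: float = 0.05
    dropout_p: float = 0.1
    db_records: int = 32
    # acquisition
    mz_min: float = 150.0
    mz_max: float = 1500.0
    scan_rate: float = 0.94
    gradient_length: float = 65.0
    acq_noise_sd: float = 0.0
    baseline_amplitude: float = 0.0
    # baseline correction
    baseline_mz_window: float = 0.01
    baseline_rt_window: float = 1.5
    baseline_quantile: float = 0.40
    # peak detection
    min_height: float = 1000.0
    detect_mz_tol: float = 0.05
    rt_min: float = 0.1
    rt_max: float = 2.5
    smoothing: float = 0.1
    similarity: float = 0.5
    # isotope grouping
    isotope_mz_tol: float = 0.001
    isotope_ppm_tol: float = 10.0
    isotope_rt_tol: float = 0.25
    max_charge: int = 2
    # alignment
    align_mz_tol: float = 0.025
    align_ppm_tol: float = 50.0
    rt_tol_before: float = 2.0
    rt_tol_after: float = 1.5
    min_inliers: float = 0.25
    inlier_threshold: float = 1.0
    # grouping
    correlation_threshold: float = 0.9
    # stats
    loading_quantile: float = 0.95
    lowess_span: float = 0.6

    def acquisition(self) -> AcquisitionSettings:
        return AcquisitionSettings(
            mz_min=self.mz_min,
            mz_max=self.mz_max,
            scan_rate=self.scan_rate,
            gradient_length=self.gradient_length,
            noise_sd=self.acq_noise_sd,
            baseline_amplitude=self.baseline_amplitude,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        config = cls()
        for key, value in overrides.items():
            old = getattr(config, key)
            if value != old:
                logger.info("config override: %s: %r -> %r", key, old, value)
            setattr(config, key, value)
        return config

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
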