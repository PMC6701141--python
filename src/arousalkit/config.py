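"""Pipeline configuration with YAML loading.

Every threshold the staging cascade and artifact rules use is exposed here;
the published analysis names only the filter passband and the band limits, so
the remaining values are this package's declared defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class FilterConfig:
    low_hz: float = 0.5
    high_hz: float = 70.0
    notch_hz: float = 50.0
    # EOG channels keep sub-0.5 Hz content so slow eye movements survive
    eog_low_hz: float = 0.1


@dataclass
class ArtifactConfig:
    pp_max_uv: float = 200.0     # peak-to-peak rejection threshold per channel
    flat_min_uv: float = 0.5     # below this peak-to-peak a channel is flat-lined


@dataclass
class PreprocessConfig:
    eog_regression: bool = False  # linear HEOG/VEOG regression instead of ICA


@dataclass
class StagingConfig:
    slow_ratio: float = 2.0          # (delta+theta)/alpha dominance for B2/3
    low_voltage_uv2: float = 10.0    # ROI-mean total power floor for B2/3
    a1_max: float = 0.5              # alpha anteriorisation ratio upper bound for A1
    a3_min: float = 1.0              # ... lower bound for A3
    sem_amp_uv: float = 30.0         # SEM deflection threshold in filtered HEOG
    sem_min_s: float = 0.5           # minimum SEM deflection duration
    alpha_fraction: float = 1.0 / 3  # calibration: fraction of median posterior alpha
    alpha_floor_uv2: float = 20.0    # calibration floor for alpha-free recordings
    min_calibration_segments: int = 30


@dataclass
class StabilityConfig:
    min_coverage_s: int = 300        # minimum valid seconds for a stability score
    min_epoch_valid: int = 45        # epochs with fewer valid seconds are skipped
    at_median: str = "stable"        # stable | unstable | drop


@dataclass
class SpectralConfig:
    zero_pad: bool = True            # pad 1-s windows to 2 s for 0.5 Hz bins
    min_windows: int = 30


@dataclass
class StatsConfig:
    welch_variance_ratio: float = 4.0  # switch to Welch when var ratio exceeds this
    fdr: bool = False                  # optional Benjamini-Hochberg correction


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    staging: StagingConfig = field(default_factory=StagingConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for section_name, values in (d or {}).items():
            if not hasattr(cfg, section_name):
                raise KeyError(f"unknown config section {section_name!r}")
            section = getattr(cfg, section_name)
            fields = {f.name for f in dataclasses.fields(section)}
            for key, val in (values or {}).items():
                if key not in fields:
                    raise KeyError(f"unknown config key {section_name}.{key}")
                setattr(section, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
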