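"""Experiment configuration: defaults, YAML loading, stable hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .scenarios import FUTURE_SCENARIOS, HISTORICAL_DECLINES, SamplingSpec

__all__ = ["ExperimentConfig", "load_config", "config_hash"]


@dataclass
class ExperimentConfig:
    """Full configuration of a simulation-experiment sweep.

    Defaults reproduce the study design: all four historical decline classes
    crossed with all four future scenarios, three dataset sizes, five end
    years, 100 replicates per cell.
    """

    historical_classes: tuple[str, ...] = tuple(HISTORICAL_DECLINES)
    future_scenarios: tuple[str, ...] = FUTURE_SCENARIOS
    sizes: tuple[int, ...] = (100, 500, 1000)
    end_years: tuple[int, ...] = (2030, 2035, 2040, 2045, 2050)
    replicates: int = 100
    master_seed: int = 42
    baseline_year: int = 1970
    intervention_year: int = 2020
    horizon_year: int = 2050
    # sampling block
    mean_series_length: float = 15.0
    fullness: float = 0.7
    obs_noise_sd: float = 0.1
    populations_per_species: int = 1
    degrade: bool = True
    # engine block
    smoothing: str = "auto"
    n_boot: int = 1000
    # inference block
    grid_first: int = 2010
    grid_last: int = 2045
    scan_structure: str = "intercepts"
    final_structure: str = "slopes"

    def __post_init__(self) -> None:
        self.historical_classes = tuple(self.historical_classes)
        self.future_scenarios = tuple(self.future_scenarios)
        self.sizes = tuple(int(s) for s in self.sizes)
        self.end_years = tuple(int(y) for y in self.end_years)
        unknown_h = set(self.historical_classes) - set(HISTORICAL_DECLINES)
        unknown_f = set(self.future_scenarios) - set(FUTURE_SCENARIOS)
        if unknown_h:
            raise ValueError(f"unknown historical classes: {sorted(unknown_h)}")
        if unknown_f:
            raise ValueError(f"unknown future scenarios: {sorted(unknown_f)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def sampling_spec(self, seed: int) -> SamplingSpec:
        return SamplingSpec(
            mean_series_length=self.mean_series_length,
            fullness=self.fullness,
            obs_noise_sd=self.obs_noise_sd,
            populations_per_species=self.populations_per_species,
            seed=seed,
        )


def load_config(path: str | Path | None = None, **overrides) -> ExperimentConfig:
    """Config from a YAML file (flat keys) with keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**values)


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the full configuration, for output provenance."""
    canonical = yaml.safe_dump(asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
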