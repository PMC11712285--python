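"""Scenario trajectories and synthetic population time series.

The simulation design crosses four historical decline classes (the fraction of
abundance lost between the baseline year and the intervention year) with four
future scenarios (what the trend does after the intervention).  Every scenario
trajectory is piecewise log-linear with at most one slope change, at the
intervention year.  Populations track the trajectory multiplicatively with
lognormal observation error, and monitoring imperfection is imposed afterwards
by subsampling each series to a random span and random within-span coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HISTORICAL_DECLINES",
    "FUTURE_SCENARIOS",
    "ScenarioSpec",
    "Trajectory",
    "SamplingSpec",
    "PopulationSeries",
    "build_trajectory",
    "simulate_populations",
    "degrade_sampling",
]

#: Decline fraction D between baseline and intervention year, by class.
HISTORICAL_DECLINES: dict[str, float] = {
    "extreme": 0.95,
    "strong": 0.70,
    "moderate": 0.50,
    "small": 0.20,
}

#: Recognised post-intervention scenarios.
FUTURE_SCENARIOS: tuple[str, ...] = (
    "bau",
    "stabilization",
    "partial_recovery",
    "recovery",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One historical-decline x future-scenario combination.

    Parameters
    ----------
    historical_class
        One of ``extreme`` (-95%), ``strong`` (-70%), ``moderate`` (-50%) or
        ``small`` (-20%): the proportional decline between ``baseline_year``
        and ``intervention_year``.
    future_scenario
        ``bau`` (the historical slope continues), ``stabilization`` (flat),
        ``partial_recovery`` (half of the log10 deficit restored by
        ``horizon_year``) or ``recovery`` (full return to baseline by
        ``horizon_year``).
    """

    historical_class: str
    future_scenario: str
    baseline_year: int = 1970
    intervention_year: int = 2020
    horizon_year: int = 2050

    def __post_init__(self) -> None:
        if self.historical_class not in HISTORICAL_DECLINES:
            raise ValueError(
                f"unknown historical_class {self.historical_class!r}; "
                f"expected one of {sorted(HISTORICAL_DECLINES)}"
            )
        if self.future_scenario not in FUTURE_SCENARIOS:
            raise ValueError(
                f"unknown future_scenario {self.future_scenario!r}; "
                f"expected one of {list(FUTURE_SCENARIOS)}"
            )
        if not (self.baseline_year < self.intervention_year < self.horizon_year):
            raise ValueError(
                "require baseline_year < intervention_year < horizon_year, got "
                f"{self.baseline_year}, {self.intervention_year}, {self.horizon_year}"
            )

    @property
    def decline_fraction(self) -> float:
        """Fraction of the index lost over the historical period (D)."""
        return HISTORICAL_DECLINES[self.historical_class]

    @property
    def slope_pre(self) -> float:
        """Historical log10-index slope per year (negative)."""
        span = self.intervention_year - self.baseline_year
        return math.log10(1.0 - self.decline_fraction) / span

    @property
    def slope_post(self) -> float:
        """Post-intervention log10-index slope per year."""
        deficit = -math.log10(1.0 - self.decline_fraction)
        span = self.horizon_year - self.intervention_year
        if self.future_scenario == "bau":
            return self.slope_pre
        if self.future_scenario == "stabilization":
            return 0.0
        if self.future_scenario == "partial_recovery":
            return 0.5 * deficit / span
        return deficit / span  # recovery


@dataclass(frozen=True)
class Trajectory:
    """Deterministic index trajectory, value 1.0 at the baseline year."""

    years: np.ndarray
    values: np.ndarray
    intervention_year: int

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.shape != values.shape:
            raise ValueError("years and values must have equal length")
        if np.any(np.diff(years) != 1):
            raise ValueError("trajectory years must be consecutive")
        if np.any(values <= 0):
            raise ValueError("trajectory values must be strictly positive")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def value_at(self, year: int) -> float:
        idx = int(year) - int(self.years[0])
        if not 0 <= idx < len(self.years):
            raise KeyError(f"year {year} outside trajectory range")
        return float(self.values[idx])

    def truncate(self, end_year: int) -> "Trajectory":
        """Trajectory restricted to years <= ``end_year``."""
        keep = self.years <= end_year
        if keep.sum() < 2:
            raise ValueError(f"end_year {end_year} leaves fewer than 2 years")
        return Trajectory(self.years[keep], self.values[keep], self.intervention_year)


@dataclass(frozen=True)
class SamplingSpec:
    """Observation-error and monitoring-imperfection parameters.

    ``obs_noise_sd`` is the standard deviation of multiplicative observation
    error on the log10 scale.  ``mean_series_length`` is the mean of the
    geometric distribution the observed span of each degraded series is drawn
    from; ``fullness`` is the probability that any year inside the span is
    actually observed.  Set ``mean_series_length=math.inf`` to force full
    spans (with ``fullness=1`` degradation is then the identity).
    """

    mean_series_length: float = 15.0
    fullness: float = 0.7
    obs_noise_sd: float = 0.1
    populations_per_species: int = 1
    seed: int = 0
    base_log10_mean: float = 2.0
    base_log10_sd: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fullness <= 1.0):
            raise ValueError("fullness must lie in (0, 1]")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be non-negative")
        if self.populations_per_species < 1:
            raise ValueError("populations_per_species must be >= 1")


@dataclass
class PopulationSeries:
    """One population's abundance record: observed years and abundances."""

    population_id: str
    species_id: str
    years: np.ndarray
    abundance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        abundance = np.asarray(self.abundance, dtype=float)
        if years.ndim != 1 or years.shape != abundance.shape:
            raise ValueError("years and abundance must be 1-D and equal length")
        if len(years) < 2:
            raise ValueError(
                f"series {self.population_id!r} has {len(years)} observation(s); need >= 2"
            )
        if np.any(np.diff(years) <= 0):
            raise ValueError(f"series {self.population_id!r}: years must strictly increase")
        if np.any(abundance < 0):
            raise ValueError(f"series {self.population_id!r}: abundance must be non-negative")
        self.years = years
        self.abundance = abundance

    def __len__(self) -> int:
        return len(self.years)


def build_trajectory(spec: ScenarioSpec) -> Trajectory:
    """Deterministic piecewise log-linear index trajectory for ``spec``.

    The historical segment runs log-linearly from 1.0 at the baseline year to
    ``1 - D`` at the intervention year; the future segment continues with the
    scenario's post-intervention slope out to the horizon year.
    """
    years = np.arange(spec.baseline_year, spec.horizon_year + 1)
    t_pre = np.minimum(years, spec.intervention_year) - spec.baseline_year
    t_post = np.maximum(years - spec.intervention_year, 0)
    log10_index = spec.slope_pre * t_pre + spec.slope_post * t_post
    return Trajectory(years, 10.0 ** log10_index, spec.intervention_year)


def _rng_pair(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent generators for simulation and degradation, from one seed."""
    sim_ss, deg_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(sim_ss), np.random.default_rng(deg_ss)


def simulate_populations(
    traj: Trajectory, n_species: int, sampling: SamplingSpec
) -> list[PopulationSeries]:
    """Simulate fully observed populations tracking ``traj``.

    Each population ``i`` has a random positive base abundance ``b_i``
    (log10-normal) and expected abundance ``b_i * I(t)``; the observed value
    is the expectation times ``10**eps`` with ``eps ~ N(0, obs_noise_sd)``.
    All randomness derives from ``sampling.seed``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng, _ = _rng_pair(sampling.seed)
    n_years = len(traj.years)
    out: list[PopulationSeries] = []
    for s in range(n_species):
        species_id = f"sp{s:05d}"
        for p in range(sampling.populations_per_species):
            log10_base = rng.normal(sampling.base_log10_mean, sampling.base_log10_sd)
            eps = (
                rng.normal(0.0, sampling.obs_noise_sd, size=n_years)
                if sampling.obs_noise_sd > 0
                else np.zeros(n_years)
            )
            abundance = 10.0 ** (log10_base + np.log10(traj.values) + eps)
            out.append(
                PopulationSeries(
                    population_id=f"{species_id}_p{p:02d}",
                    species_id=species_id,
                    years=traj.years.copy(),
                    abundance=abundance,
                )
            )
    return out


def _draw_observed_mask(
    rng: np.random.Generator, n_years: int, sampling: SamplingSpec
) -> np.ndarray:
    """One random span + within-span coverage mask over ``n_years`` years."""
    if math.isinf(sampling.mean_series_length):
        span = n_years
    else:
        span = int(rng.geometric(1.0 / sampling.mean_series_length))
        span = min(max(span, 2), n_years)
    start = int(rng.integers(0, n_years - span + 1))
    mask = np.zeros(n_years, dtype=bool)
    if sampling.fullness >= 1.0:
        mask[start : start + span] = True
    else:
        mask[start : start + span] = rng.random(span) < sampling.fullness
    return mask


def degrade_sampling(
    series: list[PopulationSeries], sampling: SamplingSpec
) -> list[PopulationSeries]:
    """Impose realistic monitoring imperfection on fully observed series.

    Each series is restricted to a random span (geometric length, uniform
    start) and, within the span, each year is retained independently with
    probability ``fullness``.  Draws leaving fewer than 2 points are redrawn
    (up to 100 attempts, then the span endpoints are kept) so the number of
    series is preserved exactly.
    """
    if sampling.mean_series_length < 2:
        raise ValueError("mean_series_length must be >= 2 years")
    _, rng = _rng_pair(sampling.seed)
    out: list[PopulationSeries] = []
    for ser in series:
        n_years = len(ser.years)
        mask = None
        for _ in range(100):
            cand = _draw_observed_mask(rng, n_years, sampling)
            if cand.sum() >= 2:
                mask = cand
                break
        if mask is None:  # pathological fullness; keep a 2-point span
            mask = np.zeros(n_years, dtype=bool)
            mask[[0, n_years - 1]] = True
        out.append(
            replace(ser, years=ser.years[mask], abundance=ser.abundance[mask])
        )
    return out
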