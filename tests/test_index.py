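"""Chained geometric-mean index engine: smoothing, rates, chaining, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from lpisim import (
    PopulationSeries,
    SamplingSpec,
    ScenarioSpec,
    bootstrap_index,
    build_trajectory,
    compute_index,
    growth_rate_table,
    population_growth_rates,
    simulate_populations,
    smooth_population,
)
from lpisim.index import GROWTH_RATE_CAP


def series(pid, sid, years, abundance):
    return PopulationSeries(pid, sid, np.asarray(years), np.asarray(abundance))


def brute_force_index(series_list, baseline_year):
    """Index straight from the definition: geometric mean of relative abundance.

    For complete (annual, common-span) data the chained form collapses to
    10 ** mean-over-species of mean-over-populations of
    (log10 N_t - log10 N_baseline).  Independent of the engine's code path.
    """
    by_species = {}
    for s in series_list:
        by_species.setdefault(s.species_id, []).append(s)
    years = series_list[0].years
    out = []
    for t_idx in range(len(years)):
        log_rel_by_sp = []
        for pops in by_species.values():
            vals = [
                math.log10(p.abundance[t_idx]) - math.log10(p.abundance[0])
                for p in pops
            ]
            log_rel_by_sp.append(sum(vals) / len(vals))
        out.append(10 ** (sum(log_rel_by_sp) / len(log_rel_by_sp)))
    return np.array(out)


class TestSmoothPopulation:
    def test_two_point_series_interpolates_endpoints(self):
        s = series("p", "s", [2000, 2001], [100.0, 110.0])
        out = smooth_population(s)
        assert np.allclose(out["abundance"], [100.0, 110.0])

    def test_constant_series_stays_flat(self):
        s = series("p", "s", range(2000, 2007), [100.0] * 7)
        out = smooth_population(s)
        assert np.allclose(out["abundance"], 100.0, rtol=1e-8)

    def test_gap_filled_at_geometric_midpoint(self):
        s = series("p", "s", [2000, 2002], [100.0, 121.0])
        out = smooth_population(s)
        assert out["abundance"].iloc[1] == pytest.approx(110.0, rel=1e-12)

    def test_gam_used_for_long_series_tracks_signal(self):
        years = np.arange(1970, 2021)
        true = 1000.0 * 10 ** (-0.02 * (years - 1970))
        rng = np.random.default_rng(0)
        s = series("p", "s", years, true * 10 ** rng.normal(0, 0.05, len(years)))
        out = smooth_population(s, method="gam")
        err = np.abs(np.log10(out["abundance"].to_numpy()) - np.log10(true))
        assert err.mean() < 0.05  # smoother tracks the log-linear signal

    def test_all_zero_series_rejected(self):
        s = series("p", "s", [2000, 2001], [0.0, 0.0])
        with pytest.raises(ValueError, match="all zeros"):
            smooth_population(s)

    def test_zero_adjustment_applied(self):
        s = series("p", "s", [2000, 2001], [0.0, 100.0])
        out = smooth_population(s)
        assert (out["abundance"] > 0).all()


class TestGrowthRates:
    @pytest.mark.parametrize(
        "n0,n1,expected",
        [(100.0, 110.0, math.log10(1.1)), (100.0, 100.0, 0.0),
         (1.0, 10_000.0, GROWTH_RATE_CAP)],
    )
    def test_rate_definition_and_cap(self, n0, n1, expected):
        ann = pd.DataFrame({"year": [2000, 2001], "abundance": [n0, n1]})
        rates = population_growth_rates(ann)
        assert rates["rate"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert rates["year"].iloc[0] == 2001  # interval labelled by end year

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            population_growth_rates(pd.DataFrame({"year": [2000], "abundance": [1.0]}))


class TestComputeIndex:
    def test_two_species_hand_oracle(self):
        """Two species moving x1.1 and x0.9 give I_1 = sqrt(0.99)."""
        data = [
            series("a", "A", [2000, 2001], [100.0, 110.0]),
            series("b", "B", [2000, 2001], [100.0, 90.0]),
        ]
        idx = compute_index(growth_rate_table(data), 2000)
        assert idx.value_at(2001) == pytest.approx(math.sqrt(0.99), rel=1e-12)

    def test_single_population_index_is_normalised_trajectory(self):
        s = series("a", "A", range(2000, 2004), [50.0, 60.0, 55.0, 70.0])
        idx = compute_index(growth_rate_table([s]), 2000)
        assert np.allclose(idx.index, s.abundance / 50.0, rtol=1e-12)

    def test_flat_when_all_rates_zero(self):
        data = [series("a", "A", range(2000, 2005), [42.0] * 5)]
        idx = compute_index(growth_rate_table(data), 2000)
        assert np.allclose(idx.index, 1.0)

    @pytest.mark.parametrize("n_species,n_years", [(1, 3), (2, 4), (3, 4)])
    def test_matches_brute_force_on_toy_datasets(self, n_species, n_years):
        rng = np.random.default_rng(n_species * 10 + n_years)
        data = []
        for s_i in range(n_species):
            for p_i in range(rng.integers(1, 3)):
                data.append(
                    series(
                        f"s{s_i}p{p_i}", f"s{s_i}",
                        range(2000, 2000 + n_years),
                        rng.uniform(10, 200, n_years),
                    )
                )
        idx = compute_index(growth_rate_table(data, method="chain"), 2000)
        expected = brute_force_index(data, 2000)
        assert np.allclose(idx.index, expected, rtol=1e-10)

    def test_scale_invariance_of_single_population(self):
        """Multiplying one population by a constant leaves the index unchanged."""
        rng = np.random.default_rng(4)
        vals = rng.uniform(10, 100, 4)
        data = [
            series("a", "A", range(2000, 2004), vals),
            series("b", "B", range(2000, 2004), rng.uniform(10, 100, 4)),
        ]
        scaled = [
            series("a", "A", range(2000, 2004), 37.5 * vals),
            data[1],
        ]
        i1 = compute_index(growth_rate_table(data), 2000)
        i2 = compute_index(growth_rate_table(scaled), 2000)
        assert np.allclose(i1.index, i2.index, rtol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        data = [
            series(f"p{i}", f"s{i % 3}", range(2000, 2005), rng.uniform(5, 50, 5))
            for i in range(6)
        ]
        i1 = compute_index(growth_rate_table(data), 2000)
        i2 = compute_index(growth_rate_table(data[::-1]), 2000)
        assert np.allclose(i1.index, i2.index, rtol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            growth_rate_table([])

    @pytest.mark.parametrize(
        "method,atol",
        [
            ("chain", 1e-6),
            # the GAM smooth rounds the slope change at the intervention year,
            # so the smoothed path is only approximate there
            ("auto", 1e-2),
        ],
    )
    def test_noise_free_round_trip_reproduces_trajectory(self, method, atol):
        """Complete noise-free populations reproduce the generating trajectory."""
        traj = build_trajectory(ScenarioSpec("strong", "recovery"))
        pops = simulate_populations(traj, 30, SamplingSpec(obs_noise_sd=0.0, seed=21))
        idx = compute_index(growth_rate_table(pops, method=method), 1970)
        assert np.allclose(idx.index, traj.values, atol=atol)

    def test_noise_free_round_trip_exact_on_kink_free_history(self):
        """Up to the intervention year the trajectory is a single log-linear
        segment, which both smoothing paths reproduce to 1e-6."""
        traj = build_trajectory(ScenarioSpec("strong", "recovery")).truncate(2020)
        pops = simulate_populations(traj, 30, SamplingSpec(obs_noise_sd=0.0, seed=21))
        for method in ("chain", "auto"):
            idx = compute_index(growth_rate_table(pops, method=method), 1970)
            assert np.allclose(idx.index, traj.values, atol=1e-6)


class TestBootstrapIndex:
    def test_single_species_envelope_collapses(self):
        data = [series("a", "A", range(2000, 2004), [10.0, 12.0, 9.0, 11.0])]
        res = bootstrap_index(growth_rate_table(data), 2000, n_boot=100, seed=0)
        assert np.allclose(res.ci_low, res.index)
        assert np.allclose(res.ci_high, res.index)

    def test_same_seed_gives_identical_envelope(self):
        rng = np.random.default_rng(3)
        data = [
            series(f"p{i}", f"s{i}", range(2000, 2006), rng.uniform(5, 50, 6))
            for i in range(5)
        ]
        rates = growth_rate_table(data)
        a = bootstrap_index(rates, 2000, n_boot=200, seed=42)
        b = bootstrap_index(rates, 2000, n_boot=200, seed=42)
        assert np.array_equal(a.ci_low, b.ci_low)
        assert np.array_equal(a.ci_high, b.ci_high)

    def test_two_species_envelope_matches_enumeration(self):
        """With 2 species the bootstrap has 3 distinct resamples: (A,A) with
        weight 1/4, (A,B) with 1/2, (B,B) with 1/4.  The 2.5th and 97.5th
        percentiles of that distribution are the extreme resample indices."""
        data = [
            series("a", "A", [2000, 2001], [100.0, 120.0]),
            series("b", "B", [2000, 2001], [100.0, 80.0]),
        ]
        rates = growth_rate_table(data)
        res = bootstrap_index(rates, 2000, n_boot=10_000, seed=7)
        d_a, d_b = math.log10(1.2), math.log10(0.8)
        atoms = sorted([10**d_a, 10 ** ((d_a + d_b) / 2), 10**d_b])
        assert res.ci_low[1] == pytest.approx(atoms[0], rel=1e-9)
        assert res.ci_high[1] == pytest.approx(atoms[2], rel=1e-9)

    def test_point_index_within_envelope(self):
        rng = np.random.default_rng(9)
        data = [
            series(f"p{i}", f"s{i}", range(2000, 2008), rng.uniform(5, 50, 8))
            for i in range(8)
        ]
        res = bootstrap_index(growth_rate_table(data), 2000, n_boot=500, seed=1)
        assert np.all(res.ci_low <= res.index + 1e-12)
        assert np.all(res.index <= res.ci_high + 1e-12)

    def test_too_few_resamples_rejected(self):
        data = [series("a", "A", [2000, 2001], [1.0, 2.0])]
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_index(growth_rate_table(data), 2000, n_boot=1)
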