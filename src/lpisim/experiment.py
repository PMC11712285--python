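"""Experimental sweep: replicate runs over the full scenario grid and
Figure-style summaries of the estimate distributions.

Every cell of the experiment is one (historical class x future scenario x
dataset size x end year x replicate) combination.  A cell simulates its
populations, degrades them to monitoring-like sparsity, fits the
broken-stick mixed model with a profile search over the intervention year,
and records the estimates next to the generating truth.  Cell seeds are
derived deterministically from the master seed and the cell coordinates, so
any single cell can be re-run in isolation and will match the full sweep.
"""

from __future__ import annotations

import logging
import time
from typing import Iterable

import numpy as np
import pandas as pd

from .changepoint import profile_intervention_year
from .config import ExperimentConfig
from .scenarios import (
    ScenarioSpec,
    build_trajectory,
    degrade_sampling,
    simulate_populations,
)

__all__ = ["cell_seed", "run_cell", "run_experiment", "summarize_estimates", "render_figure"]

logger = logging.getLogger(__name__)

_CELL_COLUMNS = [
    "historical_class",
    "future_scenario",
    "n_species",
    "end_year",
    "replicate",
    "seed",
    "slope_pre",
    "slope_post",
    "tau_hat",
    "ci_pre_low",
    "ci_pre_high",
    "ci_post_low",
    "ci_post_high",
    "ci_tau_low",
    "ci_tau_high",
    "loglik",
    "converged",
    "re_structure",
    "n_series",
    "slope_post_true",
    "tau_true",
    "error",
]


def cell_seed(
    master_seed: int,
    historical_class: str,
    future_scenario: str,
    n_species: int,
    end_year: int,
    replicate: int,
) -> int:
    """Deterministic per-cell seed from the master seed and coordinates.

    Uses a SeedSequence spawn key built from the cell coordinates, so the
    seed for any cell can be reconstructed without running the rest of the
    grid.  Kept below 2**31 so it fits any downstream integer seed slot.
    """
    from .scenarios import FUTURE_SCENARIOS, HISTORICAL_DECLINES

    key = (
        sorted(HISTORICAL_DECLINES).index(historical_class),
        FUTURE_SCENARIOS.index(future_scenario),
        int(n_species),
        int(end_year),
        int(replicate),
    )
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_cell(
    config: ExperimentConfig,
    historical_class: str,
    future_scenario: str,
    n_species: int,
    end_year: int,
    replicate: int,
) -> dict:
    """Simulate, degrade and fit one experiment cell; returns a result row.

    Failures at any stage are caught and recorded in the ``error`` column so
    a sweep never dies on a single pathological replicate.
    """
    seed = cell_seed(
        config.master_seed, historical_class, future_scenario, n_species, end_year, replicate
    )
    spec = ScenarioSpec(
        historical_class,
        future_scenario,
        baseline_year=config.baseline_year,
        intervention_year=config.intervention_year,
        horizon_year=config.horizon_year,
    )
    row: dict = {
        "historical_class": historical_class,
        "future_scenario": future_scenario,
        "n_species": n_species,
        "end_year": end_year,
        "replicate": replicate,
        "seed": seed,
        "slope_post_true": spec.slope_post,
        # under business as usual there is no intervention, hence no true tau
        "tau_true": np.nan if future_scenario == "bau" else float(spec.intervention_year),
        "error": "",
    }
    t0 = time.perf_counter()
    try:
        traj = build_trajectory(spec).truncate(end_year)
        sampling = config.sampling_spec(seed)
        series = simulate_populations(traj, n_species, sampling)
        if config.degrade:
            series = degrade_sampling(series, sampling)
        grid = np.arange(
            max(config.grid_first, traj.years[0] + 1),
            min(config.grid_last, end_year - 1) + 1,
        )
        fit = profile_intervention_year(
            series,
            grid=grid,
            end_year=end_year,
            scan_structure=config.scan_structure,
            final_structure=config.final_structure,
        )
        fit_row = fit.to_row()
        fit_row.pop("end_year")
        row.update(fit_row)
    except Exception as exc:  # recorded, sweep continues
        logger.warning(
            "cell (%s, %s, n=%d, end=%d, rep=%d) failed: %s",
            historical_class, future_scenario, n_species, end_year, replicate, exc,
        )
        row.update({"converged": False, "error": str(exc)})
    # timing goes to the structured log, not the results table, so identical
    # configurations produce byte-identical outputs
    logger.info(
        "cell (%s, %s, n=%d, end=%d, rep=%d): %.2fs converged=%s",
        historical_class, future_scenario, n_species, end_year, replicate,
        time.perf_counter() - t0, row.get("converged"),
    )
    return row


def run_experiment(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Run every cell of the configured grid; one row per cell.

    Deterministic given ``config.master_seed``: cell seeds depend only on the
    master seed and the cell coordinates.
    """
    cells = [
        (h, f, n, e, r)
        for h in config.historical_classes
        for f in config.future_scenarios
        for n in config.sizes
        for e in config.end_years
        for r in range(config.replicates)
    ]
    iterator: Iterable = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="experiment cells")
    rows = [run_cell(config, *cell) for cell in iterator]
    df = pd.DataFrame(rows)
    for col in _CELL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[_CELL_COLUMNS]


def _group_summary(g: pd.DataFrame) -> pd.Series:
    """Median and 95% inter-quantile summaries over one cell group."""
    conv = g[g["converged"].astype(bool) & (g["error"] == "")]
    out = {"n_total": len(g), "n_converged": len(conv), "empty": len(conv) == 0}
    for quantity, ci_lo, ci_hi in [
        ("slope_post", "ci_post_low", "ci_post_high"),
        ("tau_hat", "ci_tau_low", "ci_tau_high"),
    ]:
        if len(conv) == 0:
            for suffix in ("median", "q025", "q975", "ci_q025", "ci_q975"):
                out[f"{quantity}_{suffix}"] = np.nan
            continue
        est = conv[quantity].to_numpy(dtype=float)
        # linear-interpolation quantiles throughout
        out[f"{quantity}_median"] = float(np.median(est))
        out[f"{quantity}_q025"] = float(np.quantile(est, 0.025))
        out[f"{quantity}_q975"] = float(np.quantile(est, 0.975))
        lo = conv[ci_lo].to_numpy(dtype=float)
        hi = conv[ci_hi].to_numpy(dtype=float)
        out[f"{quantity}_ci_q025"] = float(np.nanquantile(lo, 0.025)) if np.any(np.isfinite(lo)) else np.nan
        out[f"{quantity}_ci_q975"] = float(np.nanquantile(hi, 0.975)) if np.any(np.isfinite(hi)) else np.nan
    truth = g["slope_post_true"].iloc[0] if len(g) else np.nan
    out["slope_post_true"] = truth
    out["tau_true"] = g["tau_true"].iloc[0] if len(g) else np.nan
    return pd.Series(out)


def summarize_estimates(cells: pd.DataFrame, pool_end_years: bool = False) -> pd.DataFrame:
    """Per-cell-group medians and 95% inter-quantile ranges.

    Groups over replicates within (historical class, future scenario, size,
    end year); with ``pool_end_years=True`` the distributions additionally
    pool across end years, the display convention of the study's summary
    figure.  Thick-bar quantities are the 2.5%/97.5% quantiles of the point
    estimates; thin-bar quantities are the same quantiles of the Wald/profile
    interval endpoints.  Groups with no converged fit are flagged, not
    fabricated.
    """
    if cells.empty:
        raise ValueError("no experiment cells to summarize")
    keys = ["historical_class", "future_scenario", "n_species"]
    if not pool_end_years:
        keys.append("end_year")
    grouped = cells.groupby(keys, sort=True).apply(_group_summary, include_groups=False)
    return grouped.reset_index()


def render_figure(summaries: pd.DataFrame, path: str, quantity: str = "slope_post"):
    """Point-plus-two-bars summary panels, written as a vector figure.

    Rows are historical decline classes, columns dataset sizes, colours the
    future scenarios; the thick bar spans the 95% inter-quantile range of the
    estimates and the thin bar that of their confidence-interval endpoints.
    Dashed lines mark the generating truth.  Business-as-usual is omitted
    from intervention-year panels (it has no intervention year).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if quantity not in {"slope_post", "tau_hat"}:
        raise ValueError(f"unknown quantity {quantity!r}")
    scenarios = ["bau", "stabilization", "partial_recovery", "recovery"]
    if quantity == "tau_hat":
        scenarios = [s for s in scenarios if s != "bau"]
    colors = dict(zip(scenarios, ("#888888", "#d95f02", "#7570b3", "#1b9e77")))

    if summaries.empty:
        hist_classes, sizes = [], []
    else:
        hist_classes = sorted(summaries["historical_class"].unique())
        sizes = sorted(summaries["n_species"].unique())
    nrows, ncols = max(len(hist_classes), 1), max(len(sizes), 1)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False, sharey="row"
    )
    for ax_row in axes:
        for ax in ax_row:
            ax.set_xticks([])
    label = "post-intervention slope (log10/yr)" if quantity == "slope_post" else "intervention year"
    for i, h in enumerate(hist_classes):
        for j, n in enumerate(sizes):
            ax = axes[i][j]
            sub = summaries[
                (summaries["historical_class"] == h) & (summaries["n_species"] == n)
            ]
            for k, scen in enumerate(scenarios):
                row = sub[sub["future_scenario"] == scen]
                if row.empty or bool(row["empty"].iloc[0]):
                    continue  # missing group stays a gap
                row = row.iloc[0]
                c = colors[scen]
                ax.plot(
                    [k, k],
                    [row[f"{quantity}_ci_q025"], row[f"{quantity}_ci_q975"]],
                    color=c, lw=1.0, alpha=0.7,
                )
                ax.plot(
                    [k, k],
                    [row[f"{quantity}_q025"], row[f"{quantity}_q975"]],
                    color=c, lw=3.0,
                )
                ax.plot([k], [row[f"{quantity}_median"]], "o", color=c, ms=5)
                truth = row["slope_post_true"] if quantity == "slope_post" else row["tau_true"]
                if np.isfinite(truth):
                    ax.hlines(truth, k - 0.35, k + 0.35, color=c, ls="--", lw=0.8)
            ax.set_xlim(-0.5, len(scenarios) - 0.5)
            ax.set_xticks(range(len(scenarios)))
            ax.set_xticklabels([s.replace("_", "\n") for s in scenarios], fontsize=6)
            if i == 0:
                ax.set_title(f"{n} species", fontsize=9)
            if j == 0:
                ax.set_ylabel(f"{h}\n{label}", fontsize=7)
    fig.suptitle(label, fontsize=10)
    fig.tight_layout()
    # fixed hashsalt + stripped creation date: identical inputs, identical bytes
    with plt.rc_context({"svg.hashsalt": "lpisim"}):
        fig.savefig(path, metadata=_stable_metadata(path))
    plt.close(fig)
    return path


def _stable_metadata(path: str) -> dict:
    if str(path).endswith(".svg"):
        return {"Date": None}
    if str(path).endswith(".pdf"):
        return {"CreationDate": None}
    return {}
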