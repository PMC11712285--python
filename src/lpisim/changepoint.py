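"""Broken-stick linear mixed-effects estimation of the intervention year.

The model for population log10 abundance is piecewise linear with a single
slope change at a candidate intervention year tau:

    log10 N_it = a + b_pre * (t - tau) + (b_post - b_pre) * max(0, t - tau)
                 + u_i + (series-level random slopes) + e_it

Time is centred at tau for numerical stability.  tau itself is estimated by
profile likelihood over an integer-year candidate grid: the fit is repeated
at every grid year and the maximising year is tau-hat, with a 95% interval
given by the grid years whose log-likelihood lies within 1.92 of the
maximum.  All fits use maximum likelihood (not REML) so profile values are
comparable.

Two random-effects structures form a fallback ladder: random intercepts plus
random pre/post slopes per series ("slopes"), falling back to random
intercepts only ("intercepts") when the richer fit does not converge or is
degenerate (residual variance ~ 0, as with noise-free data, makes the random
slopes unidentified).  The profile scan uses the intercepts-only structure at
every grid year — cheap and comparable across tau — and the winning year is
then refit with the full structure for the reported slopes and intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .index import _zero_adjust
from .scenarios import PopulationSeries

__all__ = [
    "PROFILE_DROP_95",
    "BrokenStickFit",
    "default_candidate_grid",
    "stack_observations",
    "fit_broken_stick_at_tau",
    "profile_intervention_year",
]

#: chi-square(1)/2 critical drop for a 95% profile-likelihood interval.
PROFILE_DROP_95 = 1.92

#: Residual scale below which a mixed fit is treated as degenerate.
_DEGENERATE_SCALE = 1e-10

_Z95 = 1.959963984540054


@dataclass
class BrokenStickFit:
    """Result of one broken-stick fit (tau fixed or profiled)."""

    slope_pre: float
    slope_post: float
    intercept: float
    tau: float
    ci_slope_pre: tuple[float, float]
    ci_slope_post: tuple[float, float]
    loglik: float
    end_year: int
    converged: bool
    re_structure: str
    n_series: int
    residual_scale: float
    tau_hat: float | None = None
    ci_tau: tuple[float, float] | None = None
    profile: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "slope_pre": self.slope_pre,
            "slope_post": self.slope_post,
            "tau_hat": self.tau if self.tau_hat is None else self.tau_hat,
            "ci_pre_low": self.ci_slope_pre[0],
            "ci_pre_high": self.ci_slope_pre[1],
            "ci_post_low": self.ci_slope_post[0],
            "ci_post_high": self.ci_slope_post[1],
            "ci_tau_low": np.nan if self.ci_tau is None else self.ci_tau[0],
            "ci_tau_high": np.nan if self.ci_tau is None else self.ci_tau[1],
            "loglik": self.loglik,
            "end_year": self.end_year,
            "converged": self.converged,
            "re_structure": self.re_structure,
            "n_series": self.n_series,
        }


def stack_observations(
    data: list[PopulationSeries], end_year: int | None = None
) -> pd.DataFrame:
    """Long frame (group, year, log10_n) of all observations <= end_year."""
    groups, years, values = [], [], []
    for ser in data:
        keep = slice(None) if end_year is None else ser.years <= end_year
        yrs = ser.years[keep]
        if len(yrs) < 2:
            continue
        abund = _zero_adjust(ser.abundance[keep], ser.population_id)
        groups.extend([ser.population_id] * len(yrs))
        years.extend(yrs.tolist())
        values.extend(np.log10(abund).tolist())
    if len(set(groups)) < 2:
        raise ValueError("need >= 2 series with >= 2 observations each")
    return pd.DataFrame({"group": groups, "year": years, "log10_n": values})


def _design(df: pd.DataFrame, tau: float) -> np.ndarray:
    t_c = df["year"].to_numpy(dtype=float) - tau
    return np.column_stack([np.ones(len(df)), t_c, np.clip(t_c, 0.0, None)])


def _fit_mixed(df: pd.DataFrame, tau: float, re_structure: str, start_params=None):
    """One MixedLM ML fit; returns the results object or raises."""
    exog = _design(df, tau)
    exog_re = exog if re_structure == "slopes" else exog[:, :1]
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore")
        model = MixedLM(
            df["log10_n"].to_numpy(), exog, groups=df["group"].to_numpy(), exog_re=exog_re
        )
        return model.fit(reml=False, method="lbfgs", maxiter=200, start_params=start_params)


def _is_degenerate(res) -> bool:
    if not np.isfinite(res.llf):
        return True
    if res.scale < _DEGENERATE_SCALE:
        return True
    return bool(np.any(~np.isfinite(np.asarray(res.bse_fe))))


def _wrap(res, tau: float, end_year: int, re_structure: str, n_series: int) -> BrokenStickFit:
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:3, :3]
    slope_pre = float(params[1])
    slope_post = float(params[1] + params[2])
    se_pre = float(np.sqrt(max(cov[1, 1], 0.0)))
    var_post = cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]
    se_post = float(np.sqrt(max(var_post, 0.0)))
    return BrokenStickFit(
        slope_pre=slope_pre,
        slope_post=slope_post,
        intercept=float(params[0]),
        tau=float(tau),
        ci_slope_pre=(slope_pre - _Z95 * se_pre, slope_pre + _Z95 * se_pre),
        ci_slope_post=(slope_post - _Z95 * se_post, slope_post + _Z95 * se_post),
        loglik=float(res.llf),
        end_year=int(end_year),
        converged=bool(res.converged),
        re_structure=re_structure,
        n_series=n_series,
        residual_scale=float(res.scale),
    )


def fit_broken_stick_at_tau(
    data: list[PopulationSeries] | pd.DataFrame,
    tau: float,
    end_year: int,
    re_structure: str = "slopes",
) -> BrokenStickFit:
    """Broken-stick mixed model with the slope change fixed at ``tau``.

    ``re_structure='slopes'`` requests series-level random intercepts and
    random pre/post slopes, falling back to intercepts only when that fit
    fails or is degenerate; ``'intercepts'`` requests the simpler structure
    directly.  Wald 95% intervals are reported for both slopes.
    """
    if re_structure not in {"slopes", "intercepts"}:
        raise ValueError(f"unknown re_structure {re_structure!r}")
    df = data if isinstance(data, pd.DataFrame) else stack_observations(data, end_year)
    n_series = df["group"].nunique()
    ladder = ["slopes", "intercepts"] if re_structure == "slopes" else ["intercepts"]
    last_error: Exception | None = None
    for structure in ladder:
        try:
            res = _fit_mixed(df, tau, structure)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_error = exc
            continue
        ok = bool(res.converged) and not _is_degenerate(res)
        if ok or structure == ladder[-1]:
            return _wrap(res, tau, end_year, structure, n_series)
    # every rung raised
    return BrokenStickFit(
        slope_pre=np.nan,
        slope_post=np.nan,
        intercept=np.nan,
        tau=float(tau),
        ci_slope_pre=(np.nan, np.nan),
        ci_slope_post=(np.nan, np.nan),
        loglik=np.nan,
        end_year=int(end_year),
        converged=False,
        re_structure="failed",
        n_series=n_series,
        residual_scale=np.nan,
    )


def default_candidate_grid(
    df: pd.DataFrame, first: int = 2010, last: int = 2045
) -> np.ndarray:
    """Integer candidate years, clipped strictly inside the observed range."""
    lo = int(df["year"].min()) + 1
    hi = int(df["year"].max()) - 1
    grid = np.arange(max(first, lo), min(last, hi) + 1)
    if len(grid) == 0:
        raise ValueError(
            f"no candidate years between {first} and {last} lie inside the data range"
        )
    return grid


def profile_intervention_year(
    data: list[PopulationSeries] | pd.DataFrame,
    grid: np.ndarray | None = None,
    end_year: int = 2050,
    scan_structure: str = "intercepts",
    final_structure: str = "slopes",
) -> BrokenStickFit:
    """Estimate the intervention year by profile likelihood over ``grid``.

    The broken-stick model is refit at every candidate year with the
    ``scan_structure`` random effects; tau-hat maximises the scan
    log-likelihood and ci_tau collects the grid years within 1.92 of the
    maximum.  The winning year is refit with ``final_structure`` for the
    reported slopes.  Candidate years where the model fits the data exactly
    (residual variance ~ 0; only possible for noise-free data) dominate the
    profile; if several such years exist the profile is flat among them and
    ci_tau spans them all.
    """
    df = data if isinstance(data, pd.DataFrame) else stack_observations(data, end_year)
    if grid is None:
        grid = default_candidate_grid(df)
    grid = np.asarray(grid, dtype=int)
    if len(grid) == 0:
        raise ValueError("empty candidate grid")

    rows = []
    start = None  # warm-start each scan fit from the previous tau's optimum
    for tau in grid:
        try:
            res = _fit_mixed(df, float(tau), scan_structure, start_params=start)
        except (np.linalg.LinAlgError, ValueError):
            rows.append(
                {"tau": int(tau), "loglik": np.nan, "converged": False, "residual_scale": np.nan}
            )
            continue
        if res.converged and np.isfinite(res.llf) and res.scale > _DEGENERATE_SCALE:
            start = res.params_object
        rows.append(
            {
                "tau": int(tau),
                "loglik": float(res.llf),
                "converged": bool(res.converged),
                "residual_scale": float(res.scale),
            }
        )
    profile = pd.DataFrame(rows)
    ok = profile[np.isfinite(profile["loglik"])]
    perfect = profile[profile["residual_scale"] < _DEGENERATE_SCALE]
    if len(perfect) > 0:
        # exact fits have unbounded profile likelihood in the limit
        best_tau = int(perfect.loc[perfect["loglik"].idxmax(), "tau"])
        in_ci = perfect["tau"].to_numpy()
    elif len(ok) > 0:
        best_tau = int(ok.loc[ok["loglik"].idxmax(), "tau"])
        max_llf = float(ok["loglik"].max())
        in_ci = ok.loc[ok["loglik"] >= max_llf - PROFILE_DROP_95, "tau"].to_numpy()
    else:
        raise RuntimeError(
            "broken-stick fit failed at every candidate year; per-year diagnostics:\n"
            + profile.to_string(index=False)
        )

    final = fit_broken_stick_at_tau(df, float(best_tau), end_year, re_structure=final_structure)
    final.tau_hat = float(best_tau)
    final.ci_tau = (float(in_ci.min()), float(in_ci.max()))
    final.profile = profile
    return final
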