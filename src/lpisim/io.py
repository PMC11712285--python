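"""Reading and writing the table formats the pipeline touches.

Two population-data dialects are supported: the wide layout used by public
Living Planet Database exports (one row per population, one column per
calendar year, blank cells for unobserved years) and a tidy long layout
(population_id, species_id, year, abundance).  Parsers reject malformed
input with row-level messages rather than coercing silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import PopulationSeries

__all__ = [
    "read_population_csv",
    "write_population_csv",
    "series_to_long",
    "series_to_wide",
    "write_results_csv",
    "read_results_csv",
]

_LONG_COLUMNS = ["population_id", "species_id", "year", "abundance"]


def _year_columns(columns) -> list[str]:
    """Column names that parse as calendar years (1900-2100)."""
    out = []
    for c in columns:
        try:
            y = int(str(c))
        except ValueError:
            continue
        if 1900 <= y <= 2100:
            out.append(c)
    return out


def _series_from_long(df: pd.DataFrame, source: str) -> list[PopulationSeries]:
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    years = pd.to_numeric(df["year"], errors="coerce")
    bad = df.index[years.isna() | (years != years.round())]
    if len(bad):
        raise ValueError(f"{source}: non-integer year at row(s) {list(bad[:5])}")
    abundance = pd.to_numeric(df["abundance"], errors="coerce")
    bad = df.index[abundance.isna()]
    if len(bad):
        raise ValueError(f"{source}: non-numeric abundance at row(s) {list(bad[:5])}")
    bad = df.index[abundance < 0]
    if len(bad):
        raise ValueError(f"{source}: negative abundance at row(s) {list(bad[:5])}")
    dup = df.duplicated(subset=["population_id", "year"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["population_id", "year"]].head(5).to_dict("records")
        raise ValueError(f"{source}: duplicate (population_id, year) pairs, e.g. {pairs}")
    work = df.assign(year=years.astype(int), abundance=abundance.astype(float))
    out = []
    for pid, g in work.groupby("population_id", sort=True):
        g = g.sort_values("year")
        out.append(
            PopulationSeries(
                population_id=str(pid),
                species_id=str(g["species_id"].iloc[0]),
                years=g["year"].to_numpy(),
                abundance=g["abundance"].to_numpy(),
            )
        )
    return out


def _series_from_wide(df: pd.DataFrame, source: str) -> list[PopulationSeries]:
    for col in ("population_id", "species_id"):
        if col not in df.columns:
            raise ValueError(f"{source}: missing required column {col!r}")
    year_cols = _year_columns(df.columns)
    if not year_cols:
        raise ValueError(f"{source}: no calendar-year columns found")
    years_sorted = sorted(int(c) for c in year_cols)
    if years_sorted != list(range(years_sorted[0], years_sorted[-1] + 1)):
        raise ValueError(f"{source}: year columns are not contiguous")
    if df["population_id"].duplicated().any():
        dups = df.loc[df["population_id"].duplicated(), "population_id"].head(5).tolist()
        raise ValueError(f"{source}: duplicate population_id rows, e.g. {dups}")
    meta_cols = [c for c in df.columns if c not in year_cols and c not in ("population_id", "species_id")]
    out = []
    for idx, row in df.iterrows():
        vals = pd.to_numeric(row[year_cols], errors="coerce")
        raw = row[year_cols]
        invalid = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if invalid.any():
            raise ValueError(
                f"{source}: row {idx} (population {row['population_id']!r}): "
                f"non-numeric abundance in column(s) {list(raw.index[invalid][:5])}"
            )
        observed = vals.notna()
        if (vals[observed] < 0).any():
            cols = list(vals.index[observed & (vals < 0)][:5])
            raise ValueError(
                f"{source}: row {idx} (population {row['population_id']!r}): "
                f"negative abundance in column(s) {cols}"
            )
        if observed.sum() < 2:
            raise ValueError(
                f"{source}: row {idx} (population {row['population_id']!r}) "
                f"has {int(observed.sum())} observation(s); need >= 2"
            )
        out.append(
            PopulationSeries(
                population_id=str(row["population_id"]),
                species_id=str(row["species_id"]),
                years=np.array([int(c) for c in vals.index[observed]]),
                abundance=vals[observed].to_numpy(dtype=float),
                metadata={c: row[c] for c in meta_cols},
            )
        )
    return out


def read_population_csv(path: str | Path, dialect: str = "wide") -> list[PopulationSeries]:
    """Parse population time series from a wide or long CSV file."""
    if dialect not in {"wide", "long"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, comment="#")
    source = str(path)
    return _series_from_wide(df, source) if dialect == "wide" else _series_from_long(df, source)


def series_to_long(series: list[PopulationSeries]) -> pd.DataFrame:
    """Tidy long frame: one row per (population, year) observation."""
    rows = [
        (s.population_id, s.species_id, int(y), float(a))
        for s in series
        for y, a in zip(s.years, s.abundance)
    ]
    return pd.DataFrame(rows, columns=_LONG_COLUMNS)


def series_to_wide(series: list[PopulationSeries]) -> pd.DataFrame:
    """Wide frame with one column per calendar year; blanks = unobserved."""
    if not series:
        raise ValueError("no series to write")
    lo = min(int(s.years[0]) for s in series)
    hi = max(int(s.years[-1]) for s in series)
    year_cols = [str(y) for y in range(lo, hi + 1)]
    rows = []
    for s in series:
        row = {"population_id": s.population_id, "species_id": s.species_id}
        row.update({str(int(y)): float(a) for y, a in zip(s.years, s.abundance)})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["population_id", "species_id"] + year_cols)
    return df


def write_population_csv(series: list[PopulationSeries], path: str | Path, dialect: str = "wide") -> Path:
    """Write series in the requested dialect; inverse of read_population_csv."""
    if dialect not in {"wide", "long"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = series_to_wide(series) if dialect == "wide" else series_to_long(series)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_results_csv(
    table: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
    allow_empty: bool = False,
) -> Path:
    """Write a results table with a provenance header comment.

    Column order is preserved deterministically and floats use a fixed
    ``%.10g`` format, so identical inputs produce byte-identical files.
    """
    if table.empty and not allow_empty:
        raise ValueError("refusing to write an empty results table (pass allow_empty=True)")
    path = Path(path)
    header = ["# lpisim results"]
    if config_hash is not None:
        header.append(f"# config_hash={config_hash}")
    if seed is not None:
        header.append(f"# seed={seed}")
    header.append("# quantiles: linear interpolation; years are calendar years;")
    header.append("# growth-rate intervals are labelled by their end year")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        table.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results_csv`."""
    return pd.read_csv(path, comment="#")
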