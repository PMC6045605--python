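"""Forest-inventory plot tables: schema, validation, I/O, and climate centering.

A plot table is a :class:`pandas.DataFrame` with one row per inventory plot and
the canonical columns in :data:`PLOT_COLUMNS`. Each plot carries its location,
forest type, stand age (yr), aboveground biomass (AGB, Mg ha^-1), climate
normals (mean annual temperature in degC, mean annual precipitation in mm/yr),
the inventory period it belongs to, and a disturbance flag. Plots that
reported any natural or human-caused disturbance are excluded from model
fitting via :func:`filter_undisturbed`.

Climate covariates enter the growth model centered on per-forest-type means;
:func:`climate_centers` computes those means. Centers computed on the current
period are the ones reused for hindcast and forecast, so that the intercepts
retain their "average current climate" interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PLOT_COLUMNS",
    "PERIOD_YEARS",
    "PlotRecord",
    "ClimateCenters",
    "PlotTableError",
    "read_plot_table",
    "write_plot_table",
    "validate_plot_table",
    "filter_undisturbed",
    "climate_centers",
]

#: Canonical plot-table column order.
PLOT_COLUMNS = [
    "plot_id",
    "source",
    "forest_type",
    "lon",
    "lat",
    "stand_age",
    "agb",
    "mat",
    "map",
    "period",
    "obs_year",
    "disturbed",
]

_NUMERIC_COLUMNS = ["lon", "lat", "stand_age", "agb", "mat", "map"]

#: Inclusive observation-year window per inventory period.
PERIOD_YEARS = {"past": (1990, 1999), "current": (2000, 2016)}

_SOURCES = {"FIA", "PSP", "SYNTH"}


class PlotTableError(ValueError):
    """Raised when a plot table fails schema or invariant validation."""


@dataclass(frozen=True)
class PlotRecord:
    """One inventory plot (typed view of a plot-table row)."""

    plot_id: str
    source: str
    forest_type: str
    lon: float
    lat: float
    stand_age: float
    agb: float
    mat: float
    map: float
    period: str
    obs_year: int
    disturbed: bool


@dataclass(frozen=True)
class ClimateCenters:
    """Per-forest-type climate means used to center covariates."""

    forest_type: str
    t_bar: float
    p_bar: float
    n_plots: int


_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise PlotTableError(
            f"unparseable boolean in column 'disturbed' at row {row}: "
            f"{series.iloc[row - 1]!r}"
        )
    return s.isin(_TRUE)


def validate_plot_table(df: pd.DataFrame) -> None:
    """Check plot-table invariants, raising :class:`PlotTableError` on the
    first violation (reported with 1-based data-row index)."""

    def _fail(mask: np.ndarray, message: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask)[0]) + 1
            raise PlotTableError(f"{message} at row {row}")

    _fail((df["stand_age"] <= 0).to_numpy(), "stand_age must be > 0")
    _fail((df["agb"] < 0).to_numpy(), "agb must be >= 0")
    _fail(
        (df["forest_type"].astype(str).str.len() == 0).to_numpy(),
        "forest_type must be non-empty",
    )
    _fail(
        (~df["period"].isin(PERIOD_YEARS)).to_numpy(),
        f"period must be one of {sorted(PERIOD_YEARS)}",
    )
    _fail((~df["source"].isin(_SOURCES)).to_numpy(), f"source must be one of {sorted(_SOURCES)}")
    for period, (lo, hi) in PERIOD_YEARS.items():
        mask = (df["period"] == period) & ~df["obs_year"].between(lo, hi)
        _fail(mask.to_numpy(), f"obs_year outside {lo}-{hi} for period '{period}'")


def read_plot_table(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a plot CSV into a validated plot table.

    Parameters
    ----------
    path
        CSV file with a header row; comma-separated, UTF-8, "." decimal.
    schema
        Optional map from canonical column names to the names used in the
        file, for inventory exports with nonstandard headers.

    Returns
    -------
    DataFrame with the canonical :data:`PLOT_COLUMNS`, coerced dtypes, and
    all invariants checked. Rows with missing or unparseable required fields
    raise :class:`PlotTableError` naming the row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        raw = raw.rename(columns=rename)

    have_disturbed = "disturbed" in raw.columns
    required = [c for c in PLOT_COLUMNS if c != "disturbed"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise PlotTableError(f"missing required column(s): {', '.join(missing)}")
    if not have_disturbed:
        warnings.warn(
            "plot table has no 'disturbed' column; treating all plots as "
            "undisturbed",
            stacklevel=2,
        )
        raw["disturbed"] = "false"

    df = pd.DataFrame(index=raw.index)
    for col in ("plot_id", "source", "forest_type", "period"):
        df[col] = raw[col].astype(str).str.strip()
    for col in _NUMERIC_COLUMNS + ["obs_year"]:
        # python float() is correctly rounded (pandas' fast parser is not),
        # which keeps write->read round trips bit-exact
        strings = raw[col].to_numpy()
        values = np.empty(len(strings))
        for i, s in enumerate(strings):
            try:
                values[i] = float(s)
            except (TypeError, ValueError):
                raise PlotTableError(
                    f"missing or unparseable value in column '{col}' at "
                    f"row {i + 1}: {s!r}"
                ) from None
        df[col] = values
    df["obs_year"] = df["obs_year"].astype(int)
    df["disturbed"] = _parse_bool(raw["disturbed"])
    df = df[PLOT_COLUMNS]
    validate_plot_table(df)
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    """Write a plot table to CSV losslessly (shortest round-trip floats)."""
    out = df[PLOT_COLUMNS].copy()
    out["disturbed"] = out["disturbed"].map({True: "true", False: "false"})
    for col in _NUMERIC_COLUMNS:
        # shortest round-trip decimal so read-after-write is bit-exact
        out[col] = [np.format_float_positional(v, unique=True, trim="0") for v in out[col]]
    out.to_csv(path, index=False)


def filter_undisturbed(plots: pd.DataFrame) -> pd.DataFrame:
    """Drop plots that reported any disturbance; input order preserved."""
    return plots.loc[~plots["disturbed"].astype(bool)].copy()


def climate_centers(plots: pd.DataFrame, period: str = "current") -> pd.DataFrame:
    """Per-forest-type means of temperature and precipitation in one period.

    Every forest type present anywhere in ``plots`` must have at least one
    plot in the requested period; otherwise the type is named in the error.
    Centers computed on the current period are the ones reused for hindcast
    and forecast.
    """
    if period not in PERIOD_YEARS:
        raise PlotTableError(f"unknown period {period!r}")
    sub = plots.loc[plots["period"] == period]
    all_types = set(plots["forest_type"].unique())
    have = set(sub["forest_type"].unique())
    orphans = sorted(all_types - have)
    if orphans:
        raise PlotTableError(
            f"no {period}-period plots for forest type(s): {', '.join(orphans)}"
        )
    grouped = sub.groupby("forest_type", sort=True)
    out = grouped.agg(t_bar=("mat", "mean"), p_bar=("map", "mean"), n_plots=("mat", "size"))
    return out.reset_index()


def centers_as_records(centers: pd.DataFrame) -> list[ClimateCenters]:
    """Typed view of a :func:`climate_centers` table."""
    return [
        ClimateCenters(r.forest_type, float(r.t_bar), float(r.p_bar), int(r.n_plots))
        for r in centers.itertuples(index=False)
    ]
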