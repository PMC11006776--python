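"""Growing-season weather summaries and selection environments.

Daily station weather is reduced to one summary per site-year: mean daily
maximum temperature (maxTemp, deg C), mean daily minimum temperature
(minTemp, deg C) and total precipitation (precip, cm) over the growing
season, inclusive of both window endpoints.  A clone's selection
environment is the average of these summaries over the three seasons
preceding its trial-submission year at its home site — the years during
which the clone was under selection there.  Missing station days are
filled from the nearest fallback station, with per-day provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

_VARS = ("tmax_c", "tmin_c", "precip_cm")


@dataclass(frozen=True)
class SeasonSummary:
    """Growing-season climate of one site-year."""

    site_id: str
    year: int
    maxTemp: float   # deg C, mean of daily maxima
    minTemp: float   # deg C, mean of daily minima
    precip: float    # cm, season total
    n_days_used: int
    n_days_imputed: int = 0

    def __post_init__(self) -> None:
        if self.maxTemp < self.minTemp:
            raise DataError(
                f"{self.site_id} {self.year}: maxTemp {self.maxTemp} < minTemp {self.minTemp}"
            )
        if self.precip < 0:
            raise DataError(f"{self.site_id} {self.year}: negative precipitation")
        if self.n_days_used <= 0:
            raise DataError(f"{self.site_id} {self.year}: empty season window")


@dataclass(frozen=True)
class SelectionEnv:
    """3-year pre-submission average environment at a clone's home site."""

    clone: str
    program: str
    submission_year: int
    minTemp_sel: float
    maxTemp_sel: float
    precip_sel: float
    latitude: float
    longitude: float


def impute_missing_days(
    primary: pd.DataFrame,
    fallbacks: list[pd.DataFrame],
) -> pd.DataFrame:
    """Fill missing days/values in a station series from proximal stations.

    ``fallbacks`` must be ordered by proximity.  Works value-wise: a day
    missing only tmax takes tmax from the first fallback that has it.  Adds
    a ``source_<var>`` column per variable ("primary" or "fallback<k>").
    Raises :class:`DataError`, naming the date, if a value is missing in
    every station.
    """
    out = primary.set_index("date").copy()
    all_dates = out.index
    for fb in fallbacks:
        all_dates = all_dates.union(pd.DatetimeIndex(fb["date"]))
    out = out.reindex(all_dates)
    for v in _VARS:
        out[f"source_{v}"] = np.where(out[v].notna(), "primary", None)
    for k, fb in enumerate(fallbacks, start=1):
        fb = fb.set_index("date")
        for v in _VARS:
            need = out[v].isna()
            have = fb[v].reindex(out.index).notna()
            take = need & have
            out.loc[take, v] = fb[v].reindex(out.index)[take]
            out.loc[take, f"source_{v}"] = f"fallback{k}"
    for v in _VARS:
        if out[v].isna().any():
            missing = out.index[out[v].isna()]
            raise DataError(
                f"{v} missing in all stations on {missing[0].date()}"
                + (f" and {len(missing) - 1} more days" if len(missing) > 1 else "")
            )
    n_imp = int((out[[f"source_{v}" for v in _VARS]] != "primary").any(axis=1).sum())
    if n_imp:
        logger.info("imputed values on %d days from fallback stations", n_imp)
    return out.reset_index(names="date")


def season_summary(
    daily: pd.DataFrame,
    site: str,
    year: int,
    window: tuple[int, int],
) -> SeasonSummary:
    """Summarize one site-year over an inclusive day-of-year window."""
    lo, hi = window
    if lo > hi:
        raise DataError(f"empty season window ({lo}, {hi})")
    d = daily[daily["station"] == site].copy()
    dates = pd.DatetimeIndex(d["date"])
    d = d[(dates.year == year) & (dates.dayofyear >= lo) & (dates.dayofyear <= hi)]
    if d.empty:
        raise DataError(f"no weather for {site} in {year} days {lo}-{hi}")
    if d[list(_VARS)].isna().any().any():
        raise DataError(f"{site} {year}: missing values in window; impute first")
    imputed = 0
    src_cols = [c for c in d.columns if c.startswith("source_")]
    if src_cols:
        imputed = int((d[src_cols] != "primary").any(axis=1).sum())
    return SeasonSummary(
        site_id=site,
        year=year,
        maxTemp=float(d["tmax_c"].mean()),
        minTemp=float(d["tmin_c"].mean()),
        precip=float(d["precip_cm"].sum()),
        n_days_used=len(d),
        n_days_imputed=imputed,
    )


def summarize_sites(
    daily: pd.DataFrame,
    windows: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Season summaries for every (station, year) present in ``daily``."""
    rows = []
    dates = pd.DatetimeIndex(daily["date"])
    for (site, year), _ in daily.groupby([daily["station"], dates.year]):
        s = season_summary(daily, site, int(year), windows[site])
        rows.append(vars(s))
    return pd.DataFrame(rows)


def selection_env(
    clone: str,
    submission_year: int,
    home_site: str,
    summaries: pd.DataFrame,
    latitude: float,
    longitude: float,
) -> SelectionEnv:
    """Average the home site's seasons over the 3 years before submission.

    The contributing years are exactly submission_year-3 .. submission_year-1,
    weighted equally.
    """
    want = [submission_year - 3, submission_year - 2, submission_year - 1]
    rows = summaries[(summaries["site_id"] == home_site)
                     & (summaries["year"].isin(want))]
    missing = sorted(set(want) - set(rows["year"].tolist()))
    if missing:
        raise DataError(
            f"clone {clone}: no season summary for {home_site} in years {missing}"
        )
    return SelectionEnv(
        clone=clone,
        program=home_site,
        submission_year=submission_year,
        minTemp_sel=float(rows["minTemp"].mean()),
        maxTemp_sel=float(rows["maxTemp"].mean()),
        precip_sel=float(rows["precip"].mean()),
        latitude=latitude,
        longitude=longitude,
    )


def selection_env_table(
    clone_program: pd.Series,
    clone_year: pd.Series,
    summaries: pd.DataFrame,
    site_coords: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Selection environments for a whole panel (one row per clone)."""
    rows = []
    for clone, prog in clone_program.items():
        lat, lon = site_coords[prog]
        rows.append(vars(selection_env(
            clone, int(clone_year[clone]), prog, summaries, lat, lon)))
    return pd.DataFrame(rows)


def env_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between environmental variables.

    Returns (r matrix, n matrix of paired-observation counts).  Zero-variance
    columns yield NaN entries and a warning, never a silent 0.
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise DataError("need at least 2 numeric environmental variables")
    n = pd.DataFrame(index=num.columns, columns=num.columns, dtype=float)
    for a in num.columns:
        for b in num.columns:
            n.loc[a, b] = int(num[[a, b]].dropna().shape[0])
    if (n.to_numpy() < 3).any():
        raise DataError("fewer than 3 paired observations for some variable pair")
    degenerate = [c for c in num.columns if num[c].dropna().nunique() <= 1]
    if degenerate:
        warnings.warn(f"zero-variance environmental variables: {degenerate}; "
                      "correlations undefined (NaN)", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num.corr(method="pearson", min_periods=3)
    for c in degenerate:
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
        r.loc[c, c] = np.nan
    return r, n
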