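"""Synthetic multi-environment potato trial generator.

Emulates a national chip-processing-style trial: breeding programs at
selection sites scattered across a latitudinal/longitudinal gradient,
autotetraploid SNP dosages (0-4) with optional environment-correlated
allele-frequency clines, daily site weather, plot-level yield records
following the additive model

    yield = mu + Y + L + YL + g + gY + gL + gYL + eps

plus optional planted reaction-norm QTL, and per-clone trial submission
years with optional directional allele-frequency trends.  Every planted
signal is recorded in :class:`SimTruth` so downstream analyses can be
validated against known ground truth.

All randomness flows through ``numpy.random.default_rng(seed)``: a fixed
seed and configuration reproduce output byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, InvalidConfigError

logger = logging.getLogger(__name__)

FREQ_FLOOR = 0.005  # allele-frequency clip band for planted markers
FREQ_CEIL = 0.995

# ---------------------------------------------------------------------------
# Sites and climate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateParams:
    """Daily-weather generating parameters for one site.

    Temperatures in deg C; precipitation in cm per day.  ``seasonal_amp`` is
    the amplitude of the annual temperature cycle (0 gives a flat series).
    """

    tmax_mean: float
    tmax_sd: float
    tmin_mean: float
    tmin_sd: float
    precip_mean_cm: float
    wet_day_prob: float = 0.3
    seasonal_amp: float = 8.0


@dataclass(frozen=True)
class SiteDef:
    """One program/trial site: coordinates, roles, season window, climate."""

    site_id: str
    is_selection: bool
    is_trial: bool
    latitude: float
    longitude: float
    season_window: tuple[int, int] = (135, 258)  # day-of-year, inclusive
    climate: ClimateParams | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise InvalidConfigError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise InvalidConfigError(f"longitude {self.longitude} outside [-180, 180]")
        if self.season_window[0] >= self.season_window[1]:
            raise InvalidConfigError(
                f"season window start {self.season_window[0]} must precede end "
                f"{self.season_window[1]}"
            )


def _default_climate(latitude: float, longitude: float) -> ClimateParams:
    # warmer south, wetter east; rough continental-US gradients
    tmax = 38.0 - 0.40 * (latitude - 29.0)
    return ClimateParams(
        tmax_mean=round(tmax, 2),
        tmax_sd=4.0,
        tmin_mean=round(tmax - 13.0, 2),
        tmin_sd=4.0,
        precip_mean_cm=round(max(0.05, 0.12 + 0.004 * (longitude + 120.0)), 3),
    )


# Site codes/coordinates follow the published US national-trial site tables:
# both-role sites first so any prefix of length >= 2 contains at least one
# selection site and two trial sites.
_DEFAULT_SITE_ROWS: list[tuple[str, bool, bool, float, float]] = [
    ("WI", True, True, 44.12, -89.54),
    ("MI", True, True, 43.35, -85.17),
    ("NC", True, True, 35.87, -76.65),
    ("ND", True, True, 48.53, -97.62),
    ("NY", True, True, 42.43, -76.39),
    ("OR", True, True, 45.81, -119.28),
    ("TX", True, True, 35.97, -102.73),
    ("ME", True, False, 46.65, -68.01),
    ("CA", False, True, 35.26, -118.88),
    ("FL", False, True, 29.68, -81.43),
    ("CO", True, False, 37.71, -106.14),
    ("ID", True, False, 42.95, -112.83),
    ("MO", False, True, 36.93, -89.38),
]


def simulate_programs(n_sites: int = 10, seed: int = 0) -> list[SiteDef]:
    """Return ``n_sites`` site definitions with default US-trial coordinates.

    The first 13 sites reproduce the real trial/selection network; any
    additional sites are drawn at random (deterministically under ``seed``)
    inside the continental-US bounding box.
    """
    if n_sites < 2:
        raise InvalidConfigError("need at least 2 sites (one selection, two trial roles)")
    rng = np.random.default_rng(seed)
    sites: list[SiteDef] = []
    for code, sel, tri, lat, lon in _DEFAULT_SITE_ROWS[:n_sites]:
        sites.append(
            SiteDef(code, sel, tri, lat, lon, climate=_default_climate(lat, lon))
        )
    for k in range(len(_DEFAULT_SITE_ROWS), n_sites):
        lat = float(rng.uniform(29.0, 49.0))
        lon = float(rng.uniform(-120.0, -68.0))
        sites.append(
            SiteDef(f"S{k:02d}", True, True, round(lat, 2), round(lon, 2),
                    climate=_default_climate(lat, lon))
        )
    return sites


def program_env_value(site: SiteDef, variable: str) -> float:
    """Scalar environmental covariate of a program's home site.

    Used to orient allele-frequency clines; ``minTemp``/``maxTemp``/``precip``
    map onto the site's climate parameters, ``latitude``/``longitude`` onto
    its coordinates.
    """
    if variable == "latitude":
        return site.latitude
    if variable == "longitude":
        return site.longitude
    if site.climate is None:
        raise InvalidConfigError(f"site {site.site_id} has no climate parameters")
    if variable == "maxTemp":
        return site.climate.tmax_mean
    if variable == "minTemp":
        return site.climate.tmin_mean
    if variable == "precip":
        span = site.season_window[1] - site.season_window[0] + 1
        return site.climate.precip_mean_cm * span
    raise InvalidConfigError(f"unknown environmental variable {variable!r}")


# ---------------------------------------------------------------------------
# Ground truth and dosage container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvQtl:
    """A marker whose allele frequency follows an environmental cline."""

    marker_index: int
    variable: str
    strength: float           # frequency shift per SD of the program covariate
    base_freq: float = 0.5


@dataclass(frozen=True)
class SlopeQtl:
    """A marker with a per-dosage-copy effect on environmental sensitivity."""

    marker_index: int
    variable: str
    beta_per_dosage: float
    scale: str = "raw"        # "raw": additive kg per E-unit; "log": slope on log-relative yield


@dataclass(frozen=True)
class GpsmQtl:
    """A marker whose allele frequency drifts linearly with submission year."""

    marker_index: int
    delta_per_year: float
    base_freq: float = 0.5


@dataclass
class SimTruth:
    """Everything the generator planted, for downstream validation."""

    env_qtl: list[EnvQtl] = field(default_factory=list)
    slope_qtl: list[SlopeQtl] = field(default_factory=list)
    gpsm_qtl: list[GpsmQtl] = field(default_factory=list)
    variance_components: dict[str, float] = field(
        default_factory=lambda: {"g": 0.0, "gY": 0.0, "gL": 0.0, "gYL": 0.0, "e": 1.0}
    )
    mu: float = 20.0
    year_effects: dict[int, float] = field(default_factory=dict)
    loc_effects: dict[str, float] = field(default_factory=dict)
    yl_effects: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.variance_components.items():
            if v < 0:
                raise InvalidConfigError(f"variance component {name} is negative ({v})")


@dataclass
class DosageMatrix:
    """Autotetraploid SNP dosages (0-4), markers x clones, with a genomic map."""

    markers: list[str]
    chrom: np.ndarray          # str labels, len M
    pos: np.ndarray            # int bp, 1-based, len M
    clones: list[str]
    dosages: np.ndarray        # int8, shape (M, N)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages)
        if len(set(self.markers)) != len(self.markers):
            raise DataError("duplicate marker ids")
        if self.dosages.min() < 0 or self.dosages.max() > 4:
            raise DataError("dosages outside {0,...,4}")
        # positions sorted within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise DataError(f"positions not sorted on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def allele_freqs(self) -> np.ndarray:
        """Alternative-allele frequency per marker: mean dosage / 4."""
        return self.dosages.mean(axis=1) / 4.0

    def subset_markers(self, keep: np.ndarray) -> "DosageMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return DosageMatrix(
            [self.markers[i] for i in idx],
            self.chrom[idx], self.pos[idx], list(self.clones), self.dosages[idx],
        )

    def subset_clones(self, clone_ids: list[str]) -> "DosageMatrix":
        lookup = {c: j for j, c in enumerate(self.clones)}
        cols = [lookup[c] for c in clone_ids]
        return DosageMatrix(
            list(self.markers), self.chrom.copy(), self.pos.copy(),
            list(clone_ids), self.dosages[:, cols],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.clones)
        df.insert(0, "Position", self.pos)
        df.insert(0, "Chrom", self.chrom)
        df.insert(0, "Marker", self.markers)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DosageMatrix":
        df = pd.read_csv(path)
        for col in ("Marker", "Chrom", "Position"):
            if col not in df.columns:
                raise DataError(f"genotype CSV missing column {col!r}")
        clones = [c for c in df.columns if c not in ("Marker", "Chrom", "Position")]
        return cls(
            df["Marker"].astype(str).tolist(),
            df["Chrom"].astype(str).to_numpy(),
            df["Position"].to_numpy(),
            clones,
            df[clones].to_numpy(dtype=np.int8),
        )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_clones: int,
    n_markers: int,
    sites: list[SiteDef],
    env_qtl_spec: list[EnvQtl] | None = None,
    seed: int = 0,
    n_chromosomes: int = 12,
    chrom_length_bp: int = 60_000_000,
) -> tuple[DosageMatrix, SimTruth, pd.Series]:
    """Sample an autotetraploid panel with optional environmental clines.

    Dosages are Binomial(4, p) per marker and clone (autotetraploid HWE,
    independent markers).  Neutral markers share one base frequency across
    programs; each env-QTL marker's frequency is shifted linearly in its
    program's standardized environmental covariate:
    ``p_prog = clip(p0 + strength * z_prog, 0.005, 0.995)``.

    Returns the dosage matrix, the planted truth and a clone -> program map.
    """
    env_qtl_spec = list(env_qtl_spec or [])
    if n_markers < len(env_qtl_spec):
        raise InvalidConfigError("fewer markers than requested env QTL")
    sel_sites = [s for s in sites if s.is_selection]
    if not sel_sites:
        raise InvalidConfigError("no selection sites among the provided sites")
    rng = np.random.default_rng(seed)

    clones = [f"C{j:04d}" for j in range(n_clones)]
    programs = pd.Series(
        rng.choice([s.site_id for s in sel_sites], size=n_clones),
        index=clones, name="program",
    )

    # genomic map: markers spread over chromosomes, jittered, sorted
    chrom_idx = np.sort(rng.integers(0, n_chromosomes, size=n_markers))
    chrom = np.array([f"chr{c + 1:02d}" for c in chrom_idx])
    pos = np.empty(n_markers, dtype=np.int64)
    for c in range(n_chromosomes):
        m = chrom_idx == c
        pos[m] = np.sort(rng.integers(1, chrom_length_bp, size=m.sum()))
    markers = [f"M{i:05d}" for i in range(n_markers)]

    base = 0.05 + 0.90 * rng.beta(0.75, 0.75, size=n_markers)
    p = np.repeat(base[:, None], n_clones, axis=1)

    site_by_id = {s.site_id: s for s in sel_sites}
    prog_col = programs.to_numpy()
    for q in env_qtl_spec:
        vals = np.array([program_env_value(site_by_id[s.site_id], q.variable)
                         for s in sel_sites])
        z = {s.site_id: (v - vals.mean()) / vals.std()
             for s, v in zip(sel_sites, vals)}
        pq = np.array([q.base_freq + q.strength * z[pr] for pr in prog_col])
        p[q.marker_index] = np.clip(pq, FREQ_FLOOR, FREQ_CEIL)

    dosages = rng.binomial(4, p).astype(np.int8)
    dm = DosageMatrix(markers, chrom, pos, clones, dosages)
    truth = SimTruth(env_qtl=env_qtl_spec)
    return dm, truth, programs


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

_SEASON_PEAK_DOY = 200  # annual temperature cycle peaks mid-July


def simulate_weather(
    sites: list[SiteDef],
    years: list[int],
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> pd.DataFrame:
    """Daily weather per site and calendar year.

    Columns: station, date, tmax_c, tmin_c, precip_cm.  tmax >= tmin is
    enforced on every day; precipitation is zero-inflated exponential.
    ``missing_fraction`` masks that share of days (all three variables NaN)
    to exercise fallback-station imputation downstream.
    """
    if not sites:
        raise InvalidConfigError("empty site list")
    if not years:
        raise InvalidConfigError("empty year list")
    rng = np.random.default_rng(seed)
    frames = []
    for site in sites:
        cp = site.climate or _default_climate(site.latitude, site.longitude)
        for year in years:
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            doy = dates.dayofyear.to_numpy()
            cycle = cp.seasonal_amp * np.cos(2 * np.pi * (doy - _SEASON_PEAK_DOY) / 365.25)
            tmax = cp.tmax_mean + cycle + rng.normal(0, cp.tmax_sd, len(dates))
            tmin = cp.tmin_mean + cycle + rng.normal(0, cp.tmin_sd, len(dates))
            tmin = np.minimum(tmin, tmax)  # physical constraint
            wet = rng.random(len(dates)) < cp.wet_day_prob
            amount = rng.exponential(cp.precip_mean_cm / max(cp.wet_day_prob, 1e-12),
                                     len(dates))
            precip = np.where(wet, amount, 0.0)
            frames.append(pd.DataFrame({
                "station": site.site_id,
                "date": dates,
                "tmax_c": tmax,
                "tmin_c": tmin,
                "precip_cm": precip,
            }))
    out = pd.concat(frames, ignore_index=True)
    if missing_fraction > 0:
        mask = rng.random(len(out)) < missing_fraction
        out.loc[mask, ["tmax_c", "tmin_c", "precip_cm"]] = np.nan
        logger.info("masked %d of %d weather days", int(mask.sum()), len(out))
    return out


# ---------------------------------------------------------------------------
# Yields
# ---------------------------------------------------------------------------


def make_trial_layout(
    clones: list[str],
    locations: list[str],
    years: list[int],
    n_reps: int = 2,
) -> pd.DataFrame:
    """Fully crossed plot layout: every clone in every (location, year), replicated."""
    rows = [
        {"clone": c, "location": l, "year": y}
        for c in clones for y in years for l in locations for _ in range(n_reps)
    ]
    return pd.DataFrame(rows)


def simulate_yields(
    dosage: DosageMatrix,
    truth: SimTruth,
    trial_layout: pd.DataFrame,
    trial_env: pd.DataFrame | None = None,
    seed: int = 0,
    yield_floor_frac: float = 0.01,
    plot_area_ha: float = 0.0015,
    clone_program: pd.Series | None = None,
    clone_year: pd.Series | None = None,
) -> pd.DataFrame:
    """Plot yields under mu + Y + L + YL + g + gY + gL + gYL + eps (kg).

    ``trial_env`` (columns: location, year, one column per environmental
    variable) supplies the trial-level covariate E for any planted slope
    QTL.  A "raw"-scale QTL adds ``dosage * beta * E`` kg; a "log"-scale QTL
    multiplies yield by ``exp(dosage * beta * (E - mean E))`` so the planted
    beta is the reaction-norm slope on the log-relative scale analysed
    downstream.  Yields below ``yield_floor_frac`` x trial mean are raised to
    the floor and flagged (guarantees positivity for the log step).
    """
    vc = truth.variance_components
    for name, v in vc.items():
        if v < 0:
            raise InvalidConfigError(f"negative variance component {name}")
    n_trials = trial_layout.drop_duplicates(["location", "year"]).shape[0]
    if n_trials >= 2:
        per_clone = trial_layout.drop_duplicates(["clone", "location", "year"]) \
                                .groupby("clone").size()
        if (per_clone < 2).any():
            bad = per_clone[per_clone < 2].index.tolist()[:5]
            raise DataError(f"clones in fewer than 2 trials, e.g. {bad}")
    rng = np.random.default_rng(seed)

    lay = trial_layout.reset_index(drop=True).copy()
    clones = lay["clone"].to_numpy()
    locs = lay["location"].to_numpy()
    years = lay["year"].to_numpy()

    def _draw(keys: np.ndarray, sd: float) -> np.ndarray:
        levels, inv = np.unique(keys, return_inverse=True)
        return rng.normal(0.0, sd, len(levels))[inv]

    y = np.full(len(lay), truth.mu, dtype=float)
    y += np.array([truth.year_effects.get(int(t), 0.0) for t in years])
    y += np.array([truth.loc_effects.get(l, 0.0) for l in locs])
    y += np.array([truth.yl_effects.get((l, int(t)), 0.0) for l, t in zip(locs, years)])
    y += _draw(clones, np.sqrt(vc["g"]))
    y += _draw(np.char.add(clones.astype(str), years.astype(str)), np.sqrt(vc["gY"]))
    y += _draw(np.char.add(clones.astype(str), locs.astype(str)), np.sqrt(vc["gL"]))
    cell = np.char.add(np.char.add(clones.astype(str), locs.astype(str)),
                       years.astype(str))
    y += _draw(cell, np.sqrt(vc["gYL"]))
    y += rng.normal(0.0, np.sqrt(vc["e"]), len(lay))

    log_mult = np.zeros(len(lay))
    if truth.slope_qtl:
        if trial_env is None:
            raise InvalidConfigError("slope QTL planted but no trial_env provided")
        clone_col = {c: j for j, c in enumerate(dosage.clones)}
        col = np.array([clone_col[c] for c in clones])
        for q in truth.slope_qtl:
            env = trial_env.set_index(["location", "year"])[q.variable]
            e = env.loc[list(zip(locs, years))].to_numpy(dtype=float)
            d = dosage.dosages[q.marker_index, col].astype(float)
            if q.scale == "raw":
                y += d * q.beta_per_dosage * e
            elif q.scale == "log":
                log_mult += d * q.beta_per_dosage * (e - e.mean())
            else:
                raise InvalidConfigError(f"unknown slope QTL scale {q.scale!r}")
    if log_mult.any():
        y = np.maximum(y, 1e-6) * np.exp(log_mult)

    # positivity floor per trial
    lay["plot_yield_kg"] = y
    floored = np.zeros(len(lay), dtype=bool)
    for _, idx in lay.groupby(["location", "year"]).indices.items():
        floor = yield_floor_frac * max(y[idx].mean(), 1e-9)
        low = idx[y[idx] < floor]
        y[low] = floor
        floored[low] = True
    if floored.any():
        logger.info("floored %d of %d plot yields", int(floored.sum()), len(lay))
    lay["plot_yield_kg"] = y
    lay["floored"] = floored
    lay["plot_area_ha"] = plot_area_ha
    lay["program"] = (clone_program.reindex(clones).to_numpy()
                      if clone_program is not None else pd.NA)
    lay["submission_year"] = (clone_year.reindex(clones).to_numpy()
                              if clone_year is not None else pd.NA)
    return lay[["clone", "program", "submission_year", "location", "year",
                "plot_yield_kg", "plot_area_ha", "floored"]]


# ---------------------------------------------------------------------------
# Submission years (generation proxy)
# ---------------------------------------------------------------------------


def simulate_submission_years(
    dosage: DosageMatrix,
    gpsm_qtl: list[GpsmQtl],
    year_range: tuple[int, int] = (2010, 2022),
    seed: int = 0,
) -> tuple[pd.Series, DosageMatrix]:
    """Assign submission years and plant directional frequency trends.

    Each clone draws a year uniformly from ``year_range`` (inclusive).  For
    every GPSM QTL, that marker's dosages are resampled from
    Binomial(4, p(year)) with ``p(year) = p0 + delta * (year - first year)``
    clipped to [0.005, 0.995] (a warning is logged when clipping occurs).
    Non-QTL markers are untouched, so they carry no systematic trend.
    """
    y0, y1 = year_range
    if y1 < y0:
        raise InvalidConfigError("year_range end precedes start")
    rng = np.random.default_rng(seed)
    years = pd.Series(rng.integers(y0, y1 + 1, size=dosage.n_clones),
                      index=list(dosage.clones), name="submission_year")
    new_dosages = dosage.dosages.copy()
    for q in gpsm_qtl:
        p = q.base_freq + q.delta_per_year * (years.to_numpy() - y0)
        if (p < FREQ_FLOOR).any() or (p > FREQ_CEIL).any():
            logger.warning("GPSM marker %d frequency clipped to [%.3f, %.3f]",
                           q.marker_index, FREQ_FLOOR, FREQ_CEIL)
        p = np.clip(p, FREQ_FLOOR, FREQ_CEIL)
        new_dosages[q.marker_index] = rng.binomial(4, p).astype(np.int8)
    out = replace(dosage, dosages=new_dosages)
    return years, out
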