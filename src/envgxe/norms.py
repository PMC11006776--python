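"""Per-genotype reaction-norm slopes of yield on trial environments.

For each clone, normalized log yield is regressed by ordinary least squares
on the growing-season value of one environmental variable across the trials
the clone appeared in (model per clone: value = intercept + slope * E).
The slope measures the clone's environmental sensitivity — a Finlay-
Wilkinson-style reaction norm against a measured environmental gradient
rather than a site mean — and feeds the regression GWAS as a derived
phenotype.  Slope standard errors are large relative to the slope range in
realistic designs, so :func:`slope_summary` reports how many 95% CIs cross
zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)


def estimate_slopes(
    normalized_yields: pd.DataFrame,
    trial_env: pd.DataFrame,
    variable: str,
    min_trials: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clone OLS slope of normalized yield on a trial environmental value.

    Parameters
    ----------
    normalized_yields
        Columns ``clone, location, year, value`` (from pheno.normalize_yield).
    trial_env
        Columns ``location, year, <variable>`` giving the within-trial
        seasonal value of the environmental variable.
    variable
        Environmental variable name, e.g. ``"maxTemp"``.
    min_trials
        Minimum number of *distinct* environmental values a clone must have
        been observed under.

    Returns
    -------
    (slopes, excluded):
        ``slopes`` has one row per retained clone with slope, SE, 95% CI
        (Student t), intercept and n_trials; ``excluded`` lists dropped
        clones with the reason.
    """
    if variable not in trial_env.columns:
        raise DataError(f"trial_env has no column {variable!r}")
    env = trial_env.set_index(["location", "year"])[variable]
    df = normalized_yields.copy()
    try:
        df["E"] = env.loc[list(zip(df["location"], df["year"]))].to_numpy(dtype=float)
    except KeyError as exc:
        raise DataError(f"trial missing from trial_env: {exc}") from exc

    rows, dropped = [], []
    for clone, sub in df.groupby("clone", sort=True):
        e = sub["E"].to_numpy()
        v = sub["value"].to_numpy()
        n_distinct = len(np.unique(e))
        if n_distinct < min_trials:
            dropped.append({"clone": clone,
                            "reason": f"{n_distinct} distinct env values < {min_trials}"})
            continue
        if np.ptp(e) == 0:
            dropped.append({"clone": clone, "reason": "zero variance in env values"})
            continue
        n = len(e)
        ec = e - e.mean()
        slope = float(ec @ v / (ec @ ec))
        intercept = float(v.mean() - slope * e.mean())
        resid = v - intercept - slope * e
        dfree = n - 2
        s2 = float(resid @ resid) / dfree if dfree > 0 else np.nan
        se = float(np.sqrt(s2 / (ec @ ec))) if dfree > 0 else np.nan
        tcrit = stats.t.ppf(0.975, dfree) if dfree > 0 else np.nan
        rows.append({
            "clone": clone, "variable": variable, "slope": slope, "se": se,
            "ci_lo": slope - tcrit * se, "ci_hi": slope + tcrit * se,
            "n_trials": int(sub.drop_duplicates(["location", "year"]).shape[0]),
            "intercept": intercept,
        })
    if dropped:
        logger.info("excluded %d clones from slope estimation", len(dropped))
    if not rows:
        raise DataError("no clones with enough trials for slope estimation")
    return pd.DataFrame(rows), pd.DataFrame(dropped, columns=["clone", "reason"])


def slope_summary(slope_table: pd.DataFrame) -> dict:
    """Distribution report for a slope table.

    Reports the fraction of 95% CIs that contain zero (the key caveat for
    using slopes as GWAS responses), the slope range, and SE quantiles.
    """
    if slope_table.empty:
        raise DataError("empty slope table")
    crosses = ((slope_table["ci_lo"] <= 0) & (slope_table["ci_hi"] >= 0))
    se = slope_table["se"].dropna()
    return {
        "n_clones": int(len(slope_table)),
        "frac_ci_crossing_zero": float(crosses.mean()),
        "slope_min": float(slope_table["slope"].min()),
        "slope_max": float(slope_table["slope"].max()),
        "slope_mean": float(slope_table["slope"].mean()),
        "se_median": float(se.median()) if len(se) else float("nan"),
        "se_q90": float(se.quantile(0.9)) if len(se) else float("nan"),
    }
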