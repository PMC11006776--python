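"""Yield filtering, within-trial normalization, and GxE variance decomposition.

The decomposition fits the plot-yield mixed model

    y = mu + Y + L + YL + g + gY + gL + gYL + eps

with year (Y), location (L) and year-by-location (YL) fixed and the four
genetic terms random, and reports each genetic component as a share of the
genetic variance sigma2_g + sigma2_gY + sigma2_gL + sigma2_gYL.

REML implementation
-------------------
The trial-cell fixed effects (mu + Y + L + YL) are equivalent to one mean
per (location, year) trial, so the fixed design is the trial indicator
matrix.  Replicate plots within a (clone, location, year) cell are collapsed
to their cell mean: within-cell contrasts are pure-error contrasts with
variance sigma2_e, contributing the closed-form term
(N - C) log sigma2_e + SSW / sigma2_e to -2 log REML, while the C cell
means carry all genetic information with covariance

    V = s_g A_g + s_gY A_gY + s_gL A_gL + s_gYL I + s_e diag(1/r).

Writing each component as a ratio phi_k = s_k / s_e, sigma2_e profiles out
analytically; the remaining 4-dimensional criterion is minimized by
L-BFGS-B with a zero lower bound, so negative-variance proposals are
projected onto the boundary and reported components are never negative.
This is the exact REML objective of the record-level model, verified in
the test suite against a dense record-level likelihood on tiny instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DataError

logger = logging.getLogger(__name__)

GENETIC_TERMS = ("g", "gY", "gL", "gYL")


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def filter_yields(
    records: pd.DataFrame,
    genotyped_clones: set[str] | None = None,
) -> pd.DataFrame:
    """Drop zero, negative and missing plot yields; optionally require genotypes.

    The variance decomposition uses all clones; the GWAS stages pass
    ``genotyped_clones`` to keep only clones with marker data.  Counts of
    dropped rows are logged.
    """
    n0 = len(records)
    out = records[records["plot_yield_kg"].notna()
                  & (records["plot_yield_kg"] > 0)].copy()
    n_dropped = n0 - len(out)
    if genotyped_clones is not None:
        before = len(out)
        out = out[out["clone"].isin(genotyped_clones)]
        logger.info("dropped %d records without genotypes", before - len(out))
    if n_dropped:
        logger.info("dropped %d of %d records with zero/negative/missing yield",
                    n_dropped, n0)
    if out.empty:
        raise DataError("no usable yield records after filtering")
    return out


def normalize_yield(records: pd.DataFrame) -> pd.DataFrame:
    """Log relative performance within each trial (location-year pair).

    value = ln(plot_yield / trial mean plot_yield); by construction the
    within-trial mean of the ratios is exactly 1.  Trials with a single
    record are excluded with a warning (no within-trial contrast exists).
    """
    out = records.copy()
    sizes = out.groupby(["location", "year"])["plot_yield_kg"].transform("size")
    singletons = sizes < 2
    if singletons.any():
        dropped = out.loc[singletons, ["location", "year"]].drop_duplicates()
        logger.warning("excluding %d single-record trials: %s", len(dropped),
                       dropped.to_records(index=False).tolist())
        out = out[~singletons]
    if out.empty:
        raise DataError("no multi-record trials to normalize")
    trial_mean = out.groupby(["location", "year"])["plot_yield_kg"].transform("mean")
    out["value"] = np.log(out["plot_yield_kg"] / trial_mean)
    return out


# ---------------------------------------------------------------------------
# REML variance decomposition
# ---------------------------------------------------------------------------


@dataclass
class VarianceDecomposition:
    """REML estimates for the yield mixed model."""

    components: dict[str, float]            # sigma2 for g, gY, gL, gYL, e (kg^2)
    genetic_proportions: dict[str, float]   # % of genetic variance per genetic term
    phenotypic_proportions: dict[str, float]  # % of total variance incl. residual
    n_records: int
    n_cells: int
    converged: bool
    n_iter: int
    loglik: float
    notes: list[str] = field(default_factory=list)


def _indicator(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, inv = np.unique(labels, return_inverse=True)
    return levels, inv


def _neg2remlprofile(
    phi: np.ndarray,
    Gs: list[np.ndarray],
    Dinv_r: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    ssw: float,
    n_records: int,
) -> tuple[float, np.ndarray, float]:
    """-2 profile REML (up to a constant), its gradient in phi, and sigma2_e.

    crit(phi) = dof*log(SSW + y'Py) + log|W| + log|X'W^-1 X|, with
    P = W^-1 - W^-1 X (X'W^-1 X)^-1 X'W^-1 and dof = N - rank(X).  The
    gradient per component is tr(P G_k) - dof * (Py)'G_k(Py) / (SSW + y'Py).
    """
    from scipy.linalg import cho_factor, cho_solve

    C = len(y)
    p = X.shape[1]
    W = phi[3] * np.eye(C) + np.diag(Dinv_r)
    for k in range(3):
        W += phi[k] * Gs[k]
    try:
        cf = cho_factor(W, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, np.full(4, np.nan), np.nan
    logdetW = 2.0 * np.log(np.diag(cf[0])).sum()
    Wi = cho_solve(cf, np.eye(C), check_finite=False)
    WiX = Wi @ X
    XtWiX = X.T @ WiX
    sign, logdetX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return np.inf, np.full(4, np.nan), np.nan
    A = np.linalg.solve(XtWiX, WiX.T)
    P = Wi - WiX @ A
    Py = P @ y
    Q = float(y @ Py)
    total_q = ssw + Q
    if total_q <= 0:
        return np.inf, np.full(4, np.nan), np.nan
    dof = n_records - p
    s2e = total_q / dof
    crit = dof * np.log(total_q) + logdetW + logdetX
    grad = np.empty(4)
    for k in range(3):
        grad[k] = float((P * Gs[k]).sum() - dof * (Py @ Gs[k] @ Py) / total_q)
    grad[3] = float(np.trace(P) - dof * (Py @ Py) / total_q)
    return crit, grad, s2e


def _neg2remlprofile_balanced(
    phi: np.ndarray,
    Bs: list[np.ndarray],
    Dinv_t: np.ndarray,
    Dmat: np.ndarray,
    ssw: float,
    n_records: int,
) -> tuple[float, np.ndarray, float]:
    """Balanced-layout REML: every clone in the same trials with equal reps.

    The cell covariance is then I_clones (x) B with B trials x trials, the
    trial-mean fixed effects absorb the between-trial space, and the
    criterion reduces to operations on B and the clone-by-trial residual
    matrix ``Dmat`` (cell means minus trial means).  Identical optimum to
    the dense path, at O(c t^2) per evaluation.
    """
    from scipy.linalg import cho_factor, cho_solve

    c, t = Dmat.shape
    B = phi[3] * np.eye(t) + np.diag(Dinv_t)
    for k in range(3):
        B += phi[k] * Bs[k]
    try:
        cf = cho_factor(B, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, np.full(4, np.nan), np.nan
    logdetB = 2.0 * np.log(np.diag(cf[0])).sum()
    Binv = cho_solve(cf, np.eye(t), check_finite=False)
    E = Dmat @ Binv
    Q = float((E * Dmat).sum())
    total_q = ssw + Q
    if total_q <= 0:
        return np.inf, np.full(4, np.nan), np.nan
    dof = n_records - t
    s2e = total_q / dof
    crit = dof * np.log(total_q) + (c - 1) * logdetB + t * np.log(c)
    grad = np.empty(4)
    Gmats = [*Bs, np.eye(t)]
    for k in range(4):
        tr = float((Binv * Gmats[k]).sum())
        quad = float(((E @ Gmats[k]) * E).sum())
        grad[k] = (c - 1) * tr - dof * quad / total_q
    return crit, grad, s2e


def partition_variance(
    records: pd.DataFrame,
    max_iter: int = 200,
    n_starts: int = 2,
) -> VarianceDecomposition:
    """REML decomposition of plot yield into g, gY, gL, gYL and residual.

    Requires >= 2 years, >= 2 locations and clones replicated across trials;
    separating gYL from the residual additionally requires replicate plots
    within at least some (clone, location, year) cells.  Fully balanced
    layouts (every clone in every trial, equal replication) dispatch to a
    Kronecker-structured evaluation with the same optimum; unbalanced data
    use the dense cell-level likelihood.
    """
    df = records.dropna(subset=["plot_yield_kg"])
    years = df["year"].nunique()
    locs = df["location"].nunique()
    if years < 2 or locs < 2:
        raise DataError(f"need >=2 years and >=2 locations (have {years}, {locs})")
    per_clone = df.drop_duplicates(["clone", "location", "year"]) \
                  .groupby("clone").size()
    if (per_clone < 2).all():
        raise DataError("confounded design: every clone appears in a single trial")

    y_full = df["plot_yield_kg"].to_numpy(dtype=float)
    cell_key = (df["clone"].astype(str) + "\x1f" + df["location"].astype(str)
                + "\x1f" + df["year"].astype(str)).to_numpy()
    cells, cell_inv = _indicator(cell_key)
    C = len(cells)
    N = len(df)
    r = np.bincount(cell_inv).astype(float)
    ybar = np.bincount(cell_inv, weights=y_full) / r
    ssw = float(((y_full - ybar[cell_inv]) ** 2).sum())
    if N == C:
        logger.warning("no replicate plots within cells: gYL and residual are "
                       "confounded; gYL estimate will absorb both")

    # cell-level structure
    parts = np.array([k.split("\x1f") for k in cells])
    clone_c, loc_c, year_c = parts[:, 0], parts[:, 1], parts[:, 2]
    trial_c = np.char.add(np.char.add(loc_c, "\x1f"), year_c)

    trial_levels, trial_inv = _indicator(trial_c)
    clone_levels, clone_inv = _indicator(clone_c)
    t = len(trial_levels)
    n_cl = len(clone_levels)
    balanced = (C == n_cl * t) and (np.ptp(r) == 0)

    if balanced:
        # cell means arranged clones x trials; residuals against trial means
        Y = np.full((n_cl, t), np.nan)
        Y[clone_inv, trial_inv] = ybar
        Dmat = Y - Y.mean(axis=0, keepdims=True)
        tl = np.array([lv.split("\x1f") for lv in trial_levels])
        same_loc = (tl[:, 0][:, None] == tl[:, 0][None, :]).astype(float)
        same_year = (tl[:, 1][:, None] == tl[:, 1][None, :]).astype(float)
        Bs = [np.ones((t, t)), same_year, same_loc]
        Dinv_t = np.full(t, 1.0 / r[0])

        def evaluate(phi: np.ndarray) -> tuple[float, np.ndarray, float]:
            return _neg2remlprofile_balanced(phi, Bs, Dinv_t, Dmat, ssw, N)
    else:
        def crossprod(labels: np.ndarray) -> np.ndarray:
            _, inv = _indicator(labels)
            Z = np.zeros((C, inv.max() + 1))
            Z[np.arange(C), inv] = 1.0
            return Z @ Z.T

        Gs = [crossprod(clone_c),
              crossprod(np.char.add(np.char.add(clone_c, "\x1f"), year_c)),
              crossprod(np.char.add(np.char.add(clone_c, "\x1f"), loc_c))]
        X = np.zeros((C, t))
        X[np.arange(C), trial_inv] = 1.0

        def evaluate(phi: np.ndarray) -> tuple[float, np.ndarray, float]:
            return _neg2remlprofile(phi, Gs, 1.0 / r, X, ybar, ssw, N)

    def obj(phi: np.ndarray) -> tuple[float, np.ndarray]:
        crit, grad, _ = evaluate(phi)
        if not np.isfinite(crit):
            return 1e30, np.zeros(4)
        return crit, grad

    bounds = [(0.0, 1e4)] * 4
    best = None
    starts = [np.full(4, 0.5), np.array([1.0, 0.1, 0.1, 1.0])][:n_starts]
    total_iter = 0
    for x0 in starts:
        res = optimize.minimize(obj, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": max_iter, "ftol": 1e-12})
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= 1e29:
        raise DataError("REML optimization failed: non-finite criterion "
                        f"(trace: {best.message})")
    if not best.success and "ITERATIONS" in str(best.message).upper():
        raise DataError(f"REML did not converge within {max_iter} iterations: "
                        f"{best.message}")

    phi = np.maximum(best.x, 0.0)
    crit, _, s2e = evaluate(phi)
    comps = {t: float(phi[i] * s2e) for i, t in enumerate(GENETIC_TERMS)}
    comps["e"] = float(s2e)
    gen_total = sum(comps[t] for t in GENETIC_TERMS)
    if gen_total <= 0:
        gen_props = {t: float("nan") for t in GENETIC_TERMS}
    else:
        gen_props = {t: 100.0 * comps[t] / gen_total for t in GENETIC_TERMS}
    tot = gen_total + comps["e"]
    phen_props = {t: 100.0 * comps[t] / tot for t in (*GENETIC_TERMS, "e")}
    notes = []
    if N == C:
        notes.append("gYL confounded with residual (no within-cell replication)")
    return VarianceDecomposition(
        components=comps,
        genetic_proportions=gen_props,
        phenotypic_proportions=phen_props,
        n_records=N,
        n_cells=C,
        converged=bool(best.success),
        n_iter=int(total_iter),
        loglik=float(-0.5 * crit),
        notes=notes,
    )
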