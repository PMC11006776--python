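"""Calibration and power studies on the synthetic-trial generator.

Each study simulates trials with known planted truth and measures how the
pipeline behaves: family-wise error under the null, detection power for
planted environmental clines / reaction-norm QTL / directional frequency
trends, agreement of the fast scan with an explicit dense GLS, recovery of
planted variance components, and the transience check (disjoint planted
envGWAS and GPSM signals should yield no cross-analysis hit overlap).

Every study takes a single integer seed; replicate seeds are derived from
it, so results are reproducible end to end.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import envsum, gwas, norms, pheno, pipeline, simdata

logger = logging.getLogger(__name__)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def polygenic_response(K: pd.DataFrame, h2: float, seed: int) -> pd.Series:
    """Heritable polygenic response on a kinship matrix, no single-marker QTL."""
    rng = np.random.default_rng(seed)
    s, U = np.linalg.eigh(K.to_numpy())
    g = U @ (np.sqrt(np.maximum(s, 0.0)) * rng.normal(0, 1, len(s)))
    g = g / g.std() * np.sqrt(h2)
    return pd.Series(g + rng.normal(0, np.sqrt(1 - h2), len(s)), index=K.index)


# ---------------------------------------------------------------------------
# Oracle agreement
# ---------------------------------------------------------------------------


def scan_oracle_gap(seed: int = 0, n_clones: int = 18, n_markers: int = 40) -> dict:
    """Max |p - p_dense| between the P3D scan and explicit dense GLS.

    On a small panel the mixed-model test is recomputed marker by marker
    with a dense inverse of V = sigma2_poly K + sigma2_e I; the spectral
    shortcut must agree essentially exactly.
    """
    sites = simdata.simulate_programs(10, seed)
    dm, _, _ = simdata.simulate_genotypes(n_clones, n_markers, sites, seed=seed)
    dm = gwas.maf_filter(dm, 0.05)
    K = gwas.kinship(dm)
    y = polygenic_response(K, 0.4, seed + 1)
    null = gwas.fit_null(y, K)
    res = gwas.score_markers(dm, y, null)
    V = null.sigma2_poly * K.to_numpy() + null.sigma2_e * np.eye(n_clones)
    Vi = np.linalg.inv(V)
    gap = 0.0
    for i in range(dm.n_markers):
        if res.table["monomorphic"].iloc[i]:
            continue
        X = np.column_stack([np.ones(n_clones), dm.dosages[i].astype(float)])
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y.to_numpy())
        resid = y.to_numpy() - X @ beta
        s2 = float(resid @ Vi @ resid) / (n_clones - 2)
        se = np.sqrt(s2 * np.linalg.inv(XtViX)[1, 1])
        p = 2 * stats.t.sf(abs(beta[1] / se), n_clones - 2)
        gap = max(gap, abs(float(res.table["P"].iloc[i]) - p))
    return {"max_abs_p_diff": gap, "n_clones": n_clones,
            "n_markers": int(dm.n_markers)}


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------


def null_fwer_study(
    n_sims: int = 200,
    n_clones: int = 300,
    n_markers: int = 2000,
    h2: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error rate of the M_eff-adjusted threshold under the null.

    Each replicate simulates an unstructured panel and a heritable
    polygenic response with no marker QTL, scans all markers, and records
    whether any LOD reaches the genome-wide threshold.  Also returns the
    Kolmogorov-Smirnov uniformity p-value of the first replicate's marker
    p-values.
    """
    sites = simdata.simulate_programs(10, seed)
    seeds = _spawn_seeds(seed, n_sims)
    hits = 0
    ks_p = None
    for rep, s in enumerate(seeds):
        dm, _, _ = simdata.simulate_genotypes(n_clones, n_markers, sites,
                                              seed=int(s))
        dm = gwas.maf_filter(dm, 0.01)
        K = gwas.kinship(dm)
        y = polygenic_response(K, h2, int(s) + 1)
        null = gwas.fit_null(y, K)
        res = gwas.score_markers(dm, y, null)
        _, thr = gwas.meff_threshold(dm, alpha)
        hits += int((res.table["LOD"] >= thr).any())
        if ks_p is None:
            ks_p = float(stats.kstest(res.table["P"], "uniform").pvalue)
    return {"fwer": hits / n_sims, "ks_uniformity_p": ks_p,
            "n_sims": n_sims, "n_clones": n_clones, "n_markers": n_markers}


# ---------------------------------------------------------------------------
# Power studies
# ---------------------------------------------------------------------------


def _selection_env_lookup(sites, years: tuple[int, int], seed: int) -> pd.Series:
    """minTemp 3-year selection average per (program, submission year)."""
    sel = [s for s in sites if s.is_selection]
    weather_years = list(range(years[0] - 3, years[1] + 1))
    weather = simdata.simulate_weather(sel, weather_years, seed)
    windows = {s.site_id: s.season_window for s in sel}
    summ = envsum.summarize_sites(weather, windows)
    rows = {}
    for s in sel:
        for yr in range(years[0], years[1] + 1):
            env = envsum.selection_env("x", yr, s.site_id, summ,
                                       s.latitude, s.longitude)
            rows[(s.site_id, yr)] = env.minTemp_sel
    return pd.Series(rows)


def env_qtl_power_study(
    n_reps: int = 50,
    n_clones: int = 500,
    cline: float = 0.15,
    n_markers: int = 1000,
    seed: int = 0,
) -> dict:
    """Detection rate and effect recovery for a planted environmental cline.

    The response is each clone's 3-year pre-submission minTemp average at
    its home site (weather regenerated from the site climates).  The
    reverse-regression effect implied by the planted cline is
    cov(E, dosage) / var(dosage), computed from the generator's per-program
    frequencies as the oracle.
    """
    sites = simdata.simulate_programs(10, seed)
    sel = [s for s in sites if s.is_selection]
    lookup = _selection_env_lookup(sites, (2013, 2022), seed)
    qtl_idx = 50
    seeds = _spawn_seeds(seed + 1, n_reps)
    hits = 0
    effects = []
    scan_ses = []
    for s in seeds:
        dm, truth, prog = simdata.simulate_genotypes(
            n_clones, n_markers, sites,
            [simdata.EnvQtl(qtl_idx, "minTemp", cline)], seed=int(s))
        years, dm = simdata.simulate_submission_years(dm, [], (2013, 2022),
                                                      seed=int(s) + 1)
        y = pd.Series(
            [lookup[(p, int(yr))] for p, yr in zip(prog, years)],
            index=dm.clones)
        dmf = gwas.maf_filter(dm, 0.01)
        K = gwas.kinship(dmf)
        null = gwas.fit_null(y, K)
        res = gwas.score_markers(dmf, y, null)
        _, thr = gwas.meff_threshold(dmf, 0.05)
        marker = dm.markers[qtl_idx]
        row = res.table[res.table["Marker"] == marker]
        hits += int(len(row) and float(row["LOD"].iloc[0]) >= thr)
        if len(row):
            effects.append(float(row["Effect"].iloc[0]))
            scan_ses.append(float(row["SE"].iloc[0]))
    # oracle from the generator's frequency model and the mean site climate
    env_vals = np.array([lookup[(s.site_id, yr)]
                         for s in sel for yr in range(2013, 2023)])
    zsrc = np.array([simdata.program_env_value(s, "minTemp") for s in sel])
    z = np.repeat((zsrc - zsrc.mean()) / zsrc.std(), 10)
    pq = np.clip(0.5 + cline * z, simdata.FREQ_FLOOR, simdata.FREQ_CEIL)
    mean_d = 4 * pq
    cov = float(np.mean(env_vals * mean_d) - env_vals.mean() * mean_d.mean())
    var_d = float(np.mean(4 * pq * (1 - pq)) + mean_d.var())
    oracle = cov / var_d
    effects = np.array(effects)
    return {
        "detection_rate": hits / n_reps,
        "mean_effect": float(effects.mean()),
        "effect_se_of_mean": float(effects.std(ddof=1) / np.sqrt(len(effects))),
        "mean_scan_se": float(np.mean(scan_ses)),
        "oracle_effect": oracle,
        "n_reps": n_reps, "n_clones": n_clones,
    }


def slope_qtl_power_study(
    n_reps: int = 50,
    n_clones: int = 500,
    beta: float = 0.05,
    n_markers: int = 800,
    seed: int = 0,
) -> dict:
    """Detection and effect recovery for a planted reaction-norm QTL.

    Eight trials spanning 10 deg C of growing-season maxTemp, two replicate
    plots each; the QTL adds ``beta`` to the log-relative-yield slope per
    dosage copy, which is exactly the effect the regression GWAS estimates.
    """
    sites = simdata.simulate_programs(10, seed)
    te = pd.DataFrame({"location": list("ABCD") * 2,
                       "year": [1] * 4 + [2] * 4,
                       "maxTemp": np.linspace(20.0, 30.0, 8)})
    qtl_idx = 40
    cfg = pipeline.AnalysisConfig()
    seeds = _spawn_seeds(seed + 2, n_reps)
    hits = 0
    effects = []
    scan_ses = []
    for s in seeds:
        dm, truth, _ = simdata.simulate_genotypes(n_clones, n_markers, sites,
                                                  seed=int(s))
        truth.slope_qtl = [simdata.SlopeQtl(qtl_idx, "maxTemp", beta,
                                            scale="log")]
        truth.variance_components = {"g": 0.5, "gY": 0.1, "gL": 0.3,
                                     "gYL": 0.5, "e": 1.0}
        lay = simdata.make_trial_layout(dm.clones, list("ABCD"), [1, 2], 2)
        yld = simdata.simulate_yields(dm, truth, lay, trial_env=te,
                                      seed=int(s) + 1)
        nd = pheno.normalize_yield(pheno.filter_yields(yld))
        slopes, _ = norms.estimate_slopes(nd, te, "maxTemp", cfg.min_trials)
        res = pipeline.run_regression_gwas(dm, slopes, cfg)
        marker = dm.markers[qtl_idx]
        sig = res.result.significant["Marker"].tolist()
        hits += int(marker in sig)
        row = res.result.table[res.result.table["Marker"] == marker]
        effects.append(float(row["Effect"].iloc[0]))
        scan_ses.append(float(row["SE"].iloc[0]))
    effects = np.array(effects)
    return {
        "detection_rate": hits / n_reps,
        "mean_effect": float(effects.mean()),
        "effect_se_of_mean": float(effects.std(ddof=1) / np.sqrt(len(effects))),
        "mean_scan_se": float(np.mean(scan_ses)),
        "true_effect": beta,
        "n_reps": n_reps, "n_clones": n_clones,
    }


def gpsm_power_study(
    n_reps: int = 50,
    n_clones: int = 800,
    delta: float = 0.02,
    n_markers: int = 1000,
    seed: int = 0,
) -> dict:
    """Detection rate for a planted directional allele-frequency trend."""
    sites = simdata.simulate_programs(10, seed)
    qtl_idx = 60
    cfg = pipeline.AnalysisConfig()
    seeds = _spawn_seeds(seed + 3, n_reps)
    hits = 0
    for s in seeds:
        dm, _, _ = simdata.simulate_genotypes(n_clones, n_markers, sites,
                                              seed=int(s))
        years, dm = simdata.simulate_submission_years(
            dm, [simdata.GpsmQtl(qtl_idx, delta, base_freq=0.3)],
            (2010, 2022), seed=int(s) + 1)
        res = pipeline.run_gpsm(dm, years, cfg)
        hits += int(dm.markers[qtl_idx] in
                    res.result.significant["Marker"].tolist())
    return {"detection_rate": hits / n_reps, "n_reps": n_reps,
            "n_clones": n_clones}


# ---------------------------------------------------------------------------
# Transience (disjoint envGWAS / GPSM signals)
# ---------------------------------------------------------------------------


def transience_study(
    n_reps: int = 30,
    n_clones: int = 400,
    n_markers: int = 800,
    window_bp: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """Hit-overlap between envGWAS and GPSM when their planted QTL are disjoint.

    A strong environmental cline and a strong submission-year trend are
    planted at markers on different chromosomes; in most replicates the
    1-Mb overlap between the two significant sets should be empty,
    mirroring transient (non-directional) local adaptation.
    """
    sites = simdata.simulate_programs(10, seed)
    sel = [s for s in sites if s.is_selection]
    lookup = _selection_env_lookup(sites, (2013, 2022), seed)
    cfg = pipeline.AnalysisConfig()
    env_idx, gpsm_idx = 30, n_markers - 30  # first vs last chromosome
    seeds = _spawn_seeds(seed + 4, n_reps)
    empty = 0
    for s in seeds:
        dm, _, prog = simdata.simulate_genotypes(
            n_clones, n_markers, sites,
            [simdata.EnvQtl(env_idx, "minTemp", 0.2)], seed=int(s))
        years, dm = simdata.simulate_submission_years(
            dm, [simdata.GpsmQtl(gpsm_idx, 0.025, base_freq=0.3)],
            (2013, 2022), seed=int(s) + 1)
        y = pd.Series(
            [lookup[(p, int(yr))] for p, yr in zip(prog, years)],
            index=dm.clones)
        env_res = pipeline.scan_response(dm, y, cfg, "minTemp_sel", "continuous")
        gpsm_res = pipeline.run_gpsm(dm, years, cfg)
        pairs = pipeline.window_overlap(env_res.significant_table(),
                                        gpsm_res.significant_table(),
                                        window_bp)
        empty += int(pairs.empty)
    return {"empty_overlap_rate": empty / n_reps, "n_reps": n_reps,
            "window_bp": window_bp}


# ---------------------------------------------------------------------------
# Variance-component recovery
# ---------------------------------------------------------------------------


def varcomp_recovery_study(
    components: dict[str, float],
    n_clones: int = 500,
    n_locations: int = 2,
    n_years: int = 4,
    n_reps_per_cell: int = 2,
    seed: int = 0,
) -> dict:
    """Recover planted variance components from one simulated trial set.

    Returns the estimated genetic-variance proportions (percent) next to
    the planted ones.
    """
    sites = simdata.simulate_programs(4, seed)
    dm, truth, _ = simdata.simulate_genotypes(n_clones, 10, sites, seed=seed)
    truth.variance_components = dict(components)
    locs = [f"L{i}" for i in range(n_locations)]
    years = list(range(2019, 2019 + n_years))
    lay = simdata.make_trial_layout(dm.clones, locs, years, n_reps_per_cell)
    rec = simdata.simulate_yields(dm, truth, lay, seed=seed + 1)
    vd = pheno.partition_variance(rec)
    gen_total = sum(components[k] for k in pheno.GENETIC_TERMS)
    planted = {k: 100.0 * components[k] / gen_total
               for k in pheno.GENETIC_TERMS}
    return {
        "estimated_pct": vd.genetic_proportions,
        "planted_pct": planted,
        "n_records": vd.n_records,
        "converged": vd.converged,
    }
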