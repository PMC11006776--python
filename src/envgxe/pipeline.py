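"""Orchestration of the five association analyses and result reporting.

Analyses: (1) discrete-program envGWAS (case-control per eligible
program), (2) latitude/longitude envGWAS, (3) continuous selection-
environment envGWAS (3-year minTemp/maxTemp/precip averages), (4)
regression GWAS on reaction-norm slopes, (5) generation-proxy selection
mapping (GPSM) on submission year.  All share the same engine: MAF
filter, kinship, spectral null REML, P3D scan, effective-marker
threshold, then PVE for the significant set by backward elimination.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas
from .errors import DataError, InvalidConfigError
from .simdata import DosageMatrix

logger = logging.getLogger(__name__)

KM_PER_DEGREE_LATITUDE = 111.0

CONTINUOUS_ENV_RESPONSES = ("latitude", "longitude",
                            "minTemp_sel", "maxTemp_sel", "precip_sel")


@dataclass
class AnalysisConfig:
    """Shared knobs for the association analyses."""

    name: str = "analysis"
    program_inclusion_fraction: float = 0.10
    alpha: float = 0.05
    maf_threshold: float = 0.01
    min_trials: int = 3
    overlap_windows_bp: tuple[int, ...] = (1_000_000, 2_000_000, 5_000_000)
    meff_method: str = "galwey"
    n_pcs: int = 0           # optional leading-PC covariates; kinship-only default
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.program_inclusion_fraction < 1.0:
            raise InvalidConfigError("program inclusion fraction must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if not 0.0 <= self.maf_threshold < 0.5:
            raise InvalidConfigError("MAF threshold must be in [0, 0.5)")
        if any(w <= 0 for w in self.overlap_windows_bp):
            raise InvalidConfigError("overlap windows must be positive")


@dataclass
class AnalysisResult:
    """One completed scan with its significant set and PVE report."""

    result: gwas.GwasResult
    pve: gwas.PveReport | None
    trait: str

    def significant_table(self) -> pd.DataFrame:
        """Significant markers in the published table layout."""
        sig = self.result.significant
        out = pd.DataFrame({
            "Trait": self.trait,
            "Marker": sig["Marker"],
            "Chr": sig["Chrom"],
            "Position": sig["Position"],
            "LOD Score": sig["LOD"],
            "Effect": sig["Effect"],
            "PVE": np.nan,
        })
        if self.pve is not None:
            pve_map = self.pve.per_marker.set_index("Marker")["PVE"]
            out["PVE"] = out["Marker"].map(pve_map)
        return out.reset_index(drop=True)


def eligible_programs(
    program_map: pd.Series,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Programs that submitted at least ceil(fraction x panel size) clones.

    The cutoff protects the case-control scans from tiny case groups;
    with a panel of 840 and fraction 0.10 the cutoff is 84.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidConfigError("fraction must be in (0, 1)")
    counts = program_map.value_counts()
    cutoff = math.ceil(fraction * len(program_map))
    out = counts[counts >= cutoff].rename("n_clones").reset_index()
    out.columns = ["program", "n_clones"]
    out["cutoff"] = cutoff
    if out.empty:
        logger.warning("no program reaches the inclusion cutoff of %d", cutoff)
    return out


def scan_response(
    dosage: DosageMatrix,
    response: pd.Series,
    config: AnalysisConfig,
    trait: str,
    model_tag: str,
) -> AnalysisResult:
    """One full scan: MAF filter, kinship, null REML, P3D scan, threshold, PVE."""
    clones = [c for c in dosage.clones if c in response.index
              and pd.notna(response[c])]
    if len(clones) < 3:
        raise DataError(f"{trait}: too few clones with response values")
    sub = dosage.subset_clones(clones)
    sub = gwas.maf_filter(sub, config.maf_threshold)
    K = gwas.kinship(sub)
    covars = None
    if config.n_pcs > 0:
        scores, _ = gwas.pca(sub, config.n_pcs)
        covars = scores
    null = gwas.fit_null(response.loc[clones], K, covars)
    res = gwas.score_markers(sub, response.loc[clones], null, trait, model_tag)
    res.m_eff, res.threshold_lod = gwas.meff_threshold(sub, config.alpha,
                                                       config.meff_method)
    sig = res.significant
    pve = None
    if len(sig):
        pve = gwas.pve_backward_elimination(response.loc[clones],
                                            sig["Marker"].tolist(), sub, null)
    return AnalysisResult(result=res, pve=pve, trait=trait)


def run_env_gwas(
    dosage: DosageMatrix,
    response_kind: str,
    inputs: dict,
    config: AnalysisConfig,
) -> dict[str, AnalysisResult]:
    """Environmental GWAS (reverse regression of dosage on origin descriptor).

    ``response_kind`` is one of ``program``, ``latitude``, ``longitude``,
    ``minTemp_sel``, ``maxTemp_sel``, ``precip_sel``.  ``inputs`` carries
    ``program_map`` (clone -> program Series) and, for continuous kinds,
    ``selection_env`` (DataFrame indexed by clone with the response column).
    Returns trait -> result; the program kind yields one entry per
    eligible program.
    """
    if response_kind == "program":
        program_map = inputs["program_map"]
        elig = eligible_programs(program_map, config.program_inclusion_fraction)
        out: dict[str, AnalysisResult] = {}
        for prog in elig["program"]:
            y = gwas.binary_response(program_map, prog)
            out[prog] = scan_response(dosage, y, config, trait=prog,
                                      model_tag="case-control")
        return out
    if response_kind not in CONTINUOUS_ENV_RESPONSES:
        raise InvalidConfigError(f"unknown envGWAS response kind {response_kind!r}")
    env = inputs["selection_env"]
    y = env[response_kind].astype(float)
    if np.ptp(y.to_numpy()) == 0:
        raise DataError(f"{response_kind} response has zero variance "
                        "(single selection site?)")
    return {response_kind: scan_response(dosage, y, config,
                                         trait=response_kind,
                                         model_tag="continuous")}


def run_regression_gwas(
    dosage: DosageMatrix,
    slope_table: pd.DataFrame,
    config: AnalysisConfig,
) -> AnalysisResult:
    """GWAS of per-clone reaction-norm slopes (GxE mapping)."""
    if len(slope_table) < 30:
        raise DataError(f"only {len(slope_table)} clones with slopes; "
                        "need >= 30 for a regression GWAS")
    variable = slope_table["variable"].iloc[0]
    y = slope_table.set_index("clone")["slope"].astype(float)
    return scan_response(dosage, y, config, trait=f"{variable} slope",
                         model_tag="continuous")


def run_gpsm(
    dosage: DosageMatrix,
    submission_years: pd.Series,
    config: AnalysisConfig,
) -> AnalysisResult:
    """Generation-proxy selection mapping: submission year as the response."""
    if submission_years.nunique() < 2:
        raise DataError("GPSM needs >= 2 distinct submission years")
    y = submission_years.astype(float)
    return scan_response(dosage, y, config, trait="submission year",
                         model_tag="continuous")


def effect_to_distance(effect_degrees: float, axis: str = "latitude") -> float:
    """Convert a latitude-model effect (degrees per dosage copy) to km.

    One degree of latitude spans ~111 km, so a 2-degree effect means a
    copy of the alternative allele is associated with a selection site
    222 km farther north.  Longitude is refused: the length of a degree
    of longitude depends on latitude.
    """
    if axis != "latitude":
        raise InvalidConfigError("degree-to-km conversion is latitude-only")
    if not np.isfinite(effect_degrees):
        raise DataError("non-finite effect size")
    return float(effect_degrees) * KM_PER_DEGREE_LATITUDE


def window_overlap(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    window_bp: int,
) -> pd.DataFrame:
    """Cross-set marker pairs on the same chromosome within ``window_bp``.

    Both inputs need Marker/Chr/Position columns (case per significant
    tables).  The window is inclusive at both ends; chromosome labels are
    compared as strings.
    """
    rows = []
    for _, a in hits_a.iterrows():
        for _, b in hits_b.iterrows():
            if str(a["Chr"]) != str(b["Chr"]):
                continue
            d = abs(int(a["Position"]) - int(b["Position"]))
            if d <= window_bp:
                rows.append({
                    "marker_a": a["Marker"], "marker_b": b["Marker"],
                    "chromosome": str(a["Chr"]), "distance_bp": d,
                    "window_bp": window_bp,
                })
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "chromosome",
                                       "distance_bp", "window_bp"])


def report(
    results: list[AnalysisResult],
    out_dir: str | Path | None = None,
) -> dict:
    """Result tables in the published layout plus a machine-readable summary.

    Per-trait cumulative PVE is printed as the 1-dp-rounded sum of the
    per-marker PVEs; the joint-model R^2 is carried alongside.  When
    ``out_dir`` is given, writes one significant-marker CSV, a Manhattan
    export CSV (all markers with LOD) per analysis, and a JSON summary.
    """
    if not results:
        raise DataError("no completed analyses to report")
    sig_tables = [r.significant_table() for r in results]
    combined = pd.concat(sig_tables, ignore_index=True)
    summary: dict = {"analyses": []}
    for r, sig in zip(results, sig_tables):
        entry = {
            "trait": r.trait,
            "model": r.result.model_tag,
            "n_markers": int(len(r.result.table)),
            "m_eff": r.result.m_eff,
            "threshold_lod": r.result.threshold_lod,
            "n_significant": int(len(sig)),
            "cumulative_pve": (round(float(sig["PVE"].sum()), 1)
                               if len(sig) and sig["PVE"].notna().any() else 0.0),
            "cumulative_pve_joint_r2": (round(r.pve.cumulative_joint, 1)
                                        if r.pve is not None else 0.0),
        }
        summary["analyses"].append(entry)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        combined.to_csv(out_dir / "significant_markers.csv", index=False)
        for r in results:
            safe = r.trait.replace(" ", "_").replace("/", "_")
            cols = ["Marker", "Chrom", "Position", "Effect", "SE", "P", "LOD"]
            r.result.table[cols].to_csv(out_dir / f"manhattan_{safe}.csv",
                                        index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    summary["significant"] = combined
    return summary
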