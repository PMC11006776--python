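"""Autotetraploid dosage association engine.

Single-kinship linear mixed model scanned marker-by-marker:

    response = X beta + dosage * b + u + eps,
    u ~ N(0, sigma2_poly * K),  eps ~ N(0, sigma2_e * I),

with K the realized relationship matrix from centered 0-4 dosages.  The
null variance ratio lambda = sigma2_poly / sigma2_e is estimated once by
REML through the eigendecomposition of K and reused for every marker
(P3D), which reduces each marker test to weighted least squares in the
rotated basis.  In envGWAS mode the "response" is an environmental
descriptor of each clone's origin (reverse regression); in GPSM mode it is
the clone's first trial-submission year.

Genome-wide significance uses the Li-Ji effective number of independent
tests, computed from the eigenvalues of the marker correlation matrix per
chromosome and summed; LOD threshold = -log10(alpha / M_eff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .errors import DataError, InvalidConfigError
from .simdata import DosageMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Marker filtering, kinship, structure
# ---------------------------------------------------------------------------


def maf_filter(dosage: DosageMatrix, threshold: float = 0.01) -> DosageMatrix:
    """Remove markers with folded minor allele frequency below ``threshold``.

    Allele frequency is mean dosage / 4; MAF = min(f, 1 - f).  At
    threshold 0 only strictly monomorphic markers are removed.
    """
    if not 0.0 <= threshold < 0.5:
        raise InvalidConfigError(f"MAF threshold {threshold} outside [0, 0.5)")
    f = dosage.allele_freqs()
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= threshold if threshold > 0 else maf > 0
    dropped = [m for m, k in zip(dosage.markers, keep) if not k]
    if dropped:
        logger.info("MAF filter removed %d of %d markers", len(dropped),
                    dosage.n_markers)
    if not keep.any():
        raise DataError("all markers removed by MAF filter")
    return dosage.subset_markers(keep)


def kinship(dosage: DosageMatrix) -> pd.DataFrame:
    """Realized relationship matrix K = ZZ'/c from centered dosages.

    Z is clones x markers with each marker (column) centered; the scaling
    c = trace(ZZ')/n makes the mean diagonal exactly 1.
    """
    if dosage.n_clones < 2:
        raise DataError("kinship needs >= 2 clones")
    D = dosage.dosages.astype(float)
    Z = (D - D.mean(axis=1, keepdims=True)).T  # clones x markers
    if not np.any(Z):
        raise DataError("kinship undefined: all markers monomorphic")
    K = Z @ Z.T
    c = np.trace(K) / dosage.n_clones
    K /= c
    return pd.DataFrame(K, index=dosage.clones, columns=dosage.clones)


def pca(dosage: DosageMatrix, n_components: int = 5) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the clone panel (population structure).

    Returns per-clone scores and the explained-variance fractions.
    """
    n_components = min(n_components, dosage.n_clones, dosage.n_markers)
    X = dosage.dosages.T.astype(float)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=dosage.clones, columns=cols),
            model.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# Null model (EMMA-style spectral REML) and P3D scan
# ---------------------------------------------------------------------------


@dataclass
class NullFit:
    """Null-model REML fit and the spectral cache reused across markers."""

    clones: list[str]
    eigvecs: np.ndarray      # U, n x n
    eigvals: np.ndarray      # s, len n
    lam: float               # sigma2_poly / sigma2_e at the REML optimum
    sigma2_e: float
    sigma2_poly: float
    X_rot: np.ndarray        # U' X (covariate design incl. intercept)
    y_rot: np.ndarray        # U' y
    weights: np.ndarray      # 1 / (lam * s + 1)
    loglik: float

    @property
    def heritability(self) -> float:
        return self.sigma2_poly / (self.sigma2_poly + self.sigma2_e)


def fit_null(
    response: pd.Series,
    K: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> NullFit:
    """REML fit of response = X beta + u + eps with Cov(u) = sigma2_poly K.

    One-dimensional REML over log(lambda) using the eigendecomposition of
    K; the rotation is cached and reused for every marker (P3D).
    """
    clones = list(response.index)
    y = response.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DataError("response has zero variance")
    Km = K.loc[clones, clones].to_numpy(dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.hstack([X, covariates.loc[clones].to_numpy(dtype=float)])
    p = X.shape[1]

    s, U = np.linalg.eigh(Km)
    s = np.maximum(s, 0.0)
    y_rot = U.T @ y
    X_rot = U.T @ X

    def neg2reml(loglam: float) -> float:
        lam = np.exp(loglam)
        w = 1.0 / (lam * s + 1.0)
        XtWX = (X_rot * w[:, None]).T @ X_rot
        sign, logdetX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, (X_rot * w[:, None]).T @ y_rot)
        resid = y_rot - X_rot @ beta
        rss = float(resid @ (w * resid))
        if rss <= 0:
            return np.inf
        return ((n - p) * np.log(rss) - np.log(w).sum() + logdetX)

    res = optimize.minimize_scalar(neg2reml, bounds=(-12.0, 12.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    # prefer the boundary when the interior optimum is not better
    if neg2reml(-12.0) <= res.fun:
        lam = np.exp(-12.0)
    w = 1.0 / (lam * s + 1.0)
    XtWX = (X_rot * w[:, None]).T @ X_rot
    beta = np.linalg.solve(XtWX, (X_rot * w[:, None]).T @ y_rot)
    resid = y_rot - X_rot @ beta
    sigma2_e = float(resid @ (w * resid)) / (n - p)
    return NullFit(
        clones=clones, eigvecs=U, eigvals=s, lam=lam,
        sigma2_e=sigma2_e, sigma2_poly=lam * sigma2_e,
        X_rot=X_rot, y_rot=y_rot, weights=w,
        loglik=float(-0.5 * neg2reml(np.log(lam))),
    )


@dataclass
class GwasResult:
    """Per-marker scan results plus the genome-wide threshold."""

    table: pd.DataFrame             # Marker, Chrom, Position, Effect, SE, P, LOD
    response_name: str
    model_tag: str                  # "continuous" | "case-control"
    threshold_lod: float | None = None
    m_eff: float | None = None

    @property
    def significant(self) -> pd.DataFrame:
        """Markers with LOD >= threshold (inclusive at the boundary)."""
        if self.threshold_lod is None:
            raise DataError("no threshold set on this result")
        return self.table[self.table["LOD"] >= self.threshold_lod].copy()


def score_markers(
    dosage: DosageMatrix,
    response: pd.Series,
    nullfit: NullFit,
    response_name: str = "response",
    model_tag: str = "continuous",
) -> GwasResult:
    """P3D mixed-model scan: GLS of the response on each marker's dosage.

    Under the cached null rotation each test is weighted least squares of
    the rotated response on [covariates, rotated dosage].  The variance
    ratio is fixed from the null fit; the residual scale is re-estimated
    per marker, giving a Wald t-test with n - p - 1 df that collapses to
    the textbook OLS t-test when K = I.  Markers monomorphic on the tested
    clones get p = 1 and a flag.
    """
    if list(response.index) != nullfit.clones:
        response = response.loc[nullfit.clones]
    clone_col = {c: j for j, c in enumerate(dosage.clones)}
    cols = [clone_col[c] for c in nullfit.clones]
    G = dosage.dosages[:, cols].astype(float).T       # n x M
    U, w = nullfit.eigvecs, nullfit.weights
    X_rot, y_rot = nullfit.X_rot, nullfit.y_rot
    n, p = X_rot.shape

    G_rot = U.T @ G
    # residualize dosage and response against covariates under W
    XtWX = (X_rot * w[:, None]).T @ X_rot
    XtWX_inv = np.linalg.inv(XtWX)
    proj = X_rot @ (XtWX_inv @ ((X_rot * w[:, None]).T))   # n x n hat-maker
    G_res = G_rot - proj @ G_rot
    y_res = y_rot - proj @ y_rot

    gwg = np.einsum("ij,ij->j", G_res, w[:, None] * G_res)
    gwy = (w * y_res) @ G_res
    ywy = float(y_res @ (w * y_res))

    mono = gwg <= 1e-12 * max(float(gwg.max(initial=0.0)), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(mono, 0.0, gwy / gwg)
        rss = ywy - effect * gwy
        dfree = n - p - 1
        s2 = rss / dfree
        se = np.sqrt(np.where(mono, np.nan, s2 / gwg))
        tstat = effect / se
    pvals = np.where(mono, 1.0, 2.0 * stats.t.sf(np.abs(tstat), dfree))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    if mono.any():
        logger.info("%d markers monomorphic on tested clones (p set to 1)",
                    int(mono.sum()))
    table = pd.DataFrame({
        "Marker": dosage.markers,
        "Chrom": dosage.chrom,
        "Position": dosage.pos,
        "Effect": effect,
        "SE": se,
        "P": pvals,
        "LOD": -np.log10(pvals),
        "monomorphic": mono,
    })
    return GwasResult(table=table, response_name=response_name, model_tag=model_tag)


# ---------------------------------------------------------------------------
# Multiple testing: effective number of markers
# ---------------------------------------------------------------------------


def _li_ji_meff(eigvals: np.ndarray) -> float:
    lam = np.abs(eigvals)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def _galwey_meff(eigvals: np.ndarray) -> float:
    lam = np.maximum(eigvals, 0.0)
    return float(np.sqrt(lam).sum() ** 2 / lam.sum())


def meff_threshold(
    dosage: DosageMatrix,
    alpha: float = 0.05,
    method: str = "galwey",
) -> tuple[float, float]:
    """Effective marker count and the genome-wide LOD threshold.

    The effective number of independent tests comes from the eigenvalues
    of the marker correlation matrix, computed per chromosome and summed.
    The default is Galwey's (sum sqrt(lambda))^2 / sum(lambda): it is
    continuous in the eigenvalues and exactly invariant to duplicating
    markers (perfect LD collapses to one effective test).  The Li-Ji count
    (``method="li-ji"``) is available but its integer-jump at lambda = 1, 2,
    ... makes it overcount near-duplicate markers estimated from finite
    panels; ``method="bonferroni"`` uses the raw marker count.
    Threshold LOD = -log10(alpha / M_eff).
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidConfigError(f"alpha {alpha} outside (0, 1)")
    if dosage.n_markers < 2:
        raise DataError("need >= 2 markers for a genome-wide threshold")
    if method == "bonferroni":
        m_eff = float(dosage.n_markers)
    elif method in ("galwey", "li-ji"):
        per_block = _galwey_meff if method == "galwey" else _li_ji_meff
        m_eff = 0.0
        D = dosage.dosages.astype(float)
        sd = D.std(axis=1)
        if (sd == 0).any():
            logger.info("excluding %d monomorphic markers from M_eff",
                        int((sd == 0).sum()))
        for c in pd.unique(dosage.chrom):
            sub = D[(dosage.chrom == c) & (sd > 0)]
            if len(sub) == 0:
                continue
            if len(sub) == 1:
                m_eff += 1.0
                continue
            R = np.corrcoef(sub)
            m_eff += per_block(np.linalg.eigvalsh(R))
    else:
        raise InvalidConfigError(f"unknown M_eff method {method!r}")
    threshold = float(-np.log10(alpha / m_eff))
    return m_eff, threshold


# ---------------------------------------------------------------------------
# PVE by backward elimination
# ---------------------------------------------------------------------------


@dataclass
class PveReport:
    """Percent variance explained for the significant marker set."""

    per_marker: pd.DataFrame        # Marker, PVE, elimination order
    cumulative_joint: float         # joint-model R^2 x 100
    dropped_collinear: list[str] = field(default_factory=list)

    @property
    def cumulative_sum(self) -> float:
        """Sum of per-marker PVEs (the additivity printed in result tables)."""
        return float(self.per_marker["PVE"].sum())


def pve_backward_elimination(
    response: pd.Series,
    significant_markers: list[str],
    dosage: DosageMatrix,
    nullfit: NullFit,
    tolerance: float = 1e-10,
) -> PveReport:
    """PVE per significant marker via drop-one R^2 under the null covariance.

    All significant markers enter one whitened (GLS) fixed-effects model;
    a marker's PVE is the drop in model R^2 when it alone is removed
    (x100), and the cumulative PVE is the joint-model R^2 (x100).  Of a
    collinear pair, the member with the smaller marginal effect is dropped
    with a warning.  R^2 changes below ``tolerance`` report as 0.
    """
    if not significant_markers:
        raise DataError("empty significant set")
    midx = {m: i for i, m in enumerate(dosage.markers)}
    missing = [m for m in significant_markers if m not in midx]
    if missing:
        raise DataError(f"markers absent from dosage matrix: {missing}")
    clone_col = {c: j for j, c in enumerate(dosage.clones)}
    cols = [clone_col[c] for c in nullfit.clones]
    sqw = np.sqrt(nullfit.weights)[:, None]
    U = nullfit.eigvecs
    Xw = sqw * nullfit.X_rot
    yw = (sqw[:, 0]) * nullfit.y_rot

    keep = list(significant_markers)
    G = dosage.dosages[np.ix_([midx[m] for m in keep], cols)].astype(float).T
    Gw = sqw * (U.T @ G)
    dropped: list[str] = []
    # greedy collinearity pruning on the whitened design
    while len(keep) > 1:
        M = np.hstack([Xw, Gw])
        if np.linalg.matrix_rank(M, tol=1e-8) == M.shape[1]:
            break
        # drop the collinear marker with the smallest marginal |effect|
        effects = np.abs(np.linalg.lstsq(M, yw, rcond=None)[0][Xw.shape[1]:])
        j = int(np.argmin(effects))
        logger.warning("dropping collinear marker %s from PVE model", keep[j])
        dropped.append(keep.pop(j))
        Gw = np.delete(Gw, j, axis=1)

    def r2(design: np.ndarray) -> float:
        rss_null = float(yw @ yw - yw @ Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0])
        coef, *_ = np.linalg.lstsq(design, yw, rcond=None)
        rss = float(((yw - design @ coef) ** 2).sum())
        return 1.0 - rss / rss_null

    full_design = np.hstack([Xw, Gw])
    r2_full = r2(full_design)
    rows = []
    for j, m in enumerate(keep):
        reduced = np.hstack([Xw, np.delete(Gw, j, axis=1)])
        delta = r2_full - r2(reduced)
        rows.append({"Marker": m,
                     "PVE": 0.0 if delta < tolerance else 100.0 * delta,
                     "elimination_order": j + 1})
    return PveReport(
        per_marker=pd.DataFrame(rows),
        cumulative_joint=100.0 * r2_full,
        dropped_collinear=dropped,
    )


# ---------------------------------------------------------------------------
# Case-control response
# ---------------------------------------------------------------------------


def binary_response(program_map: pd.Series, target_program: str) -> pd.Series:
    """0/1 response: 1 for clones from ``target_program``.

    The linear-model treatment of this binary response is a first-order
    approximation to the logistic model; effect sizes read as the change in
    the probability a clone came from the target program per dosage copy.
    """
    if target_program not in set(program_map):
        raise DataError(f"unknown program {target_program!r}")
    y = (program_map == target_program).astype(float)
    n_case = int(y.sum())
    if n_case == 0 or n_case == len(y):
        raise DataError(f"degenerate case-control split for {target_program!r}")
    logger.info("case-control %s: %d cases / %d controls",
                target_program, n_case, len(y) - n_case)
    return y.rename(f"program={target_program}")
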