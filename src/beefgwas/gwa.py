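"""Kinship mixed-model association analysis.

The model for one trait is

    y = X b + Z u + e,    u ~ N(0, sigma2_a G),    e ~ N(0, sigma2_e I)

with G the VanRaden genomic relationship matrix built from centred SNP
dosages.  Variance components are estimated once per trait by REML under
the null (no-SNP) model, profiling the ratio lambda = sigma2_a / sigma2_e
on a single spectral decomposition of G; each marker is then tested by
generalized least squares with the covariance sigma2_a G + sigma2_e I held
fixed (the standard one-variance-fit approximation).  Exact per-marker
REML is available behind ``per_snp_reml=True`` for small panels.

Fixed effects default to an intercept plus year-of-birth; population
structure is absorbed by G (breed-composition covariates can be added
through ``extra_covariates`` but are off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .formats_io import GenotypeMatrix, Variant

__all__ = [
    "Grm",
    "VarianceComponents",
    "AssocResult",
    "JointModelResult",
    "preprocess_trait",
    "johnson_su_params",
    "compute_grm",
    "fit_reml",
    "scan",
    "conditional_scan",
    "joint_fit",
]


# ---------------------------------------------------------------------------
# Phenotype preprocessing
# ---------------------------------------------------------------------------


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offsets, average ranks)."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    n = len(x)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def johnson_su_params(x: np.ndarray, z: float = 0.524) -> tuple[float, float, float, float] | None:
    """Fit Johnson SU parameters (gamma, delta, xi, lam) by quantile matching.

    Uses the four symmetric sample quantiles at +-z and +-3z standard-normal
    points (Slifker & Shapiro's selection rule).  Returns None when the
    quantile spreads place the sample outside the SU region or the fitted
    transform would not be strictly increasing, in which case the caller
    falls back to the rank-based inverse-normal transform.
    """
    x = np.asarray(x, dtype=float)
    probs = stats.norm.cdf([-3 * z, -z, z, 3 * z])
    x1, x2, x3, x4 = np.quantile(x, probs)
    m = x4 - x3
    n_ = x2 - x1
    p = x3 - x2
    if p <= 0 or m <= 0 or n_ <= 0:
        return None
    ratio = m * n_ / p**2
    if ratio <= 1.0 + 1e-9:
        return None  # SB / SL / SN region
    mp, np_ = m / p, n_ / p
    try:
        delta = 2 * z / math.acosh(0.5 * (mp + np_))
        gamma = delta * math.asinh((np_ - mp) / (2 * math.sqrt(ratio - 1)))
        lam = (
            2 * p * math.sqrt(ratio - 1) / ((mp + np_ - 2) * math.sqrt(mp + np_ + 2))
        )
        xi = 0.5 * (x3 + x2) + p * (np_ - mp) / (2 * (mp + np_ - 2))
    except (ValueError, ZeroDivisionError):
        return None
    if not (delta > 0 and lam > 0) or not all(
        map(math.isfinite, (gamma, delta, xi, lam))
    ):
        return None
    return gamma, delta, xi, lam


def preprocess_trait(values: np.ndarray | pd.Series, trait_name: str) -> np.ndarray:
    """Analysis-ready transform of a raw trait vector.

    * WBSF: natural log (values must be positive);
    * marbling and connective tissue: Johnson SU normalization fitted by
      quantile matching, falling back to the rank-based inverse-normal
      transform when the SU fit is unavailable;
    * other traits: passed through unchanged.

    Missing values are preserved; all transforms are strictly monotone, so
    rank order is never changed.  Distribution fitting requires at least 30
    non-missing values.
    """
    v = np.asarray(values, dtype=float)
    name = trait_name.strip().lower()
    out = v.copy()
    obs = ~np.isnan(v)
    if name == "wbsf":
        if np.any(v[obs] <= 0):
            raise ValueError("WBSF values must be positive for log transform")
        out[obs] = np.log(v[obs])
        return out
    if name in ("marbling", "connective_tissue", "connective tissue"):
        x = v[obs]
        if len(x) < 30:
            raise ValueError(
                f"{trait_name}: need >= 30 non-missing values for normalization, "
                f"got {len(x)}"
            )
        params = johnson_su_params(x)
        if params is not None:
            gamma, delta, xi, lam = params
            out[obs] = gamma + delta * np.arcsinh((x - xi) / lam)
        else:
            out[obs] = inverse_normal_transform(x)
        return out
    return out


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


@dataclass
class Grm:
    """VanRaden method-1 genomic relationship matrix."""

    matrix: np.ndarray
    freqs: np.ndarray
    n_variants: int

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")


def compute_grm(g: GenotypeMatrix) -> Grm:
    """G = W W' / (2 sum p(1-p)) with W the dosages centred at 2p.

    Missing dosages are mean-imputed (equivalently, centred to zero).
    Monomorphic variants make the centring degenerate and must be removed
    by QC first.
    """
    x = g.imputed()
    p = x.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        bad = g.variant_ids[int(np.argmax((p <= 0) | (p >= 1)))]
        raise ValueError(
            f"monomorphic variant {bad} present; run qc_filter before compute_grm"
        )
    w = x - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    mat = (w @ w.T) / denom
    mat = 0.5 * (mat + mat.T)
    return Grm(matrix=mat, freqs=p, n_variants=g.n_variants)


# ---------------------------------------------------------------------------
# REML via spectral decomposition
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    lam: float
    h2: float
    reml_loglik: float
    at_boundary: bool = False


_LOG_LAMBDA_BOUNDS = (-5.0, 5.0)  # log10 scale


def _reml_neg_loglik(
    log10_lam: float,
    d: np.ndarray,
    yr: np.ndarray,
    xr: np.ndarray,
) -> float:
    """-2x restricted log-likelihood profile in lambda (up to a constant).

    ``d`` are eigenvalues of G, ``yr``/``xr`` the rotated response/design.
    """
    lam = 10.0**log10_lam
    w = 1.0 / (lam * d + 1.0)
    n, p = xr.shape
    xtwx = xr.T @ (w[:, None] * xr)
    xtwy = xr.T @ (w * yr)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yr - xr @ beta
    rss = float(np.sum(w * resid**2))
    if rss <= 0:
        return np.inf
    sigma2_e = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    ll2 = (
        (n - p) * math.log(sigma2_e)
        + float(np.sum(np.log(lam * d + 1.0)))
        + logdet_xtwx
        + (n - p)
    )
    return ll2


def _fit_reml_rotated(
    d: np.ndarray, yr: np.ndarray, xr: np.ndarray
) -> VarianceComponents:
    lo, hi = _LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, 61)
    vals = np.array([_reml_neg_loglik(t, d, yr, xr) for t in grid])
    best = int(np.argmin(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(a, b),
        args=(d, yr, xr),
        method="bounded",
        options={"xatol": 1e-7},
    )
    log10_lam = float(res.x) if res.fun <= vals[best] else grid[best]
    lam = 10.0**log10_lam
    at_boundary = log10_lam <= lo + 1e-3 or log10_lam >= hi - 1e-3
    # recover sigma2_e at the optimum
    w = 1.0 / (lam * d + 1.0)
    n, p = xr.shape
    xtwx = xr.T @ (w[:, None] * xr)
    beta = np.linalg.solve(xtwx, xr.T @ (w * yr))
    rss = float(np.sum(w * (yr - xr @ beta) ** 2))
    sigma2_e = rss / (n - p)
    sigma2_a = lam * sigma2_e
    # boundary at the low end means essentially no additive variance
    if at_boundary and log10_lam <= lo + 1e-3:
        sigma2_a = 0.0
        lam = 0.0
    ll = -0.5 * (
        _reml_neg_loglik(log10_lam, d, yr, xr) + (n - p) * math.log(2 * math.pi)
    )
    return VarianceComponents(
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        lam=lam,
        h2=sigma2_a / (sigma2_a + sigma2_e),
        reml_loglik=ll,
        at_boundary=at_boundary,
    )


def _eigh_psd(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with small negative eigenvalues clipped to zero."""
    d, u = np.linalg.eigh(gmat)
    if d.min() < -1e-6 * max(1.0, abs(d.max())):
        # genuinely indefinite input is still clipped but worth a loud check
        if d.min() < -1e-2 * max(1.0, abs(d.max())):
            raise ValueError("relationship matrix is not positive semi-definite")
    return np.clip(d, 0.0, None), u


def fit_reml(
    y: np.ndarray,
    X_covariates: np.ndarray,
    grm: Grm | np.ndarray,
) -> VarianceComponents:
    """REML variance components for ``y = X b + u + e`` with ``u ~ N(0, s2a G)``.

    ``y`` must be complete: drop missing samples (with the matching rows of
    X and G) before calling.  lambda = sigma2_a/sigma2_e is profiled on the
    log10 scale over [-5, 5] by a coarse grid followed by bounded scalar
    minimization; a solution pinned at either end is flagged via
    ``at_boundary`` rather than treated as an error.
    """
    gmat = grm.matrix if isinstance(grm, Grm) else np.asarray(grm, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X_covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(y).any():
        raise ValueError("y contains missing values; subset samples first")
    if not (len(y) == X.shape[0] == gmat.shape[0]):
        raise ValueError("y, X and G have inconsistent sample dimensions")
    d, u = _eigh_psd(gmat)
    return _fit_reml_rotated(d, u.T @ y, u.T @ X)


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------


def _design_matrix(
    pheno: pd.DataFrame,
    covariates: tuple[str, ...],
    rows: np.ndarray,
) -> np.ndarray:
    """Intercept plus dummy-coded categorical / numeric covariates."""
    cols = [np.ones(rows.sum())]
    sub = pheno.loc[rows]
    for cov in covariates:
        if cov not in pheno.columns:
            raise KeyError(f"covariate {cov!r} not in phenotype table")
        col = sub[cov]
        if col.dtype.kind in "OUSb" or cov in ("year", "breed_group"):
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


def _aligned_trait(
    g: GenotypeMatrix, pheno: pd.DataFrame, trait: str, preprocess: bool
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Align phenotype rows to genotype samples; returns (y, sample_mask, pheno_aligned)."""
    ph = pheno.set_index("sample_id").reindex(g.samples).reset_index()
    if trait not in ph.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    raw = ph[trait].to_numpy(float)
    y = preprocess_trait(raw, trait) if preprocess else raw
    mask = ~np.isnan(y)
    return y, mask, ph


# ---------------------------------------------------------------------------
# Single-marker scan
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    variant: Variant
    trait: str
    beta: float
    se: float
    wald: float
    p: float
    note: str = ""

    @property
    def ok(self) -> bool:
        return not math.isnan(self.p)


def _gls_scan_rotated(
    ystar: np.ndarray,
    xstar: np.ndarray,
    sstar: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column GLS of SNP added to covariates, in whitened coordinates.

    Returns (beta, se, wald, p) arrays; collinear columns come back NaN.
    """
    n, p = xstar.shape
    q, _ = np.linalg.qr(xstar)
    y_res = ystar - q @ (q.T @ ystar)
    s_res = sstar - q @ (q.T @ sstar)
    sxx = np.einsum("ij,ij->j", s_res, s_res)
    sxy = y_res @ s_res
    yy = float(y_res @ y_res)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = yy - beta * sxy
        dof = n - p - 1
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / sxx)
        wald = beta**2 / se**2
    bad = sxx <= 1e-10 * n
    beta[bad] = np.nan
    se[bad] = np.nan
    wald[bad] = np.nan
    pvals = stats.chi2.sf(wald, df=1)
    pvals = np.where(np.isnan(wald), np.nan, np.maximum(pvals, 1e-300))
    return beta, se, wald, pvals


def scan(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    covariates: tuple[str, ...] = ("year",),
    vc: VarianceComponents | None = None,
    grm: Grm | None = None,
    preprocess: bool = True,
    extra_covariate_columns: np.ndarray | None = None,
    variant_subset: list[str] | None = None,
    per_snp_reml: bool = False,
) -> list[AssocResult]:
    """Single-marker mixed-model scan for one trait.

    Each variant's dosage is added in turn to the fixed effects (intercept +
    ``covariates``) and tested with a 1-df two-sided Wald test under the
    covariance ``sigma2_a G + sigma2_e I`` fixed at the null-model REML
    estimates (pass ``vc`` to reuse them).  ``extra_covariate_columns``
    appends already-aligned numeric columns (used by the conditional scan).
    With ``sigma2_a == 0`` the test reduces exactly to ordinary least
    squares.
    """
    y_full, mask, ph = _aligned_trait(g, pheno, trait, preprocess)
    if mask.sum() < 3:
        raise ValueError(f"trait {trait!r}: fewer than 3 non-missing samples")
    rows = np.where(mask)[0]
    y = y_full[rows]
    X = _design_matrix(ph, covariates, mask)
    if extra_covariate_columns is not None:
        extra = np.atleast_2d(np.asarray(extra_covariate_columns, dtype=float))
        if extra.shape[0] != mask.sum():
            extra = extra.T
        X = np.column_stack([X, extra])

    gsub = g.subset(sample_idx=rows)
    if grm is None:
        grm = compute_grm(gsub)
    gmat = grm.matrix
    if gmat.shape[0] == g.n_samples and mask.sum() != g.n_samples:
        gmat = gmat[np.ix_(rows, rows)]
    d, u = _eigh_psd(gmat)
    yr, xr = u.T @ y, u.T @ X
    if vc is None:
        vc = _fit_reml_rotated(d, yr, xr)

    dose = gsub.imputed()
    if variant_subset is not None:
        keep = [gsub.column_index(vid) for vid in variant_subset]
        dose = dose[:, keep]
        variants = [gsub.variants[j] for j in keep]
    else:
        variants = gsub.variants

    if per_snp_reml:
        results: list[AssocResult] = []
        sr_all = u.T @ dose
        for j, v in enumerate(variants):
            xr_j = np.column_stack([xr, sr_all[:, j]])
            vc_j = _fit_reml_rotated(d, yr, xr_j)
            w = np.sqrt(1.0 / (vc_j.lam * d + 1.0))
            b, s, wd, p = _gls_scan_rotated(
                w * yr, w * xr, (w * sr_all[:, j])[:, None]
            )
            results.append(_make_result(v, trait, b[0], s[0], wd[0], p[0]))
        return results

    w = np.sqrt(1.0 / (vc.lam * d + 1.0))
    ystar = w * yr
    xstar = w[:, None] * xr
    sstar = w[:, None] * (u.T @ dose)
    beta, se, wald, pvals = _gls_scan_rotated(ystar, xstar, sstar)
    return [
        _make_result(v, trait, beta[j], se[j], wald[j], pvals[j])
        for j, v in enumerate(variants)
    ]


def _make_result(
    v: Variant, trait: str, beta: float, se: float, wald: float, p: float
) -> AssocResult:
    note = "" if not math.isnan(p) else "collinear with covariates"
    return AssocResult(
        variant=v, trait=trait, beta=float(beta), se=float(se), wald=float(wald),
        p=float(p), note=note,
    )


def conditional_scan(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    condition_on: str,
    region: tuple[str, int, int] | None = None,
    covariates: tuple[str, ...] = ("year",),
    vc: VarianceComponents | None = None,
    preprocess: bool = True,
) -> list[AssocResult]:
    """Re-scan a region with one SNP's dosage fitted as a fixed effect.

    Mirrors the follow-up analysis in which the most significant SNP of a
    QTL region is added to the fixed effects and the remaining SNPs are
    tested individually; the conditioning SNP itself is excluded from the
    output.  ``region`` is (chrom, start1, end1); None means genome-wide.
    """
    cond_col_full = g.column(condition_on)
    with np.errstate(invalid="ignore"):
        if np.nanstd(cond_col_full) == 0:
            raise ValueError(f"conditioning SNP {condition_on} is monomorphic")

    _, mask, _ = _aligned_trait(g, pheno, trait, preprocess)
    rows = np.where(mask)[0]
    cond = cond_col_full[rows]
    if np.isnan(cond).any():
        cond = np.where(np.isnan(cond), np.nanmean(cond), cond)

    if region is None:
        in_region = [v.id for v in g.variants]
    else:
        chrom, start1, end1 = region
        in_region = [
            v.id
            for v in g.variants
            if v.chrom == chrom and start1 <= v.pos <= end1
        ]
    targets = [vid for vid in in_region if vid != condition_on]
    if not targets:
        return []
    return scan(
        g,
        pheno,
        trait,
        covariates=covariates,
        vc=vc,
        preprocess=preprocess,
        extra_covariate_columns=cond,
        variant_subset=targets,
    )


# ---------------------------------------------------------------------------
# Joint multi-SNP model with backward elimination
# ---------------------------------------------------------------------------


@dataclass
class JointModelResult:
    gene_id: str
    trait: str
    retained: list[str]
    betas: dict[str, float]
    pvalues: dict[str, float]
    trace: list[tuple[str, float]] = field(default_factory=list)
    """(variant_id, p at removal) in elimination order."""


def joint_fit(
    g: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    snps: list[str],
    alpha: float = 0.05,
    gene_id: str = "",
    covariates: tuple[str, ...] = ("year",),
    preprocess: bool = True,
) -> JointModelResult:
    """Fit a gene's pruned SNPs simultaneously; drop until all are significant.

    All SNPs enter the mixed model together (covariance from the null-model
    REML fit, as in :func:`scan`); while any joint Wald p exceeds ``alpha``
    the least significant SNP is removed (ties broken by larger p then by
    larger input index) and the model refitted.  The final model therefore
    contains only SNPs jointly significant at ``alpha``.
    """
    if not snps:
        raise ValueError("joint_fit needs a non-empty SNP list")
    y_full, mask, ph = _aligned_trait(g, pheno, trait, preprocess)
    rows = np.where(mask)[0]
    y = y_full[rows]
    X = _design_matrix(ph, covariates, mask)
    gsub = g.subset(sample_idx=rows)
    grm = compute_grm(gsub)
    d, u = _eigh_psd(grm.matrix)
    yr, xr = u.T @ y, u.T @ X
    vc = _fit_reml_rotated(d, yr, xr)
    w = np.sqrt(1.0 / (vc.lam * d + 1.0))
    ystar, xstar = w * yr, w[:, None] * xr

    dose = gsub.imputed()
    cols = {vid: w * (u.T @ dose[:, gsub.column_index(vid)]) for vid in snps}

    current = list(snps)
    trace: list[tuple[str, float]] = []
    while current:
        S = np.column_stack([cols[vid] for vid in current])
        design = np.column_stack([xstar, S])
        beta_all, *_ = np.linalg.lstsq(design, ystar, rcond=None)
        resid = ystar - design @ beta_all
        dof = len(ystar) - design.shape[1]
        if dof <= 0:
            raise ValueError("joint model has no residual degrees of freedom")
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.pinv(design.T @ design)
        se_all = np.sqrt(sigma2 * np.diag(xtx_inv))
        k0 = xstar.shape[1]
        betas = beta_all[k0:]
        ses = se_all[k0:]
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = betas**2 / ses**2
        pvals = stats.chi2.sf(wald, df=1)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        worst = max(range(len(current)), key=lambda i: (pvals[i], i))
        if pvals[worst] > alpha:
            trace.append((current[worst], float(pvals[worst])))
            current.pop(worst)
            continue
        return JointModelResult(
            gene_id=gene_id,
            trait=trait,
            retained=list(current),
            betas={vid: float(b) for vid, b in zip(current, betas)},
            pvalues={vid: float(p) for vid, p in zip(current, pvals)},
            trace=trace,
        )
    return JointModelResult(
        gene_id=gene_id, trait=trait, retained=[], betas={}, pvalues={}, trace=trace
    )
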