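"""Weighted mixed-model association scans for recombination phenotypes.

The phenotype of an animal is the mean of its per-meiosis measurements
(genome-wide crossover count, hotspot usage, or subtelomeric crossover
count) over ``w`` meioses, so its residual variance shrinks as 1/w.
The model is

    y = X g + Z a + e,    a ~ N(0, A sigma_a^2),   e ~ N(0, R sigma_e^2)

with A the genomic relationship matrix (VanRaden method 1) and R
diagonal with entries 1/w.  Variance components are REML-estimated once
on the null model via a single eigendecomposition of the
weight-standardized GRM, then held fixed while each SNP is tested by
generalized least squares with a Wald test — the standard
two-stage approximation for large scans; an exact per-SNP REML mode is
available for small problems.  Conditional scans add chosen SNPs to the
fixed effects; a joint fit estimates all chosen SNPs simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from recpipe.crossover import MeiosisCallSet
from recpipe.pedio import MISSING

# Bonferroni 0.05 / ~312,500 tests: the genome-wide threshold at full
# HD-imputed SNP density; scans over fewer SNPs use 0.05 / #tests.
GENOME_WIDE_ALPHA_HD = 1.6e-7


def significance_threshold(n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return 0.05 / n_tests


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def build_phenotypes(
    callset: MeiosisCallSet,
    kind: str = "rate",
    corrected_counts: pd.DataFrame | None = None,
    usage_records: pd.DataFrame | None = None,
    chrom_lengths: dict[int, int] | None = None,
    subtelomere_fraction: float = 0.15,
) -> pd.DataFrame:
    """Animal-level phenotypes with meiosis-count weights.

    ``rate``: mean crossover count per meiosis, chip-corrected when
    ``corrected_counts`` (from :func:`recpipe.recmap.chip_correct`,
    columns ``meiosis_id``/``corrected_count``) is given.
    ``usage``: passes through animal-level ``usage_records``.
    ``subtelomeric``: mean count of crossovers whose region midpoint
    lies in the terminal ``subtelomere_fraction`` of its chromosome
    (cattle autosomes are acrocentric, so only the far end counts).

    Returns columns ``animal_id``, ``sex``, ``y``, ``w``.
    """
    meta = callset.meta
    if kind == "usage":
        if usage_records is None:
            raise ValueError("kind='usage' needs usage_records")
        out = usage_records.rename(columns={"usage": "y"})
        return out[["animal_id", "sex", "y", "w"]].copy()
    if kind == "rate":
        counts = meta[["meiosis_id", "parent", "parent_sex", "n_calls"]].copy()
        counts["value"] = counts["n_calls"].astype(float)
        if corrected_counts is not None:
            cc = corrected_counts.set_index("meiosis_id")["corrected_count"]
            counts["value"] = counts["meiosis_id"].map(cc)
            counts = counts.dropna(subset=["value"])
    elif kind == "subtelomeric":
        if chrom_lengths is None:
            raise ValueError("kind='subtelomeric' needs chrom_lengths")
        per_meiosis: dict[str, int] = {m: 0 for m in meta["meiosis_id"]}
        for r in callset.regions:
            mid = 0.5 * (r.left_pos + r.right_pos)
            if mid / chrom_lengths[r.chrom] >= 1.0 - subtelomere_fraction:
                per_meiosis[r.meiosis_id] += 1
        counts = meta[["meiosis_id", "parent", "parent_sex"]].copy()
        counts["value"] = counts["meiosis_id"].map(per_meiosis).astype(float)
    else:
        raise ValueError(f"unknown phenotype kind {kind!r}")
    grouped = counts.groupby(["parent", "parent_sex"], sort=False)["value"].agg(["mean", "size"])
    out = grouped.reset_index()
    out.columns = ["animal_id", "sex", "y", "w"]
    return out


# ---------------------------------------------------------------------------
# SNP filtering and GRM
# ---------------------------------------------------------------------------

def _impute_mean(dosages: np.ndarray) -> np.ndarray:
    G = dosages.astype(float)
    missing = dosages == MISSING
    if missing.any():
        G[missing] = np.nan
        col_mean = np.nanmean(G, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        G = np.where(np.isnan(G), col_mean[None, :], G)
    return G


def filter_snps(
    dosages: np.ndarray,
    snp_map: pd.DataFrame,
    maf_min: float = 0.001,
    r_max: float = 0.95,
    window: int = 50,
) -> np.ndarray:
    """Indices of SNPs passing MAF and redundancy/LD filters.

    Drops SNPs with MAF < ``maf_min``, then walks each chromosome in map
    order keeping a SNP only if its dosage correlation with every
    already-kept SNP in the trailing ``window`` stays at or below
    ``r_max`` in absolute value (duplicated columns, r = 1, always go).
    """
    G = _impute_mean(dosages)
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    candidates = np.flatnonzero(maf >= maf_min)
    sd = G.std(axis=0)
    Z = np.zeros_like(G)
    ok = sd > 0
    Z[:, ok] = (G[:, ok] - G[:, ok].mean(axis=0)) / sd[ok]
    n = G.shape[0]
    kept: list[int] = []
    chroms = snp_map["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        chrom_cands = candidates[chroms[candidates] == chrom]
        kept_chrom: list[int] = []
        for j in chrom_cands:
            recent = kept_chrom[-window:]
            if recent:
                r = Z[:, recent].T @ Z[:, j] / n
                if np.any(np.abs(r) > r_max):
                    continue
            kept_chrom.append(int(j))
        kept.extend(kept_chrom)
    return np.array(kept, dtype=int)


def grm(dosages: np.ndarray, freqs: np.ndarray | None = None, ridge: float = 1e-8) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method 1.

    A = (M - 2p)(M - 2p)' / (2 sum p(1-p)) with observed allele
    frequencies; a small ridge keeps A numerically positive
    semi-definite.  Monomorphic SNPs carry no relationship information
    and must be filtered out first.
    """
    G = _impute_mean(dosages)
    if freqs is None:
        freqs = G.mean(axis=0) / 2.0
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("monomorphic SNP in GRM input; filter first")
    Z = G - 2.0 * freqs[None, :]
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    A = Z @ Z.T / denom
    A = 0.5 * (A + A.T)
    A[np.diag_indices_from(A)] += ridge
    return A


# ---------------------------------------------------------------------------
# variance components and scan
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Fitted null LMM plus the rotation reused by the scan.

    The transform D = diag(sqrt(w)) standardizes residual variances;
    with eigendecomposition D A D = U diag(s) U', rotated observations
    are independent with variance sigma_e^2 (lambda s_i + 1), where
    lambda = sigma_a^2 / sigma_e^2.
    """

    sigma_a2: float
    sigma_e2: float
    lam: float
    beta: np.ndarray
    reml_loglik: float
    sqrt_w: np.ndarray
    U: np.ndarray
    s: np.ndarray
    Xr: np.ndarray  # rotated fixed-effect design
    yr: np.ndarray  # rotated phenotype
    y: np.ndarray
    w: np.ndarray
    A: np.ndarray
    X: np.ndarray

    @property
    def rotated_variances(self) -> np.ndarray:
        return self.sigma_e2 * (self.lam * self.s + 1.0)


def _reml_profile(log_lam: float, yr: np.ndarray, Xr: np.ndarray, s: np.ndarray) -> tuple:
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    Wd = 1.0 / d
    XtWX = Xr.T @ (Xr * Wd[:, None])
    XtWy = Xr.T @ (yr * Wd)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(np.sum(resid**2 * Wd))
    n, p = yr.size, Xr.shape[1]
    sigma_e2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf, beta, sigma_e2
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma_e2)
        + float(np.sum(np.log(d)))
        + logdet_XtWX
        + (n - p)
    )
    return ll, beta, sigma_e2


def fit_null(
    y: np.ndarray,
    w: np.ndarray,
    A: np.ndarray,
    covariates: np.ndarray | None = None,
    log_lam_bounds: tuple[float, float] = (-12.0, 12.0),
) -> NullModel:
    """REML fit of (sigma_a^2, sigma_e^2) under R = diag(1/w).

    ``covariates`` (without intercept; one is added) enter as fixed
    effects.  The variance ratio is profiled on a single
    eigendecomposition, so the fit costs one symmetric eigensolve plus
    a 1-D bounded optimization.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights (meiosis counts) must be positive")
    n = y.size
    if A.shape != (n, n):
        raise ValueError("A must be n x n matching the phenotype vector")
    X = np.ones((n, 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.hstack([X, covariates])
    sqrt_w = np.sqrt(w)
    As = sqrt_w[:, None] * A * sqrt_w[None, :]
    s, U = np.linalg.eigh(0.5 * (As + As.T))
    s = np.clip(s, 0.0, None)
    yr = U.T @ (sqrt_w * y)
    Xr = U.T @ (sqrt_w[:, None] * X)

    def neg_ll(log_lam: float) -> float:
        return -_reml_profile(log_lam, yr, Xr, s)[0]

    res = optimize.minimize_scalar(neg_ll, bounds=log_lam_bounds, method="bounded",
                                   options={"xatol": 1e-6})
    ll, beta, sigma_e2 = _reml_profile(res.x, yr, Xr, s)
    lam = float(np.exp(res.x))
    # a ratio pinned at the lower bound is a boundary (sigma_a^2 = 0) fit
    if res.x <= log_lam_bounds[0] + 1e-6:
        lam = 0.0
        ll, beta, sigma_e2 = _reml_profile(-745.0, yr, Xr, s)
    return NullModel(
        sigma_a2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        lam=lam,
        beta=beta,
        reml_loglik=ll,
        sqrt_w=sqrt_w,
        U=U,
        s=s,
        Xr=Xr,
        yr=yr,
        y=y,
        w=w,
        A=A,
        X=X,
    )


def _whiten(null: NullModel) -> tuple[np.ndarray, np.ndarray]:
    v = null.rotated_variances
    inv_sd = 1.0 / np.sqrt(v)
    return null.yr * inv_sd, null.Xr * inv_sd[:, None]


def _rotate_genotypes(null: NullModel, G: np.ndarray) -> np.ndarray:
    Gs = null.sqrt_w[:, None] * _impute_mean(G)
    return null.U.T @ Gs


def scan(
    null: NullModel,
    genotypes: np.ndarray,
    snp_meta: pd.DataFrame | None = None,
    covariate_snps: np.ndarray | list[int] | None = None,
    exact_reml: bool = False,
) -> pd.DataFrame:
    """Single-SNP association scan at the null variance components.

    Each SNP is tested by GLS with V = A sigma_a^2 + R sigma_e^2 held at
    the null REML estimates (Wald test).  ``covariate_snps`` (column
    indices into ``genotypes``) are added to the fixed effects for a
    conditional analysis; a test SNP collinear with a covariate SNP is
    skipped with a warning.  With ``exact_reml`` the variance ratio is
    re-estimated for every SNP (small problems only).

    Returns per-SNP ``beta``, ``se``, ``p`` and allele frequency,
    joined with ``snp_meta`` when given.
    """
    G = np.asarray(genotypes)
    n, n_snps = G.shape
    freq = _impute_mean(G).mean(axis=0) / 2.0
    Gr = _rotate_genotypes(null, G)
    Xr = null.Xr
    cov_idx: list[int] = list(covariate_snps) if covariate_snps is not None else []
    if cov_idx:
        Xr = np.hstack([Xr, Gr[:, cov_idx]])

    beta = np.full(n_snps, np.nan)
    se = np.full(n_snps, np.nan)
    pval = np.full(n_snps, np.nan)

    if exact_reml:
        Ginp = _impute_mean(G)
        base_cov = null.X[:, 1:] if null.X.shape[1] > 1 else None
        if cov_idx:
            extra = Ginp[:, cov_idx]
            base_cov = extra if base_cov is None else np.hstack([base_cov, extra])
        for j in range(n_snps):
            if j in cov_idx:
                continue
            gj = Ginp[:, j : j + 1]
            Xj = gj if base_cov is None else np.hstack([base_cov, gj])
            try:
                fit = fit_null(null.y, null.w, null.A, covariates=Xj)
            except np.linalg.LinAlgError:
                continue
            yw, Xw = _whiten(fit)
            XtX = Xw.T @ Xw
            cov_beta = np.linalg.inv(XtX)
            beta[j] = fit.beta[-1]
            se[j] = np.sqrt(cov_beta[-1, -1])
            pval[j] = 2.0 * stats.norm.sf(abs(beta[j] / se[j]))
    else:
        v = null.rotated_variances
        inv_sd = 1.0 / np.sqrt(v)
        yw = null.yr * inv_sd
        Xw = Xr * inv_sd[:, None]
        Gw = Gr * inv_sd[:, None]
        XtX = Xw.T @ Xw
        coefs = np.linalg.solve(XtX, Xw.T @ np.column_stack([yw, Gw]))
        yp = yw - Xw @ coefs[:, 0]
        Gp = Gw - Xw @ coefs[:, 1:]
        denom = np.einsum("ij,ij->j", Gp, Gp)
        skipped = denom <= 1e-10 * n
        if skipped.any():
            warnings.warn(
                f"{int(skipped.sum())} SNPs collinear with covariates or constant; skipped"
            )
        good = ~skipped
        beta[good] = (Gp[:, good].T @ yp) / denom[good]
        se[good] = 1.0 / np.sqrt(denom[good])
        z = beta[good] / se[good]
        pval[good] = 2.0 * stats.norm.sf(np.abs(z))
        for j in cov_idx:
            beta[j] = se[j] = pval[j] = np.nan

    out = pd.DataFrame({"freq": freq, "beta": beta, "se": se, "p": pval})
    if snp_meta is not None:
        out = pd.concat([snp_meta.reset_index(drop=True), out], axis=1)
    out.attrs["threshold"] = significance_threshold(n_snps - len(cov_idx))
    return out


def joint_fit(
    null: NullModel, genotypes: np.ndarray, snp_indices: list[int]
) -> pd.DataFrame:
    """Fit all chosen SNPs simultaneously as fixed effects (GLS).

    Used after a scan to re-estimate the effects of every significant
    SNP in one model.
    """
    if not snp_indices:
        raise ValueError("joint_fit needs at least one SNP")
    Gr = _rotate_genotypes(null, np.asarray(genotypes))
    v = null.rotated_variances
    inv_sd = 1.0 / np.sqrt(v)
    yw = null.yr * inv_sd
    Xw = np.hstack([null.Xr, Gr[:, snp_indices]]) * inv_sd[:, None]
    XtX = Xw.T @ Xw
    coef = np.linalg.solve(XtX, Xw.T @ yw)
    cov = np.linalg.inv(XtX)
    k = null.Xr.shape[1]
    betas = coef[k:]
    ses = np.sqrt(np.diag(cov)[k:])
    z = betas / ses
    return pd.DataFrame({
        "snp_index": snp_indices,
        "beta": betas,
        "se": ses,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    })


def genomic_inflation(pvalues: np.ndarray) -> float:
    """QQ-plot inflation factor: median test chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
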