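"""Positional and temporal recombination profiles, and an LD screen.

``position_profile`` smooths interval recombination rates on relative
chromosomal position (position / chromosome length) with a fixed
degrees-of-freedom regression spline, after trimming chromosome ends
where sparse SNP coverage depresses detection power.  ``time_trend``
residualizes per-meiosis crossover counts on nuisance covariates (chip
categories, parental genomic inbreeding, informative-SNP counts with
polynomial and interaction terms) and smooths the adjusted counts on
birth year.  ``ld_screen`` checks a SNP's physical placement through
two-point linkage against every other SNP on its chromosome: for a
correctly placed SNP the LOD score peaks at the SNP and decays with
distance while the recombination-fraction estimate does the opposite;
a deviating pattern flags the SNP (and any hotspot it anchors) as
suspect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

from recpipe.crossover import MeiosisCallSet, grandparental_origin
from recpipe.pedio import GenotypeTable
from recpipe.phasing import PhasedMeiosis
from recpipe.recmap import RecombinationMap


def _spline_fit(x: np.ndarray, y: np.ndarray, df: int, grid: np.ndarray) -> np.ndarray:
    """Least-squares B-spline smooth with fixed degrees of freedom."""
    if df >= np.unique(x).size:
        raise ValueError(f"spline df={df} needs more than {df} distinct x values")
    basis = dmatrix("bs(x, df=df, include_intercept=False)", {"x": x, "df": df})
    model = sm.OLS(y, np.asarray(basis)).fit()
    design_info = basis.design_info
    grid_basis = np.asarray(
        dmatrix(design_info, {"x": np.clip(grid, x.min(), x.max()), "df": df})
    )
    return grid_basis @ model.params


@dataclass
class PositionProfile:
    """Smoothed recombination rate against relative chromosome position."""

    points: pd.DataFrame  # relpos, value, chrom (the data the spline saw)
    grid: np.ndarray
    curve: np.ndarray
    trim_bp: float
    spline_df: int


def position_profile(
    rmap: RecombinationMap,
    chrom_lengths: dict[int, int],
    trim_bp: float = 2e6,
    spline_df: int = 5,
    grid_size: int = 201,
) -> PositionProfile:
    """Pooled-autosome profile of interval rate vs relative position.

    Intervals overlapping the first or last ``trim_bp`` of their
    chromosome are excluded.  The response is the per-bp rate of each
    interval (rate / physical length) scaled by the genome-average
    interval length, evaluated at the interval midpoint.
    """
    iv = rmap.intervals
    chroms = iv["chrom"].to_numpy()
    start = iv["start_pos"].to_numpy(dtype=float)
    end = iv["end_pos"].to_numpy(dtype=float)
    lengths = np.array([chrom_lengths[int(c)] for c in chroms], dtype=float)
    keep = (start >= trim_bp) & (end <= lengths - trim_bp)
    widths = end - start
    mean_width = widths[keep].mean()
    relpos = (0.5 * (start + end) / lengths)[keep]
    value = (rmap.rates[keep] / widths[keep]) * mean_width
    grid = np.linspace(relpos.min(), relpos.max(), grid_size)
    curve = _spline_fit(relpos, value, spline_df, grid)
    points = pd.DataFrame({"relpos": relpos, "value": value, "chrom": chroms[keep]})
    return PositionProfile(points=points, grid=grid, curve=curve,
                           trim_bp=trim_bp, spline_df=spline_df)


def single_double_profiles(
    callset: MeiosisCallSet,
    chrom_lengths: dict[int, int],
    trim_bp: float = 2e6,
    spline_df: int = 5,
    grid_size: int = 201,
) -> dict[str, PositionProfile]:
    """Crossover-position densities for single- vs double-crossover chromosomes.

    A (meiosis, chromosome) with exactly one call contributes to the
    ``single`` stratum, with exactly two to ``double``; each call enters
    at its region midpoint's relative position.  The spline smooths a
    histogram-density of those positions.
    """
    per = {}
    for r in callset.regions:
        per.setdefault((r.meiosis_id, r.chrom), []).append(r)
    strata = {"single": [], "double": []}
    for (mid, chrom), regions in per.items():
        name = {1: "single", 2: "double"}.get(len(regions))
        if name is None:
            continue
        L = chrom_lengths[chrom]
        for r in regions:
            pos = 0.5 * (r.left_pos + r.right_pos)
            if trim_bp <= pos <= L - trim_bp:
                strata[name].append(pos / L)
    out = {}
    for name, positions in strata.items():
        positions = np.asarray(positions)
        if positions.size < spline_df + 2:
            continue
        hist, edges = np.histogram(positions, bins=40, range=(0, 1), density=True)
        mids = 0.5 * (edges[:-1] + edges[1:])
        nonempty = hist > 0
        grid = np.linspace(0, 1, grid_size)
        curve = _spline_fit(mids[nonempty], hist[nonempty], spline_df, grid)
        out[name] = PositionProfile(
            points=pd.DataFrame({"relpos": mids, "value": hist, "chrom": 0}),
            grid=grid, curve=curve, trim_bp=trim_bp, spline_df=spline_df,
        )
    return out


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedy QR-based removal of linearly dependent design columns."""
    kept: list[int] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            kept.append(j)
    if len(kept) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in kept]
        warnings.warn(f"dropping aliased design columns: {dropped}")
    return X[:, kept], [names[j] for j in kept]


@dataclass
class TimeTrend:
    """Covariate-adjusted trend of a recombination phenotype over years."""

    grid: np.ndarray
    curve: np.ndarray
    adjusted: pd.DataFrame  # birth_year, adjusted value per meiosis
    coefficients: pd.DataFrame  # term, beta, se, p for the adjustment model
    inbreeding_beta: float = float("nan")
    inbreeding_p: float = float("nan")


def time_trend(
    meiosis_table: pd.DataFrame,
    value_col: str = "count",
    year_col: str = "birth_year",
    adjusters: list[str] | None = None,
    categorical: list[str] | None = None,
    informative_cols: list[str] | None = None,
    inbreeding_col: str | None = None,
    spline_df: int = 5,
    grid_size: int = 101,
) -> TimeTrend:
    """Adjusted time trend of per-meiosis crossover counts.

    The adjustment is an ordinary linear model of the count on the
    listed covariates; ``informative_cols`` (numbers of phased
    heterozygous SNPs in offspring and parent) additionally enter with
    quadratic, cubic and pairwise-interaction terms, since inbreeding
    and chip density act on counts through the informative-SNP supply.
    Residuals plus the grand mean are then smoothed on birth year.  With
    no adjusters this reduces to a spline of the raw counts.
    """
    df = meiosis_table.reset_index(drop=True)
    y = df[value_col].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for c in adjusters or []:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    if inbreeding_col is not None and inbreeding_col not in (adjusters or []):
        cols.append(df[inbreeding_col].to_numpy(dtype=float))
        names.append(inbreeding_col)
    for c in categorical or []:
        dummies = pd.get_dummies(df[c], prefix=c, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(dtype=float))
            names.append(name)
    info = informative_cols or []
    for c in info:
        x = df[c].to_numpy(dtype=float)
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        cols.extend([x, x**2, x**3])
        names.extend([c, f"{c}^2", f"{c}^3"])
    if len(info) == 2:
        a = cols[names.index(info[0])]
        b = cols[names.index(info[1])]
        cols.append(a * b)
        names.append(f"{info[0]}:{info[1]}")
    X = np.column_stack(cols)
    X, names = _drop_aliased(X, names)
    fit = sm.OLS(y, X).fit()
    coeffs = pd.DataFrame({"term": names, "beta": fit.params,
                           "se": fit.bse, "p": fit.pvalues})
    adjusted = fit.resid + y.mean()
    years = df[year_col].to_numpy(dtype=float)
    grid = np.linspace(years.min(), years.max(), grid_size)
    curve = _spline_fit(years, adjusted, spline_df, grid)
    inbreeding_beta = inbreeding_p = float("nan")
    if inbreeding_col is not None and inbreeding_col in names:
        k = names.index(inbreeding_col)
        inbreeding_beta = float(fit.params[k])
        inbreeding_p = float(fit.pvalues[k])
    return TimeTrend(
        grid=grid,
        curve=curve,
        adjusted=pd.DataFrame({year_col: years, "adjusted": adjusted}),
        coefficients=coeffs,
        inbreeding_beta=inbreeding_beta,
        inbreeding_p=inbreeding_p,
    )


# ---------------------------------------------------------------------------
# two-point linkage screen
# ---------------------------------------------------------------------------

def origin_matrix(meioses: list[PhasedMeiosis], genotypes: GenotypeTable,
                  chrom: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-meiosis grandparental origins for one chromosome.

    Returns ``(M, positions)`` with ``M[k, j]`` in {0, 1, -1}.
    """
    sl = genotypes.chrom_slices()[chrom]
    M = np.stack([grandparental_origin(m)[sl] for m in meioses])
    return M, genotypes.chrom_positions(chrom)


@dataclass
class LdScreenResult:
    candidate_index: int
    candidate_pos: int
    table: pd.DataFrame  # snp_index, pos_bp, n, rhat, lod
    flag: str  # "normal" | "suspicious"
    lod_argmax_pos: int = 0
    reasons: list[str] = field(default_factory=list)


def two_point_lod(R: np.ndarray, N: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recombination-fraction MLE and LOD against free recombination.

    r-hat = R/N capped at 0.5; LOD = log10 L(r-hat)/L(0.5) with
    L(r) = r^R (1-r)^(N-R).  Nonnegative by construction.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.minimum(np.where(N > 0, R / N, 0.5), 0.5)
        lod = np.where(R > 0, R * np.log10(np.maximum(rhat, 1e-300)), 0.0)
        lod += np.where(N - R > 0, (N - R) * np.log10(np.maximum(1 - rhat, 1e-300)), 0.0)
        lod -= N * np.log10(0.5)
    return rhat, np.maximum(lod, 0.0)


def ld_screen(
    candidate_index: int,
    origins: np.ndarray,
    positions: np.ndarray,
    min_meioses: int = 20,
    max_peak_distance_bp: float = 1e7,
    n_bins: int = 10,
    decay_tolerance: float = 0.05,
) -> LdScreenResult:
    """Two-point linkage of one SNP against all others on its chromosome.

    ``origins`` is the meiosis-by-SNP grandparental-origin matrix for
    the chromosome (phase-known transmissions).  The SNP is flagged
    suspicious when the LOD maximum lies more than
    ``max_peak_distance_bp`` from its mapped position, or when mean LOD
    binned by distance from the SNP fails to decay monotonically (an
    increase above ``decay_tolerance`` of the peak LOD counts as a
    violation).
    """
    n_snps = origins.shape[1]
    if n_snps < 11:
        raise ValueError("need at least 10 other SNPs on the chromosome")
    oc = origins[:, candidate_index]
    valid = (oc[:, None] >= 0) & (origins >= 0)
    N = valid.sum(axis=0)
    diff = valid & (oc[:, None] != origins)
    R = diff.sum(axis=0)
    rhat, lod = two_point_lod(R.astype(float), N.astype(float))
    keep = (N >= min_meioses)
    keep[candidate_index] = True  # self-comparison: rhat 0, LOD maximal
    idx = np.flatnonzero(keep)
    table = pd.DataFrame({
        "snp_index": idx,
        "pos_bp": positions[idx],
        "n": N[idx],
        "rhat": rhat[idx],
        "lod": lod[idx],
    })
    cand_pos = int(positions[candidate_index])
    reasons: list[str] = []
    others = table[table["snp_index"] != candidate_index]
    if len(others) == 0:
        raise ValueError("no informative SNP pairs for this candidate")
    peak_pos = int(others.loc[others["lod"].idxmax(), "pos_bp"])
    if abs(peak_pos - cand_pos) > max_peak_distance_bp:
        reasons.append(f"LOD peak {abs(peak_pos - cand_pos) / 1e6:.1f} Mb from mapped position")
    dist = np.abs(others["pos_bp"].to_numpy() - cand_pos)
    lod_o = others["lod"].to_numpy()
    bins = np.quantile(dist, np.linspace(0, 1, n_bins + 1))
    bins = np.unique(bins)
    if bins.size >= 3:
        which = np.clip(np.searchsorted(bins, dist, side="right") - 1, 0, bins.size - 2)
        means = np.array([lod_o[which == b].mean() if (which == b).any() else np.nan
                          for b in range(bins.size - 1)])
        means = means[np.isfinite(means)]
        tol = decay_tolerance * (lod_o.max() if lod_o.max() > 0 else 1.0)
        if np.any(np.diff(means) > tol):
            reasons.append("binned LOD does not decay monotonically with distance")
    return LdScreenResult(
        candidate_index=candidate_index,
        candidate_pos=cand_pos,
        table=table,
        flag="suspicious" if reasons else "normal",
        lod_argmax_pos=peak_pos,
        reasons=reasons,
    )
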