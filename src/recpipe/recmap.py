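"""Sex-specific recombination maps via EM over crossover regions.

Each called crossover is only localized to a region of m adjacent-SNP
intervals.  The EM algorithm turns these interval-censored observations
into per-interval crossover probabilities: the initiation step assigns
an expected count of 1/m to each of a region's m intervals; the M-step
estimates each interval's probability as its total expected count over
the n meioses divided by n; the E-step redistributes each region's one
crossover over its intervals proportionally to the current probability
estimates.  The fixed point is the maximum-likelihood estimate of a
multinomial model in which every crossover falls in exactly one
interval but is observed only up to region membership.

Map distance is reported as the raw expected crossovers per meiosis
(1 Morgan = 1 expected crossover); Haldane-adjusted lengths are an
alternative output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from recpipe.crossover import CrossoverRegion

logger = logging.getLogger(__name__)


def intervals_from_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Adjacent-SNP interval grid: one row per (pos_i, pos_{i+1}] interval.

    Row order matches chromosome-local interval indices used by
    :class:`~recpipe.crossover.CrossoverRegion`.
    """
    frames = []
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        if pos.size < 2:
            continue
        frames.append(
            pd.DataFrame({"chrom": chrom, "start_pos": pos[:-1], "end_pos": pos[1:]})
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class RecombinationMap:
    """Per-interval crossover probability per meiosis, for one sex.

    ``rates[i]`` is the expected number of crossovers per meiosis in
    interval ``i`` of the grid ``intervals`` (columns ``chrom``,
    ``start_pos``, ``end_pos``).
    """

    intervals: pd.DataFrame
    rates: np.ndarray
    n_meioses: int
    sex: str = ""

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.intervals) != self.rates.size:
            raise ValueError("rates must align with the interval grid")
        if np.any(self.rates < 0):
            raise ValueError("negative interval rate")

    @property
    def n_intervals(self) -> int:
        return self.rates.size

    def total_morgans(self) -> float:
        return float(self.rates.sum())

    def per_chrom_morgans(self) -> pd.Series:
        return pd.Series(self.rates).groupby(self.intervals["chrom"].to_numpy()).sum()

    def cum_cm(self) -> np.ndarray:
        """Cumulative genetic position (cM) at each interval end, per chromosome."""
        out = np.empty(self.rates.size)
        chroms = self.intervals["chrom"].to_numpy()
        for c in np.unique(chroms):
            m = chroms == c
            out[m] = np.cumsum(self.rates[m]) * 100.0
        return out

    def chrom_offsets(self) -> dict[int, int]:
        """Global index of each chromosome's first interval."""
        chroms = self.intervals["chrom"].to_numpy()
        offsets: dict[int, int] = {}
        for i, c in enumerate(chroms):
            offsets.setdefault(int(c), i)
        return offsets

    def global_indices(self, region: CrossoverRegion) -> np.ndarray:
        off = self.chrom_offsets()[region.chrom]
        return np.arange(off + region.left_index, off + region.right_index)

    def to_df(self) -> pd.DataFrame:
        df = self.intervals.copy()
        df["rate"] = self.rates
        df["cum_cM"] = self.cum_cm()
        return df


def _region_global_indices(
    regions: list[CrossoverRegion], intervals: pd.DataFrame
) -> list[np.ndarray]:
    chroms = intervals["chrom"].to_numpy()
    offsets: dict[int, int] = {}
    counts: dict[int, int] = {}
    for i, c in enumerate(chroms):
        offsets.setdefault(int(c), i)
        counts[int(c)] = counts.get(int(c), 0) + 1
    out = []
    for r in regions:
        if r.chrom not in offsets:
            raise ValueError(f"region on chromosome {r.chrom} absent from interval grid")
        if r.right_index > counts[r.chrom]:
            raise ValueError(
                f"region {r.meiosis_id} chr{r.chrom} references interval "
                f"{r.right_index - 1} beyond the grid"
            )
        out.append(np.arange(offsets[r.chrom] + r.left_index, offsets[r.chrom] + r.right_index))
    return out


def em_fit_indices(
    region_intervals: list[np.ndarray],
    n: int,
    n_intervals: int,
    tol: float = 1e-8,
    max_iter: int = 20000,
    track_likelihood: bool = False,
) -> tuple[np.ndarray, dict]:
    """EM on raw interval-index lists; the computational core of em_fit.

    Returns ``(rates, info)`` where ``info`` carries ``n_iter``,
    ``converged`` and, when requested, the per-iteration log-likelihood
    ``sum_r log(sum_{i in r} p_i)`` and total-mass trace.
    """
    if n < 1:
        raise ValueError("n (meiosis count) must be >= 1")
    for r in region_intervals:
        if len(r) == 0:
            raise ValueError("crossover region referencing zero intervals")
    R = len(region_intervals)
    p = np.zeros(n_intervals)
    if R == 0:
        return p, {"n_iter": 0, "converged": True}
    idx = np.concatenate(region_intervals)
    sizes = np.array([len(r) for r in region_intervals])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    rep = np.repeat(np.arange(R), sizes)
    # initiation: expected count 1/m to each of a region's m intervals
    p = np.bincount(idx, weights=np.repeat(1.0 / sizes, sizes), minlength=n_intervals) / n
    ll_trace: list[float] = []
    mass_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        seg = p[idx]
        sums = np.add.reduceat(seg, offsets)
        if track_likelihood:
            with np.errstate(divide="ignore"):
                ll_trace.append(float(np.sum(np.log(sums))))
            mass_trace.append(float(p.sum()) * n)
        zero = sums <= 0.0
        if zero.any():
            # a region whose intervals all hit the EM zero fixed point:
            # fall back to uniform within the region
            sums = sums.copy()
            sums[zero] = 1.0
            seg = seg.copy()
            uni = zero[rep]
            seg[uni] = 1.0 / sizes[rep][uni]
        w = seg / sums[rep]
        p_new = np.bincount(idx, weights=w, minlength=n_intervals) / n
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations (last step {delta:.2e})")
    info: dict = {"n_iter": it, "converged": converged}
    if track_likelihood:
        info["loglik"] = ll_trace
        info["mass"] = mass_trace
    return p, info


def em_fit(
    regions: list[CrossoverRegion],
    n: int,
    intervals: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 20000,
    sex: str = "",
) -> RecombinationMap:
    """Fit a recombination map from called crossover regions.

    ``n`` is the number of meioses considered (not the number of
    regions); ``intervals`` is the grid from
    :func:`intervals_from_snp_map`.
    """
    region_idx = _region_global_indices(regions, intervals)
    rates, info = em_fit_indices(region_idx, n, len(intervals), tol=tol, max_iter=max_iter)
    logger.info("EM(%s): %d regions, %d meioses, %d iterations", sex or "?",
                len(regions), n, info["n_iter"])
    return RecombinationMap(intervals=intervals, rates=rates, n_meioses=n, sex=sex)


@dataclass
class ChipCorrection:
    """Multiplicative crossover-count correction per chip category.

    Factors rescale each category's mean crossover count to the
    reference (all highest-density chip) category's mean, per sex, so
    the corrected count no longer depends on how densely the family was
    genotyped.
    """

    reference: str
    factors: pd.DataFrame  # parent_sex, category, mean_count, factor

    def factor(self, parent_sex: str, category: str) -> float:
        m = (self.factors["parent_sex"] == parent_sex) & (self.factors["category"] == category)
        if not m.any():
            raise KeyError(f"no correction factor for {parent_sex}/{category}")
        return float(self.factors.loc[m, "factor"].iloc[0])


def chip_correct(
    counts: pd.DataFrame, reference_category: str
) -> tuple[pd.DataFrame, ChipCorrection]:
    """Scale per-meiosis crossover counts onto the reference chip category.

    ``counts`` needs columns ``meiosis_id``, ``parent_sex``,
    ``category``, ``count``.  Each count is multiplied by (reference
    category mean / own category mean) within its sex.  Categories with
    no meioses in a sex simply do not occur; a category whose mean is 0
    cannot be rescaled and is excluded with a warning.
    """
    required = {"meiosis_id", "parent_sex", "category", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    rows = []
    corrected_parts = []
    for sex, grp in counts.groupby("parent_sex", sort=False):
        ref = grp.loc[grp["category"] == reference_category, "count"]
        if ref.empty:
            raise ValueError(f"reference category {reference_category!r} empty for sex {sex}")
        ref_mean = float(ref.mean())
        for cat, sub in grp.groupby("category", sort=False):
            cat_mean = float(sub["count"].mean())
            if cat_mean == 0.0:
                warnings.warn(f"chip category {cat!r} ({sex}) has zero mean count; excluded")
                continue
            factor = ref_mean / cat_mean
            rows.append((sex, cat, cat_mean, factor))
            out = sub.copy()
            out["corrected_count"] = out["count"] * factor
            corrected_parts.append(out)
    factors = pd.DataFrame(rows, columns=["parent_sex", "category", "mean_count", "factor"])
    corrected = pd.concat(corrected_parts, ignore_index=True)
    return corrected, ChipCorrection(reference=reference_category, factors=factors)


def haldane_length(rmap: RecombinationMap) -> pd.DataFrame:
    """Haldane-adjusted genetic length per chromosome.

    Each interval's crossover probability c is mapped to distance
    d = -0.5 ln(1 - 2c), which corrects for the double crossovers an
    observed recombination fraction misses (assuming no interference).
    Requires every c < 0.5.  Returns per-chromosome raw and adjusted
    Morgans; totals are column sums.
    """
    c = rmap.rates
    bad = np.flatnonzero(c >= 0.5)
    if bad.size:
        row = rmap.intervals.iloc[bad[0]]
        raise ValueError(
            f"interval chr{row['chrom']}:{row['start_pos']}-{row['end_pos']} has rate "
            f"{c[bad[0]]:.3f} >= 0.5; Haldane distance undefined"
        )
    d = -0.5 * np.log1p(-2.0 * c)
    chroms = rmap.intervals["chrom"].to_numpy()
    df = pd.DataFrame({"chrom": chroms, "raw": c, "haldane": d})
    out = df.groupby("chrom").sum()
    out.columns = ["raw_morgans", "haldane_morgans"]
    return out


def map_summary(map_male: RecombinationMap, map_female: RecombinationMap) -> dict:
    """Per-chromosome and genome totals plus male-female rate correlation.

    kb/cM = physical span / genetic length; the correlation is Pearson's
    r between per-interval rates of the two sexes on the shared grid.
    """
    if not map_male.intervals[["chrom", "start_pos", "end_pos"]].equals(
        map_female.intervals[["chrom", "start_pos", "end_pos"]]
    ):
        raise ValueError("male and female maps must share the interval grid")
    iv = map_male.intervals
    chroms = iv["chrom"].to_numpy()
    span = iv["end_pos"].to_numpy() - iv["start_pos"].to_numpy()
    per = pd.DataFrame({
        "chrom": chroms,
        "span_bp": span,
        "morgans_male": map_male.rates,
        "morgans_female": map_female.rates,
    }).groupby("chrom").sum()
    for sex in ("male", "female"):
        with np.errstate(divide="ignore", invalid="ignore"):
            per[f"kb_per_cm_{sex}"] = (per["span_bp"] / 1000.0) / (per[f"morgans_{sex}"] * 100.0)
    tot_span = float(per["span_bp"].sum())
    tot_m = float(per["morgans_male"].sum())
    tot_f = float(per["morgans_female"].sum())
    if map_male.rates.std() > 0 and map_female.rates.std() > 0:
        corr = float(np.corrcoef(map_male.rates, map_female.rates)[0, 1])
    else:
        corr = float("nan")
    return {
        "per_chrom": per,
        "genome_morgans_male": tot_m,
        "genome_morgans_female": tot_f,
        "genome_kb_per_cm_male": tot_span / 1000.0 / (tot_m * 100.0) if tot_m else float("nan"),
        "genome_kb_per_cm_female": tot_span / 1000.0 / (tot_f * 100.0) if tot_f else float("nan"),
        "interval_rate_correlation": corr,
    }
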