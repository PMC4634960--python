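"""Recombination hotspots and per-animal hotspot usage.

A hotspot is a SNP interval whose per-meiosis crossover rate exceeds
the genome-wide mean by ``k_sd`` standard deviations (default 2.5,
strict inequality), computed over all autosomal intervals of one sex's
map.  A distance-standardized variant divides each rate by the
interval's physical length first and drops very short intervals whose
per-bp rate is unstable.

Hotspot usage is the proportion of an individual's crossovers that fall
in hotspot intervals.  A crossover localized to a multi-interval region
contributes fractionally: its region's hotspot share under the fitted
map (sum of hotspot-interval rates over sum of all the region's rates),
consistent with the EM posterior over the crossover's true interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from recpipe.crossover import MeiosisCallSet
from recpipe.recmap import RecombinationMap

logger = logging.getLogger(__name__)


@dataclass
class HotspotSet:
    """Hotspot intervals of one sex's map, as a mask over its grid."""

    sex: str
    threshold: float
    mask: np.ndarray  # boolean, aligned with rmap.intervals
    intervals: pd.DataFrame  # the hotspot rows, with rates
    genome_fraction: float  # bp in hotspots / bp in the grid
    k_sd: float
    standardized: bool = False

    @property
    def n_hotspots(self) -> int:
        return int(self.mask.sum())

    def to_bed(self) -> pd.DataFrame:
        """Hotspots as 0-based half-open BED records."""
        return pd.DataFrame({
            "chrom": self.intervals["chrom"],
            "start": self.intervals["start_pos"].astype(int),  # 1-based (start, end] -> 0-based [start, end)
            "end": self.intervals["end_pos"].astype(int),
            "rate": self.intervals["rate"],
        })


def _build_set(rmap: RecombinationMap, values: np.ndarray, eligible: np.ndarray,
               k_sd: float, standardized: bool) -> HotspotSet:
    vals = values[eligible]
    if vals.size < 2:
        raise ValueError("need at least 2 eligible intervals to call hotspots")
    threshold = float(vals.mean() + k_sd * vals.std(ddof=0))
    mask = np.zeros(values.size, dtype=bool)
    mask[eligible] = vals > threshold
    iv = rmap.intervals.copy()
    iv["rate"] = rmap.rates
    if standardized:
        iv["standardized_rate"] = values
    hot = iv.loc[mask].reset_index(drop=True)
    widths = (rmap.intervals["end_pos"] - rmap.intervals["start_pos"]).to_numpy(dtype=float)
    frac = float(widths[mask].sum() / widths.sum())
    return HotspotSet(
        sex=rmap.sex, threshold=threshold, mask=mask, intervals=hot,
        genome_fraction=frac, k_sd=k_sd, standardized=standardized,
    )


def call_hotspots(rmap: RecombinationMap, k_sd: float = 2.5) -> HotspotSet:
    """Intervals with rate strictly above mean + ``k_sd`` x SD."""
    eligible = np.ones(rmap.n_intervals, dtype=bool)
    return _build_set(rmap, rmap.rates, eligible, k_sd, standardized=False)


def standardized_hotspots(
    rmap: RecombinationMap, min_interval_bp: int = 500, k_sd: float = 0.6
) -> HotspotSet:
    """Hotspots on per-bp (distance-standardized) rates.

    Intervals shorter than ``min_interval_bp`` are excluded from both
    the threshold computation and the calling; the standardized rates
    vary much less than raw rates, hence the lower default cutoff.
    """
    widths = (rmap.intervals["end_pos"] - rmap.intervals["start_pos"]).to_numpy(dtype=float)
    zero = widths <= 0
    if zero.any():
        logger.warning("%d zero-length intervals excluded from hotspot calling", int(zero.sum()))
    eligible = (widths >= min_interval_bp) & ~zero
    with np.errstate(divide="ignore", invalid="ignore"):
        per_bp = np.where(widths > 0, rmap.rates / widths, 0.0)
    return _build_set(rmap, per_bp, eligible, k_sd, standardized=True)


def shared_hotspots(set_m: HotspotSet, set_f: HotspotSet) -> dict:
    """Hotspot intervals called in both sexes, with per-sex shared fractions."""
    if set_m.mask.size != set_f.mask.size:
        raise ValueError("hotspot sets are on different interval grids")
    shared_mask = set_m.mask & set_f.mask
    n_shared = int(shared_mask.sum())
    return {
        "shared_mask": shared_mask,
        "n_shared": n_shared,
        "fraction_male": n_shared / set_m.n_hotspots if set_m.n_hotspots else float("nan"),
        "fraction_female": n_shared / set_f.n_hotspots if set_f.n_hotspots else float("nan"),
    }


def hotspot_usage(
    callset: MeiosisCallSet,
    hotspots: HotspotSet,
    rmap: RecombinationMap,
    hard_assignment: bool = False,
) -> pd.DataFrame:
    """Per-animal mean hotspot usage with meiosis-count weights.

    Per meiosis, each crossover region contributes the fraction of its
    rate mass lying in hotspot intervals (with ``hard_assignment``, 1 if
    that fraction exceeds 0.5, else 0); usage is the mean contribution
    over the meiosis' crossovers.  A region whose intervals all carry
    zero fitted rate falls back to a uniform split over its intervals.
    The animal-level record averages usage over the parent's meioses
    that carry at least one crossover; ``w`` is that meiosis count.

    Returns a DataFrame with columns ``animal_id``, ``sex``, ``usage``,
    ``w``.
    """
    offsets = rmap.chrom_offsets()
    hot_rates = np.where(hotspots.mask, rmap.rates, 0.0)
    usage_per_meiosis: dict[str, float] = {}
    n_fallback = 0
    for mid, regions in callset.by_meiosis().items():
        if not regions:
            continue
        total = 0.0
        for r in regions:
            gi = np.arange(offsets[r.chrom] + r.left_index, offsets[r.chrom] + r.right_index)
            mass = float(rmap.rates[gi].sum())
            if mass > 0:
                share = float(hot_rates[gi].sum()) / mass
            else:
                share = float(hotspots.mask[gi].mean())
                n_fallback += 1
            if hard_assignment:
                share = 1.0 if share > 0.5 else 0.0
            total += share
        usage_per_meiosis[mid] = total / len(regions)
    if n_fallback:
        logger.warning("%d regions over zero-rate intervals: uniform fallback split", n_fallback)
    meta = callset.meta
    rows = []
    for (parent, sex), grp in meta.groupby(["parent", "parent_sex"], sort=False):
        vals = [usage_per_meiosis[m] for m in grp["meiosis_id"] if m in usage_per_meiosis]
        if not vals:
            continue
        rows.append((parent, sex, float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["animal_id", "sex", "usage", "w"])
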