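"""Crossover detection from grandparental-origin switches.

A site is informative for a meiosis when the transmitting parent is
heterozygous with known phase and the transmitted allele is known; the
transmitted allele then identifies which parental haplotype (grand
paternal or grand-maternal) the offspring inherited there.  A crossover
is an origin switch along the chromosome, called only when supported by
at least ``min_support`` consecutive informative SNPs on both flanks,
and localized to the run of adjacent-SNP intervals between the two
flanking informative SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from recpipe.pedio import GenotypeTable
from recpipe.phasing import UNKNOWN, PhasedMeiosis

UNINFORMATIVE = -1


@dataclass(frozen=True)
class CrossoverRegion:
    """A called crossover localized to a run of adjacent SNP intervals.

    ``left_index``/``right_index`` are chromosome-local indices of the
    two flanking informative SNPs; the region covers the half-open bp
    interval ``(left_pos, right_pos]`` and the adjacent-SNP intervals
    ``left_index .. right_index - 1`` (``m = right_index - left_index``
    intervals, the unit the EM redistributes over).
    """

    meiosis_id: str
    parent_sex: str
    chrom: int
    left_index: int
    right_index: int
    left_pos: int
    right_pos: int
    support_left: int
    support_right: int

    def __post_init__(self) -> None:
        if self.right_index <= self.left_index:
            raise ValueError("right flank must lie right of left flank")

    @property
    def n_intervals(self) -> int:
        return self.right_index - self.left_index

    @property
    def intervals(self) -> range:
        return range(self.left_index, self.right_index)

    def covers(self, pos_bp: float) -> bool:
        return self.left_pos < pos_bp <= self.right_pos


@dataclass
class MeiosisCallSet:
    """Crossover calls plus per-meiosis bookkeeping for n meioses."""

    regions: list[CrossoverRegion]
    meta: pd.DataFrame  # meiosis_id, offspring, parent, parent_sex, n_informative, n_calls

    @property
    def n_meioses(self) -> int:
        return len(self.meta)

    def regions_df(self) -> pd.DataFrame:
        rows = [
            (r.meiosis_id, r.parent_sex, r.chrom, r.left_pos, r.right_pos,
             r.left_index, r.right_index, r.n_intervals)
            for r in self.regions
        ]
        return pd.DataFrame(
            rows,
            columns=["meiosis_id", "parent_sex", "chrom", "left_pos", "right_pos",
                     "left_index", "right_index", "n_intervals"],
        )

    def by_meiosis(self) -> dict[str, list[CrossoverRegion]]:
        out: dict[str, list[CrossoverRegion]] = {m: [] for m in self.meta["meiosis_id"]}
        for r in self.regions:
            out[r.meiosis_id].append(r)
        return out


def grandparental_origin(meiosis: PhasedMeiosis) -> np.ndarray:
    """Per-SNP grandparental origin: 0 grand-paternal, 1 grand-maternal.

    Uninformative sites (parent not heterozygous, phase unknown,
    transmitted allele unknown, or transmitted allele matching neither
    parental haplotype) are -1.
    """
    t, hp, hm = meiosis.transmitted, meiosis.parent_pat, meiosis.parent_mat
    informative = (
        (t != UNKNOWN) & (hp != UNKNOWN) & (hm != UNKNOWN) & (hp != hm)
    )
    origin = np.full(t.size, UNINFORMATIVE, dtype=np.int8)
    origin[informative & (t == hp)] = 0
    origin[informative & (t == hm)] = 1
    return origin


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a label vector as (label, start, stop)."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def _run_support(members: np.ndarray, strict_adjacency: bool) -> int:
    """Support of a run of informative-SNP indices.

    Default: every informative SNP in the run counts (uninformative
    sites between them do not interrupt).  Strict: only the longest
    block of SNPs adjacent on the map counts.
    """
    if not strict_adjacency:
        return members.size
    if members.size == 0:
        return 0
    breaks = np.flatnonzero(np.diff(members) != 1)
    block_sizes = np.diff(np.concatenate([[-1], breaks, [members.size - 1]]))
    return int(block_sizes.max())


def call_crossovers(
    origin_vector: np.ndarray,
    positions: np.ndarray,
    min_support: int = 3,
    meiosis_id: str = "",
    parent_sex: str = "",
    chrom: int = 0,
    strict_adjacency: bool = False,
) -> list[CrossoverRegion]:
    """Call crossovers on one chromosome of one meiosis.

    Origin runs shorter than ``min_support`` informative SNPs are
    unresolved: they neither create calls nor break their flanking runs,
    so a short discordant run between two same-origin runs yields no
    call (a possible double crossover is deliberately not counted).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    origin_vector = np.asarray(origin_vector)
    positions = np.asarray(positions)
    if origin_vector.size != positions.size:
        raise ValueError("origin vector and positions must align")
    inf_idx = np.flatnonzero(origin_vector >= 0)
    if inf_idx.size == 0:
        return []
    labels = origin_vector[inf_idx]
    supported = [
        (lab, a, b)
        for lab, a, b in _runs(labels)
        if _run_support(inf_idx[a:b], strict_adjacency) >= min_support
    ]
    regions: list[CrossoverRegion] = []
    for (lab_l, a_l, b_l), (lab_r, a_r, b_r) in zip(supported, supported[1:]):
        if lab_l == lab_r:
            continue
        left = int(inf_idx[b_l - 1])
        right = int(inf_idx[a_r])
        regions.append(
            CrossoverRegion(
                meiosis_id=meiosis_id,
                parent_sex=parent_sex,
                chrom=chrom,
                left_index=left,
                right_index=right,
                left_pos=int(positions[left]),
                right_pos=int(positions[right]),
                support_left=b_l - a_l,
                support_right=b_r - a_r,
            )
        )
    return regions


def call_meiosis(
    meiosis: PhasedMeiosis,
    genotypes: GenotypeTable,
    min_support: int = 3,
    strict_adjacency: bool = False,
) -> tuple[list[CrossoverRegion], int]:
    """All crossover calls for one meiosis, plus its informative-SNP count."""
    origin = grandparental_origin(meiosis)
    pos = genotypes.snp_map["pos_bp"].to_numpy()
    regions: list[CrossoverRegion] = []
    for chrom, sl in genotypes.chrom_slices().items():
        regions.extend(
            call_crossovers(
                origin[sl], pos[sl], min_support,
                meiosis_id=meiosis.meiosis_id,
                parent_sex=meiosis.parent_sex,
                chrom=chrom,
                strict_adjacency=strict_adjacency,
            )
        )
    return regions, int((origin >= 0).sum())


def build_callset(
    meioses: list[PhasedMeiosis],
    genotypes: GenotypeTable,
    min_support: int = 3,
    strict_adjacency: bool = False,
) -> MeiosisCallSet:
    """Call crossovers for a set of phased meioses."""
    all_regions: list[CrossoverRegion] = []
    meta_rows = []
    for m in meioses:
        regions, n_inf = call_meiosis(m, genotypes, min_support, strict_adjacency)
        all_regions.extend(regions)
        meta_rows.append((m.meiosis_id, m.offspring, m.parent, m.parent_sex, n_inf, len(regions)))
    meta = pd.DataFrame(
        meta_rows,
        columns=["meiosis_id", "offspring", "parent", "parent_sex", "n_informative", "n_calls"],
    )
    return MeiosisCallSet(regions=all_regions, meta=meta)


def detection_power(callset: MeiosisCallSet, truth_crossovers: pd.DataFrame) -> float:
    """Fraction of true crossovers overlapped by a called region.

    A true crossover at bp ``x`` is detected when some called region of
    the same meiosis and chromosome satisfies ``left_pos < x <=
    right_pos``.  ``truth_crossovers`` needs columns ``meiosis_id``,
    ``chrom``, ``pos_bp``.
    """
    if len(truth_crossovers) == 0:
        raise ValueError("power is undefined with no true crossovers")
    index: dict[tuple[str, int], list[CrossoverRegion]] = {}
    for r in callset.regions:
        index.setdefault((r.meiosis_id, r.chrom), []).append(r)
    hits = 0
    for mid, chrom, pos in zip(
        truth_crossovers["meiosis_id"], truth_crossovers["chrom"], truth_crossovers["pos_bp"]
    ):
        regions = index.get((mid, int(chrom)), ())
        if any(r.covers(pos) for r in regions):
            hits += 1
    return hits / len(truth_crossovers)
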