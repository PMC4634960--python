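"""Synthetic cattle-pedigree simulator with known crossover truth.

Emulates the data a dense multi-generation dairy pedigree provides:
three-generation families genotyped on nested SNP chips over 29
autosomes (~2,516 Mb), with meiotic crossovers drawn from sex-specific
genetic maps (25.5 Morgans male, 23.2 Morgans female by default),
optional chiasma interference, chip-specific SNP masks, genotyping error
and missingness.  Every meiosis that the pipeline can observe (sire ->
offspring and dam -> offspring within a family) is recorded in a
:class:`TruthSet` together with the pre-masking phased haplotypes, so
phasing accuracy, crossover-detection power and map recovery can all be
scored against ground truth.

Founder haplotypes are linkage-equilibrium draws: each site is an
independent Bernoulli with a chip-ascertainment-like MAF law (default
Uniform(0.05, 0.5)).  Family rules, not LD, drive the phasing stages, so
background LD is deliberately not emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from recpipe.pedio import (
    MISSING,
    GenotypeTable,
    Pedigree,
    write_genotypes,
    write_pedigree,
)

# Approximate physical lengths of the 29 cattle autosomes (Mb), largest
# to smallest; rescaled so the genome default totals 2,516 Mb.
_CATTLE_AUTOSOME_MB = np.array(
    [158.3, 137.1, 121.4, 120.8, 121.2, 119.5, 112.6, 113.4, 105.7, 104.3,
     107.3, 91.2, 84.2, 84.6, 85.3, 81.7, 75.2, 66.0, 64.1, 72.0,
     71.6, 61.4, 52.5, 62.7, 42.9, 51.7, 45.4, 46.3, 51.5]
)

GENOME_BP_DEFAULT = 2_516_000_000
MALE_MORGANS_DEFAULT = 25.5
FEMALE_MORGANS_DEFAULT = 23.2


def cattle_chrom_lengths(n_chromosomes: int = 29, genome_bp: int = GENOME_BP_DEFAULT) -> list[int]:
    """Autosome lengths in bp, proportional to the cattle karyotype."""
    mb = _CATTLE_AUTOSOME_MB[:n_chromosomes]
    scaled = mb / mb.sum() * genome_bp
    return [int(round(x)) for x in scaled]


@dataclass
class SimConfig:
    """All knobs of the simulator.

    ``male_map_morgans`` / ``female_map_morgans`` are per-chromosome
    genetic lengths; totals are split proportionally to physical length
    by :meth:`cattle_default`.  ``chip_panels`` maps a chip name to the
    number of SNPs on it (``None`` = all SNPs); panels are built nested,
    each a subset of the next larger one.  ``interference_nu`` is the
    gamma-renewal shape: 1 reproduces interference-free (Poisson)
    crossovers, larger values give more evenly spaced crossovers.
    ``hotspot_bp_fraction`` / ``hotspot_mass_fraction`` optionally
    concentrate part of the map mass into a small physical fraction of
    designated hotspot intervals.
    """

    n_chromosomes: int = 29
    chrom_lengths_bp: list[int] = field(default_factory=cattle_chrom_lengths)
    n_snps: int = 54_000
    maf_law: tuple = ("uniform", 0.05, 0.5)
    male_map_morgans: list[float] | None = None
    female_map_morgans: list[float] | None = None
    interference_nu: float = 1.0
    obligate_crossover: bool = False
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    chip_panels: dict = field(default_factory=lambda: {"50K": None})
    chip_mix: dict = field(default_factory=lambda: {"50K": 1.0})
    granddam_mix: tuple[float, float, float] = (0.364, 0.410, 0.226)
    progeny_per_sire: int = 5
    hotspot_bp_fraction: float | None = None
    hotspot_mass_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if len(self.chrom_lengths_bp) != self.n_chromosomes:
            raise ValueError("chrom_lengths_bp length mismatch")
        if self.male_map_morgans is None:
            self.male_map_morgans = self._split_total(MALE_MORGANS_DEFAULT)
        if self.female_map_morgans is None:
            self.female_map_morgans = self._split_total(FEMALE_MORGANS_DEFAULT)
        if isinstance(self.male_map_morgans, (int, float)):
            self.male_map_morgans = self._split_total(float(self.male_map_morgans))
        if isinstance(self.female_map_morgans, (int, float)):
            self.female_map_morgans = self._split_total(float(self.female_map_morgans))
        for name, lens in (("male", self.male_map_morgans), ("female", self.female_map_morgans)):
            if len(lens) != self.n_chromosomes or any(l < 0 for l in lens):
                raise ValueError(f"invalid {name} map lengths")
        if self.interference_nu < 1:
            raise ValueError("interference_nu must be >= 1")
        if self.n_snps < 2 * self.n_chromosomes:
            raise ValueError("need at least 2 SNPs per chromosome")
        if not 0 <= self.genotype_error_rate < 1 or not 0 <= self.missing_rate < 1:
            raise ValueError("rates must be in [0, 1)")
        if abs(sum(self.granddam_mix) - 1.0) > 1e-9:
            raise ValueError("granddam_mix must sum to 1")

    def _split_total(self, total: float) -> list[float]:
        lens = np.asarray(self.chrom_lengths_bp, dtype=float)
        return list(total * lens / lens.sum())

    @classmethod
    def cattle_default(cls, **overrides) -> "SimConfig":
        """Full-scale default: 29 autosomes, 2,516 Mb, 54K SNPs."""
        return cls(**overrides)

    @classmethod
    def small(cls, n_chromosomes: int = 2, n_snps: int = 400, seed: int = 0, **overrides) -> "SimConfig":
        """Reduced genome for fast tests (same per-bp recombination density)."""
        lengths = cattle_chrom_lengths(n_chromosomes, genome_bp=n_chromosomes * 80_000_000)
        frac = sum(lengths) / GENOME_BP_DEFAULT
        return cls(
            n_chromosomes=n_chromosomes,
            chrom_lengths_bp=lengths,
            n_snps=n_snps,
            male_map_morgans=overrides.pop("male_map_morgans", MALE_MORGANS_DEFAULT * frac),
            female_map_morgans=overrides.pop("female_map_morgans", FEMALE_MORGANS_DEFAULT * frac),
            seed=seed,
            **overrides,
        )


class GeneticMap:
    """Monotone bp <-> Morgan coordinate transform for one chromosome.

    Piecewise linear between knots; uniform maps have two knots, maps
    with designated hotspot intervals have one knot per rate change.
    """

    def __init__(self, bp_knots: np.ndarray, morgan_knots: np.ndarray):
        bp_knots = np.asarray(bp_knots, dtype=float)
        morgan_knots = np.asarray(morgan_knots, dtype=float)
        if bp_knots.size < 2 or bp_knots.size != morgan_knots.size:
            raise ValueError("need matching bp/Morgan knot arrays of length >= 2")
        if np.any(np.diff(bp_knots) <= 0) or np.any(np.diff(morgan_knots) < 0):
            raise ValueError("knots must be monotone")
        self.bp_knots = bp_knots
        self.morgan_knots = morgan_knots

    @classmethod
    def uniform(cls, length_bp: int, morgans: float) -> "GeneticMap":
        return cls(np.array([0.0, length_bp]), np.array([0.0, morgans]))

    @property
    def length_bp(self) -> float:
        return float(self.bp_knots[-1])

    @property
    def total_morgans(self) -> float:
        return float(self.morgan_knots[-1])

    def morgans_at(self, bp: np.ndarray | float) -> np.ndarray | float:
        return np.interp(bp, self.bp_knots, self.morgan_knots)

    def bp_at(self, morgans: np.ndarray | float) -> np.ndarray | float:
        return np.interp(morgans, self.morgan_knots, self.bp_knots)

    def interval_morgans(self, positions_bp: np.ndarray) -> np.ndarray:
        """Genetic length of each interval between adjacent positions."""
        g = self.morgans_at(np.asarray(positions_bp, dtype=float))
        return np.diff(g)


def hotspot_enriched_map(
    length_bp: int,
    morgans: float,
    positions_bp: np.ndarray,
    bp_fraction: float,
    mass_fraction: float,
    rng: np.random.Generator,
) -> tuple[GeneticMap, np.ndarray]:
    """Concentrate ``mass_fraction`` of the map into ``bp_fraction`` of bp.

    A random subset of adjacent-SNP intervals totalling about
    ``bp_fraction`` of the chromosome is designated hotspot; those
    intervals share ``mass_fraction`` of the genetic length uniformly
    per bp, the rest share the remainder.  Returns the map and a boolean
    hotspot flag per interval (length ``len(positions_bp) - 1``).
    """
    positions_bp = np.asarray(positions_bp)
    widths = np.diff(positions_bp).astype(float)
    n_int = widths.size
    order = rng.permutation(n_int)
    target = bp_fraction * length_bp
    cum = np.cumsum(widths[order])
    n_hot = max(1, int(np.searchsorted(cum, target)))
    hot = np.zeros(n_int, dtype=bool)
    hot[order[:n_hot]] = True
    hot_bp = widths[hot].sum()
    cold_bp = length_bp - hot_bp
    rate_hot = mass_fraction * morgans / hot_bp
    rate_cold = (1 - mass_fraction) * morgans / cold_bp
    # knots: chromosome start, every SNP, chromosome end; flanks cold
    bp_knots = np.concatenate([[0.0], positions_bp.astype(float), [float(length_bp)]])
    rates = np.concatenate([[rate_cold], np.where(hot, rate_hot, rate_cold), [rate_cold]])
    seg = np.diff(bp_knots) * rates
    morgan_knots = np.concatenate([[0.0], np.cumsum(seg)])
    morgan_knots *= morgans / morgan_knots[-1]
    return GeneticMap(bp_knots, morgan_knots), hot


def draw_maf(maf_law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-SNP alternate-allele frequencies from a MAF law."""
    kind = maf_law[0]
    if kind == "point":
        freqs = np.full(n, float(maf_law[1]))
    elif kind == "uniform":
        lo, hi = float(maf_law[1]), float(maf_law[2])
        freqs = rng.uniform(lo, hi, size=n)
    elif kind == "beta":
        freqs = np.clip(rng.beta(float(maf_law[1]), float(maf_law[2]), size=n), 0.0, 0.5)
    else:
        raise ValueError(f"unknown maf_law {maf_law!r}")
    # randomize which allele is minor so dosage means are not all < 1
    flip = rng.random(n) < 0.5
    return np.where(flip, 1.0 - freqs, freqs)


def simulate_founders(
    config: SimConfig,
    n_founders: int,
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw founder haplotypes at linkage equilibrium.

    Returns ``(haplotypes, freqs)`` where ``haplotypes`` has shape
    ``(n_founders, 2, n_snps)`` and each allele is an independent
    Bernoulli draw with its site's alternate-allele frequency.
    """
    if n_founders <= 0:
        raise ValueError("n_founders must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if freqs is None:
        freqs = draw_maf(config.maf_law, config.n_snps, rng)
    haps = (rng.random((n_founders, 2, len(freqs))) < freqs).astype(np.int8)
    return haps, freqs


def _crossover_positions(
    gmap: GeneticMap, nu: float, rng: np.random.Generator, obligate: bool = False
) -> np.ndarray:
    """Crossover bp positions for one meiosis on one chromosome.

    Chiasmata form a gamma-renewal process on the four-strand bundle at
    genetic rate 2 per Morgan (shape ``nu``, scale ``1/(2 nu)``); each
    chiasma involves the sampled chromatid with probability 1/2.  With
    ``nu = 1`` the thinned process is Poisson with intensity 1 per
    Morgan.  A 5-Morgan burn-in approximates the stationary renewal
    start.
    """
    total = gmap.total_morgans
    if total <= 0:
        return np.empty(0)
    burnin = 5.0
    for _ in range(1000):
        horizon = burnin + total
        # expected arrivals = 2 * horizon; draw with headroom, extend if short
        n_draw = max(16, int(2 * horizon + 6 * math.sqrt(2 * horizon)))
        arrivals = np.cumsum(rng.gamma(nu, 1.0 / (2.0 * nu), size=n_draw))
        while arrivals[-1] < horizon:
            extra = np.cumsum(rng.gamma(nu, 1.0 / (2.0 * nu), size=n_draw)) + arrivals[-1]
            arrivals = np.concatenate([arrivals, extra])
        chiasma_g = arrivals[(arrivals > burnin) & (arrivals <= horizon)] - burnin
        kept = chiasma_g[rng.random(chiasma_g.size) < 0.5]
        if kept.size or not obligate:
            return np.sort(np.asarray(gmap.bp_at(kept)))
    raise RuntimeError("obligate crossover: no crossover after many redraws")


def simulate_meiosis(
    parent_haplotypes: np.ndarray,
    positions_bp: np.ndarray,
    genetic_map: GeneticMap,
    interference_nu: float = 1.0,
    rng: np.random.Generator | None = None,
    obligate_crossover: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sample one gamete from a parent's haplotype pair.

    Returns ``(gamete, crossover_bp, start_hap)``: the transmitted
    haplotype over ``positions_bp``, the true crossover positions in bp,
    and which parental haplotype (0 or 1) the gamete starts on at the
    chromosome's left end.  The gamete alternates between the two
    parental haplotypes at each crossover.
    """
    if rng is None:
        rng = np.random.default_rng()
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.ndim != 2 or parent_haplotypes.shape[0] != 2:
        raise ValueError("parent_haplotypes must have shape (2, n_snps)")
    positions_bp = np.asarray(positions_bp)
    if parent_haplotypes.shape[1] != positions_bp.size:
        raise ValueError("haplotype length must match positions")
    if genetic_map.bp_knots.size < 2:
        raise ValueError("empty genetic map")
    if interference_nu < 1:
        raise ValueError("interference_nu must be >= 1")
    xo_bp = _crossover_positions(genetic_map, interference_nu, rng, obligate_crossover)
    start = int(rng.integers(0, 2))
    origin = (start + np.searchsorted(xo_bp, positions_bp)) % 2
    gamete = parent_haplotypes[origin, np.arange(positions_bp.size)]
    return gamete, xo_bp, start


@dataclass
class TrueMeiosis:
    """Ground truth for one observable meiosis (parent -> offspring)."""

    meiosis_id: str
    offspring: str
    parent: str
    parent_sex: str  # "M" (paternal meiosis) or "F" (maternal)
    # per chromosome: (start haplotype 0/1, crossover bp positions)
    segments: dict[int, tuple[int, np.ndarray]]

    def origin_vector(self, chrom: int, positions_bp: np.ndarray) -> np.ndarray:
        """True parental-haplotype origin (0/1) at each SNP position."""
        start, xo = self.segments[chrom]
        return (start + np.searchsorted(xo, positions_bp)) % 2


@dataclass
class TruthSet:
    """Everything the simulator knows that the pipeline must infer."""

    haplotypes: dict[str, np.ndarray]  # animal -> (2, n_snps); row 0 paternal
    meioses: list[TrueMeiosis]
    genetic_maps: dict[tuple[str, int], GeneticMap]  # (sex, chrom) -> map
    hotspot_intervals: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def crossovers_df(self) -> pd.DataFrame:
        rows = []
        for m in self.meioses:
            for chrom, (_, xo) in m.segments.items():
                for pos in xo:
                    rows.append((m.meiosis_id, m.offspring, m.parent, m.parent_sex, chrom, pos))
        return pd.DataFrame(
            rows, columns=["meiosis_id", "offspring", "parent", "parent_sex", "chrom", "pos_bp"]
        )

    def n_crossovers(self) -> int:
        return sum(xo.size for m in self.meioses for _, xo in m.segments.values())

    def true_interval_rates(self, sex: str, chrom: int, positions_bp: np.ndarray) -> np.ndarray:
        """Expected crossovers per meiosis in each adjacent-SNP interval."""
        return self.genetic_maps[(sex, chrom)].interval_morgans(positions_bp)


def _allocate_snps(config: SimConfig) -> list[int]:
    """SNPs per chromosome, proportional to length, largest remainder."""
    lens = np.asarray(config.chrom_lengths_bp, dtype=float)
    raw = config.n_snps * lens / lens.sum()
    counts = np.maximum(np.floor(raw).astype(int), 2)
    while counts.sum() < config.n_snps:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > config.n_snps:
        over = np.where(counts > 2)[0]
        counts[over[np.argmin((raw - counts)[over])]] -= 1
    return counts.tolist()


def _snp_positions(length_bp: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct sorted 1-based positions, uniform over the chromosome."""
    pos = set()
    while len(pos) < n:
        draw = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos.update(int(p) for p in draw)
    return np.array(sorted(pos), dtype=np.int64)


def build_snp_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = _allocate_snps(config)
    frames = []
    for c, (n, length) in enumerate(zip(per_chrom, config.chrom_lengths_bp), start=1):
        pos = _snp_positions(length, n, rng)
        frames.append(
            pd.DataFrame(
                {"chrom": c, "snp_id": [f"snp{c}_{i}" for i in range(n)], "pos_bp": pos}
            )
        )
    return pd.concat(frames, ignore_index=True)


def build_chip_masks(
    n_snps: int, chip_panels: dict, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Nested boolean SNP masks per chip, largest panel first.

    Each smaller panel is a uniform random subset of the next larger
    one, mirroring nested commercial chip designs.
    """
    sizes = {
        name: (n_snps if size is None else min(int(size), n_snps))
        for name, size in chip_panels.items()
    }
    ordered = sorted(sizes, key=lambda k: -sizes[k])
    masks: dict[str, np.ndarray] = {}
    current = np.arange(n_snps)
    for name in ordered:
        keep = sizes[name]
        if keep < current.size:
            current = np.sort(rng.choice(current, size=keep, replace=False))
        mask = np.zeros(n_snps, dtype=bool)
        mask[current] = True
        masks[name] = mask
    return masks


def _make_genetic_maps(
    config: SimConfig, snp_map: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[tuple[str, int], GeneticMap], dict[tuple[str, int], np.ndarray]]:
    gmaps: dict[tuple[str, int], GeneticMap] = {}
    hot: dict[tuple[str, int], np.ndarray] = {}
    for c in range(1, config.n_chromosomes + 1):
        length = config.chrom_lengths_bp[c - 1]
        pos = snp_map.loc[snp_map["chrom"] == c, "pos_bp"].to_numpy()
        for sex, morgans in (("M", config.male_map_morgans[c - 1]),
                             ("F", config.female_map_morgans[c - 1])):
            if config.hotspot_bp_fraction is not None:
                gmap, flags = hotspot_enriched_map(
                    length, morgans, pos,
                    config.hotspot_bp_fraction,
                    config.hotspot_mass_fraction if config.hotspot_mass_fraction is not None else 0.25,
                    rng,
                )
                gmaps[(sex, c)] = gmap
                hot[(sex, c)] = flags
            else:
                gmaps[(sex, c)] = GeneticMap.uniform(length, morgans)
    return gmaps, hot


def _gamete(
    haps: np.ndarray,
    chrom_bounds: list[tuple[int, int, int]],  # (chrom, start_col, stop_col)
    gmaps: dict[tuple[str, int], GeneticMap],
    sex: str,
    snp_pos: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[int, tuple[int, np.ndarray]]]:
    gamete = np.empty(haps.shape[1], dtype=np.int8)
    segments: dict[int, tuple[int, np.ndarray]] = {}
    for chrom, a, b in chrom_bounds:
        g, xo, start = simulate_meiosis(
            haps[:, a:b], snp_pos[a:b], gmaps[(sex, chrom)],
            config.interference_nu, rng, config.obligate_crossover,
        )
        gamete[a:b] = g
        segments[chrom] = (start, xo)
    return gamete, segments


def simulate_pedigree(
    config: SimConfig, n_families: int
) -> tuple[Pedigree, GenotypeTable, TruthSet]:
    """Simulate ``n_families`` three-generation families end to end.

    Sires are shared across families (``config.progeny_per_sire``
    progeny each) to reproduce the many-offspring-per-bull pedigree
    structure; dams and all four grandparents per parent are founders.
    Chip masks, genotyping error and missingness are applied to the
    emitted genotypes only, after the truth is recorded.  Deterministic
    given ``config.seed``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(config.seed)
    snp_map = build_snp_map(config, rng)
    snp_pos = snp_map["pos_bp"].to_numpy()
    n_snps = len(snp_map)
    chrom_bounds = []
    chroms = snp_map["chrom"].to_numpy()
    for c in range(1, config.n_chromosomes + 1):
        idx = np.flatnonzero(chroms == c)
        chrom_bounds.append((c, int(idx[0]), int(idx[-1]) + 1))
    gmaps, hot = _make_genetic_maps(config, snp_map, rng)
    masks = build_chip_masks(n_snps, config.chip_panels, rng)
    freqs = draw_maf(config.maf_law, n_snps, rng)

    n_sires = math.ceil(n_families / config.progeny_per_sire)
    haplotypes: dict[str, np.ndarray] = {}
    ped_rows: list[tuple] = []
    meioses: list[TrueMeiosis] = []

    chip_names = list(config.chip_mix)
    chip_probs = np.array([config.chip_mix[c] for c in chip_names], dtype=float)
    chip_probs /= chip_probs.sum()

    def founder(name: str, sex: str, year: int, chip: str) -> None:
        h, _ = simulate_founders(config, 1, rng, freqs)
        haplotypes[name] = h[0]
        ped_rows.append((name, "", "", sex, year, chip))

    def bred(name: str, sire: str, dam: str, sex: str, year: int, chip: str,
             record: bool = False) -> None:
        pat, pat_seg = _gamete(haplotypes[sire], chrom_bounds, gmaps, "M", snp_pos, config, rng)
        mat, mat_seg = _gamete(haplotypes[dam], chrom_bounds, gmaps, "F", snp_pos, config, rng)
        haplotypes[name] = np.stack([pat, mat])
        ped_rows.append((name, sire, dam, sex, year, chip))
        if record:
            meioses.append(TrueMeiosis(f"{name}|{sire}", name, sire, "M", pat_seg))
            meioses.append(TrueMeiosis(f"{name}|{dam}", name, dam, "F", mat_seg))

    def pick_chip() -> str:
        return chip_names[int(rng.choice(len(chip_names), p=chip_probs))]

    # sires with their founder parents (grandsires always on the reference chip)
    ref_chip = max(config.chip_panels, key=lambda k: np.count_nonzero(masks[k]))
    granddam_genotyped: dict[str, bool] = {}
    for s in range(n_sires):
        sire = f"S{s:05d}"
        gs, gd = f"{sire}_GS", f"{sire}_GD"
        year = int(rng.integers(1975, 1995))
        founder(gs, "M", year - 6, ref_chip)
        founder(gd, "F", year - 6, pick_chip())
        granddam_genotyped[gd] = False  # decided per family below, sire-level here
        bred(sire, gs, gd, "M", year, pick_chip())

    families_meta = []
    for f in range(n_families):
        sire = f"S{f % n_sires:05d}"
        dam = f"D{f:05d}"
        off = f"O{f:05d}"
        gs, gd = f"{dam}_GS", f"{dam}_GD"
        year = int(rng.integers(1980, 2000))
        founder(gs, "M", year - 6, ref_chip)
        founder(gd, "F", year - 6, pick_chip())
        bred(dam, gs, gd, "F", year, pick_chip())
        bred(off, sire, dam, rng.choice(["M", "F"]), year + 5, pick_chip(), record=True)
        # how many granddams of this family are genotyped
        n_gd = int(rng.choice(3, p=[config.granddam_mix[2], config.granddam_mix[1],
                                    config.granddam_mix[0]]))
        pat_gd = f"{sire}_GD"
        if n_gd == 2:
            chosen = [pat_gd, gd]
        elif n_gd == 1:
            chosen = [pat_gd if rng.random() < 0.5 else gd]
        else:
            chosen = []
        for g in chosen:
            granddam_genotyped[g] = True
        granddam_genotyped.setdefault(gd, False)
        families_meta.append((off, n_gd))

    pedigree = Pedigree(
        pd.DataFrame(ped_rows, columns=["animal_id", "sire_id", "dam_id", "sex", "birth_year", "chip"])
    )

    # emit genotypes: everyone except ungenotyped granddams
    genotyped = [r[0] for r in ped_rows
                 if not (r[0] in granddam_genotyped and not granddam_genotyped[r[0]])]
    chips = {a: pedigree.chip(a) for a in genotyped}
    dosages = np.empty((len(genotyped), n_snps), dtype=np.int8)
    for i, a in enumerate(genotyped):
        dosages[i] = haplotypes[a].sum(axis=0, dtype=np.int8)
        dosages[i, ~masks[chips[a]]] = MISSING
    if config.genotype_error_rate > 0:
        err = (rng.random(dosages.shape) < config.genotype_error_rate) & (dosages != MISSING)
        # flip to a uniformly chosen different valid dosage
        shift = rng.integers(1, 3, size=dosages.shape).astype(np.int8)
        dosages[err] = (dosages[err] + shift[err]) % 3
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = MISSING

    table = GenotypeTable(snp_map=snp_map, dosages=dosages, animal_ids=genotyped, chips=chips)
    truth = TruthSet(haplotypes=haplotypes, meioses=meioses, genetic_maps=gmaps,
                     hotspot_intervals=hot)
    return pedigree, table, truth


def simulate_phased_meioses(
    config: SimConfig,
    n_meioses: int,
    n_parents: int | None = None,
    sex: str = "M",
) -> tuple[list, GenotypeTable, TruthSet]:
    """Meioses with truth-known parental phase, bypassing family phasing.

    Founder parents are drawn at linkage equilibrium and each meiosis
    samples one gamete; the returned phased meioses carry the parent's
    true haplotypes and the true transmitted alleles, so every site
    where the parent is heterozygous is informative.  This isolates
    crossover calling, map estimation and hotspot usage from phasing
    losses — the tool for parameter-recovery experiments at large n.

    Returns ``(meioses, genotypes, truth)``; genotypes hold the parents'
    error-free dosages on the full SNP grid.
    """
    from recpipe.phasing import PhasedMeiosis  # deferred: avoids import cycle

    if n_meioses < 1:
        raise ValueError("n_meioses must be >= 1")
    if n_parents is None:
        n_parents = max(1, min(200, n_meioses // 20))
    rng = np.random.default_rng(config.seed)
    snp_map = build_snp_map(config, rng)
    snp_pos = snp_map["pos_bp"].to_numpy()
    chroms = snp_map["chrom"].to_numpy()
    chrom_bounds = []
    for c in range(1, config.n_chromosomes + 1):
        idx = np.flatnonzero(chroms == c)
        chrom_bounds.append((c, int(idx[0]), int(idx[-1]) + 1))
    gmaps, hot = _make_genetic_maps(config, snp_map, rng)
    freqs = draw_maf(config.maf_law, len(snp_map), rng)
    parent_haps, _ = simulate_founders(config, n_parents, rng, freqs)
    parent_ids = [f"P{i:05d}" for i in range(n_parents)]

    meioses: list[PhasedMeiosis] = []
    truth_meioses: list[TrueMeiosis] = []
    for k in range(n_meioses):
        p = k % n_parents
        gamete, segments = _gamete(parent_haps[p], chrom_bounds, gmaps, sex,
                                   snp_pos, config, rng)
        mid = f"G{k:06d}|{parent_ids[p]}"
        meioses.append(
            PhasedMeiosis(
                meiosis_id=mid,
                offspring=f"G{k:06d}",
                parent=parent_ids[p],
                parent_sex=sex,
                transmitted=gamete,
                parent_pat=parent_haps[p][0],
                parent_mat=parent_haps[p][1],
            )
        )
        truth_meioses.append(TrueMeiosis(mid, f"G{k:06d}", parent_ids[p], sex, segments))

    dosages = parent_haps.sum(axis=1, dtype=np.int8)
    table = GenotypeTable(
        snp_map=snp_map, dosages=dosages, animal_ids=parent_ids,
        chips={a: "50K" for a in parent_ids},
    )
    truth = TruthSet(
        haplotypes={a: parent_haps[i] for i, a in enumerate(parent_ids)},
        meioses=truth_meioses,
        genetic_maps=gmaps,
        hotspot_intervals=hot,
    )
    return meioses, table, truth


def write_sim_outputs(
    outdir: str | Path,
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    truth: TruthSet,
    dialect: str = "tsv",
) -> None:
    """Write pedigree TSV, genotypes, and the truth crossover table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(pedigree, outdir / "pedigree.tsv")
    write_genotypes(genotypes, outdir / "genotypes", dialect=dialect)
    truth.crossovers_df().to_csv(outdir / "truth_crossovers.tsv", sep="\t", index=False)
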