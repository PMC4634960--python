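"""Config-driven end-to-end pipeline over a run directory.

Stages communicate exclusively through TSV files in the run directory,
so any stage can be re-run or inspected in isolation:

    simulate    pedigree.tsv, genotypes.{map,geno}.tsv, truth_crossovers.tsv
    calls       families.tsv, meioses.tsv, crossovers.tsv
    map         map_M.tsv, map_F.tsv, map_summary.tsv
    hotspots    hotspots_{M,F}.tsv, hotspots_shared.tsv, usage.tsv
    gwas        phenotypes_{M,F}.tsv, scan_{M,F}.tsv
    diagnostics profile_{M,F}.tsv

Every run writes ``manifest.json`` (config, config hash, seed, package
and numpy versions), and all randomness flows from the single root seed,
so reruns with an identical config are bit-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from recpipe import __version__
from recpipe.crossover import CrossoverRegion, MeiosisCallSet, build_callset, detection_power
from recpipe.diagnostics import position_profile
from recpipe.gwas import build_phenotypes, filter_snps, fit_null, grm, scan
from recpipe.hotspot import call_hotspots, hotspot_usage, shared_hotspots
from recpipe.pedio import (
    GenotypeTable,
    Pedigree,
    extract_families,
    read_genotypes,
    read_pedigree,
)
from recpipe.phasing import phase_family
from recpipe.recmap import RecombinationMap, em_fit, intervals_from_snp_map, map_summary
from recpipe.simdata import SimConfig, simulate_pedigree, write_sim_outputs

logger = logging.getLogger(__name__)

STAGES = ("simulate", "calls", "map", "hotspots", "gwas", "diagnostics")


@dataclass
class RunConfig:
    """Pipeline configuration; YAML-serializable, CLI-overridable."""

    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulation
    n_families: int = 200
    sim_scale: str = "small"  # "small" | "cattle"
    sim_overrides: dict = field(default_factory=dict)
    # thresholds
    min_support: int = 3
    k_sd: float = 2.5
    em_tol: float = 1e-8
    maf_min: float = 0.001
    r_max: float = 0.95
    trim_bp: float = 2e6
    spline_df: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> SimConfig:
        overrides = dict(self.sim_overrides)
        overrides["seed"] = self.seed
        if self.sim_scale == "cattle":
            return SimConfig.cattle_default(**overrides)
        return SimConfig.small(**overrides)


class MissingStageOutput(FileNotFoundError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageOutput(
            f"{path.name} not found in {path.parent}; run the '{stage}' stage first"
        )
    return path


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    pedigree, genotypes, truth = simulate_pedigree(cfg.sim_config(), cfg.n_families)
    write_sim_outputs(out, pedigree, genotypes, truth)
    logger.info("simulated %d families, %d animals, %d SNPs",
                cfg.n_families, genotypes.n_animals, genotypes.n_snps)


def _load_inputs(out: Path) -> tuple[Pedigree, GenotypeTable]:
    pedigree = read_pedigree(_require(out / "pedigree.tsv", "simulate"))
    genotypes = read_genotypes(out / "genotypes", dialect="tsv")
    return pedigree, genotypes


def stage_calls(cfg: RunConfig, out: Path) -> None:
    pedigree, genotypes = _load_inputs(out)
    families = extract_families(pedigree, genotypes.animal_ids)
    fam_df = pd.DataFrame([
        (f.offspring, f.sire, f.dam, f.paternal_grandsire, f.maternal_grandsire,
         f.paternal_granddam or "", f.maternal_granddam or "", f.n_granddams)
        for f in families
    ], columns=["offspring", "sire", "dam", "paternal_grandsire", "maternal_grandsire",
                "paternal_granddam", "maternal_granddam", "n_granddams"])
    fam_df.to_csv(out / "families.tsv", sep="\t", index=False)
    meioses = []
    for fam in families:
        ph = phase_family(fam, genotypes)
        if ph.flagged:
            logger.warning("family %s flagged (Mendelian rate %.3f); excluded",
                           fam.offspring, ph.mendel_rate)
            continue
        meioses.extend([ph.paternal, ph.maternal])
    callset = build_callset(meioses, genotypes, min_support=cfg.min_support)
    df = callset.regions_df()
    df["support_left"] = [r.support_left for r in callset.regions]
    df["support_right"] = [r.support_right for r in callset.regions]
    df.to_csv(out / "crossovers.tsv", sep="\t", index=False)
    callset.meta.to_csv(out / "meioses.tsv", sep="\t", index=False)
    truth_path = out / "truth_crossovers.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        power = detection_power(callset, truth)
        (out / "power.json").write_text(json.dumps({"power": power}))
        logger.info("detection power vs truth: %.4f", power)


def load_callset(out: Path) -> MeiosisCallSet:
    df = pd.read_csv(_require(out / "crossovers.tsv", "calls"), sep="\t")
    meta = pd.read_csv(_require(out / "meioses.tsv", "calls"), sep="\t",
                       dtype={"meiosis_id": str, "offspring": str, "parent": str})
    regions = [
        CrossoverRegion(
            meiosis_id=r.meiosis_id, parent_sex=r.parent_sex, chrom=int(r.chrom),
            left_index=int(r.left_index), right_index=int(r.right_index),
            left_pos=int(r.left_pos), right_pos=int(r.right_pos),
            support_left=int(r.support_left), support_right=int(r.support_right),
        )
        for r in df.itertuples()
    ]
    return MeiosisCallSet(regions=regions, meta=meta)


def stage_map(cfg: RunConfig, out: Path) -> dict[str, RecombinationMap]:
    _, genotypes = _load_inputs(out)
    callset = load_callset(out)
    intervals = intervals_from_snp_map(genotypes.snp_map)
    maps = {}
    for sex in ("M", "F"):
        regions = [r for r in callset.regions if r.parent_sex == sex]
        n = int((callset.meta["parent_sex"] == sex).sum())
        maps[sex] = em_fit(regions, n, intervals, tol=cfg.em_tol, sex=sex)
        maps[sex].to_df().to_csv(out / f"map_{sex}.tsv", sep="\t", index=False)
    summary = map_summary(maps["M"], maps["F"])
    summary["per_chrom"].to_csv(out / "map_summary.tsv", sep="\t")
    return maps


def _load_map(out: Path, sex: str) -> RecombinationMap:
    df = pd.read_csv(_require(out / f"map_{sex}.tsv", "map"), sep="\t")
    meta = pd.read_csv(_require(out / "meioses.tsv", "calls"), sep="\t")
    n = int((meta["parent_sex"] == sex).sum())
    return RecombinationMap(
        intervals=df[["chrom", "start_pos", "end_pos"]],
        rates=df["rate"].to_numpy(),
        n_meioses=n,
        sex=sex,
    )


def stage_hotspots(cfg: RunConfig, out: Path) -> None:
    callset = load_callset(out)
    sets = {}
    usage_parts = []
    for sex in ("M", "F"):
        rmap = _load_map(out, sex)
        hs = call_hotspots(rmap, k_sd=cfg.k_sd)
        sets[sex] = hs
        df = hs.intervals.copy()
        df.to_csv(out / f"hotspots_{sex}.tsv", sep="\t", index=False)
        sub = MeiosisCallSet(
            regions=[r for r in callset.regions if r.parent_sex == sex],
            meta=callset.meta[callset.meta["parent_sex"] == sex].reset_index(drop=True),
        )
        usage_parts.append(hotspot_usage(sub, hs, rmap))
    shared = shared_hotspots(sets["M"], sets["F"])
    pd.DataFrame([{
        "n_male": sets["M"].n_hotspots,
        "n_female": sets["F"].n_hotspots,
        "n_shared": shared["n_shared"],
        "fraction_male": shared["fraction_male"],
        "fraction_female": shared["fraction_female"],
    }]).to_csv(out / "hotspots_shared.tsv", sep="\t", index=False)
    pd.concat(usage_parts, ignore_index=True).to_csv(out / "usage.tsv", sep="\t", index=False)


def stage_gwas(cfg: RunConfig, out: Path) -> None:
    _, genotypes = _load_inputs(out)
    callset = load_callset(out)
    phen = build_phenotypes(callset, kind="rate")
    for sex in ("M", "F"):
        sub = phen[phen["sex"] == sex].reset_index(drop=True)
        sub.to_csv(out / f"phenotypes_{sex}.tsv", sep="\t", index=False)
        rows = [genotypes._index[a] for a in sub["animal_id"] if genotypes.has_animal(a)]
        sub = sub[[genotypes.has_animal(a) for a in sub["animal_id"]]].reset_index(drop=True)
        if len(sub) < 30:
            logger.warning("gwas(%s): only %d animals; skipping scan", sex, len(sub))
            continue
        G = genotypes.dosages[rows]
        kept = filter_snps(G, genotypes.snp_map, maf_min=cfg.maf_min, r_max=cfg.r_max)
        Gk = G[:, kept]
        null = fit_null(sub["y"].to_numpy(), sub["w"].to_numpy(), grm(Gk))
        result = scan(null, Gk, snp_meta=genotypes.snp_map.iloc[kept].reset_index(drop=True))
        result.to_csv(out / f"scan_{sex}.tsv", sep="\t", index=False)


def stage_diagnostics(cfg: RunConfig, out: Path) -> None:
    _, genotypes = _load_inputs(out)
    chrom_lengths = {
        int(c): int(g["pos_bp"].max())
        for c, g in genotypes.snp_map.groupby("chrom")
    }
    for sex in ("M", "F"):
        rmap = _load_map(out, sex)
        try:
            profile = position_profile(rmap, chrom_lengths, trim_bp=cfg.trim_bp,
                                       spline_df=cfg.spline_df)
        except ValueError as exc:
            logger.warning("diagnostics(%s): %s", sex, exc)
            continue
        pd.DataFrame({"relpos": profile.grid, "rate": profile.curve}).to_csv(
            out / f"profile_{sex}.tsv", sep="\t", index=False
        )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "calls": stage_calls,
    "map": stage_map,
    "hotspots": stage_hotspots,
    "gwas": stage_gwas,
    "diagnostics": stage_diagnostics,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages in dependency order; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "recpipe_version": __version__,
        "numpy_version": np.__version__,
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("stage: %s", stage)
        _STAGE_FUNCS[stage](cfg, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
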