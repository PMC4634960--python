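"""Input/output, validation, and three-generation family extraction.

Conventions used throughout the package:

* SNP positions are 1-based base pairs, strictly increasing within a
  chromosome; the interval between adjacent retained SNPs ``i`` and
  ``i+1`` is half-open ``(pos_i, pos_{i+1}]``.
* Dosages are counts of the alternate allele, ``0/1/2``, with ``-1``
  for a missing call.
* Chromosomes are autosomes numbered ``1..29`` (cattle); the X is never
  analyzed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

PEDIGREE_COLUMNS = ["animal_id", "sire_id", "dam_id", "sex", "birth_year", "chip"]
SNPMAP_COLUMNS = ["chrom", "snp_id", "pos_bp"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts)."""


@dataclass
class GenotypeTable:
    """SNP map plus a dense animal-by-SNP dosage matrix.

    Parameters
    ----------
    snp_map
        DataFrame with columns ``chrom``, ``snp_id``, ``pos_bp``, sorted
        by chromosome then position.
    dosages
        ``int8`` array of shape ``(n_animals, n_snps)`` with values in
        ``{0, 1, 2, -1}``.
    animal_ids
        Row labels for ``dosages``.
    chips
        Chip label per animal (e.g. ``"50K"``); used for chip-density
        correction downstream.
    """

    snp_map: pd.DataFrame
    dosages: np.ndarray
    animal_ids: list[str]
    chips: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_map = self.snp_map.reset_index(drop=True)
        missing_cols = set(SNPMAP_COLUMNS) - set(self.snp_map.columns)
        if missing_cols:
            raise FormatError(f"SNP map lacks columns {sorted(missing_cols)}")
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_map)):
            raise FormatError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("dosages must be 0/1/2 or -1 (missing)")
        self._check_positions()
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    def _check_positions(self) -> None:
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise FormatError(f"SNP positions not strictly increasing on chromosome {chrom}")
        if self.snp_map["snp_id"].duplicated().any():
            dups = self.snp_map.loc[self.snp_map["snp_id"].duplicated(), "snp_id"].tolist()
            raise FormatError(f"duplicated SNP ids: {dups[:5]}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def row(self, animal_id: str) -> np.ndarray:
        """Dosage vector for one animal."""
        return self.dosages[self._index[animal_id]]

    def has_animal(self, animal_id: str) -> bool:
        return animal_id in self._index

    def chrom_slices(self) -> dict[int, slice]:
        """Column slice of the dosage matrix covered by each chromosome."""
        out: dict[int, slice] = {}
        chroms = self.snp_map["chrom"].to_numpy()
        boundaries = np.flatnonzero(np.diff(chroms)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [len(chroms)]])
        for s, e in zip(starts, stops):
            out[int(chroms[s])] = slice(int(s), int(e))
        return out

    def chrom_positions(self, chrom: int) -> np.ndarray:
        sl = self.chrom_slices()[chrom]
        return self.snp_map["pos_bp"].to_numpy()[sl]


@dataclass
class Pedigree:
    """Per-animal pedigree records: parents, sex, birth year, chip label.

    ``sire_id``/``dam_id`` use the empty string for unknown parents.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PEDIGREE_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"pedigree lacks columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["animal_id"].duplicated().any():
            raise PedigreeError("duplicated animal ids in pedigree")
        self._records = self.table.set_index("animal_id")
        self._validate()

    def _validate(self) -> None:
        sex = self._records["sex"]
        for col, want in (("sire_id", "M"), ("dam_id", "F")):
            parents = self._records[col]
            known = parents[parents != ""].unique()
            present = [p for p in known if p in self._records.index]
            wrong = [p for p in present if sex.loc[p] != want]
            if wrong:
                raise PedigreeError(f"{col} entries with sex != {want}: {wrong[:5]}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative DFS; recursion depth would be a problem on deep pedigrees
        color: dict[str, int] = {}
        for start in self._records.index:
            if color.get(start, 0) == 2:
                continue
            stack = [(start, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    color[node] = 2
                    continue
                if color.get(node, 0) == 1:
                    raise PedigreeError(f"pedigree cycle involving {node}")
                if color.get(node, 0) == 2:
                    continue
                color[node] = 1
                stack.append((node, True))
                for col in ("sire_id", "dam_id"):
                    parent = self._records.at[node, col]
                    if parent and parent in self._records.index and color.get(parent, 0) != 2:
                        stack.append((parent, False))

    def parents(self, animal_id: str) -> tuple[str, str]:
        rec = self._records.loc[animal_id]
        return rec["sire_id"], rec["dam_id"]

    def sex(self, animal_id: str) -> str:
        return self._records.at[animal_id, "sex"]

    def birth_year(self, animal_id: str):
        return self._records.at[animal_id, "birth_year"]

    def chip(self, animal_id: str) -> str:
        return self._records.at[animal_id, "chip"]

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._records.index

    def animals(self) -> list[str]:
        return list(self._records.index)


@dataclass(frozen=True)
class TrioFamily:
    """One analyzable three-generation unit.

    The offspring, its two parents and the two grandsires must all be
    genotyped; granddams are recorded when genotyped but are optional.
    Each family yields exactly one paternal meiosis (sire -> offspring)
    and one maternal meiosis (dam -> offspring).
    """

    offspring: str
    sire: str
    dam: str
    paternal_grandsire: str
    maternal_grandsire: str
    paternal_granddam: str | None = None
    maternal_granddam: str | None = None

    @property
    def n_granddams(self) -> int:
        return sum(g is not None for g in (self.paternal_granddam, self.maternal_granddam))

    def members(self) -> list[str]:
        core = [self.offspring, self.sire, self.dam, self.paternal_grandsire, self.maternal_grandsire]
        return core + [g for g in (self.paternal_granddam, self.maternal_granddam) if g is not None]


def extract_families(pedigree: Pedigree, genotyped_ids: Iterable[str]) -> list[TrioFamily]:
    """Find every three-generation family with full genotype coverage.

    An offspring founds a family iff its sire, dam and both grandsires
    are genotyped.  Granddams are attached when genotyped.  An animal may
    appear in many families (a bull with hundreds of progeny is a sire in
    each, and possibly an offspring in its own family).

    The result is sorted by offspring id and independent of the ordering
    of ``genotyped_ids``.
    """
    genotyped = set(genotyped_ids)
    families: list[TrioFamily] = []
    for offspring in pedigree.animals():
        if offspring not in genotyped:
            continue
        sire, dam = pedigree.parents(offspring)
        if not sire or not dam or sire not in genotyped or dam not in genotyped:
            continue
        if sire not in pedigree or dam not in pedigree:
            continue
        pgs, pgd = pedigree.parents(sire)
        mgs, mgd = pedigree.parents(dam)
        if not pgs or not mgs or pgs not in genotyped or mgs not in genotyped:
            continue
        families.append(
            TrioFamily(
                offspring=offspring,
                sire=sire,
                dam=dam,
                paternal_grandsire=pgs,
                maternal_grandsire=mgs,
                paternal_granddam=pgd if pgd and pgd in genotyped else None,
                maternal_granddam=mgd if mgd and mgd in genotyped else None,
            )
        )
    families.sort(key=lambda f: f.offspring)
    return families


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "sire_id": str, "dam_id": str})
    df[["sire_id", "dam_id"]] = df[["sire_id", "dam_id"]].fillna("")
    return Pedigree(df)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.table.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeTable:
    """Read genotypes in one of the supported text dialects.

    ``tsv``
        A SNP map file ``<path>.map.tsv`` plus a dense matrix
        ``<path>.geno.tsv`` whose first two columns are ``animal_id``
        and ``chip`` and remaining columns are SNP dosages (``NA`` or
        ``-9`` for missing).
    ``ped``
        PLINK text ``<path>.ped`` / ``<path>.map``: alleles coded
        ``1``/``2`` (``0`` missing), dosage = count of allele ``2``.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "ped":
        return _read_ped(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(table: GenotypeTable, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "tsv":
        _write_tsv(table, path)
    elif dialect == "ped":
        _write_ped(table, path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_tsv(path: Path) -> GenotypeTable:
    snp_map = pd.read_csv(f"{path}.map.tsv", sep="\t", dtype={"chrom": int, "snp_id": str, "pos_bp": int})
    geno = pd.read_csv(f"{path}.geno.tsv", sep="\t", dtype={"animal_id": str, "chip": str})
    animal_ids = geno["animal_id"].tolist()
    chips = dict(zip(animal_ids, geno["chip"]))
    mat = geno[snp_map["snp_id"]].to_numpy(dtype=float)
    mat = np.where(np.isnan(mat) | (mat == -9), MISSING, mat).astype(np.int8)
    return GenotypeTable(snp_map=snp_map, dosages=mat, animal_ids=animal_ids, chips=chips)


def _write_tsv(table: GenotypeTable, path: Path) -> None:
    table.snp_map.to_csv(f"{path}.map.tsv", sep="\t", index=False)
    df = pd.DataFrame(table.dosages, columns=table.snp_map["snp_id"])
    df = df.replace(MISSING, -9)
    df.insert(0, "chip", [table.chips.get(a, "50K") for a in table.animal_ids])
    df.insert(0, "animal_id", table.animal_ids)
    df.to_csv(f"{path}.geno.tsv", sep="\t", index=False)


def _read_ped(path: Path) -> GenotypeTable:
    map_df = pd.read_csv(
        f"{path}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": int, "snp_id": str, "pos_bp": int},
    )
    snp_map = map_df[["chrom", "snp_id", "pos_bp"]].copy()
    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(f"{path}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snp_map):
                raise FormatError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * len(snp_map)}"
                )
            animal_ids.append(parts[1])
            alleles = np.array(parts[6:], dtype="U2").reshape(-1, 2)
            dosage = (alleles == "2").sum(axis=1).astype(np.int8)
            dosage[(alleles == "0").any(axis=1)] = MISSING
            rows.append(dosage)
    mat = np.vstack(rows) if rows else np.empty((0, len(snp_map)), dtype=np.int8)
    return GenotypeTable(snp_map=snp_map, dosages=mat, animal_ids=animal_ids)


def _write_ped(table: GenotypeTable, path: Path) -> None:
    map_df = table.snp_map.assign(cm=0)[["chrom", "snp_id", "cm", "pos_bp"]]
    map_df.to_csv(f"{path}.map", sep="\t", index=False, header=False)
    # dosage -> allele pair: 0 -> "1 1", 1 -> "1 2", 2 -> "2 2", missing -> "0 0"
    pair = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}
    with open(f"{path}.ped", "w") as fh:
        for animal, row in zip(table.animal_ids, table.dosages):
            genos = " ".join(pair[int(d)] for d in row)
            fh.write(f"FAM {animal} 0 0 0 -9 {genos}\n")


def write_truth_crossovers(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_truth_crossovers(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"meiosis_id": str, "parent_sex": str})


def drop_snps(table: GenotypeTable, blacklist: Sequence[str]) -> GenotypeTable:
    """Remove SNPs by id from both the map and the dosage matrix.

    Unknown ids are skipped with a warning; used to drop markers whose
    pairwise-LD pattern indicates a misplaced physical position.
    """
    blacklist = list(blacklist)
    known = set(table.snp_map["snp_id"])
    unknown = [s for s in blacklist if s not in known]
    if unknown:
        warnings.warn(f"blacklist ids not in SNP map, skipped: {unknown[:10]}")
        logger.warning("drop_snps: %d unknown ids skipped", len(unknown))
    keep = ~table.snp_map["snp_id"].isin(blacklist).to_numpy()
    return GenotypeTable(
        snp_map=table.snp_map.loc[keep].reset_index(drop=True),
        dosages=table.dosages[:, keep],
        animal_ids=list(table.animal_ids),
        chips=dict(table.chips),
    )


def read_blacklist(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
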