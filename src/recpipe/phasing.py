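"""Within-family Mendelian phasing with parent-of-origin assignment.

Each family is phased on its own: homozygous genotypes phase trivially,
and a heterozygous genotype is phased whenever the two parental
genotypes do not both equal 1 — equivalently, whenever exactly one
ordered (paternal, maternal) allele assignment is consistent with
Mendelian transmission.  No LD and no pooling across multiple offspring
is used, so paternal and maternal meioses are treated on an equal
footing.  Grandparent genotypes phase the parents the same way, which
labels each parental haplotype as grand-paternal or grand-maternal;
when a granddam is ungenotyped, a heterozygous parent site is phased
only if the grandsire is homozygous.

Sites with no Mendelian-consistent assignment are masked (set unknown
for all members) and counted, never corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from recpipe.pedio import MISSING, GenotypeTable, TrioFamily

UNKNOWN = -1

_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


def _enumerate_assignments(child: int, pat_parent: int | None, mat_parent: int | None):
    """All (paternal, maternal) allele pairs consistent with transmission.

    ``None`` for a parent means that parent is unobserved (alleles
    unconstrained).  This enumeration is the definition the vectorized
    lookup tables are compiled from.
    """
    pat_opts = _ALLELES[pat_parent] if pat_parent is not None else (0, 1)
    mat_opts = _ALLELES[mat_parent] if mat_parent is not None else (0, 1)
    return {
        (p, m)
        for p, m in itertools.product(pat_opts, mat_opts)
        if p + m == child
    }


def _compile_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Phase lookup tables over dosage codes {-1, 0, 1, 2} -> index 0..3."""
    trio_pat = np.full((4, 4, 4), UNKNOWN, dtype=np.int8)
    trio_mat = np.full((4, 4, 4), UNKNOWN, dtype=np.int8)
    trio_bad = np.zeros((4, 4, 4), dtype=bool)
    duo_pat = np.full((4, 4), UNKNOWN, dtype=np.int8)
    duo_mat = np.full((4, 4), UNKNOWN, dtype=np.int8)
    duo_bad = np.zeros((4, 4), dtype=bool)
    for child in (0, 1, 2):
        ci = child + 1
        for sire in (0, 1, 2):
            si = sire + 1
            # duo: other parent unobserved
            opts = _enumerate_assignments(child, sire, None)
            if not opts:
                duo_bad[ci, si] = True
            elif len(opts) == 1:
                (p, m), = opts
                duo_pat[ci, si], duo_mat[ci, si] = p, m
            else:
                pats = {p for p, _ in opts}
                mats = {m for _, m in opts}
                if len(pats) == 1:
                    duo_pat[ci, si] = pats.pop()
                if len(mats) == 1:
                    duo_mat[ci, si] = mats.pop()
            for dam in (0, 1, 2):
                di = dam + 1
                opts = _enumerate_assignments(child, sire, dam)
                if not opts:
                    trio_bad[ci, si, di] = True
                elif len(opts) == 1:
                    (p, m), = opts
                    trio_pat[ci, si, di], trio_mat[ci, si, di] = p, m
    return trio_pat, trio_mat, trio_bad, duo_pat, duo_mat, duo_bad


_TRIO_PAT, _TRIO_MAT, _TRIO_BAD, _DUO_PAT, _DUO_MAT, _DUO_BAD = _compile_tables()


def phase_offspring(
    offspring_g: np.ndarray, sire_g: np.ndarray, dam_g: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase an offspring against its two parents.

    Returns ``(paternal, maternal, inconsistent)`` where the first two
    are per-SNP transmitted alleles (0/1, or -1 unknown) and
    ``inconsistent`` marks sites with no Mendelian-consistent
    assignment.  A missing genotype in any member leaves the site
    unphased without flagging it.
    """
    o, s, d = (np.asarray(v, dtype=np.int8) for v in (offspring_g, sire_g, dam_g))
    if not (o.shape == s.shape == d.shape):
        raise ValueError("offspring/sire/dam dosage vectors must share one SNP set")
    oi, si, di = o + 1, s + 1, d + 1
    pat = _TRIO_PAT[oi, si, di]
    mat = _TRIO_MAT[oi, si, di]
    bad = _TRIO_BAD[oi, si, di]
    observed = (o != MISSING) & (s != MISSING) & (d != MISSING)
    pat = np.where(observed, pat, UNKNOWN).astype(np.int8)
    mat = np.where(observed, mat, UNKNOWN).astype(np.int8)
    bad &= observed
    pat[bad] = UNKNOWN
    mat[bad] = UNKNOWN
    return pat, mat, bad


def phase_parent(
    parent_g: np.ndarray,
    grandsire_g: np.ndarray,
    granddam_g: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase a parent against its own sire (and dam, when genotyped).

    Returns ``(paternal_hap, maternal_hap, inconsistent)``: the parent's
    grand-paternal and grand-maternal haplotype alleles.  With no
    granddam, a heterozygous parent site is resolved only if the
    grandsire is homozygous (its allele goes to the paternal haplotype).
    """
    if granddam_g is not None:
        return phase_offspring(parent_g, grandsire_g, granddam_g)
    p, gs = (np.asarray(v, dtype=np.int8) for v in (parent_g, grandsire_g))
    if p.shape != gs.shape:
        raise ValueError("parent/grandsire dosage vectors must share one SNP set")
    pi, gi = p + 1, gs + 1
    pat = _DUO_PAT[pi, gi]
    mat = _DUO_MAT[pi, gi]
    bad = _DUO_BAD[pi, gi]
    observed = (p != MISSING) & (gs != MISSING)
    pat = np.where(observed, pat, UNKNOWN).astype(np.int8)
    mat = np.where(observed, mat, UNKNOWN).astype(np.int8)
    bad &= observed
    pat[bad] = UNKNOWN
    mat[bad] = UNKNOWN
    return pat, mat, bad


@dataclass
class PhasedMeiosis:
    """One parent -> offspring transmission, phased and origin-labeled.

    ``transmitted`` is the allele the offspring received from this
    parent; ``parent_pat`` / ``parent_mat`` are the parent's own
    grand-paternal / grand-maternal haplotypes.  All are per-SNP arrays
    with -1 for unknown.
    """

    meiosis_id: str
    offspring: str
    parent: str
    parent_sex: str  # "M" = paternal meiosis, "F" = maternal
    transmitted: np.ndarray
    parent_pat: np.ndarray
    parent_mat: np.ndarray

    def __post_init__(self) -> None:
        n = self.transmitted.size
        if self.parent_pat.size != n or self.parent_mat.size != n:
            raise ValueError("per-SNP arrays must have equal length")

    @property
    def n_snps(self) -> int:
        return self.transmitted.size


@dataclass
class FamilyPhasing:
    """Phasing result for one three-generation family."""

    paternal: PhasedMeiosis
    maternal: PhasedMeiosis
    mendel_rate: float  # inconsistent sites / observed sites, offspring trio
    flagged: bool


def phase_family(
    family: TrioFamily,
    genotypes: GenotypeTable,
    mendel_flag_rate: float = 0.02,
) -> FamilyPhasing:
    """Phase one family into its paternal and maternal meioses.

    Applies the trio rule to the offspring, then phases each parent
    against its grandparents to label the parental haplotypes by grand
    parental origin.  Families whose offspring-trio Mendelian
    inconsistency rate exceeds ``mendel_flag_rate`` are flagged for
    exclusion (genotyping error or pedigree error suspects), not fixed.
    """
    off = genotypes.row(family.offspring)
    sire = genotypes.row(family.sire)
    dam = genotypes.row(family.dam)
    t_pat, t_mat, bad = phase_offspring(off, sire, dam)

    observed = (off != MISSING) & (sire != MISSING) & (dam != MISSING)
    n_obs = int(observed.sum())
    mendel_rate = float(bad.sum()) / n_obs if n_obs else 0.0

    def parent_phase(parent_id: str, gs_id: str, gd_id: str | None):
        pg = genotypes.row(parent_id)
        gsg = genotypes.row(gs_id)
        gdg = genotypes.row(gd_id) if gd_id is not None and genotypes.has_animal(gd_id) else None
        return phase_parent(pg, gsg, gdg)

    s_pat, s_mat, _ = parent_phase(family.sire, family.paternal_grandsire, family.paternal_granddam)
    d_pat, d_mat, _ = parent_phase(family.dam, family.maternal_grandsire, family.maternal_granddam)

    paternal = PhasedMeiosis(
        meiosis_id=f"{family.offspring}|{family.sire}",
        offspring=family.offspring,
        parent=family.sire,
        parent_sex="M",
        transmitted=t_pat,
        parent_pat=s_pat,
        parent_mat=s_mat,
    )
    maternal = PhasedMeiosis(
        meiosis_id=f"{family.offspring}|{family.dam}",
        offspring=family.offspring,
        parent=family.dam,
        parent_sex="F",
        transmitted=t_mat,
        parent_pat=d_pat,
        parent_mat=d_mat,
    )
    return FamilyPhasing(
        paternal=paternal,
        maternal=maternal,
        mendel_rate=mendel_rate,
        flagged=mendel_rate > mendel_flag_rate,
    )
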