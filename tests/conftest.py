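"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from recpipe.crossover import build_callset
from recpipe.pedio import extract_families
from recpipe.phasing import phase_family
from recpipe.simdata import SimConfig, simulate_pedigree


@pytest.fixture(scope="session")
def small_sim():
    """Error-free 2-chromosome pedigree: 40 families, 1,200 SNPs."""
    cfg = SimConfig.small(n_chromosomes=2, n_snps=1200, seed=7)
    pedigree, genotypes, truth = simulate_pedigree(cfg, 40)
    return cfg, pedigree, genotypes, truth


@pytest.fixture(scope="session")
def small_callset(small_sim):
    """Phased meioses and crossover calls for the small pedigree."""
    _, pedigree, genotypes, truth = small_sim
    families = extract_families(pedigree, genotypes.animal_ids)
    meioses = []
    for fam in families:
        ph = phase_family(fam, genotypes)
        meioses.extend([ph.paternal, ph.maternal])
    callset = build_callset(meioses, genotypes)
    return meioses, callset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
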