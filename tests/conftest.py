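"""Shared fixtures: small calibrated profiles and planted genomes.

Everything is generated programmatically and deterministically; session
scope keeps the numba-compiled kernels and Gumbel calibrations warm across
test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from riboscan import genomes, profiles, search, synthetic


@pytest.fixture(scope="session")
def small_families():
    """Five synthetic families with consensus proteins and calibrated PSSMs."""
    fams = []
    for i in range(5):
        aln, consensus = synthetic.make_family(
            100 + i, n_members=8, length=110, divergence=0.25
        )
        pssm = profiles.build_pssm(aln)
        profiles.calibrate(pssm, decoy_count=300, decoy_length=150, seed=11)
        fams.append((aln, consensus, pssm))
    return fams


@pytest.fixture(scope="session")
def seed_sets(small_families):
    return {aln.family_id: aln.sequences for aln, _, _ in small_families}


@pytest.fixture(scope="session")
def reverse_validator(seed_sets):
    return search.ReverseValidator(seed_sets, decoy_count=300, seed=5)


@pytest.fixture(scope="session")
def planted(small_families):
    """A 60 kb two-replicon genome with one copy of each family planted."""
    fams = [
        (aln.family_id, consensus, 1, 0.15)
        for aln, consensus, _ in small_families
    ]
    genome, truth = synthetic.plant_genome(
        7, fams, genome_length=60_000, n_replicons=2
    )
    orfs = genomes.extract_orfs(genome)
    return genome, truth, orfs
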