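"""Shared fixtures: a small seeded world with simulated Hi-C at the depths
the analyses need, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import archcompare as ac
from archcompare import matrix

WORLD_SEED = 1
DEPTH_PER_MB = 84_000  # contacts per Mb of genome, matching deep Hi-C coverage


def sim_depth(world, species):
    return int(DEPTH_PER_MB * sum(world.genomes[species].values()) / 1e6)


@pytest.fixture(scope="session")
def small_world():
    """3 species, 2-3 chromosomes of 6-14 Mb, conserved_fraction 0.8."""
    return ac.make_world(
        n_species=3,
        seed=WORLD_SEED,
        chrom_count_range=(2, 3),
        chrom_len_range=(6_000_000, 14_000_000),
    )


@pytest.fixture(scope="session")
def hic20(small_world):
    """Balanced 20-kb matrix for sp1 at deep coverage."""
    m = ac.simulate_hic(
        small_world, "sp1", 20_000, sim_depth(small_world, "sp1"), seed=3
    )
    return matrix.iterative_correction(m)


@pytest.fixture(scope="session")
def hic100(hic20):
    return matrix.iterative_correction(matrix.coarsen(hic20, 5))


@pytest.fixture(scope="session")
def tracks(small_world):
    return ac.simulate_tracks(small_world, "sp1", seed=5)


def call_species_tads(world, species, seed):
    """Simulate, cis-balance, and call TADs for one species."""
    from archcompare import tads

    m = matrix.iterative_correction(
        ac.simulate_hic(world, species, 20_000, sim_depth(world, species), seed=seed),
        scope="cis",
    )
    di = tads.directionality_index(m, window=400_000)
    return tads.call_tads(di, seed=0, min_run=2)


@pytest.fixture(scope="session")
def called_tads(small_world):
    return call_species_tads(small_world, "sp1", seed=3)


@pytest.fixture(scope="session")
def all_called_tads(small_world, called_tads):
    """Called TADs for every species of the small world."""
    out = {"sp1": called_tads}
    for k, spn in enumerate(small_world.species[1:], start=1):
        out[spn] = call_species_tads(small_world, spn, seed=3 + k)
    return out


def boundary_recovery(world, species, tadset, tol=20_000):
    """Fraction of planted boundaries with a called boundary within tol."""
    planted = [(c, (s + e) // 2) for c, s, e in world.boundaries_of(species)]
    called: dict[str, list[int]] = {}
    for c, s, e in tadset.boundaries:
        called.setdefault(c, []).append((s + e) // 2)
    hits = sum(
        1
        for c, mid in planted
        if called.get(c) and min(abs(np.array(called[c]) - mid)) <= tol
    )
    return hits, len(planted)
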