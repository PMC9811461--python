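"""Shared fixtures: registry, tiny hand-built configurations, random systems."""

from __future__ import annotations

import numpy as np
import pytest

from hifcolloids.system import BoxSpec, SystemConfiguration, concat_molecules
from hifcolloids.topology import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def single_bead_config(positions, box_length, species=None):
    """One single-bead molecule per position (defaults to fatty-acid heads)."""
    positions = np.asarray(positions, dtype=float)
    species = species or ["W"] * len(positions)
    parts = [(p[None, :], sp, None) for p, sp in zip(positions, species)]
    return concat_molecules(BoxSpec(box_length), parts)


def molecules_config(mol_positions, box_length, species):
    """Multi-bead molecules from a list of (n_i, 3) arrays."""
    parts = [(np.asarray(p, dtype=float), sp, None) for p, sp in zip(mol_positions, species)]
    return concat_molecules(BoxSpec(box_length), parts)


def random_config(rng, n_molecules=30, box_length=6.0, max_beads=4, species_pool=("FA", "TC", "MAG")):
    """Random small system for oracle-equivalence tests.

    Molecules are compact random chains, so brute-force oracles stay cheap.
    """
    parts = []
    for _ in range(n_molecules):
        sp = species_pool[rng.integers(len(species_pool))]
        from hifcolloids.topology import get_topology, default_registry

        n = get_topology(default_registry(), sp).n_beads
        center = rng.uniform(0, box_length, size=3)
        offsets = np.cumsum(rng.normal(scale=0.3, size=(n, 3)), axis=0)
        parts.append((center + offsets - offsets.mean(axis=0), sp, None))
    return concat_molecules(BoxSpec(box_length), parts)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
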