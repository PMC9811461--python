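"""Manual digestion and absorption transformations.

Digestion replaces glycerides in place, reusing bead positions so the total
bead count is exactly conserved: every TAG becomes one DAG plus one free
fatty acid, and every DAG becomes two free fatty acids (complete
digestion; the biorelevant DAG -> MAG + FA route has no consistent
bead-role mapping here).  Absorption removes free fatty acids from a colloid in
small batches — five at a time by default — until 60% of them are gone,
mirroring the intra-individual drop of fatty-acid concentration over the
fed state.  The relaxation dynamics between batches are out of scope; the
operator emits a configuration snapshot after each batch for external use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .system import SystemConfiguration, concat_molecules
from .topology import SpeciesRegistry, check_digestion_conservation, default_registry, get_topology

#: default absorption parameters
DEFAULT_BATCH_SIZE = 5
DEFAULT_REMOVED_FRACTION = 0.6


@dataclass(frozen=True)
class RemodelingPlan:
    """Parameters of the stepwise fatty-acid absorption operator."""

    batch_size: int = DEFAULT_BATCH_SIZE
    target_removed_fraction: float = DEFAULT_REMOVED_FRACTION

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.target_removed_fraction <= 1.0:
            raise ValueError("target_removed_fraction must be in [0, 1]")


class ConservationError(RuntimeError):
    """Registry violates the digestion bead-conservation identities."""


def _require_conservation(registry: SpeciesRegistry) -> None:
    ok, violations = check_digestion_conservation(registry)
    if not ok:
        raise ConservationError("; ".join(violations))


def _rebuild(
    config: SystemConfiguration,
    molecules: list[tuple[np.ndarray, str]],
    registry: SpeciesRegistry,
) -> SystemConfiguration:
    parts = []
    for pos, sp in molecules:
        labels = [b.label for b in get_topology(registry, sp).beads]
        parts.append((pos, sp, labels))
    out = concat_molecules(config.box, parts, frame_id=config.frame_id)
    return out


def digest_tags(
    config: SystemConfiguration, registry: SpeciesRegistry | None = None
) -> SystemConfiguration:
    """Replace every TAG with one DAG and one free fatty acid, in place.

    The TAG's bead positions are reused: its first ``n_beads(DAG)`` beads
    become the DAG, the remainder the fatty acid.  Total bead count is
    unchanged; the molecule count grows by the number of TAGs.
    """
    registry = registry or default_registry()
    _require_conservation(registry)
    n_dag = get_topology(registry, "DAG").n_beads
    molecules: list[tuple[np.ndarray, str]] = []
    for m, sp in enumerate(config.species):
        pos = config.mol_positions(m)
        if get_topology(registry, sp).molecule_class == "TAG":
            molecules.append((pos[:n_dag], "DAG"))
            molecules.append((pos[n_dag:], "FA"))
        else:
            molecules.append((pos, sp))
    return _rebuild(config, molecules, registry)


def digest_dags(
    config: SystemConfiguration, registry: SpeciesRegistry | None = None
) -> SystemConfiguration:
    """Replace every DAG with two free fatty acids, reusing its bead positions."""
    registry = registry or default_registry()
    _require_conservation(registry)
    n_fa = get_topology(registry, "FA").n_beads
    molecules: list[tuple[np.ndarray, str]] = []
    for m, sp in enumerate(config.species):
        pos = config.mol_positions(m)
        if get_topology(registry, sp).molecule_class == "DAG":
            molecules.append((pos[:n_fa], "FA"))
            molecules.append((pos[n_fa:], "FA"))
        else:
            molecules.append((pos, sp))
    return _rebuild(config, molecules, registry)


def absorb_fatty_acids(
    config: SystemConfiguration,
    cluster: frozenset[int] | set[int],
    plan: RemodelingPlan | None = None,
    seed: int = 0,
    registry: SpeciesRegistry | None = None,
) -> tuple[list[SystemConfiguration], float]:
    """Stepwise removal of a colloid's free fatty acids.

    Removes ``round(target_removed_fraction x initial FA count)`` fatty
    acids from the cluster, ``batch_size`` at a time (uniform random,
    seeded; the last batch may be partial), emitting one configuration
    snapshot after each batch.

    Returns ``(snapshots, removed_percentage)``.
    """
    plan = plan or RemodelingPlan()
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    fa_ids = sorted(
        m
        for m in cluster
        if get_topology(registry, config.species[m]).molecule_class == "fatty_acid"
    )
    if not fa_ids:
        raise ValueError("cluster contains no fatty acids")
    n_initial = len(fa_ids)
    n_remove = int(math.floor(plan.target_removed_fraction * n_initial + 0.5))
    if n_remove > n_initial:
        raise ValueError("removal target exceeds available fatty acids")
    removal_order = rng.permutation(fa_ids)[:n_remove]

    snapshots: list[SystemConfiguration] = []
    removed: set[int] = set()
    for start in range(0, n_remove, plan.batch_size):
        removed.update(removal_order[start : start + plan.batch_size].tolist())
        molecules = [
            (config.mol_positions(m), sp)
            for m, sp in enumerate(config.species)
            if m not in removed
        ]
        snap = _rebuild(config, molecules, registry)
        snapshots.append(snap.with_frame_id(len(snapshots)))
    removed_pct = 100.0 * len(removed) / n_initial
    return snapshots, removed_pct
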