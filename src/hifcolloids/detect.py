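"""Colloid detection: periodic single-linkage clustering of molecules.

Two molecules belong to the same colloid when any bead of one lies within
the criterion distance (default 0.5 nm, inclusive) of any bead of the other,
measured with the minimum-image convention.  Solvent (water, antifreeze) and
ions never participate.  Clusters of a single molecule are monomers.

The neighbor search uses a periodic k-d tree (cell-list equivalent); every
candidate pair is re-measured with the same minimum-image arithmetic the
brute-force oracle uses, so accelerated and brute-force detection agree
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .system import SystemConfiguration, minimum_image
from .topology import SpeciesRegistry, default_registry

DEFAULT_CUTOFF = 0.5


@dataclass
class ColloidPartition:
    """Assignment of non-solvent molecules to colloids or monomer status."""

    clusters: list[frozenset[int]]
    monomers: frozenset[int]
    merge_log: list[tuple[int, ...]] = field(default_factory=list)
    cutoff_nm: float = DEFAULT_CUTOFF

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[int, int]:
        """Molecule id -> cluster index (-1 for monomers)."""
        out = {m: -1 for m in self.monomers}
        for k, cl in enumerate(self.clusters):
            for m in cl:
                out[m] = k
        return out


def molecule_min_distance(
    config: SystemConfiguration, mol_a: int, mol_b: int
) -> float:
    """Minimum over all bead pairs of the minimum-image distance, in nm."""
    if mol_a == mol_b:
        raise ValueError("molecule compared with itself")
    pa = config.mol_positions(mol_a)
    pb = config.mol_positions(mol_b)
    d = minimum_image(pa[:, None, :] - pb[None, :, :], config.box.length)
    return float(np.sqrt((d**2).sum(axis=-1)).min())


def _pair_edges(
    config: SystemConfiguration,
    active_mols: np.ndarray,
    cutoff: float,
) -> set[tuple[int, int]]:
    """Molecule pairs with any bead pair within ``cutoff`` (inclusive)."""
    bead_sel = np.isin(config.mol_index, active_mols)
    idx = np.nonzero(bead_sel)[0]
    if len(idx) < 2:
        return set()
    pos = config.positions[idx]
    L = config.box.length
    tree = cKDTree(pos, boxsize=L)
    # slightly inflated radius, then exact minimum-image re-measurement
    pairs = tree.query_pairs(cutoff * (1 + 1e-9) + 1e-12, output_type="ndarray")
    if len(pairs) == 0:
        return set()
    di = minimum_image(pos[pairs[:, 0]] - pos[pairs[:, 1]], L)
    dist = np.sqrt((di**2).sum(axis=1))
    ok = dist <= cutoff
    ma = config.mol_index[idx[pairs[ok, 0]]]
    mb = config.mol_index[idx[pairs[ok, 1]]]
    edges = set()
    for a, b in zip(ma.tolist(), mb.tolist()):
        if a != b:
            edges.add((a, b) if a < b else (b, a))
    return edges


def detect(
    config: SystemConfiguration,
    cutoff: float = DEFAULT_CUTOFF,
    registry: SpeciesRegistry | None = None,
) -> ColloidPartition:
    """Partition non-solvent molecules into colloids and monomers.

    Single-linkage connected components of the molecule graph whose edges
    are pairs closer than ``cutoff`` (inclusive) under periodic boundaries.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    registry = registry or default_registry()
    solvent = config.solvent_mask(registry)
    active = np.nonzero(~solvent)[0]
    g = nx.Graph()
    g.add_nodes_from(active.tolist())
    g.add_edges_from(_pair_edges(config, active, cutoff))
    clusters: list[frozenset[int]] = []
    monomers: set[int] = set()
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            clusters.append(frozenset(comp))
        else:
            monomers.update(comp)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ColloidPartition(clusters=clusters, monomers=frozenset(monomers), cutoff_nm=cutoff)


def detect_brute_force(
    config: SystemConfiguration,
    cutoff: float = DEFAULT_CUTOFF,
    registry: SpeciesRegistry | None = None,
) -> ColloidPartition:
    """O(n^2) reference implementation of :func:`detect` (oracle for tests)."""
    registry = registry or default_registry()
    solvent = config.solvent_mask(registry)
    active = np.nonzero(~solvent)[0].tolist()
    g = nx.Graph()
    g.add_nodes_from(active)
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            if molecule_min_distance(config, a, b) <= cutoff:
                g.add_edge(a, b)
    clusters = []
    monomers: set[int] = set()
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            clusters.append(frozenset(comp))
        else:
            monomers.update(comp)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ColloidPartition(clusters=clusters, monomers=frozenset(monomers), cutoff_nm=cutoff)


def merge_clusters(
    partition: ColloidPartition, cluster_ids: tuple[int, ...] | list[int]
) -> ColloidPartition:
    """Union the listed clusters into one (manual correction), logging the merge."""
    ids = tuple(cluster_ids)
    if len(ids) < 2 or len(set(ids)) != len(ids):
        raise ValueError("need at least two distinct cluster ids")
    for i in ids:
        if not 0 <= i < len(partition.clusters):
            raise KeyError(f"unknown cluster id {i}")
    merged = frozenset().union(*(partition.clusters[i] for i in ids))
    rest = [c for k, c in enumerate(partition.clusters) if k not in set(ids)]
    clusters = sorted(rest + [merged], key=lambda c: (-len(c), min(c)))
    return ColloidPartition(
        clusters=clusters,
        monomers=partition.monomers,
        merge_log=partition.merge_log + [ids],
        cutoff_nm=partition.cutoff_nm,
    )


def unwrap_cluster(
    config: SystemConfiguration,
    cluster: frozenset[int] | set[int],
    cutoff: float | None = None,
) -> tuple[np.ndarray, list[int]]:
    """A connected periodic image of a cluster's beads.

    Breadth-first traversal of the intra-cluster adjacency graph; each newly
    discovered molecule is shifted by the lattice vector that brings it next
    to its discovered neighbor.  Returns (bead coordinates, molecule order);
    coordinates are no longer confined to the box.

    Raises ``ValueError`` if the cluster is not connected at the cutoff.
    """
    cutoff = cutoff if cutoff is not None else DEFAULT_CUTOFF
    mols = sorted(cluster)
    L = config.box.length

    def whole(mol: int) -> np.ndarray:
        # reconnect a molecule's own beads (it may be wrapped across a face);
        # molecule extent is assumed < L/2
        p = config.mol_positions(mol)
        return p[0] + minimum_image(p - p[0], L)

    if len(mols) == 1:
        return whole(mols[0]), mols
    edges = _pair_edges(config, np.asarray(mols), cutoff)
    g = nx.Graph()
    g.add_nodes_from(mols)
    g.add_edges_from(edges)
    if not nx.is_connected(g):
        raise ValueError("cluster is not connected at the detection cutoff")
    made_whole = {m: whole(m) for m in mols}
    shifts: dict[int, np.ndarray] = {mols[0]: np.zeros(3)}
    for parent, child in nx.bfs_edges(g, mols[0]):
        pa = made_whole[parent] + shifts[parent]
        pb = made_whole[child]
        # bead pair realizing the min-image minimum distance to the parent image
        d = pa[:, None, :] - pb[None, :, :]
        dmi = minimum_image(d, L)
        flat = np.sqrt((dmi**2).sum(axis=-1)).ravel()
        i, j = np.unravel_index(int(flat.argmin()), (len(pa), len(pb)))
        # child image position of bead j closest to parent bead i
        target = pa[i] - dmi[i, j]
        shifts[child] = target - pb[j]
    coords = np.concatenate([made_whole[m] + shifts[m] for m in mols])
    return coords, mols


# ---------------------------------------------------------------------------
# serialization


def partition_to_dict(partition: ColloidPartition) -> dict:
    return {
        "cutoff_nm": partition.cutoff_nm,
        "clusters": [sorted(c) for c in partition.clusters],
        "monomers": sorted(partition.monomers),
        "merge_log": [list(m) for m in partition.merge_log],
    }


def partition_from_dict(data: dict) -> ColloidPartition:
    return ColloidPartition(
        clusters=[frozenset(c) for c in data["clusters"]],
        monomers=frozenset(data["monomers"]),
        merge_log=[tuple(m) for m in data.get("merge_log", [])],
        cutoff_nm=float(data.get("cutoff_nm", DEFAULT_CUTOFF)),
    )
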