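"""Drug solubilization scoring via contact ratios.

The solubilization proxy is the number of contacts between drug (API)
beads and colloid beads divided by the number of contacts between API
beads and water beads, averaged over the final frames of a trajectory
(25 by default).  A high ratio means the drug partitions into the colloid
rather than staying hydrated.  Contacts are bead pairs within a cutoff
(default 0.6 nm, the first CG neighbor shell) under the minimum-image
convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .detect import ColloidPartition
from .stats import KruskalDunnResult, kruskal_dunn
from .system import SystemConfiguration, minimum_image
from .topology import SpeciesRegistry, default_registry, get_topology

log = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 0.6
DEFAULT_LAST_K = 25


@dataclass
class ContactProfile:
    """Per-frame API contact counts and the colloid/water contact ratio."""

    frame_id: int
    contacts_colloid: int
    contacts_water: int
    per_class: dict[str, int]
    cutoff_nm: float

    @property
    def ratio(self) -> float:
        if self.contacts_water <= 0:
            return math.nan
        return self.contacts_colloid / self.contacts_water


@dataclass
class AffinitySummary:
    """Mean contact ratio of one API over the final K analyzed frames."""

    api: str
    mean_ratio: float
    k: int
    profiles: list[ContactProfile]
    per_class_mean: dict[str, float]
    per_class_normalized: dict[str, float] | None = None


def count_contacts(
    config: SystemConfiguration,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> int:
    """Number of bead pairs (a in A, b in B) within ``cutoff`` (inclusive).

    Periodic k-d-tree accelerated; candidate pairs are re-measured with the
    same minimum-image arithmetic as the brute-force oracle.
    """
    group_a = np.asarray(group_a, dtype=np.intp)
    group_b = np.asarray(group_b, dtype=np.intp)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    if not len(group_a) or not len(group_b):
        return 0
    L = config.box.length
    pa = config.positions[group_a]
    pb = config.positions[group_b]
    tree_a = cKDTree(pa, boxsize=L)
    tree_b = cKDTree(pb, boxsize=L)
    neighbors = tree_a.query_ball_tree(tree_b, cutoff * (1 + 1e-9) + 1e-12)
    count = 0
    for i, nbrs in enumerate(neighbors):
        if not nbrs:
            continue
        d = minimum_image(pa[i] - pb[nbrs], L)
        count += int(((d**2).sum(axis=1) <= cutoff**2).sum())
    return count


def count_contacts_brute_force(
    config: SystemConfiguration,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> int:
    """O(n*m) oracle for :func:`count_contacts`."""
    pa = config.positions[np.asarray(group_a, dtype=np.intp)]
    pb = config.positions[np.asarray(group_b, dtype=np.intp)]
    if not len(pa) or not len(pb):
        return 0
    d = minimum_image(pa[:, None, :] - pb[None, :, :], config.box.length)
    return int(((d**2).sum(axis=-1) <= cutoff**2).sum())


def beads_of_molecules(config: SystemConfiguration, mols) -> np.ndarray:
    """Bead indices of the given molecule ids."""
    mols = np.asarray(sorted(mols), dtype=np.intp)
    return np.nonzero(np.isin(config.mol_index, mols))[0]


def api_beads(config: SystemConfiguration, registry: SpeciesRegistry | None = None) -> np.ndarray:
    registry = registry or default_registry()
    mols = [
        m
        for m, sp in enumerate(config.species)
        if get_topology(registry, sp).molecule_class == "api"
    ]
    return beads_of_molecules(config, mols)


def water_beads(config: SystemConfiguration, registry: SpeciesRegistry | None = None) -> np.ndarray:
    registry = registry or default_registry()
    mols = [
        m
        for m, sp in enumerate(config.species)
        if get_topology(registry, sp).molecule_class in ("water", "antifreeze")
    ]
    return beads_of_molecules(config, mols)


def contact_profile(
    config: SystemConfiguration,
    api: np.ndarray,
    colloid: np.ndarray,
    water: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    registry: SpeciesRegistry | None = None,
) -> ContactProfile:
    """Contacts of API beads against colloid and water groups for one frame."""
    registry = registry or default_registry()
    n_colloid = count_contacts(config, api, colloid, cutoff)
    n_water = count_contacts(config, api, water, cutoff)
    per_class = _per_class_counts(config, api, colloid, cutoff, registry)
    return ContactProfile(
        frame_id=config.frame_id,
        contacts_colloid=n_colloid,
        contacts_water=n_water,
        per_class=per_class,
        cutoff_nm=cutoff,
    )


def _per_class_counts(config, api, colloid, cutoff, registry) -> dict[str, int]:
    colloid = np.asarray(colloid, dtype=np.intp)
    classes = {}
    mol_class = [get_topology(registry, sp).molecule_class for sp in config.species]
    for b in colloid:
        classes.setdefault(mol_class[config.mol_index[b]], []).append(b)
    return {
        cls: count_contacts(config, api, np.asarray(beads), cutoff)
        for cls, beads in sorted(classes.items())
    }


def contact_ratio(
    frames: list[SystemConfiguration],
    api: np.ndarray,
    colloid: np.ndarray,
    water: np.ndarray,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    last_k: int = DEFAULT_LAST_K,
    api_name: str = "API",
    registry: SpeciesRegistry | None = None,
) -> AffinitySummary:
    """Mean API-colloid / API-water contact ratio over the final frames.

    The last ``last_k`` frames are analyzed; frames with zero water
    contacts are excluded from the mean with a logged warning.  If every
    frame has zero water contacts the summary mean is ``nan``.
    """
    if len(frames) < last_k:
        raise ValueError(f"need at least {last_k} frames, got {len(frames)}")
    registry = registry or default_registry()
    profiles = [
        contact_profile(f, api, colloid, water, cutoff, registry)
        for f in frames[-last_k:]
    ]
    ratios = [p.ratio for p in profiles if not math.isnan(p.ratio)]
    n_dropped = last_k - len(ratios)
    if n_dropped:
        log.warning("%d of %d frames had zero API-water contacts; excluded", n_dropped, last_k)
    mean_ratio = float(np.mean(ratios)) if ratios else math.nan
    per_class_mean = {}
    for p in profiles:
        for cls, n in p.per_class.items():
            per_class_mean.setdefault(cls, []).append(n)
    per_class_mean = {cls: float(np.mean(v)) for cls, v in per_class_mean.items()}
    return AffinitySummary(
        api=api_name,
        mean_ratio=mean_ratio,
        k=last_k,
        profiles=profiles,
        per_class_mean=per_class_mean,
    )


def per_species_breakdown(
    config: SystemConfiguration,
    api: np.ndarray,
    partition: ColloidPartition,
    cluster_id: int = 0,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    registry: SpeciesRegistry | None = None,
) -> tuple[dict[str, int], dict[str, float]]:
    """API contacts split by colloid molecule class, raw and normalized.

    The normalized value is the class's share of API contacts divided by
    its share of the colloid's molecules, so 1 means the drug touches the
    class exactly in proportion to its abundance; above 1 means enrichment
    (for classes with contacts, ``nan`` for contactless checks against an
    absent class never arises since only present classes are reported).
    """
    registry = registry or default_registry()
    # drug molecules may be assigned to the cluster by detection, but they
    # never count as colloid material
    cluster = [
        m
        for m in partition.clusters[cluster_id]
        if get_topology(registry, config.species[m]).molecule_class != "api"
    ]
    raw = _per_class_counts(
        config, api, beads_of_molecules(config, cluster), cutoff, registry
    )
    total_contacts = sum(raw.values())
    class_counts: dict[str, int] = {}
    for m in cluster:
        cls = get_topology(registry, config.species[m]).molecule_class
        class_counts[cls] = class_counts.get(cls, 0) + 1
    n_mols = sum(class_counts.values())
    normalized = {}
    for cls, n in raw.items():
        contact_share = n / total_contacts if total_contacts else math.nan
        comp_share = class_counts[cls] / n_mols
        normalized[cls] = contact_share / comp_share if comp_share else math.nan
    return raw, normalized


def compare_affinities(
    summaries: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[list[str], KruskalDunnResult]:
    """Rank APIs by mean contact ratio and test group differences.

    ``summaries`` maps API name -> per-replicate mean ratios (>= 3 each).
    Returns the ranking (decreasing mean) and the Kruskal-Wallis/Dunn
    results.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two APIs to compare")
    result = kruskal_dunn(summaries)
    ranking = sorted(summaries, key=lambda k: -float(np.mean(summaries[k])))
    return ranking, result
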