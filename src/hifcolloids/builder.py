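"""Convert mM compositions into bead configurations in a periodic cubic box.

Concentration <-> molecule-count conversion uses the Avogadro factor
6.02214076e-4 molecules per nm^3 per mM, so e.g. 2 mM in a 20 nm box is
10 molecules.  Three starting-configuration modes are supported: a fully
random distribution, the same without glycerides (the fat-droplet
assumption), and an overlay of fed-state molecules onto an existing
(e.g. fasted-state) frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .system import BoxSpec, SystemConfiguration, concat_molecules, wrap
from .topology import SpeciesRegistry, default_registry, get_topology

#: molecules per nm^3 per mM (Avogadro's number x 1e-3 mol/m^3 x 1e-27 m^3/nm^3)
MOLECULES_PER_NM3_PER_MM = 6.02214076e-4

#: default intra-molecule bead bond length, nm (CG sigma-like spacing)
BOND_LENGTH = 0.47

#: effective volume of one CG bead used for occupancy accounting, nm^3
BEAD_VOLUME = 0.1

DEFAULT_BILE_SALT_SPLIT = {"TC": 0.25, "TDC": 0.25, "GC": 0.25, "GDC": 0.25}
DEFAULT_PHOSPHOLIPID_SPLIT = {"PPC": 0.5, "POPC": 0.5}

_CLASS_TO_SPECIES = {
    "fatty_acid": "FA",
    "MAG": "MAG",
    "DAG": "DAG",
    "TAG": "TAG",
    "cholesterol": "CHOL",
    "api": "API",
}


class PackingError(RuntimeError):
    """Requested occupancy exceeds the feasible packing limit."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mm_to_count(concentration_mm: float, box: BoxSpec) -> int:
    """Number of molecules corresponding to ``concentration_mm`` in ``box``."""
    if concentration_mm < 0:
        raise ValueError("concentration must be non-negative")
    return _round_half_up(concentration_mm * MOLECULES_PER_NM3_PER_MM * box.volume)


def count_to_mm(count: int, box: BoxSpec) -> float:
    """Inverse of :func:`mm_to_count` (exact, before rounding)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (MOLECULES_PER_NM3_PER_MM * box.volume)


@dataclass(frozen=True)
class CompositionSpec:
    """Per-class concentrations in mM plus species splits within a class."""

    concentrations: dict[str, float]
    bile_salt_split: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BILE_SALT_SPLIT)
    )
    phospholipid_split: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHOSPHOLIPID_SPLIT)
    )
    include_glycerides: bool = True

    def __post_init__(self) -> None:
        for cls, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {cls}")
        for name, split in (
            ("bile_salt_split", self.bile_salt_split),
            ("phospholipid_split", self.phospholipid_split),
        ):
            if split and abs(sum(split.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions must sum to 1")


def load_presets() -> dict[str, CompositionSpec]:
    """The shipped fed-state composition presets (HV3/6/9/16/20)."""
    text = resources.files("hifcolloids.data").joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: CompositionSpec(concentrations={k: float(v) for k, v in conc.items()})
        for name, conc in raw.items()
    }


def strip_glycerides(composition: CompositionSpec) -> CompositionSpec:
    """Zero the MAG/DAG/TAG concentrations (glyceride-free starting set)."""
    conc = dict(composition.concentrations)
    for cls in ("MAG", "DAG", "TAG"):
        if cls in conc:
            conc[cls] = 0.0
    return replace(composition, concentrations=conc, include_glycerides=False)


def _largest_remainder(total: int, fractions: dict[str, float]) -> dict[str, int]:
    """Split ``total`` into integer parts proportional to ``fractions``.

    Largest-remainder rounding: class totals are preserved exactly.
    Ties broken by insertion order of ``fractions``.
    """
    names = list(fractions)
    quotas = np.array([fractions[n] * total for n in names])
    base = np.floor(quotas).astype(int)
    remainder = total - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:remainder]:
        base[i] += 1
    return dict(zip(names, base.tolist()))


def species_counts(
    composition: CompositionSpec, box: BoxSpec, registry: SpeciesRegistry | None = None
) -> dict[str, int]:
    """Integer molecule counts per species implied by a composition.

    Per-class totals equal ``mm_to_count`` of the class concentration;
    species within bile salts / phospholipids are split by the composition's
    fractions with largest-remainder rounding.
    """
    counts: dict[str, int] = {}
    for cls, conc in composition.concentrations.items():
        n = mm_to_count(conc, box)
        if n == 0:
            continue
        if cls == "bile_salt":
            counts.update({k: v for k, v in _largest_remainder(n, composition.bile_salt_split).items() if v})
        elif cls == "phospholipid":
            counts.update({k: v for k, v in _largest_remainder(n, composition.phospholipid_split).items() if v})
        elif cls in _CLASS_TO_SPECIES:
            counts[_CLASS_TO_SPECIES[cls]] = n
        else:
            raise ValueError(f"unknown composition class {cls!r}")
    return counts


def _random_chain(n_beads: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding bead chain around the origin, bond length 0.47 nm."""
    pos = np.zeros((n_beads, 3))
    for i in range(1, n_beads):
        for _ in range(30):
            step = rng.normal(size=3)
            step *= BOND_LENGTH / np.linalg.norm(step)
            cand = pos[i - 1] + step
            d = np.linalg.norm(pos[:i] - cand, axis=1)
            if d.min() > 0.3 * BOND_LENGTH + 1e-12:
                break
        pos[i] = cand
    return pos - pos.mean(axis=0)


def _place_molecules(
    counts: dict[str, int],
    box: BoxSpec,
    registry: SpeciesRegistry,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, str, list[str]]]:
    parts: list[tuple[np.ndarray, str, list[str]]] = []
    for sp in sorted(counts):
        topo = get_topology(registry, sp)
        labels = [b.label for b in topo.beads]
        for _ in range(counts[sp]):
            center = rng.uniform(0.0, box.length, size=3)
            chain = _random_chain(topo.n_beads, rng)
            parts.append((chain + center, sp, labels))
    return parts


def build_random(
    composition: CompositionSpec,
    box: BoxSpec,
    seed: int,
    registry: SpeciesRegistry | None = None,
    water_density: float = 8.0,
    occupancy_limit: float = 0.7,
) -> SystemConfiguration:
    """Random starting configuration for a composition.

    Molecules are placed with uniform random centers and orientations (each
    molecule a compact self-avoiding chain); the remaining volume is filled
    with water beads at ``water_density`` beads/nm^3 net of solute volume.
    Deterministic for a fixed seed.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    counts = species_counts(composition, box, registry)
    n_solute_beads = sum(get_topology(registry, s).n_beads * n for s, n in counts.items())
    solute_volume = n_solute_beads * BEAD_VOLUME
    if solute_volume > occupancy_limit * box.volume:
        raise PackingError(
            f"solute occupancy {solute_volume / box.volume:.2f} exceeds "
            f"limit {occupancy_limit}"
        )
    parts = _place_molecules(counts, box, registry, rng)
    n_water = max(0, _round_half_up(water_density * (box.volume - solute_volume)))
    water_pos = rng.uniform(0.0, box.length, size=(n_water, 3))
    for p in water_pos:
        parts.append((p[None, :], "W", ["W"]))
    return concat_molecules(box, parts)


def overlay(
    base: SystemConfiguration,
    composition: CompositionSpec,
    seed: int,
    registry: SpeciesRegistry | None = None,
    clearance: float = 0.3,
    max_retries: int = 200,
) -> SystemConfiguration:
    """Insert a composition's molecules into an existing frame.

    New molecules are placed at random positions whose beads keep at least
    ``clearance`` nm from every existing non-water bead and every previously
    inserted bead; water beads closer than ``clearance`` to an inserted bead
    are removed (displaced). Existing molecules are never moved.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    L = base.box.length
    counts = species_counts(composition, base.box, registry)

    solvent = base.solvent_mask(registry)
    water_like = np.array(
        [get_topology(registry, s).molecule_class in ("water", "antifreeze") for s in base.species]
    )
    hard_mol = ~water_like  # everything but water blocks insertion
    hard_beads = base.positions[np.isin(base.mol_index, np.nonzero(hard_mol)[0])]
    tree = cKDTree(hard_beads, boxsize=L) if len(hard_beads) else None

    new_parts: list[tuple[np.ndarray, str, list[str]]] = []
    inserted: list[np.ndarray] = []
    for sp in sorted(counts):
        topo = get_topology(registry, sp)
        labels = [b.label for b in topo.beads]
        for _ in range(counts[sp]):
            for attempt in range(max_retries):
                center = rng.uniform(0.0, L, size=3)
                chain = wrap(_random_chain(topo.n_beads, rng) + center, L)
                ok = True
                if tree is not None and tree.query(chain, k=1)[0].min() < clearance:
                    ok = False
                if ok and inserted:
                    itree = cKDTree(np.concatenate(inserted), boxsize=L)
                    if itree.query(chain, k=1)[0].min() < clearance:
                        ok = False
                if ok:
                    new_parts.append((chain, sp, labels))
                    inserted.append(chain)
                    break
            else:
                raise PackingError(
                    f"could not insert {sp} after {max_retries} attempts"
                )

    # displace water beads overlapping insertions
    keep = np.ones(base.n_molecules, dtype=bool)
    if inserted:
        new_tree = cKDTree(np.concatenate(inserted), boxsize=L)
        for m in np.nonzero(water_like)[0]:
            d, _ = new_tree.query(base.mol_positions(m), k=1)
            if d.min() < clearance:
                keep[m] = False

    parts: list[tuple[np.ndarray, str, list[str]]] = []
    for m in np.nonzero(keep)[0]:
        sp = base.species[m]
        topo = get_topology(registry, sp)
        parts.append((base.mol_positions(m), sp, [b.label for b in topo.beads]))
    parts.extend(new_parts)
    return concat_molecules(base.box, parts)


def substitute_antifreeze(
    config: SystemConfiguration, fraction: float, seed: int
) -> SystemConfiguration:
    """Relabel a uniformly chosen fraction of water beads as antifreeze.

    ``round(fraction * n_water)`` water molecules become species ``WF``;
    positions are unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    water_ids = [i for i, s in enumerate(config.species) if s == "W"]
    n_sub = _round_half_up(fraction * len(water_ids))
    chosen = set(rng.choice(water_ids, size=n_sub, replace=False).tolist()) if n_sub else set()
    out = config.copy()
    for i in chosen:
        out.species[i] = "WF"
        if out.bead_labels is not None:
            out.bead_labels[out.beads_of(i)] = "WF"
    return out
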