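"""Coarse-grained species registry.

Every molecule class that appears in the fed-state intestinal-fluid model
(bile salts, phospholipids, free fatty acids, glycerides, cholesterol,
solvent, ions and drug placeholders) is described by an ordered bead layout.
Only bead counts and roles matter downstream — the registry carries no
force-field parameters, it is pure composition bookkeeping.

The digestion transformations (TAG -> DAG + FA, DAG -> 2 FA) are only
well defined when bead counts are conserved; :func:`check_digestion_conservation`
verifies both identities for a registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

BEAD_ROLES = frozenset({"head", "tail", "linker", "solvent"})

MOLECULE_CLASSES = frozenset(
    {
        "bile_salt",
        "phospholipid",
        "fatty_acid",
        "MAG",
        "DAG",
        "TAG",
        "cholesterol",
        "water",
        "antifreeze",
        "ion",
        "api",
    }
)

#: Classes treated as solvent/ions, excluded from colloid detection.
SOLVENT_CLASSES = frozenset({"water", "antifreeze", "ion"})

#: Glyceride classes, in digestion order.
GLYCERIDE_CLASSES = ("MAG", "DAG", "TAG")

_REQUIRED_SPECIES = (
    "TC",
    "TDC",
    "GC",
    "GDC",
    "PPC",
    "POPC",
    "FA",
    "MAG",
    "DAG",
    "TAG",
    "CHOL",
    "W",
    "WF",
    "API",
)


class UnknownSpeciesError(KeyError):
    """Raised when a species name is not present in the registry."""


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: a label (Martini-style bead-type string) and a role."""

    label: str
    role: str
    mass: float = 1.0

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("bead label must be non-empty")
        if self.role not in BEAD_ROLES:
            raise ValueError(f"bead role {self.role!r} not in {sorted(BEAD_ROLES)}")
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")


@dataclass(frozen=True)
class MoleculeTopology:
    """Ordered bead layout of one species.

    ``n_tails`` counts hydrophobic tails; each glyceride tail contributes
    exactly four tail-role beads (16-18 carbon chains at Martini resolution).
    """

    species: str
    molecule_class: str
    beads: tuple[BeadSpec, ...]
    n_tails: int = 0

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(
                f"molecule class {self.molecule_class!r} not in {sorted(MOLECULE_CLASSES)}"
            )
        if not self.beads:
            raise ValueError("bead list must be non-empty")
        if self.molecule_class in GLYCERIDE_CLASSES:
            n_tail_beads = sum(1 for b in self.beads if b.role == "tail")
            if n_tail_beads != 4 * self.n_tails:
                raise ValueError(
                    f"{self.species}: glyceride with {self.n_tails} tails must have "
                    f"{4 * self.n_tails} tail beads, found {n_tail_beads}"
                )

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(b.mass for b in self.beads)


@dataclass
class SpeciesRegistry:
    """Mapping of species name -> :class:`MoleculeTopology`."""

    entries: dict[str, MoleculeTopology] = field(default_factory=dict)

    def add(self, topology: MoleculeTopology) -> None:
        self.entries[topology.species] = topology

    def __contains__(self, species: str) -> bool:
        return species in self.entries

    def species_of_class(self, molecule_class: str) -> list[str]:
        return [s for s, t in self.entries.items() if t.molecule_class == molecule_class]

    def validate(self) -> None:
        missing = [s for s in _REQUIRED_SPECIES if s not in self.entries]
        if missing:
            raise ValueError(f"registry is missing required species: {missing}")


def get_topology(registry: SpeciesRegistry, species: str) -> MoleculeTopology:
    """Look up the immutable topology record for ``species``.

    Raises :class:`UnknownSpeciesError` naming the species if absent.
    """
    try:
        return registry.entries[species]
    except KeyError:
        raise UnknownSpeciesError(
            f"species {species!r} is not registered "
            f"(known: {sorted(registry.entries)})"
        ) from None


def bead_count(registry: SpeciesRegistry, species: str) -> int:
    return get_topology(registry, species).n_beads


def check_digestion_conservation(
    registry: SpeciesRegistry,
) -> tuple[bool, list[str]]:
    """Check the bead-conservation identities behind manual digestion.

    TAG -> DAG + FA requires  n(TAG) = n(DAG) + n(FA);
    DAG -> 2 FA       requires n(DAG) = 2 n(FA).

    Returns ``(ok, violations)`` where ``violations`` lists the failed
    identities as human-readable strings (empty when ok).
    """
    n_tag = bead_count(registry, "TAG")
    n_dag = bead_count(registry, "DAG")
    n_fa = bead_count(registry, "FA")
    violations: list[str] = []
    if n_tag != n_dag + n_fa:
        violations.append(
            f"bead_count(TAG)={n_tag} != bead_count(DAG)+bead_count(FA)={n_dag + n_fa}"
        )
    if n_dag != 2 * n_fa:
        violations.append(f"bead_count(DAG)={n_dag} != 2*bead_count(FA)={2 * n_fa}")
    return (not violations, violations)


# ---------------------------------------------------------------------------
# serialization


def registry_to_dict(registry: SpeciesRegistry) -> dict:
    out: dict = {}
    for species, topo in registry.entries.items():
        out[species] = {
            "class": topo.molecule_class,
            "n_tails": topo.n_tails,
            "beads": [
                {"label": b.label, "role": b.role, "mass": b.mass} for b in topo.beads
            ],
        }
    return out


def registry_from_dict(data: Mapping) -> SpeciesRegistry:
    reg = SpeciesRegistry()
    for species, entry in data.items():
        beads = tuple(
            BeadSpec(b["label"], b["role"], float(b.get("mass", 1.0)))
            for b in entry["beads"]
        )
        reg.add(
            MoleculeTopology(
                species=str(species),
                molecule_class=entry["class"],
                beads=beads,
                n_tails=int(entry.get("n_tails", 0)),
            )
        )
    return reg


def save_registry(registry: SpeciesRegistry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(registry_to_dict(registry), fh, sort_keys=True)


def load_registry(path) -> SpeciesRegistry:
    with open(path) as fh:
        return registry_from_dict(yaml.safe_load(fh))


def default_registry() -> SpeciesRegistry:
    """The shipped default registry (see ``data/registry.yaml``)."""
    text = resources.files("hifcolloids.data").joinpath("registry.yaml").read_text()
    reg = registry_from_dict(yaml.safe_load(text))
    reg.validate()
    return reg


def residue_name_map(registry: SpeciesRegistry) -> dict[str, str]:
    """Residue-name -> species map used when reading structure files.

    Identity by default: species names double as residue names (all are
    <= 4 characters, fitting GRO/PDB residue columns).
    """
    return {s: s for s in registry.entries}
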