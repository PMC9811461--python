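"""The in-memory bead configuration every pipeline stage consumes.

A :class:`SystemConfiguration` is a flat array of bead positions (nm) in a
periodic cubic box, plus molecule/species indexing: beads of one molecule are
stored contiguously, and each molecule has a registered species name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .topology import SOLVENT_CLASSES, SpeciesRegistry, get_topology


@dataclass(frozen=True)
class BoxSpec:
    """Periodic cubic box with edge ``length`` in nm."""

    length: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("box length must be positive")

    @property
    def volume(self) -> float:
        return self.length**3


@dataclass
class SystemConfiguration:
    """All beads of one frame with molecule and species indexing.

    Attributes
    ----------
    box : BoxSpec
        The periodic cubic box.
    positions : (n_beads, 3) float array
        Coordinates in nm, wrapped into [0, L).
    mol_index : (n_beads,) int array
        Owning molecule id per bead; beads of a molecule are contiguous.
    species : list of str, length n_molecules
        Registered species name per molecule.
    bead_labels : (n_beads,) str array or None
        Optional per-bead names for file output.
    frame_id : int
    """

    box: BoxSpec
    positions: np.ndarray
    mol_index: np.ndarray
    species: list[str]
    bead_labels: np.ndarray | None = None
    frame_id: int = 0
    _mol_start: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.mol_index = np.asarray(self.mol_index, dtype=np.intp)
        if self.positions.shape[0] != self.mol_index.shape[0]:
            raise ValueError("positions and mol_index length mismatch")
        if self.positions.size:
            if self.positions.min() < 0 or self.positions.max() >= self.box.length:
                raise ValueError("bead coordinates must lie in [0, L)")
        if self.mol_index.size:
            # contiguity: mol ids must be non-decreasing and cover 0..M-1
            diffs = np.diff(self.mol_index)
            if (diffs < 0).any() or (diffs > 1).any() or self.mol_index[0] != 0:
                raise ValueError("beads of each molecule must be stored contiguously")
            if self.mol_index[-1] + 1 != len(self.species):
                raise ValueError("species list does not match molecule count")
        elif self.species:
            raise ValueError("species listed but no beads present")

    # -- indexing helpers ---------------------------------------------------

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def mol_start(self) -> np.ndarray:
        """(n_molecules + 1,) bead offsets; molecule m owns [start[m], start[m+1])."""
        if self._mol_start is None:
            counts = np.bincount(self.mol_index, minlength=self.n_molecules)
            self._mol_start = np.concatenate(([0], np.cumsum(counts)))
        return self._mol_start

    def beads_of(self, mol: int) -> slice:
        s = self.mol_start
        return slice(int(s[mol]), int(s[mol + 1]))

    def mol_positions(self, mol: int) -> np.ndarray:
        return self.positions[self.beads_of(mol)]

    def classes(self, registry: SpeciesRegistry) -> np.ndarray:
        """Molecule class per molecule, as an object array of strings."""
        return np.array(
            [get_topology(registry, s).molecule_class for s in self.species],
            dtype=object,
        )

    def solvent_mask(self, registry: SpeciesRegistry) -> np.ndarray:
        """Boolean per-molecule mask of solvent (water/antifreeze/ion) molecules."""
        cls = self.classes(registry)
        return np.isin(cls, list(SOLVENT_CLASSES))

    def species_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.species:
            out[s] = out.get(s, 0) + 1
        return out

    def masses(self, registry: SpeciesRegistry) -> np.ndarray:
        """Per-bead masses from the registry layouts."""
        m = np.empty(self.n_beads)
        start = self.mol_start
        for i, sp in enumerate(self.species):
            m[start[i] : start[i + 1]] = get_topology(registry, sp).masses
        return m

    def copy(self) -> "SystemConfiguration":
        return SystemConfiguration(
            box=self.box,
            positions=self.positions.copy(),
            mol_index=self.mol_index.copy(),
            species=list(self.species),
            bead_labels=None if self.bead_labels is None else self.bead_labels.copy(),
            frame_id=self.frame_id,
        )

    def with_frame_id(self, frame_id: int) -> "SystemConfiguration":
        return replace(self, frame_id=frame_id, _mol_start=self._mol_start)


def wrap(positions: np.ndarray, length: float) -> np.ndarray:
    """Wrap coordinates into [0, L), guarding against the x == L round-off edge."""
    wrapped = np.mod(positions, length)
    wrapped[wrapped >= length] = 0.0
    return wrapped


def minimum_image(d: np.ndarray, length: float) -> np.ndarray:
    """Minimum-image displacement(s) for a cubic box of edge ``length``."""
    return d - length * np.round(d / length)


def concat_molecules(
    box: BoxSpec,
    parts: list[tuple[np.ndarray, str, list[str] | None]],
    frame_id: int = 0,
) -> SystemConfiguration:
    """Assemble a configuration from (bead_positions, species, bead_labels) parts.

    Each part is one molecule. Positions are wrapped into the box.
    """
    if not parts:
        return SystemConfiguration(
            box=box,
            positions=np.empty((0, 3)),
            mol_index=np.empty(0, dtype=np.intp),
            species=[],
            frame_id=frame_id,
        )
    pos = np.concatenate([np.atleast_2d(p[0]) for p in parts])
    mol_index = np.concatenate(
        [np.full(len(np.atleast_2d(p[0])), i, dtype=np.intp) for i, p in enumerate(parts)]
    )
    species = [p[1] for p in parts]
    labels: np.ndarray | None = None
    if all(p[2] is not None for p in parts):
        labels = np.concatenate([np.asarray(p[2], dtype=object) for p in parts])
    return SystemConfiguration(
        box=box,
        positions=wrap(pos, box.length),
        mol_index=mol_index,
        species=species,
        bead_labels=labels,
        frame_id=frame_id,
    )
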