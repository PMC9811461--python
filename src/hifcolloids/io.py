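"""Structure-file readers/writers and the end-to-end pipeline driver.

GRO (nm, fixed columns) and PDB (Angstrom, CRYST1 box) files are read and
written through MDAnalysis; internally all coordinates are nm.  One
molecule maps to one residue, and residue names are species names resolved
through the registry's naming map.  Frame sequences are directories (or
explicit lists) of structure files, ordered by name.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detect import ColloidPartition, partition_from_dict, partition_to_dict
from .system import BoxSpec, SystemConfiguration, wrap
from .topology import (
    SpeciesRegistry,
    default_registry,
    get_topology,
    residue_name_map,
)

log = logging.getLogger(__name__)


class StructureFormatError(ValueError):
    """Malformed or unrecognized structure file."""


def write_structure(
    config: SystemConfiguration,
    path,
    fmt: str | None = None,
    registry: SpeciesRegistry | None = None,
) -> None:
    """Write a configuration as GRO (nm) or PDB (Angstrom, CRYST1 box).

    Atom ordering is deterministic (molecule id, then bead order), so two
    writes of the same configuration are byte-identical.
    """
    import MDAnalysis as mda

    registry = registry or default_registry()
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("gro", "pdb"):
        raise StructureFormatError(f"unsupported format {fmt!r}")

    if config.bead_labels is not None:
        names = [str(x) for x in config.bead_labels]
    else:
        names = []
        for sp in config.species:
            names.extend(b.label for b in get_topology(registry, sp).beads)

    u = mda.Universe.empty(
        config.n_beads,
        n_residues=config.n_molecules,
        atom_resindex=config.mol_index,
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", list(config.species))
    u.add_TopologyAttr("resids", (np.arange(config.n_molecules) % 99999) + 1)
    u.atoms.positions = config.positions * 10.0  # nm -> Angstrom
    u.dimensions = [config.box.length * 10.0] * 3 + [90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_structure(
    path, registry: SpeciesRegistry | None = None, frame_id: int = 0
) -> SystemConfiguration:
    """Read a GRO or PDB file into a configuration (coordinates in nm).

    Residue names are mapped to registered species; an unknown residue
    name is an explicit error.  The box is taken from the file's box
    record and must be cubic.
    """
    import MDAnalysis as mda

    registry = registry or default_registry()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise StructureFormatError(f"could not parse {path}: {exc}") from exc
    if u.dimensions is None:
        raise StructureFormatError(f"{path} carries no box record")
    lx, ly, lz = (float(x) / 10.0 for x in u.dimensions[:3])
    if not (abs(lx - ly) < 1e-3 and abs(lx - lz) < 1e-3):
        raise StructureFormatError(f"{path}: box is not cubic ({lx}, {ly}, {lz})")

    name_map = residue_name_map(registry)
    species = []
    for resname in u.residues.resnames:
        if resname not in name_map:
            raise StructureFormatError(
                f"{path}: unknown residue name {resname!r} "
                f"(known: {sorted(name_map)})"
            )
        species.append(name_map[resname])

    box = BoxSpec(length=lx)
    return SystemConfiguration(
        box=box,
        positions=wrap(u.atoms.positions.astype(float) / 10.0, box.length),
        mol_index=u.atoms.resindices.astype(np.intp),
        species=species,
        bead_labels=np.asarray(u.atoms.names, dtype=object),
        frame_id=frame_id,
    )


def read_frames(paths_or_dir, registry: SpeciesRegistry | None = None) -> list[SystemConfiguration]:
    """Read a frame sequence: a directory of structure files or a path list."""
    p = Path(paths_or_dir) if isinstance(paths_or_dir, (str, Path)) else None
    if p is not None and p.is_dir():
        paths = sorted(x for x in p.iterdir() if x.suffix.lower() in (".gro", ".pdb"))
    else:
        paths = [Path(x) for x in paths_or_dir]
    return [read_structure(x, registry, frame_id=i) for i, x in enumerate(paths)]


def save_partition(partition: ColloidPartition, path) -> None:
    with open(path, "w") as fh:
        json.dump(partition_to_dict(partition), fh, indent=1, sort_keys=True)


def load_partition(path) -> ColloidPartition:
    with open(path) as fh:
        return partition_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Parameters of one end-to-end run (build/load -> detect -> metrics)."""

    output_dir: str
    structure: str | None = None  # input file; otherwise build from preset
    preset: str | None = None  # e.g. "HV3"
    box_length: float = 45.0
    build_set: str = "random"  # random | noglyceride
    detection_cutoff: float = 0.5
    contact_cutoff: float = 0.6
    last_k: int = 25
    seed: int = 0
    registry_path: str | None = None
    water_density: float = 8.0
    with_surface: bool = False

    def __post_init__(self) -> None:
        if self.detection_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.box_length <= 0:
            raise ValueError("box length must be positive")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Build or load a configuration, detect colloids, write all reports.

    Emits, under ``cfg.output_dir``: the starting structure (if built),
    the partition (JSON), the per-colloid metrics table (TSV), the monomer
    summary (JSON) and a run log recording every parameter and seed.
    Returns a dict of the in-memory results.
    """
    from . import builder
    from .detect import detect
    from .metrics import reports_to_table, summarize
    from .topology import load_registry

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(cfg.registry_path) if cfg.registry_path else default_registry()

    try:
        if cfg.structure:
            config = read_structure(cfg.structure, registry)
            source = cfg.structure
        else:
            if not cfg.preset:
                raise ValueError("either a structure file or a preset is required")
            comp = builder.load_presets()[cfg.preset]
            if cfg.build_set == "noglyceride":
                comp = builder.strip_glycerides(comp)
            elif cfg.build_set != "random":
                raise ValueError(f"unknown build set {cfg.build_set!r}")
            config = builder.build_random(
                comp,
                BoxSpec(cfg.box_length),
                seed=cfg.seed,
                registry=registry,
                water_density=cfg.water_density,
            )
            source = f"built:{cfg.preset}:{cfg.build_set}"
            write_structure(config, out / "start.gro", registry=registry)
    except Exception as exc:
        raise RuntimeError(f"[stage: input] {exc}") from exc

    try:
        partition = detect(config, cutoff=cfg.detection_cutoff, registry=registry)
        save_partition(partition, out / "partition.json")
    except Exception as exc:
        raise RuntimeError(f"[stage: detect] {exc}") from exc

    try:
        reports, monomers = summarize(
            partition, config, registry=registry, with_surface=cfg.with_surface
        )
        table = reports_to_table(reports)
        table.to_csv(out / "colloids.tsv", sep="\t", index=False)
        with open(out / "monomers.json", "w") as fh:
            json.dump(monomers, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"[stage: metrics] {exc}") from exc

    run_log = {
        "tool": "hifcolloids",
        "version": _version(),
        "source": source,
        "parameters": {
            "box_length_nm": cfg.box_length,
            "detection_cutoff_nm": cfg.detection_cutoff,
            "contact_cutoff_nm": cfg.contact_cutoff,
            "last_k": cfg.last_k,
            "build_set": cfg.build_set,
            "preset": cfg.preset,
            "water_density": cfg.water_density,
        },
        "seed": cfg.seed,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    return {"partition": partition, "reports": reports, "monomers": monomers}


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("hifcolloids")
    except Exception:  # noqa: BLE001
        return "unknown"
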