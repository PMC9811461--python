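"""Per-colloid geometry, composition and morphology classification.

Metrics follow the conventions used for CG intestinal-fluid colloids:

* ``N_agg`` — number of molecules in the colloid,
* ``D_max`` — greatest bead-bead distance within the colloid,
* shape factor — ratio of the largest to the smallest principal moment of
  inertia (1 for a perfect sphere; the less spherical, the larger),
* morphology — vesicle (enclosed aqueous core), elongated micelle
  (shape factor > 2), else oblate or prolate by the inertia-eigenvalue
  pattern,
* bile-salt/phospholipid and bile-salt/fatty-acid count ratios,
* surface coverage per molecule class via a probe-accessibility test.

All geometry is computed on unwrapped (periodically reconnected) cluster
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

from .detect import ColloidPartition, unwrap_cluster
from .system import SystemConfiguration, minimum_image
from .topology import SpeciesRegistry, default_registry, get_topology

import networkx as nx

COLLOID_TYPES = ("prolate", "oblate", "elongated", "vesicle")

#: shape-factor threshold above which a micelle counts as elongated
ELONGATED_THRESHOLD = 2.0

#: CG bead radius used by the surface probe test, nm
BEAD_RADIUS = 0.235


@dataclass
class ColloidReport:
    """One colloid's metrics record."""

    colloid_id: int
    n_agg: int
    d_max: float
    shape_factor: float
    inertia_eigenvalues: tuple[float, float, float]
    colloid_type: str
    composition: dict[str, int]
    bs_pl_ratio: float
    bs_ffa_ratio: float
    surface_coverage: dict[str, float] | None
    has_water_core: bool
    interior_water_count: int = 0


def d_max(coords: np.ndarray) -> float:
    """Greatest pairwise distance between beads (convex-hull accelerated).

    Equals the brute-force O(n^2) maximum exactly: the diameter of a point
    set is attained between hull vertices.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two beads")
    pts = coords
    if len(coords) > 16:
        try:
            pts = coords[ConvexHull(coords).vertices]
        except QhullError:
            pts = coords  # degenerate (flat) cluster: fall back to all points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def d_max_brute_force(coords: np.ndarray) -> float:
    """O(n^2) oracle for :func:`d_max`."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two beads")
    best = 0.0
    for i in range(len(coords) - 1):
        d2 = ((coords[i + 1 :] - coords[i]) ** 2).sum(axis=1)
        best = max(best, float(d2.max()))
    return math.sqrt(best)


def inertia_eigenvalues(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> np.ndarray:
    """Ascending principal moments of inertia about the center of mass."""
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    r = coords - com
    r2 = (r**2).sum(axis=1)
    tensor = np.diag(np.full(3, (masses * r2).sum())) - np.einsum(
        "i,ij,ik->jk", masses, r, r
    )
    eig = np.linalg.eigvalsh(tensor)
    return np.sort(eig)


def shape_factor(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Largest over smallest principal moment of inertia.

    Raises for degenerate (collinear) geometry where the smallest moment
    vanishes.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least three beads")
    eig = inertia_eigenvalues(coords, masses)
    if eig[2] <= 0 or eig[0] / eig[2] < 1e-9:
        raise ValueError("degenerate (collinear) geometry: smallest moment ~ 0")
    return float(eig[2] / eig[0])


def ellipsoid_shape_factor(a: float, b: float, c: float) -> float:
    """Closed-form shape factor of a uniform solid ellipsoid, semi-axes a>=b>=c."""
    a, b, c = sorted((a, b, c), reverse=True)
    return (a**2 + b**2) / (b**2 + c**2)


def classify(
    shape_factor_value: float, inertia_eigs, has_water_core: bool
) -> str:
    """Morphology label with precedence vesicle > elongated > oblate/prolate.

    A colloid with an enclosed aqueous core is a vesicle regardless of shape;
    otherwise a shape factor above 2 marks an elongated micelle; otherwise
    the middle inertia eigenvalue decides the ellipsoid family: a disc
    (oblate) has two large, nearly equal moments (lambda_mid close to
    lambda_min), a rod (prolate) two small, nearly equal ones (lambda_mid
    close to lambda_max).  Ties (spheres) fall to prolate, matching the
    prolate-or-spherical micelle family.
    """
    if has_water_core:
        return "vesicle"
    if shape_factor_value > ELONGATED_THRESHOLD:
        return "elongated"
    lo, mid, hi = np.sort(np.asarray(inertia_eigs, dtype=float))
    return "oblate" if mid / hi < lo / mid else "prolate"


def detect_water_core(
    config: SystemConfiguration,
    cluster: frozenset[int] | set[int],
    registry: SpeciesRegistry | None = None,
    water_cutoff: float = 0.6,
    min_core_size: int = 10,
    cluster_coords: np.ndarray | None = None,
    cutoff: float | None = None,
) -> tuple[bool, int]:
    """Does the cluster enclose an aqueous core?

    Water beads are clustered by periodic single linkage at ``water_cutoff``.
    A component of at least ``min_core_size`` beads counts as an interior
    core when at least 90% of its beads fall inside the convex hull of the
    (unwrapped) cluster.  The bulk phase never satisfies this containment
    test (it surrounds the colloid), whether it forms one connected
    component or fragments at low density.

    Returns ``(has_core, interior water bead count)``.
    """
    registry = registry or default_registry()
    water_mols = np.array(
        [
            i
            for i, s in enumerate(config.species)
            if get_topology(registry, s).molecule_class in ("water", "antifreeze")
        ],
        dtype=np.intp,
    )
    if len(water_mols) == 0:
        return False, 0
    bead_sel = np.isin(config.mol_index, water_mols)
    wpos = config.positions[bead_sel]
    L = config.box.length
    tree = cKDTree(wpos, boxsize=L)
    pairs = tree.query_pairs(water_cutoff * (1 + 1e-9), output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(len(wpos)))
    if len(pairs):
        di = minimum_image(wpos[pairs[:, 0]] - wpos[pairs[:, 1]], L)
        ok = (di**2).sum(axis=1) <= water_cutoff**2
        g.add_edges_from(map(tuple, pairs[ok]))
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if not comps:
        return False, 0

    if cluster_coords is None:
        cluster_coords, _ = unwrap_cluster(config, cluster, cutoff=cutoff)
    try:
        hull = Delaunay(cluster_coords)
    except QhullError:
        return False, 0
    cluster_centroid = cluster_coords.mean(axis=0)

    total_interior = 0
    for comp in comps:
        if len(comp) < min_core_size:
            continue
        idx = np.fromiter(comp, dtype=np.intp)
        # unwrap the component around its first bead, then shift it into the
        # periodic image closest to the cluster centroid
        ref = wpos[idx[0]]
        rel = ref + minimum_image(wpos[idx] - ref, L)
        shift = minimum_image(rel.mean(axis=0) - cluster_centroid, L) - (
            rel.mean(axis=0) - cluster_centroid
        )
        inside = hull.find_simplex(rel + shift) >= 0
        if inside.mean() >= 0.9:
            total_interior += len(comp)
    return total_interior > 0, total_interior


def composition_ratios(
    cluster: frozenset[int] | set[int],
    species: list[str],
    registry: SpeciesRegistry | None = None,
) -> tuple[float, float, dict[str, int]]:
    """Bile-salt/phospholipid and bile-salt/fatty-acid count ratios.

    A zero denominator yields ``nan`` (undefined marker), never an exception.
    Also returns the full per-species composition counts.
    """
    if not cluster:
        raise ValueError("empty cluster")
    registry = registry or default_registry()
    comp: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for m in cluster:
        sp = species[m]
        comp[sp] = comp.get(sp, 0) + 1
        cls = get_topology(registry, sp).molecule_class
        class_counts[cls] = class_counts.get(cls, 0) + 1
    bs = class_counts.get("bile_salt", 0)
    pl = class_counts.get("phospholipid", 0)
    ffa = class_counts.get("fatty_acid", 0)
    bs_pl = bs / pl if pl else math.nan
    bs_ffa = bs / ffa if ffa else math.nan
    return bs_pl, bs_ffa, comp


def surface_coverage(
    config: SystemConfiguration,
    cluster: frozenset[int] | set[int],
    probe_radius: float = 0.26,
    grid_resolution: float = 0.25,
    registry: SpeciesRegistry | None = None,
    cluster_coords: np.ndarray | None = None,
    mol_order: list[int] | None = None,
    cutoff: float | None = None,
) -> dict[str, float]:
    """Fraction of surface beads per molecule class.

    Surface beads are found with a grid-based exterior flood fill: grid
    cells within one bead radius plus one probe radius of any cluster bead
    are blocked; cells reachable from outside the bounding box are exterior;
    beads adjacent to exterior cells are surface beads.  Fractions over
    classes sum to 1.  ``cutoff`` is the detection cutoff the cluster was
    found at (used for unwrapping when coordinates are not supplied).
    """
    registry = registry or default_registry()
    if cluster_coords is None or mol_order is None:
        cluster_coords, mol_order = unwrap_cluster(config, cluster, cutoff=cutoff)
    if len(cluster_coords) < 20:
        raise ValueError("cluster too small for a surface estimate (< 20 beads)")

    reach = BEAD_RADIUS + probe_radius
    lo = cluster_coords.min(axis=0) - (reach + 2 * grid_resolution)
    hi = cluster_coords.max(axis=0) + (reach + 2 * grid_resolution)
    shape = np.maximum(np.ceil((hi - lo) / grid_resolution).astype(int), 3)
    axes = [lo[k] + grid_resolution * (np.arange(shape[k]) + 0.5) for k in range(3)]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(cluster_coords)
    dist, _ = tree.query(centers, k=1)
    blocked = (dist <= reach).reshape(tuple(shape))

    open_cells, n_lab = ndimage.label(~blocked)
    boundary_labels = set()
    for k in range(3):
        face = [slice(None)] * 3
        for edge in (0, -1):
            face[k] = edge
            boundary_labels.update(np.unique(open_cells[tuple(face)]).tolist())
    boundary_labels.discard(0)
    exterior = np.isin(open_cells, list(boundary_labels))

    ext_centers = centers.reshape(*shape, 3)[exterior]
    if len(ext_centers) == 0:
        raise ValueError("no exterior region found; cluster fills the grid")
    ext_tree = cKDTree(ext_centers)
    d_surf = reach + grid_resolution * math.sqrt(3) / 2
    bead_d, _ = ext_tree.query(cluster_coords, k=1)
    is_surface = bead_d <= d_surf

    # map beads back to molecule classes
    classes = []
    for m in mol_order:
        cls = get_topology(registry, config.species[m]).molecule_class
        classes.extend([cls] * (config.beads_of(m).stop - config.beads_of(m).start))
    classes = np.array(classes, dtype=object)
    surf_classes = classes[is_surface]
    n_surf = len(surf_classes)
    if n_surf == 0:
        raise ValueError("no surface beads found (degenerate cluster)")
    out: dict[str, float] = {}
    for cls in np.unique(surf_classes):
        out[str(cls)] = float((surf_classes == cls).sum() / n_surf)
    return out


def summarize(
    partition: ColloidPartition,
    config: SystemConfiguration,
    registry: SpeciesRegistry | None = None,
    masses: np.ndarray | None = None,
    with_surface: bool = True,
) -> tuple[list[ColloidReport], dict[str, int]]:
    """One :class:`ColloidReport` per cluster plus monomer counts by class."""
    registry = registry or default_registry()
    reports: list[ColloidReport] = []
    for k, cluster in enumerate(partition.clusters):
        coords, order = unwrap_cluster(config, cluster, cutoff=partition.cutoff_nm)
        m = None
        if masses is not None:
            sel = np.concatenate([np.arange(config.beads_of(i).start, config.beads_of(i).stop) for i in order])
            m = masses[sel]
        eig = inertia_eigenvalues(coords, m)
        sf = float(eig[2] / eig[0])
        has_core, n_core = detect_water_core(
            config, cluster, registry=registry, cluster_coords=coords
        )
        ctype = classify(sf, eig, has_core)
        bs_pl, bs_ffa, comp = composition_ratios(cluster, config.species, registry)
        cov = None
        if with_surface and len(coords) >= 20:
            cov = surface_coverage(
                config, cluster, registry=registry, cluster_coords=coords, mol_order=order
            )
        reports.append(
            ColloidReport(
                colloid_id=k,
                n_agg=len(cluster),
                d_max=d_max(coords),
                shape_factor=sf,
                inertia_eigenvalues=tuple(float(x) for x in eig),
                colloid_type=ctype,
                composition=comp,
                bs_pl_ratio=bs_pl,
                bs_ffa_ratio=bs_ffa,
                surface_coverage=cov,
                has_water_core=has_core,
                interior_water_count=n_core,
            )
        )
    monomer_counts: dict[str, int] = {}
    for m_id in partition.monomers:
        cls = get_topology(registry, config.species[m_id]).molecule_class
        monomer_counts[cls] = monomer_counts.get(cls, 0) + 1
    return reports, monomer_counts


def reports_to_table(reports: list[ColloidReport]):
    """Flatten reports into a pandas DataFrame (one row per colloid)."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append(
            {
                "colloid_id": r.colloid_id,
                "type": r.colloid_type,
                "n_agg": r.n_agg,
                "d_max_nm": r.d_max,
                "shape_factor": r.shape_factor,
                "bs_pl_ratio": r.bs_pl_ratio,
                "bs_ffa_ratio": r.bs_ffa_ratio,
                "has_water_core": r.has_water_core,
                "interior_water": r.interior_water_count,
                "composition": ";".join(f"{k}:{v}" for k, v in sorted(r.composition.items())),
                "surface_coverage": ""
                if r.surface_coverage is None
                else ";".join(f"{k}:{v:.3f}" for k, v in sorted(r.surface_coverage.items())),
            }
        )
    return pd.DataFrame(rows)
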