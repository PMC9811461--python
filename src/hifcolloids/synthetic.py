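"""Synthetic colloid generator with known ground truth.

Produces bead configurations containing colloids of the four morphologies
seen in fed-state intestinal-fluid models — prolate, oblate and elongated
micelles (uniform ellipsoidal bead clouds) and vesicles (spherical bilayer
shells enclosing an aqueous core) — embedded in bulk water in a periodic
cubic box, together with exact ground-truth membership, composition and
geometry.  These are geometric fixtures, not physically packed structures:
beads sit on jittered lattices with nearest-neighbor spacing below the
0.5 nm clustering criterion, so each generated colloid is one cluster by
construction, and the layered role assignment (glycerides innermost, tails
inward, bile salts and head groups at the surface) mirrors the layering the
morphologies exhibit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .system import BoxSpec, SystemConfiguration, concat_molecules, minimum_image
from .topology import SpeciesRegistry, default_registry, get_topology

#: default lattice spacing of generated colloids, nm (below the 0.5 nm criterion)
DEFAULT_SPACING = 0.45

#: spacing above which a composition cannot form one cluster
MAX_SPACING = 0.497

#: bulk/core water number density, beads per nm^3
WATER_DENSITY = 8.0


class SparseCompositionError(ValueError):
    """Composition has too few beads to tile the requested geometry."""


@dataclass
class GroundTruth:
    """Exact membership, type, geometry and composition of generated colloids."""

    membership: dict[int, int]  # molecule id -> colloid index, -1 for monomers
    intended_type: list[str]
    geometry: list[dict]
    composition: list[dict[str, int]]

    def colloid_members(self, k: int) -> frozenset[int]:
        return frozenset(m for m, c in self.membership.items() if c == k)

    @property
    def monomer_ids(self) -> frozenset[int]:
        return frozenset(m for m, c in self.membership.items() if c == -1)


@dataclass(frozen=True)
class MicelleSpec:
    semi_axes: tuple[float, float, float]
    composition: dict[str, int]
    kind: str = "micelle"

    @property
    def bounding_radius(self) -> float:
        return max(self.semi_axes)


@dataclass(frozen=True)
class VesicleSpec:
    outer_radius: float
    bilayer_thickness: float
    composition: dict[str, int]
    kind: str = "vesicle"

    @property
    def bounding_radius(self) -> float:
        return self.outer_radius


# ---------------------------------------------------------------------------
# lattice site generation


def _ellipsoid_sites(
    semi_axes: tuple[float, float, float], n_beads: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Jittered cubic-lattice points filling an ellipsoid, with depth scores.

    Spacing adapts so the site count matches ``n_beads``; if the implied
    spacing exceeds the clustering criterion the composition is too sparse.
    Returns (points, depth) with depth ascending = interior -> surface.
    """
    a, b, c = semi_axes
    if not (a >= b >= c > 0):
        raise ValueError("semi-axes must satisfy a >= b >= c > 0")
    if n_beads < 4:
        raise SparseCompositionError("need at least 4 beads")
    volume = 4.0 / 3.0 * math.pi * a * b * c
    s = min(DEFAULT_SPACING, 0.98 * (volume / n_beads) ** (1.0 / 3.0))
    if (volume / n_beads) ** (1.0 / 3.0) > MAX_SPACING:
        raise SparseCompositionError(
            f"{n_beads} beads cannot tile an ellipsoid of volume {volume:.1f} nm^3 "
            f"at <= {MAX_SPACING} nm spacing"
        )
    while True:
        grid = [np.arange(-ax, ax + s, s) for ax in (a, b, c)]
        pts = np.stack(np.meshgrid(*grid, indexing="ij"), axis=-1).reshape(-1, 3)
        r_e = np.sqrt(
            (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2
        )
        inside = r_e <= 1.0
        if inside.sum() >= n_beads:
            break
        s *= 0.96
    pts = pts[inside]
    r_e = r_e[inside]
    order = np.argsort(r_e, kind="stable")[:n_beads]
    pts = pts[order] + rng.uniform(-0.06 * s, 0.06 * s, size=(n_beads, 3))
    return pts, r_e[order]


def _shell_sites(
    outer_radius: float,
    thickness: float,
    n_beads: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentric Fibonacci-sphere shells spanning the bilayer region.

    Returns (points, depth) where depth ascends from mid-bilayer (interior)
    to either water-facing surface.
    """
    R, t = outer_radius, thickness
    if not R > t > 0:
        raise ValueError("need outer_radius > bilayer_thickness > 0")
    n_r = max(2, int(math.ceil(t / 0.4)) + 1)
    radii = np.linspace(R - t, R, n_r)
    area = float(4 * math.pi * (radii**2).sum())
    s_ang = math.sqrt(area / n_beads)
    if s_ang > MAX_SPACING:
        raise SparseCompositionError(
            f"{n_beads} beads cannot tile a bilayer shell of area {area:.1f} nm^2 "
            f"at <= {MAX_SPACING} nm spacing"
        )
    quotas = 4 * math.pi * radii**2 / s_ang**2
    counts = np.floor(quotas).astype(int)
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[: n_beads - int(counts.sum())]:
        counts[i] += 1
    mid = R - t / 2.0
    pts_list, depth_list = [], []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for r, n in zip(radii, counts):
        if n <= 0:
            continue
        k = np.arange(n)
        z = 1.0 - 2.0 * (k + 0.5) / n
        rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        phi = golden * k + rng.uniform(0, 2 * math.pi)  # random shell offset
        shell = r * np.stack((rho * np.cos(phi), rho * np.sin(phi), z), axis=1)
        pts_list.append(shell)
        depth_list.append(np.full(n, abs(r - mid)))
    pts = np.concatenate(pts_list)
    depth = np.concatenate(depth_list)
    pts += rng.uniform(-0.03, 0.03, size=pts.shape)
    return pts, depth


# ---------------------------------------------------------------------------
# carving sites into molecules


def _take_nearest(
    tree: cKDTree, pool: np.ndarray, used: np.ndarray, point: np.ndarray, m: int
) -> list[int]:
    """Indices (into the pool) of the m nearest unused sites to ``point``."""
    n = len(pool)
    k = min(n, max(4 * m, 16))
    while True:
        _, idx = tree.query(point, k=k)
        idx = np.atleast_1d(idx)
        free = [int(i) for i in idx if i < n and not used[i]][:m]
        if len(free) == m or k >= n:
            if len(free) < m:
                raise RuntimeError("site pool exhausted")
            return free
        k = min(n, 4 * k)


def _assemble_molecules(
    points: np.ndarray,
    depth: np.ndarray,
    composition: dict[str, int],
    registry: SpeciesRegistry,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, str, list[str]]]:
    """Carve lattice sites into molecules, layering roles by depth.

    Interior sites host glyceride and drug beads, middle sites the
    hydrophobic tails (and cholesterol), and the outermost sites the bile
    salts and the fatty-acid/phospholipid head groups.
    """
    core_classes = {"MAG", "DAG", "TAG", "api"}
    n_core = n_surf = n_tail = 0
    for sp, cnt in composition.items():
        topo = get_topology(registry, sp)
        cls = topo.molecule_class
        if cls in core_classes:
            n_core += cnt * topo.n_beads
        elif cls == "bile_salt":
            n_surf += cnt * topo.n_beads
        elif cls in ("fatty_acid", "phospholipid"):
            heads = sum(1 for b in topo.beads if b.role == "head")
            n_surf += cnt * heads
            n_tail += cnt * (topo.n_beads - heads)
        elif cls == "cholesterol":
            n_tail += cnt * topo.n_beads
        else:
            raise ValueError(f"species {sp} ({cls}) not placeable in a colloid")
    total = n_core + n_tail + n_surf
    if total != len(points):
        raise ValueError("site count does not match composition bead count")

    order = np.argsort(depth, kind="stable")

    def _sweep_order(pool: np.ndarray) -> np.ndarray:
        # spatially coherent consumption order (2 nm slabs), so that the
        # pools deplete locally in sync and molecules stay compact
        if not len(pool):
            return np.empty(0, dtype=np.intp)
        xb = np.floor(pool[:, 0] / 2.0)
        yb = np.floor(pool[:, 1] / 2.0)
        return np.lexsort((pool[:, 2], yb, xb))

    pools: dict[str, dict] = {}
    for name, sel in (
        ("core", order[:n_core]),
        ("tail", order[n_core : n_core + n_tail]),
        ("surf", order[n_core + n_tail :]),
    ):
        pool = points[sel]
        pools[name] = {
            "pos": pool,
            "used": np.zeros(len(pool), dtype=bool),
            "tree": cKDTree(pool) if len(pool) else None,
            "seeds": _sweep_order(pool),
            "ptr": 0,
        }

    _FALLBACK = {
        "core": ("tail", "surf"),
        "tail": ("core", "surf"),
        "surf": ("tail", "core"),
    }

    def grab(pool_name: str, point: np.ndarray, m: int) -> np.ndarray:
        """The m best free sites near ``point``, preferring the designated pool.

        Sites from other pools may be taken at a distance penalty; this
        absorbs local pool-ratio mismatches at the end of the assembly so
        molecules never stretch across the colloid.
        """
        search = [(1.0, pool_name)] + [
            (3.0 * (j + 1), nm) for j, nm in enumerate(_FALLBACK[pool_name])
        ]
        cands: list[tuple[float, str, int]] = []
        for penalty, name in search:
            pool = pools[name]
            if pool["tree"] is None:
                continue
            k = min(len(pool["pos"]), max(4 * m, 16))
            while True:
                d, idx = pool["tree"].query(point, k=k)
                d, idx = np.atleast_1d(d), np.atleast_1d(idx)
                free = [
                    (float(dd) * penalty, name, int(i))
                    for dd, i in zip(d, idx)
                    if i < len(pool["pos"]) and not pool["used"][i]
                ]
                if len(free) >= m or k >= len(pool["pos"]):
                    cands.extend(free[: 2 * m])
                    break
                k = min(len(pool["pos"]), 4 * k)
        cands.sort()
        if len(cands) < m:
            raise RuntimeError("site pools exhausted")
        out = np.empty((m, 3))
        for j, (_, name, i) in enumerate(cands[:m]):
            pools[name]["used"][i] = True
            out[j] = pools[name]["pos"][i]
        return out

    def first_free(pool_name: str) -> np.ndarray:
        for name in (pool_name, *_FALLBACK[pool_name]):
            p = pools[name]
            while p["ptr"] < len(p["seeds"]):
                i = int(p["seeds"][p["ptr"]])
                p["ptr"] += 1
                if not p["used"][i]:
                    p["used"][i] = True
                    return p["pos"][i]
        raise RuntimeError("site pools exhausted")

    parts: list[tuple[np.ndarray, str, list[str]]] = []

    def compact_molecule(sp: str, pool_name: str) -> None:
        topo = get_topology(registry, sp)
        labels = [b.label for b in topo.beads]
        seed = first_free(pool_name)
        rest = grab(pool_name, seed, topo.n_beads - 1) if topo.n_beads > 1 else np.empty((0, 3))
        parts.append((np.vstack([seed[None, :], rest]), sp, labels))

    def amphiphile_molecule(sp: str) -> None:
        # head group(s) at the surface, remaining beads just inside it
        topo = get_topology(registry, sp)
        n_heads = sum(1 for b in topo.beads if b.role == "head")
        labels = [b.label for b in topo.beads]
        head_slots = [i for i, b in enumerate(topo.beads) if b.role == "head"]
        other_slots = [i for i, b in enumerate(topo.beads) if b.role != "head"]
        seed = first_free("surf")
        heads = np.vstack(
            [seed[None, :]] + ([grab("surf", seed, n_heads - 1)] if n_heads > 1 else [])
        )
        tails = grab("tail", seed, topo.n_beads - n_heads)
        pos = np.empty((topo.n_beads, 3))
        pos[head_slots] = heads
        pos[other_slots] = tails
        parts.append((pos, sp, labels))

    # interleave all molecules in one shuffled pass so every surface/tail/core
    # region is consumed by a proportional species mix and molecules stay
    # compact (no species is left with scattered leftover sites)
    mol_list: list[str] = []
    for sp, cnt in sorted(composition.items()):
        mol_list.extend([sp] * cnt)
    rng.shuffle(mol_list)
    for sp in mol_list:
        cls = get_topology(registry, sp).molecule_class
        if cls in core_classes:
            compact_molecule(sp, "core")
        elif cls == "bile_salt":
            compact_molecule(sp, "surf")
        elif cls == "cholesterol":
            compact_molecule(sp, "tail")
        else:
            amphiphile_molecule(sp)
    return parts


# ---------------------------------------------------------------------------
# public constructors


def _water_lattice(
    rng: np.random.Generator, density: float = WATER_DENSITY
) -> float:
    return (1.0 / density) ** (1.0 / 3.0)


def make_micelle(
    semi_axes: tuple[float, float, float],
    composition: dict[str, int],
    seed: int,
    box: BoxSpec | None = None,
    center: np.ndarray | None = None,
    registry: SpeciesRegistry | None = None,
) -> tuple[SystemConfiguration, GroundTruth]:
    """One ellipsoidal micelle with glyceride core and bile-salt-rich surface.

    The bead cloud is a jittered uniform lattice clipped to the ellipsoid,
    so its inertia tensor matches the uniform-ellipsoid closed form and its
    nearest-neighbor spacing stays below the 0.5 nm clustering criterion.
    No bulk water is added (use :func:`make_scene` for embedded colloids).
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    parts, geometry = _micelle_parts(semi_axes, composition, registry, rng)
    a = max(semi_axes)
    box = box or BoxSpec(length=2 * a + 4.0)
    center = np.full(3, box.length / 2.0) if center is None else np.asarray(center)
    parts = [(p + center, sp, lab) for p, sp, lab in parts]
    config = concat_molecules(box, parts)
    truth = GroundTruth(
        membership={m: 0 for m in range(config.n_molecules)},
        intended_type=[_micelle_type(semi_axes)],
        geometry=[geometry],
        composition=[dict(composition)],
    )
    return config, truth


def _micelle_parts(semi_axes, composition, registry, rng):
    n_beads = sum(
        get_topology(registry, sp).n_beads * c for sp, c in composition.items()
    )
    pts, depth = _ellipsoid_sites(tuple(sorted(semi_axes, reverse=True)), n_beads, rng)
    parts = _assemble_molecules(pts, depth, composition, registry, rng)
    geometry = {"semi_axes": tuple(sorted(semi_axes, reverse=True))}
    return parts, geometry


def _micelle_type(semi_axes) -> str:
    from .metrics import classify, ellipsoid_shape_factor

    a, b, c = sorted(semi_axes, reverse=True)
    sf = ellipsoid_shape_factor(a, b, c)
    eigs = (b**2 + c**2, a**2 + c**2, a**2 + b**2)
    return classify(sf, eigs, has_water_core=False)


def make_vesicle(
    outer_radius: float,
    bilayer_thickness: float,
    composition: dict[str, int],
    seed: int,
    box: BoxSpec | None = None,
    center: np.ndarray | None = None,
    registry: SpeciesRegistry | None = None,
    core_water: bool = True,
) -> tuple[SystemConfiguration, GroundTruth]:
    """One spherical vesicle: bilayer shell plus enclosed aqueous core.

    Fatty-acid/phospholipid leaflets with heads at both water-facing
    surfaces, bile salts at both surfaces, glycerides between the leaflets,
    and the interior filled with water beads at bulk density.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    parts, geometry = _vesicle_parts(
        outer_radius, bilayer_thickness, composition, registry, rng, core_water
    )
    box = box or BoxSpec(length=2 * outer_radius + 4.0)
    center = np.full(3, box.length / 2.0) if center is None else np.asarray(center)
    parts = [(p + center, sp, lab) for p, sp, lab in parts]
    config = concat_molecules(box, parts)
    membership = {
        m: (0 if config.species[m] != "W" else -2)
        for m in range(config.n_molecules)
    }
    membership = {m: c for m, c in membership.items() if c != -2}
    truth = GroundTruth(
        membership=membership,
        intended_type=["vesicle"],
        geometry=[geometry],
        composition=[dict(composition)],
    )
    return config, truth


def _vesicle_parts(R, t, composition, registry, rng, core_water=True):
    n_beads = sum(
        get_topology(registry, sp).n_beads * c for sp, c in composition.items()
    )
    pts, depth = _shell_sites(R, t, n_beads, rng)
    parts = _assemble_molecules(pts, depth, composition, registry, rng)
    n_core_water = 0
    if core_water:
        r_core = R - t - 0.35
        if r_core > 0.5:
            s = _water_lattice(rng)
            grid = np.arange(-r_core, r_core + s, s)
            w = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
            w = w[(w**2).sum(axis=1) <= r_core**2]
            w = w + rng.uniform(-0.05, 0.05, size=w.shape)
            for p in w:
                parts.append((p[None, :], "W", ["W"]))
            n_core_water = len(w)
    geometry = {
        "outer_radius": R,
        "bilayer_thickness": t,
        "core_water_beads": n_core_water,
    }
    return parts, geometry


@dataclass
class Scene:
    """Colloids plus free monomers plus bulk water in one periodic box."""

    config: SystemConfiguration
    truth: GroundTruth


def make_scene(
    colloid_specs: list[MicelleSpec | VesicleSpec],
    monomer_counts: dict[str, int],
    box: BoxSpec,
    seed: int,
    registry: SpeciesRegistry | None = None,
    water_density: float = WATER_DENSITY,
    min_gap: float = 2.0,
    monomer_clearance: float = 1.2,
    max_tries: int = 500,
) -> tuple[SystemConfiguration, GroundTruth]:
    """Place colloids at non-overlapping random centers and fill with water.

    Colloid centers may sit near the box faces, so colloids can straddle
    periodic boundaries; surface-to-surface gaps are kept at or above
    ``min_gap`` and monomer beads keep ``monomer_clearance`` from every
    other non-water bead, so detection at 0.5 nm recovers the ground truth
    exactly.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    L = box.length

    # 1. sample colloid centers with min-image separation constraints
    radii = [spec.bounding_radius for spec in colloid_specs]
    if radii and 2 * max(radii) + min_gap > L:
        raise ValueError("box too small for the requested colloids")
    centers: list[np.ndarray] = []
    for k, spec in enumerate(colloid_specs):
        for _ in range(max_tries):
            cand = rng.uniform(0, L, size=3)
            ok = all(
                np.linalg.norm(minimum_image(cand - c, L))
                >= radii[k] + radii[j] + min_gap
                for j, c in enumerate(centers)
            )
            if ok:
                centers.append(cand)
                break
        else:
            raise ValueError("could not place colloids without overlap")

    parts: list[tuple[np.ndarray, str, list[str]]] = []
    membership: dict[int, int] = {}
    intended, geoms, comps = [], [], []
    mol_counter = 0
    for k, (spec, center) in enumerate(zip(colloid_specs, centers)):
        if isinstance(spec, MicelleSpec):
            cparts, geometry = _micelle_parts(spec.semi_axes, spec.composition, registry, rng)
            intended.append(_micelle_type(spec.semi_axes))
        else:
            cparts, geometry = _vesicle_parts(
                spec.outer_radius, spec.bilayer_thickness, spec.composition, registry, rng
            )
            intended.append("vesicle")
        geoms.append(geometry)
        comps.append(dict(spec.composition))
        for p, sp, lab in cparts:
            parts.append((p + center, sp, lab))
            if sp != "W":  # core water is solvent, not a member
                membership[mol_counter] = k
            mol_counter += 1

    # 2. free monomers with clearance from everything non-water
    solute_beads = (
        np.concatenate([np.mod(p, L) for p, sp, _ in parts if sp != "W"])
        if any(sp != "W" for _, sp, _ in parts)
        else np.empty((0, 3))
    )
    from .builder import _random_chain  # compact chain placement

    for sp in sorted(monomer_counts):
        topo = get_topology(registry, sp)
        labels = [b.label for b in topo.beads]
        for _ in range(monomer_counts[sp]):
            for _ in range(max_tries):
                center = rng.uniform(0, L, size=3)
                chain = np.mod(_random_chain(topo.n_beads, rng) + center, L)
                if len(solute_beads):
                    tree = cKDTree(solute_beads, boxsize=L)
                    if tree.query(chain, k=1)[0].min() < monomer_clearance:
                        continue
                parts.append((chain, sp, labels))
                membership[mol_counter] = -1
                mol_counter += 1
                solute_beads = (
                    np.vstack([solute_beads, chain]) if len(solute_beads) else chain
                )
                break
            else:
                raise ValueError(f"could not place monomer {sp}")

    # 3. bulk water lattice avoiding all existing beads
    if water_density > 0:
        s = _water_lattice(rng, water_density)
        grid = np.arange(0, L, s)
        w = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
        w = np.mod(w + rng.uniform(-0.05, 0.05, size=w.shape), L)
        all_beads = np.concatenate([np.mod(p, L) for p, _, _ in parts]) if parts else None
        if all_beads is not None and len(all_beads):
            tree = cKDTree(all_beads, boxsize=L)
            d, _ = tree.query(w, k=1)
            w = w[d > 0.4]
        for p in w:
            parts.append((p[None, :], "W", ["W"]))

    config = concat_molecules(box, parts)
    truth = GroundTruth(
        membership=membership,
        intended_type=intended,
        geometry=geoms,
        composition=comps,
    )
    return config, truth


def locate_elongation_boundary(
    precision: float = 0.01,
    seed: int = 0,
    b_axis: float = 2.0,
    lo: float = 1.3,
    hi: float = 2.4,
    registry: SpeciesRegistry | None = None,
) -> tuple[float, int]:
    """Shape-factor value where the micelle classifier flips to elongated.

    Bisects over the aspect ratio x of core-only prolate micelles with
    semi-axes (x*b, b, b): each candidate micelle is generated, detected,
    unwrapped and classified, and the bracketing measured shape factors are
    narrowed until they differ by less than ``precision``.  Returns the
    bracket midpoint and the number of micelles evaluated.
    """
    from .detect import detect, unwrap_cluster
    from .metrics import classify, inertia_eigenvalues

    registry = registry or default_registry()

    def measure(x: float, i: int) -> tuple[float, str]:
        axes = (x * b_axis, b_axis, b_axis)
        comp = default_micelle_composition(axes, registry)
        cfg, _ = make_micelle(axes, comp, seed=seed + i, registry=registry)
        part = detect(cfg, registry=registry)
        coords, _ = unwrap_cluster(cfg, part.clusters[0])
        eig = inertia_eigenvalues(coords)
        sf = float(eig[2] / eig[0])
        return sf, classify(sf, eig, has_water_core=False)

    n_eval = 0
    sf_lo, label_lo = measure(lo, n_eval)
    n_eval += 1
    sf_hi, label_hi = measure(hi, n_eval)
    n_eval += 1
    if label_lo == "elongated" or label_hi != "elongated":
        raise RuntimeError("bisection bracket does not straddle the boundary")
    while abs(sf_hi - sf_lo) >= precision and n_eval < 64:
        mid = 0.5 * (lo + hi)
        sf_mid, label_mid = measure(mid, n_eval)
        n_eval += 1
        if label_mid == "elongated":
            hi, sf_hi = mid, sf_mid
        else:
            lo, sf_lo = mid, sf_mid
    return 0.5 * (sf_lo + sf_hi), n_eval


# ---------------------------------------------------------------------------
# realistic default compositions


def _beads_to_counts(n_beads: int, registry: SpeciesRegistry, weights: dict[str, float]) -> dict[str, int]:
    """Split a bead budget across species by weight fractions."""
    counts: dict[str, int] = {}
    for sp, w in weights.items():
        nb = get_topology(registry, sp).n_beads
        counts[sp] = max(0, int(round(w * n_beads / nb)))
    return {k: v for k, v in counts.items() if v > 0}


def default_micelle_composition(
    semi_axes: tuple[float, float, float], registry: SpeciesRegistry | None = None
) -> dict[str, int]:
    """Mixed-micelle composition filling the ellipsoid at ~0.45 nm spacing.

    Bead-budget weights: ~25% bile salts, ~30% fatty acids, ~15%
    phospholipids, ~30% glycerides (mostly MAG) — the layering seen in
    glyceride-containing fed-state micelles.
    """
    registry = registry or default_registry()
    a, b, c = semi_axes
    volume = 4.0 / 3.0 * math.pi * a * b * c
    n_beads = int(volume / DEFAULT_SPACING**3)
    weights = {
        "TC": 0.07, "TDC": 0.06, "GC": 0.06, "GDC": 0.06,
        "FA": 0.30,
        "PPC": 0.07, "POPC": 0.08,
        "MAG": 0.15, "DAG": 0.09, "TAG": 0.06,
    }
    return _beads_to_counts(n_beads, registry, weights)


def default_vesicle_composition(
    outer_radius: float,
    bilayer_thickness: float,
    registry: SpeciesRegistry | None = None,
) -> dict[str, int]:
    """Vesicle membrane composition: fatty-acid-rich bilayer.

    Bead-budget weights: ~45% fatty acids, ~20% bile salts, ~15%
    phospholipids, ~20% glycerides.
    """
    registry = registry or default_registry()
    R, t = outer_radius, bilayer_thickness
    n_r = max(2, int(math.ceil(t / 0.4)) + 1)
    radii = np.linspace(R - t, R, n_r)
    n_beads = int(4 * math.pi * (radii**2).sum() / DEFAULT_SPACING**2)
    weights = {
        "TC": 0.06, "TDC": 0.05, "GC": 0.05, "GDC": 0.04,
        "FA": 0.45,
        "PPC": 0.07, "POPC": 0.08,
        "MAG": 0.10, "DAG": 0.06, "TAG": 0.04,
    }
    return _beads_to_counts(n_beads, registry, weights)
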