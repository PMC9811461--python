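"""Colloid geometry, water-core detection, classification, composition, surface."""

import math

import numpy as np
import pytest

from conftest import molecules_config
from hifcolloids.detect import detect, unwrap_cluster
from hifcolloids.metrics import (
    classify,
    composition_ratios,
    d_max,
    d_max_brute_force,
    detect_water_core,
    ellipsoid_shape_factor,
    inertia_eigenvalues,
    shape_factor,
    summarize,
    surface_coverage,
)
from hifcolloids.synthetic import (
    MicelleSpec,
    VesicleSpec,
    default_micelle_composition,
    default_vesicle_composition,
    make_micelle,
    make_scene,
    make_vesicle,
)
from hifcolloids.system import BoxSpec


def sphere_lattice(radius=2.0, spacing=0.1):
    g = np.arange(-radius, radius + spacing, spacing)
    pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    return pts[(pts**2).sum(axis=1) <= radius**2]


def ellipsoid_lattice(a, b, c, spacing=0.1):
    gx = np.arange(-a, a + spacing, spacing)
    gy = np.arange(-b, b + spacing, spacing)
    gz = np.arange(-c, c + spacing, spacing)
    pts = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
    r = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2
    return pts[r <= 1.0]


class TestDmax:
    def test_two_beads(self):
        assert d_max(np.array([[0, 0, 0], [0, 0, 3.0]])) == pytest.approx(3.0)

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pts = rng.normal(size=(200, 3)) * rng.uniform(0.5, 3.0)
            assert d_max(pts) == pytest.approx(d_max_brute_force(pts), abs=1e-12)

    def test_degenerate_planar_cloud(self):
        rng = np.random.default_rng(3)
        pts = np.zeros((50, 3))
        pts[:, :2] = rng.normal(size=(50, 2))
        assert d_max(pts) == pytest.approx(d_max_brute_force(pts))

    def test_single_bead_rejected(self):
        with pytest.raises(ValueError):
            d_max(np.array([[0, 0, 0.0]]))


class TestShapeFactor:
    def test_sphere_lattice_is_one(self):
        sf = shape_factor(sphere_lattice(2.0, 0.1))
        assert sf == pytest.approx(1.0, rel=0.02)

    def test_uniform_prolate_ellipsoid_closed_form(self):
        # semi-axes (2b, b, b): ratio (a^2+b^2)/(2 b^2) = 2.5
        sf = shape_factor(ellipsoid_lattice(4.0, 2.0, 2.0, 0.1))
        assert sf == pytest.approx(2.5, rel=0.05)

    def test_random_aspect_ratios_match_closed_form(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            axes = np.sort(rng.uniform(1.0, 3.0, size=3))[::-1]
            a, b, c = axes
            sf = shape_factor(ellipsoid_lattice(a, b, c, 0.08))
            assert sf == pytest.approx(ellipsoid_shape_factor(a, b, c), rel=0.05)

    def test_rotation_invariance(self):
        pts = ellipsoid_lattice(3.0, 1.5, 1.0, 0.12)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [0.3, 1.1, -0.7]).as_matrix()
        assert abs(shape_factor(pts) - shape_factor(pts @ rot.T)) < 1e-9

    def test_dilation_leaves_ratio_unchanged(self):
        pts = ellipsoid_lattice(3.0, 1.5, 1.0, 0.12)
        assert shape_factor(pts) == pytest.approx(shape_factor(pts * 3.7), abs=1e-12)

    def test_collinear_geometry_rejected(self):
        pts = np.column_stack([np.linspace(0, 5, 30), np.zeros(30), np.zeros(30)])
        with pytest.raises(ValueError, match="collinear"):
            shape_factor(pts)

    def test_mass_weighting_changes_moments(self):
        pts = ellipsoid_lattice(2.0, 1.0, 1.0, 0.2)
        masses = np.where(pts[:, 0] > 0, 5.0, 1.0)
        assert shape_factor(pts, masses) != pytest.approx(shape_factor(pts), abs=1e-6)


class TestClassify:
    def test_water_core_wins_regardless_of_shape(self):
        assert classify(5.0, (1.0, 2.0, 3.0), has_water_core=True) == "vesicle"

    def test_shape_factor_above_two_is_elongated(self):
        assert classify(2.5, (1.0, 2.0, 2.5), has_water_core=False) == "elongated"

    def test_oblate_and_prolate_eigenvalue_patterns(self):
        # uniform (b, b, b/2): moments prop. to (b^2+b^2/4, b^2+b^2/4, 2b^2) -> oblate
        obl = inertia_eigenvalues(ellipsoid_lattice(2.0, 2.0, 1.0, 0.1))
        sf = obl[2] / obl[0]
        assert classify(sf, obl, False) == "oblate"
        # uniform (2b, b, b) -> prolate
        pro = inertia_eigenvalues(ellipsoid_lattice(3.0, 1.8, 1.8, 0.1))
        sf = pro[2] / pro[0]
        assert sf <= 2.0
        assert classify(sf, pro, False) == "prolate"


class TestWaterCore:
    def test_synthetic_vesicle_has_enclosed_core(self):
        comp = default_vesicle_composition(4.5, 2.0)
        cfg, truth = make_vesicle(4.5, 2.0, comp, seed=1)
        part = detect(cfg)
        has, count = detect_water_core(cfg, part.clusters[0])
        assert has
        placed = truth.geometry[0]["core_water_beads"]
        assert count == pytest.approx(placed, rel=0.2)

    def test_micelle_has_no_core(self):
        comp = default_micelle_composition((3.0, 2.0, 2.0))
        cfg, _ = make_micelle((3.0, 2.0, 2.0), comp, seed=2)
        part = detect(cfg)
        assert detect_water_core(cfg, part.clusters[0]) == (False, 0)

    def test_bulk_water_around_micelle_is_not_a_core(self):
        spec = MicelleSpec((2.5, 2.0, 2.0), default_micelle_composition((2.5, 2.0, 2.0)))
        cfg, truth = make_scene([spec], {}, BoxSpec(12.0), seed=3)
        part = detect(cfg)
        assert detect_water_core(cfg, part.clusters[0])[0] is False


class TestCompositionRatios:
    def test_ratio_arithmetic(self):
        species = ["TC"] * 10 + ["PPC"] * 5 + ["FA"] * 20
        bs_pl, bs_ffa, comp = composition_ratios(set(range(35)), species)
        assert bs_pl == pytest.approx(2.0)
        assert bs_ffa == pytest.approx(0.5)
        assert comp == {"TC": 10, "PPC": 5, "FA": 20}

    def test_zero_denominator_is_nan_marker(self):
        species = ["TC"] * 4 + ["FA"] * 2
        bs_pl, bs_ffa, _ = composition_ratios(set(range(6)), species)
        assert math.isnan(bs_pl)
        assert bs_ffa == pytest.approx(2.0)

    def test_synthetic_colloid_matches_generator_spec(self):
        comp_spec = default_micelle_composition((3.0, 2.0, 2.0))
        cfg, truth = make_micelle((3.0, 2.0, 2.0), comp_spec, seed=5)
        part = detect(cfg)
        _, _, comp = composition_ratios(part.clusters[0], cfg.species)
        assert comp == truth.composition[0]


class TestSurfaceCoverage:
    def test_single_species_cluster_fraction_is_one(self):
        rng = np.random.default_rng(0)
        mols = [rng.normal(scale=0.2, size=(5, 3)) + c for c in rng.uniform(3, 5, size=(8, 3))]
        cfg = molecules_config(mols, 10.0, ["FA"] * 8)
        part = detect(cfg, cutoff=3.0)
        cov = surface_coverage(cfg, part.clusters[0], cutoff=3.0)
        assert cov == {"fatty_acid": pytest.approx(1.0)}

    def test_fractions_sum_to_one_and_bile_salts_enriched(self):
        axes = (3.0, 2.5, 2.5)
        comp = default_micelle_composition(axes)
        cfg, _ = make_micelle(axes, comp, seed=8)
        part = detect(cfg)
        cov = surface_coverage(cfg, part.clusters[0])
        assert sum(cov.values()) == pytest.approx(1.0, abs=1e-6)
        # bulk bead share of bile salts in the default composition is ~25%
        from hifcolloids.topology import default_registry, get_topology

        reg = default_registry()
        total_beads = sum(get_topology(reg, s).n_beads * n for s, n in comp.items())
        bs_beads = sum(
            get_topology(reg, s).n_beads * n
            for s, n in comp.items()
            if get_topology(reg, s).molecule_class == "bile_salt"
        )
        assert cov["bile_salt"] > bs_beads / total_beads


class TestSummarize:
    def test_empty_partition(self):
        from hifcolloids.detect import ColloidPartition

        cfg = molecules_config([np.array([[1.0, 1, 1]])], 5.0, ["FA"])
        part = ColloidPartition(clusters=[], monomers=frozenset({0}))
        reports, monomers = summarize(part, cfg)
        assert reports == []
        assert monomers == {"fatty_acid": 1}

    def test_scene_reports_match_ground_truth(self):
        specs = [
            MicelleSpec((3.0, 2.0, 2.0), default_micelle_composition((3.0, 2.0, 2.0))),
            VesicleSpec(4.0, 1.8, default_vesicle_composition(4.0, 1.8)),
        ]
        cfg, truth = make_scene(specs, {"TC": 8}, BoxSpec(16.0), seed=4, water_density=2.0)
        part = detect(cfg)
        reports, monomers = summarize(part, cfg, with_surface=False)
        by_members = {frozenset(c): r for c, r in zip(part.clusters, reports)}
        for k, intended in enumerate(truth.intended_type):
            members = truth.colloid_members(k)
            r = by_members[members]
            assert r.colloid_type == intended
            assert r.n_agg == len(members)
            assert r.composition == {
                s: n for s, n in truth.composition[k].items()
            }
        assert monomers == {"bile_salt": 8}
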