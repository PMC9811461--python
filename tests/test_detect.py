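"""Periodic single-linkage detection, manual merges, and cluster unwrapping."""

import numpy as np
import pytest

from conftest import molecules_config, random_config, single_bead_config
from hifcolloids.detect import (
    detect,
    detect_brute_force,
    merge_clusters,
    molecule_min_distance,
    unwrap_cluster,
)
from hifcolloids.metrics import d_max
from hifcolloids.synthetic import default_micelle_composition, make_micelle
from hifcolloids.system import BoxSpec, wrap


def two_bead_molecules(pos_a, pos_b, box_length, species=("FA", "FA")):
    return molecules_config(
        [np.atleast_2d(pos_a), np.atleast_2d(pos_b)], box_length, list(species)
    )


class TestMinDistance:
    def test_direct_distance(self):
        cfg = two_bead_molecules([1, 1, 1], [1, 1, 1.4], 20.0)
        assert molecule_min_distance(cfg, 0, 1) == pytest.approx(0.4)

    def test_minimum_image_across_the_face(self):
        cfg = two_bead_molecules([0.2, 5, 5], [44.8, 5, 5], 45.0)
        # brute force over the 27 periodic images agrees
        brute = min(
            np.linalg.norm(np.array([0.2, 5, 5]) - (np.array([44.8, 5, 5]) + 45.0 * np.array(s)))
            for s in np.ndindex(3, 3, 3)
            for s in [np.array(s) - 1]
        )
        got = molecule_min_distance(cfg, 0, 1)
        assert got == pytest.approx(0.4)
        assert got == pytest.approx(brute)

    def test_multibead_equals_all_pairs_oracle(self, rng):
        cfg = random_config(rng, n_molecules=6, box_length=4.0)
        L = cfg.box.length
        for a in range(5):
            for b in range(a + 1, 6):
                pa, pb = cfg.mol_positions(a), cfg.mol_positions(b)
                brute = min(
                    np.linalg.norm(x - (y + L * np.array(s)))
                    for x in pa
                    for y in pb
                    for s in np.ndindex(3, 3, 3)
                    for s in [np.array(s) - 1]
                )
                assert molecule_min_distance(cfg, a, b) == pytest.approx(brute)

    def test_same_molecule_rejected(self, rng):
        cfg = random_config(rng, n_molecules=2)
        with pytest.raises(ValueError):
            molecule_min_distance(cfg, 1, 1)


class TestDetect:
    def test_single_linkage_transitivity(self):
        cfg = molecules_config(
            [np.array([[1.0, 1, 1]]), np.array([[1.4, 1, 1]]), np.array([[1.8, 1, 1]])],
            10.0,
            ["FA", "FA", "FA"],
        )
        part = detect(cfg, cutoff=0.5)
        assert part.n_clusters == 1
        assert part.clusters[0] == frozenset({0, 1, 2})

    def test_pair_beyond_cutoff_stays_monomeric(self):
        cfg = two_bead_molecules([1, 1, 1], [1, 1, 1.6], 10.0)
        part = detect(cfg, cutoff=0.5)
        assert part.n_clusters == 0
        assert part.monomers == frozenset({0, 1})

    def test_distance_equal_to_cutoff_connects(self):
        cfg = two_bead_molecules([1, 1, 1], [1, 1, 1.5], 10.0)
        part = detect(cfg, cutoff=0.5)
        assert part.n_clusters == 1

    def test_solvent_and_ions_excluded(self):
        cfg = molecules_config(
            [np.array([[1.0, 1, 1]]), np.array([[1.3, 1, 1]]), np.array([[1.6, 1, 1]])],
            10.0,
            ["FA", "W", "ION"],
        )
        part = detect(cfg, cutoff=0.5)
        assert part.n_clusters == 0
        assert part.monomers == frozenset({0})

    @pytest.mark.parametrize("seed", range(50))
    def test_cell_list_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cfg = random_config(
            rng,
            n_molecules=int(rng.integers(5, 40)),
            box_length=float(rng.uniform(3.0, 8.0)),
        )
        fast = detect(cfg, cutoff=0.5)
        slow = detect_brute_force(cfg, cutoff=0.5)
        assert fast.clusters == slow.clusters
        assert fast.monomers == slow.monomers

    def test_translation_invariance(self, rng):
        cfg = random_config(rng, n_molecules=25, box_length=6.0)
        shifted = cfg.copy()
        shifted.positions = wrap(cfg.positions + np.array([2.3, -1.1, 4.9]), 6.0)
        a = detect(cfg)
        b = detect(shifted)
        assert a.clusters == b.clusters
        assert a.monomers == b.monomers

    def test_growing_cutoff_never_fragments(self, rng):
        cfg = random_config(rng, n_molecules=30, box_length=6.0)
        previous = None
        for cutoff in (0.3, 0.5, 0.8, 1.2):
            part = detect(cfg, cutoff=cutoff)
            n_units = part.n_clusters + len(part.monomers)
            if previous is not None:
                assert n_units <= previous
            previous = n_units


class TestMerge:
    @pytest.fixture
    def partition(self):
        cfg = molecules_config(
            [
                np.array([[1.0, 1, 1]]),
                np.array([[1.3, 1, 1]]),
                np.array([[5.0, 5, 5]]),
                np.array([[5.3, 5, 5]]),
            ],
            10.0,
            ["FA"] * 4,
        )
        return cfg, detect(cfg, cutoff=0.5)

    def test_union_and_log(self, partition):
        _, part = partition
        merged = merge_clusters(part, [0, 1])
        assert merged.n_clusters == 1
        assert merged.clusters[0] == frozenset({0, 1, 2, 3})
        assert merged.merge_log == [(0, 1)]

    def test_merged_d_max_not_smaller(self, partition):
        cfg, part = partition
        d_before = max(
            d_max(unwrap_cluster(cfg, c)[0]) for c in part.clusters
        )
        merged = merge_clusters(part, [0, 1])
        coords, _ = unwrap_cluster(cfg, merged.clusters[0], cutoff=10.0)
        assert d_max(coords) >= d_before

    def test_unknown_id_rejected(self, partition):
        _, part = partition
        with pytest.raises(KeyError):
            merge_clusters(part, [0, 7])

    def test_duplicate_ids_rejected(self, partition):
        _, part = partition
        with pytest.raises(ValueError):
            merge_clusters(part, [0, 0])


class TestUnwrap:
    def test_interior_cluster_unchanged(self):
        cfg = molecules_config(
            [np.array([[3.0, 3, 3]]), np.array([[3.4, 3, 3]])], 10.0, ["FA", "FA"]
        )
        part = detect(cfg)
        coords, mols = unwrap_cluster(cfg, part.clusters[0])
        assert mols == [0, 1]
        assert np.allclose(coords, [[3, 3, 3], [3.4, 3, 3]])

    def test_boundary_straddling_micelle_diameter_recovered(self):
        axes = (3.0, 2.0, 2.0)
        comp = default_micelle_composition(axes)
        box = BoxSpec(12.0)
        # center on a corner so the colloid wraps across three faces
        cfg, _ = make_micelle(axes, comp, seed=4, box=box, center=np.zeros(3))
        part = detect(cfg)
        assert part.n_clusters == 1
        coords, _ = unwrap_cluster(cfg, part.clusters[0])
        assert d_max(coords) == pytest.approx(2 * axes[0], rel=0.15)

    def test_global_translation_preserves_pairwise_distances(self, rng):
        cfg = random_config(rng, n_molecules=12, box_length=5.0)
        part = detect(cfg, cutoff=1.5)
        big = max(part.clusters, key=len)
        coords, _ = unwrap_cluster(cfg, big, cutoff=1.5)
        shifted = cfg.copy()
        shifted.positions = wrap(cfg.positions + 1.7, 5.0)
        coords2, _ = unwrap_cluster(shifted, big, cutoff=1.5)
        d1 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        d2 = np.linalg.norm(coords2[:, None] - coords2[None, :], axis=-1)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_disconnected_input_rejected(self):
        cfg = molecules_config(
            [np.array([[1.0, 1, 1]]), np.array([[5.0, 5, 5]])], 10.0, ["FA", "FA"]
        )
        with pytest.raises(ValueError, match="not connected"):
            unwrap_cluster(cfg, {0, 1}, cutoff=0.5)
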