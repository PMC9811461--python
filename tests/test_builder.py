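"""Concentration/count conversion, splits, and starting-configuration builders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hifcolloids.builder import (
    MOLECULES_PER_NM3_PER_MM,
    CompositionSpec,
    build_random,
    count_to_mm,
    load_presets,
    mm_to_count,
    overlay,
    species_counts,
    strip_glycerides,
    substitute_antifreeze,
)
from hifcolloids.detect import molecule_min_distance
from hifcolloids.system import BoxSpec
from hifcolloids.topology import get_topology


class TestConversion:
    def test_two_mm_in_a_20nm_box_is_ten_molecules(self):
        assert mm_to_count(2.0, BoxSpec(20.0)) == 10

    def test_zero_concentration_is_zero_molecules(self):
        assert mm_to_count(0.0, BoxSpec(45.0)) == 0

    def test_bile_salt_concentration_hv3(self):
        # 10.8 mM x 6.02214e-4 / (mM nm^3) x 45^3 nm^3 = 592.65 -> 593
        assert mm_to_count(10.8, BoxSpec(45.0)) == 593

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mm_to_count(-1.0, BoxSpec(20.0))

    @given(
        c=st.floats(min_value=0.0, max_value=100.0),
        length=st.floats(min_value=5.0, max_value=50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_within_half_molecule(self, c, length):
        box = BoxSpec(length)
        back = count_to_mm(mm_to_count(c, box), box)
        assert abs(back - c) <= 0.5 / (MOLECULES_PER_NM3_PER_MM * box.volume) + 1e-12


class TestSpeciesCounts:
    def test_split_rounding_preserves_class_totals(self):
        box = BoxSpec(45.0)
        for name, comp in load_presets().items():
            counts = species_counts(comp, box)
            bs_total = sum(counts.get(s, 0) for s in ("TC", "TDC", "GC", "GDC"))
            assert bs_total == mm_to_count(comp.concentrations["bile_salt"], box), name
            pl_total = sum(counts.get(s, 0) for s in ("PPC", "POPC"))
            assert pl_total == mm_to_count(comp.concentrations["phospholipid"], box)

    def test_uneven_split_uses_largest_remainder(self):
        comp = CompositionSpec(
            concentrations={"bile_salt": 2.0},
            bile_salt_split={"TC": 0.5, "TDC": 0.3, "GC": 0.1, "GDC": 0.1},
        )
        box = BoxSpec(20.0)  # 10 bile salts total
        counts = species_counts(comp, box)
        assert sum(counts.values()) == 10
        assert counts["TC"] == 5 and counts["TDC"] == 3

    def test_split_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CompositionSpec(
                concentrations={"bile_salt": 1.0},
                bile_salt_split={"TC": 0.6, "TDC": 0.6},
            )


class TestStripGlycerides:
    def test_zeroes_glycerides_only(self):
        hv3 = load_presets()["HV3"]
        stripped = strip_glycerides(hv3)
        assert stripped.concentrations["MAG"] == 0.0
        assert stripped.concentrations["DAG"] == 0.0
        assert stripped.concentrations["TAG"] == 0.0
        assert stripped.concentrations["bile_salt"] == 10.8

    def test_idempotent(self):
        once = strip_glycerides(load_presets()["HV3"])
        twice = strip_glycerides(once)
        assert once.concentrations == twice.concentrations

    def test_molecule_count_drops_by_exactly_the_glycerides(self):
        box = BoxSpec(45.0)
        hv3 = load_presets()["HV3"]
        full = species_counts(hv3, box)
        reduced = species_counts(strip_glycerides(hv3), box)
        diff = sum(full.values()) - sum(reduced.values())
        expected = sum(mm_to_count(hv3.concentrations[g], box) for g in ("MAG", "DAG", "TAG"))
        assert diff == expected


class TestBuildRandom:
    def test_water_only_composition(self):
        comp = CompositionSpec(concentrations={})
        cfg = build_random(comp, BoxSpec(4.0), seed=0, water_density=3.0)
        assert set(cfg.species) == {"W"}

    def test_deterministic_for_fixed_seed(self):
        comp = CompositionSpec(concentrations={"fatty_acid": 10.0, "bile_salt": 5.0})
        a = build_random(comp, BoxSpec(6.0), seed=42, water_density=1.0)
        b = build_random(comp, BoxSpec(6.0), seed=42, water_density=1.0)
        assert np.array_equal(a.positions, b.positions)
        assert a.species == b.species

    def test_coordinates_inside_box(self):
        comp = CompositionSpec(concentrations={"fatty_acid": 20.0, "TAG": 5.0})
        cfg = build_random(comp, BoxSpec(5.0), seed=1, water_density=0.5)
        assert cfg.positions.min() >= 0.0
        assert cfg.positions.max() < 5.0

    def test_counts_follow_composition(self, registry):
        comp = CompositionSpec(concentrations={"fatty_acid": 12.0, "MAG": 4.0})
        box = BoxSpec(8.0)
        cfg = build_random(comp, box, seed=3, water_density=0.0)
        counts = cfg.species_counts()
        assert counts["FA"] == mm_to_count(12.0, box)
        assert counts["MAG"] == mm_to_count(4.0, box)

    def test_infeasible_packing_raises(self):
        comp = CompositionSpec(concentrations={"TAG": 5000.0})
        with pytest.raises(Exception, match="occupancy"):
            build_random(comp, BoxSpec(5.0), seed=0)


class TestOverlay:
    @pytest.fixture
    def base(self):
        comp = CompositionSpec(concentrations={"fatty_acid": 8.0})
        return build_random(comp, BoxSpec(7.0), seed=5, water_density=2.0)

    def test_base_molecules_untouched(self, base):
        added = CompositionSpec(concentrations={"bile_salt": 4.0})
        result = overlay(base, added, seed=9)
        # base non-water molecules appear first with identical coordinates
        n_base_fa = base.species_counts()["FA"]
        base_fa = [m for m, s in enumerate(base.species) if s == "FA"]
        res_fa = [m for m, s in enumerate(result.species) if s == "FA"]
        assert len(res_fa) == n_base_fa
        for mb, mr in zip(base_fa, res_fa):
            assert np.array_equal(base.mol_positions(mb), result.mol_positions(mr))

    def test_species_counts_additive(self, base):
        added = CompositionSpec(concentrations={"bile_salt": 4.0, "MAG": 2.0})
        result = overlay(base, added, seed=9)
        want = species_counts(added, base.box)
        got = result.species_counts()
        for sp, n in want.items():
            assert got.get(sp, 0) == n
        assert got["FA"] == base.species_counts()["FA"]

    def test_clearance_respected(self, base):
        added = CompositionSpec(concentrations={"bile_salt": 4.0})
        result = overlay(base, added, seed=9, clearance=0.3)
        new_ids = [m for m, s in enumerate(result.species) if s in ("TC", "TDC", "GC", "GDC")]
        old_ids = [m for m, s in enumerate(result.species) if s == "FA"]
        for a in new_ids:
            for b in old_ids:
                assert molecule_min_distance(result, a, b) >= 0.3


class TestAntifreeze:
    def test_ten_percent_of_water_relabeled(self):
        comp = CompositionSpec(concentrations={})
        cfg = build_random(comp, BoxSpec(5.0), seed=0, water_density=8.0)
        n_w = cfg.species_counts()["W"]
        sub = substitute_antifreeze(cfg, 0.10, seed=1)
        assert sub.species_counts().get("WF", 0) == round(0.10 * n_w)
        assert np.array_equal(sub.positions, cfg.positions)

    def test_zero_fraction_is_identity(self):
        comp = CompositionSpec(concentrations={})
        cfg = build_random(comp, BoxSpec(4.0), seed=0, water_density=2.0)
        sub = substitute_antifreeze(cfg, 0.0, seed=1)
        assert sub.species == cfg.species

    @given(
        n_water=st.integers(min_value=0, max_value=400),
        fraction=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_relabeled_count_matches_rounding_rule(self, n_water, fraction):
        from conftest import single_bead_config

        rng = np.random.default_rng(n_water + 1)
        cfg = single_bead_config(rng.uniform(0, 10, size=(max(n_water, 1), 3)), 10.0)
        if n_water == 0:
            cfg.species[0] = "FA"  # no waters at all
        sub = substitute_antifreeze(cfg, fraction, seed=0)
        n_w = sum(1 for s in cfg.species if s == "W")
        assert sum(1 for s in sub.species if s == "WF") == int(np.floor(fraction * n_w + 0.5))
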