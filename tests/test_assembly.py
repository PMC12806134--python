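"""Planner arithmetic: apportionment, area matching, stress variants,
sterol asymmetry and double-bilayer ion bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memasym.assembly import (
    AssemblyPlan,
    LeafletPlan,
    area_match_offsets,
    combine_asymchol,
    composition_counts,
    plan_physiol_system,
    realize_plan,
    stress_variant,
)


class TestCompositionCounts:
    def test_exact_products(self):
        assert composition_counts({"PC": 0.55, "SM": 0.45}, 40) == {"PC": 22, "SM": 18}

    def test_largest_remainder_example(self):
        assert composition_counts({"PE": 0.5, "PC": 0.3, "PS": 0.2}, 47) == {
            "PE": 24,
            "PC": 14,
            "PS": 9,
        }

    def test_n_zero_gives_all_zeros(self):
        assert composition_counts({"PC": 0.7, "SM": 0.3}, 0) == {"PC": 0, "SM": 0}

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            composition_counts({"PC": 1.2, "SM": -0.2}, 10)

    @given(
        n=st.integers(min_value=0, max_value=500),
        weights=st.lists(
            st.floats(min_value=0.01, max_value=10.0), min_size=1, max_size=6
        ),
    )
    def test_counts_sum_exactly_and_apportionment_error_below_one(self, n, weights):
        total = sum(weights)
        fractions = {f"S{k}": w / total for k, w in enumerate(weights)}
        counts = composition_counts(fractions, n)
        assert sum(counts.values()) == n
        for sp, f in fractions.items():
            assert abs(counts[sp] - f * n) < 1.0


class TestAreaMatching:
    def test_printed_zero_chol_pair_gives_five_lipid_offset(self):
        # measured leaflet areas 70.7 vs 67.8 nm^2, mean phospholipid area 0.6 nm^2
        offset, adjusted = area_match_offsets(
            70.7, 67.8, "outer", {"PC": 0.55, "SM": 0.45}
        )
        assert abs(offset) == 5  # round(2.9 / 0.6)
        assert offset < 0  # outer is larger, so lipids are removed from it
        assert abs(adjusted.expected_area - 67.8) <= 0.3

    def test_adding_to_inner_instead(self):
        offset, adjusted = area_match_offsets(
            70.7, 67.8, "inner", {"PE": 0.5, "PC": 0.3, "PS": 0.2}
        )
        assert offset == 5  # inner is smaller: lipids are added

    def test_equal_areas_no_offset(self):
        offset, adjusted = area_match_offsets(60.0, 60.0, "outer", {"PC": 1.0})
        assert offset == 0
        assert adjusted.total == 100

    def test_sign_reverses_when_outer_is_smaller(self):
        # the 20% sterol pair: outer smaller by 2.7 nm^2
        off_small, _ = area_match_offsets(60.0, 62.7, "outer", {"PC": 1.0})
        off_large, _ = area_match_offsets(62.7, 60.0, "outer", {"PC": 1.0})
        assert off_small > 0 > off_large
        assert abs(off_small) == abs(off_large) == round(2.7 / 0.6)

    def test_residual_bound_holds_generally(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a_out = float(rng.uniform(40, 80))
            a_in = float(rng.uniform(40, 80))
            frac = {"PC": 0.5, "SM": 0.2, "CHOL": 0.3}
            mean_apl = 0.5 * 0.6 + 0.2 * 0.6 + 0.3 * 0.3
            _, adjusted = area_match_offsets(a_out, a_in, "outer", frac)
            residual = abs(adjusted.expected_area - a_in)
            assert residual <= mean_apl / 2 + mean_apl  # half-step + one-lipid rounding


class TestStressVariant:
    @pytest.fixture
    def h20_like(self):
        return AssemblyPlan(
            outer=LeafletPlan({"PC": 27, "SM": 21, "CHOL": 12}),
            inner=LeafletPlan({"PE": 21, "PC": 15, "PS": 12, "CHOL": 12}),
            box=(6.0, 6.0, 10.0),
            label="H20",
            headgroup_charge={"PS": -1.0},
        )

    @pytest.mark.parametrize("percent,expected", [(5, 63), (-5, 57), (-10, 54), (0, 60)])
    def test_outer_total_scaling(self, h20_like, percent, expected):
        assert stress_variant(h20_like, percent).outer.total == expected

    def test_inner_leaflet_untouched(self, h20_like):
        sv = stress_variant(h20_like, -10)
        assert sv.inner.counts == h20_like.inner.counts

    def test_fractions_preserved_within_rounding(self, h20_like):
        sv = stress_variant(h20_like, 5)
        n = sv.outer.total
        for sp, f in h20_like.outer.fractions().items():
            assert abs(sv.outer.counts[sp] / n - f) <= 1.0 / n

    def test_emptying_the_leaflet_is_an_error(self, h20_like):
        with pytest.raises(ValueError, match="empties"):
            stress_variant(h20_like, -100)


class TestAsymChol:
    def test_outer_adjusted_toward_inner_area(self):
        outer = LeafletPlan({"PC": 20, "SM": 16, "CHOL": 18})  # 33% sterol
        inner = LeafletPlan({"PE": 25, "PC": 20, "PS": 10})  # sterol-free
        plan = combine_asymchol(outer, inner)
        mean_apl = plan.outer.mean_apl()
        assert abs(plan.outer.expected_area - inner.expected_area) <= mean_apl
        assert plan.inner.counts == inner.counts  # inner never modified

    def test_identical_areas_leave_outer_unchanged(self):
        outer = LeafletPlan({"PC": 50})
        inner = LeafletPlan({"PE": 50})
        plan = combine_asymchol(outer, inner)
        assert plan.outer.counts == {"PC": 50}


class TestPhysiol:
    @pytest.fixture
    def bilayer(self):
        return AssemblyPlan(
            outer=LeafletPlan({"PC": 30, "SM": 18, "CHOL": 12}),
            inner=LeafletPlan({"PE": 21, "PC": 18, "PS": 9, "CHOL": 12}),
            box=(6.0, 6.0, 10.0),
            label="H20",
            headgroup_charge={"PS": -1.0},
        )

    def test_150_mm_in_100_nm3_gives_9_ion_pairs(self, bilayer):
        plan = plan_physiol_system(bilayer, 150.0, 0.0, 100.0, 50.0)
        assert plan.ions["interior"] == {"cation": 9, "anion": 9}
        assert plan.ions["exterior"] == {"cation": 0, "anion": 0}

    def test_counterions_restore_exact_neutrality(self, bilayer):
        plan = plan_physiol_system(bilayer, 150.0, 150.0, 100.0, 100.0)
        # 9 PS per inner leaflet x 2 bilayers -> 18 extra interior cations
        assert plan.extra_cations == {"interior": 18}
        assert plan.net_charge() == 0.0

    def test_no_ions_without_concentration_or_charge(self):
        neutral = AssemblyPlan(
            outer=LeafletPlan({"PC": 30}),
            inner=LeafletPlan({"PC": 30}),
            box=(5.0, 5.0, 10.0),
        )
        plan = plan_physiol_system(neutral, 0.0, 0.0, 80.0, 80.0)
        assert plan.extra_cations == {}
        assert all(v == 0 for c in plan.ions.values() for v in c.values())

    def test_validation(self, bilayer):
        with pytest.raises(ValueError, match=">= 0"):
            plan_physiol_system(bilayer, -1.0, 0.0, 10.0, 10.0)
        with pytest.raises(ValueError, match="positive"):
            plan_physiol_system(bilayer, 0.0, 0.0, 0.0, 10.0)


class TestRealize:
    def test_structure_counts_match_manifest(self):
        plan = AssemblyPlan(
            outer=LeafletPlan({"PC": 33, "SM": 15, "CHOL": 12}),
            inner=LeafletPlan({"PE": 21, "PC": 18, "PS": 9, "CHOL": 12}),
            box=(6.0, 6.0, 10.0),
            label="audit",
            headgroup_charge={"PS": -1.0},
        )
        traj, manifest = realize_plan(plan, seed=4, water_count=60)
        species = list(traj.topology.molecules.values())
        leaf_counts = {}
        from memasym.trajectory import assign_leaflets, recenter_frames

        leaf = assign_leaflets(recenter_frames(traj))
        for leaflet in ("outer", "inner"):
            got = {}
            for m in leaf.molecule_ids(leaflet):
                sp = traj.topology.molecules[m]
                got[sp] = got.get(sp, 0) + 1
            assert got == manifest["leaflets"][leaflet]
        assert sum(1 for sp in species if sp == "PC") == 33 + 18

    def test_physiol_realisation_is_mirror_symmetric(self):
        base = AssemblyPlan(
            outer=LeafletPlan({"PC": 12, "SM": 6}),
            inner=LeafletPlan({"PE": 10, "PC": 8}),
            box=(4.0, 4.0, 10.0),
        )
        plan = plan_physiol_system(base, 100.0, 100.0, 60.0, 60.0)
        traj, manifest = realize_plan(plan, seed=5, water_count=40)
        assert manifest["double_bilayer"]
        # two mirror bilayers: species counts double, coordinates mirror in z
        species = list(traj.topology.molecules.values())
        assert sum(1 for sp in species if sp == "PC") == 2 * (12 + 8)
        z = traj.frames[0].coords[:, 2]
        heads = traj.topology.atom_indices(role="headgroup_ref")
        assert (z[heads] > 0).sum() == (z[heads] < 0).sum()

    def test_every_emitted_plan_is_charge_neutral(self):
        base = AssemblyPlan(
            outer=LeafletPlan({"PC": 20, "CHOL": 10}),
            inner=LeafletPlan({"PS": 10, "PC": 20}),
            box=(5.0, 5.0, 10.0),
            headgroup_charge={"PS": -1.0},
        )
        for plan in (
            base,
            stress_variant(base, 5),
            plan_physiol_system(base, 120.0, 30.0, 90.0, 90.0),
        ):
            traj, _ = realize_plan(plan, seed=6, water_count=30)
            assert abs(traj.topology.charges().sum()) < 1e-9
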