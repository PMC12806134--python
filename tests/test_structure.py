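"""Structural observables: area statistics, density profiles, thickness,
tilt and chain order parameters, including generator-recovery checks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memasym import (
    assign_leaflets,
    chain_order_parameters,
    density_profile,
    lateral_area_stats,
    membrane_thickness,
    tilt_distribution,
)
from memasym.structure import DensityProfile
from memasym.synthetic import BilayerSpec, LeafletSpec, generate_bilayer_trajectory
from memasym.trajectory import Frame, Trajectory, recenter_frames


# ---------------------------------------------------------------------------
# lateral area
# ---------------------------------------------------------------------------


class TestAreaStats:
    def test_constant_box_mean_and_zero_sd(self, tiny_bilayer):
        traj, _truth, _spec = tiny_bilayer
        const_frames = [
            Frame(time=fr.time, box=np.array([8.4, 8.4, 10.0]), coords=fr.coords)
            for fr in traj.frames
        ]
        const = Trajectory(topology=traj.topology, frames=const_frames, dt=traj.dt)
        stats = lateral_area_stats(const, assign_leaflets(const))
        assert stats.mean == pytest.approx(70.56)
        assert stats.sd == 0.0

    def test_population_sd_of_known_series(self, tiny_bilayer):
        traj, _truth, _spec = tiny_bilayer
        sides = [math.sqrt(a) for a in (70.0, 71.0, 69.0, 70.0)]
        frames = [
            Frame(time=float(k), box=np.array([s, s, 10.0]), coords=traj.frames[0].coords)
            for k, s in enumerate(sides)
        ]
        t = Trajectory(topology=traj.topology, frames=frames, dt=1.0)
        stats = lateral_area_stats(t, assign_leaflets(t))
        assert stats.mean == pytest.approx(70.0)
        assert stats.sd == pytest.approx(math.sqrt(0.5))

    def test_area_per_lipid_divides_by_leaflet_count(self, tiny_bilayer):
        traj, _truth, _spec = tiny_bilayer
        leaf = assign_leaflets(traj)
        stats = lateral_area_stats(traj, leaf)
        n_outer = len(leaf.molecule_ids("outer"))
        assert stats.area_per_lipid["outer"] == pytest.approx(stats.mean / n_outer)

    def test_generator_area_sd_recovered(self, bilayer200, bilayer200_leaflets):
        traj, truth, _spec = bilayer200
        stats = lateral_area_stats(traj, bilayer200_leaflets)
        assert stats.sd == pytest.approx(truth.area_sd, rel=1e-9)


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------


class TestDensityProfile:
    @given(bin_width=st.sampled_from([0.05, 0.08, 0.1, 0.2, 0.25]))
    def test_mass_conservation_for_any_bin_width(self, bin_width):
        spec = BilayerSpec(
            outer=LeafletSpec({"PC": 1.0}, 6),
            inner=LeafletSpec({"PC": 1.0}, 6),
            water_count=20,
            seed=5,
        )
        traj, _ = generate_bilayer_trajectory(spec, 2)
        traj = recenter_frames(traj)
        idx = traj.topology.atom_indices(
            molecule_ids=set(traj.topology.lipid_molecule_ids())
        )
        prof = density_profile(traj, idx, bin_width=bin_width)
        total = traj.topology.masses()[idx].sum()
        assert prof.integral() == pytest.approx(total, rel=1e-6)

    def test_charge_profile_of_neutral_system_integrates_to_zero(self, bilayer200):
        traj, _truth, _spec = bilayer200
        prof = density_profile(
            traj, np.arange(traj.n_atoms), bin_width=0.1, weight="charge"
        )
        assert abs(prof.integral()) < 1e-9

    def test_uniform_water_slab_is_flat(self):
        spec = BilayerSpec(
            outer=LeafletSpec({"PC": 1.0}, 4),
            inner=LeafletSpec({"PC": 1.0}, 4),
            water_count=4000,
            seed=8,
        )
        traj, _ = generate_bilayer_trajectory(spec, 20)
        traj = recenter_frames(traj)
        idx = traj.topology.atom_indices(role="water_oxygen")
        prof = density_profile(traj, idx, bin_width=0.2)
        # interior of the upper water slab (waters fill ~[2.25, 4.9])
        sel = (prof.bin_centers > 2.6) & (prof.bin_centers < 4.5)
        vals = prof.values[sel]
        assert vals.std() / vals.mean() < 0.15  # flat within counting noise

    def test_empty_selection_is_an_error(self, tiny_bilayer):
        traj, _truth, _spec = tiny_bilayer
        with pytest.raises(ValueError, match="empty"):
            density_profile(traj, np.array([], dtype=int))


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------


def _profile_from_values(centers, values):
    w = centers[1] - centers[0]
    edges = np.concatenate([centers - w / 2, [centers[-1] + w / 2]])
    return DensityProfile(
        bin_edges=edges, values=np.asarray(values, float), weight="mass", mean_area=1.0
    )


class TestThickness:
    def test_exact_symmetric_peaks(self):
        centers = np.arange(-3.95, 4.0, 0.1)
        values = np.exp(-((np.abs(centers) - 2.0) ** 2) / (2 * 0.09))
        prof = _profile_from_values(centers, values)
        assert membrane_thickness(prof) == pytest.approx(4.0, abs=1e-6)

    def test_invariant_under_rescaling_and_reflection(self):
        centers = np.arange(-3.95, 4.0, 0.1)
        values = np.exp(-((np.abs(centers - 0.02) - 1.9) ** 2) / (2 * 0.09))
        prof = _profile_from_values(centers, values)
        t0 = membrane_thickness(prof)
        scaled = _profile_from_values(centers, 7.3 * values)
        assert membrane_thickness(scaled) == pytest.approx(t0, abs=1e-12)
        reflected = _profile_from_values(centers, values[::-1])
        assert membrane_thickness(reflected) == pytest.approx(t0, abs=1e-9)

    def test_single_sided_profile_is_an_error(self):
        centers = np.arange(0.05, 4.0, 0.1)
        with pytest.raises(ValueError, match="both leaflets"):
            membrane_thickness(_profile_from_values(centers, np.ones_like(centers)))

    def test_monotone_side_has_no_peak(self):
        centers = np.arange(-3.95, 4.0, 0.1)
        with pytest.raises(ValueError, match="no leaflet peak"):
            membrane_thickness(_profile_from_values(centers, centers + 5.0))

    def test_generator_thickness_recovered_within_one_bin(self, bilayer200):
        traj, truth, _spec = bilayer200
        idx = traj.topology.atom_indices(
            molecule_ids=set(traj.topology.lipid_molecule_ids())
        )
        prof = density_profile(traj, idx, bin_width=0.1)
        assert membrane_thickness(prof) == pytest.approx(truth.thickness, abs=0.1)


# ---------------------------------------------------------------------------
# tilt
# ---------------------------------------------------------------------------


class TestTilt:
    def test_axis_conventions_via_constructed_molecules(self, tiny_bilayer):
        # build a one-frame trajectory whose PC axis is exactly vertical
        traj, _truth, _spec = tiny_bilayer
        top = traj.topology
        coords = traj.frames[0].coords.copy()
        leaf = assign_leaflets(traj)
        mols = [m for m in leaf.molecule_ids("outer") if top.molecules[m] == "PC"]
        by_mol = top.molecule_atom_indices()
        for m in mols:
            names = {top.atoms[i].name: i for i in by_mol[m]}
            p = coords[names["P"]]
            # terminal carbons directly below the head: axis (0, 0, -L)
            for nm in ("C16A", "C18B"):
                coords[names[nm]] = p - np.array([0.0, 0.0, 1.5])
        frame = Frame(time=0.0, box=traj.frames[0].box.copy(), coords=coords)
        t = Trajectory(topology=top, frames=[frame], dt=traj.dt)
        td = tilt_distribution(t, "PC", leaf, leaflet="outer")
        assert td.mode_deg == pytest.approx(90.0, abs=1.0)
        assert td.angles_mean == pytest.approx(90.0, abs=1e-9)
        # in-plane axis -> 0 degrees
        for m in mols:
            names = {top.atoms[i].name: i for i in by_mol[m]}
            p = coords[names["P"]]
            for nm in ("C16A", "C18B"):
                coords[names[nm]] = p + np.array([1.5, 0.0, 0.0])
        t = Trajectory(
            topology=top,
            frames=[Frame(time=0.0, box=traj.frames[0].box.copy(), coords=coords)],
            dt=traj.dt,
        )
        td = tilt_distribution(t, "PC", leaf, leaflet="outer")
        assert td.angles_mean == pytest.approx(0.0, abs=1e-9)

    def test_histogram_normalised_and_mode_in_range(self, bilayer200, bilayer200_leaflets):
        traj, _truth, _spec = bilayer200
        td = tilt_distribution(traj, "SM", bilayer200_leaflets, leaflet="outer")
        assert td.density.sum() == pytest.approx(1.0)
        assert 0.0 <= td.mode_deg <= 90.0

    @pytest.mark.parametrize(
        "species,leaflet", [("CHOL", "outer"), ("CHOL", "inner"), ("PC", "outer"), ("PS", "inner")]
    )
    def test_generator_tilt_mode_recovered(
        self, bilayer200, bilayer200_leaflets, species, leaflet
    ):
        traj, truth, _spec = bilayer200
        td = tilt_distribution(traj, species, bilayer200_leaflets, leaflet=leaflet)
        assert td.mode_deg == pytest.approx(truth.tilt_modes[(species, leaflet)], abs=1.0)

    def test_absent_species_is_an_error(self, bilayer200, bilayer200_leaflets):
        traj, _truth, _spec = bilayer200
        with pytest.raises(ValueError, match="absent"):
            tilt_distribution(traj, "PE", bilayer200_leaflets, leaflet="outer")


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------


def brute_force_scd(traj, species, chain_index, leaflets, leaflet):
    """Independent oracle: explicit loops over frames, molecules, carbons."""
    top = traj.topology
    chain = top.species_meta[species].chains[chain_index]
    mols = [
        m
        for m in sorted(leaflets.molecule_ids(leaflet))
        if top.molecules[m] == species
    ]
    by_mol = top.molecule_atom_indices()
    n_car = len(chain) - 2
    per_frame = np.zeros((traj.n_frames, n_car))
    for k, fr in enumerate(traj.frames):
        for c in range(n_car):
            acc = 0.0
            for m in mols:
                names = {top.atoms[i].name: i for i in by_mol[m]}
                v = fr.coords[names[chain[c + 2]]] - fr.coords[names[chain[c]]]
                cos2 = v[2] ** 2 / (v @ v)
                acc += (3 * cos2 - 1) / 2
            per_frame[k, c] = acc / len(mols)
    return per_frame.mean(axis=0)


class TestOrderParameters:
    def test_matches_brute_force_oracle(self, tiny_bilayer):
        traj, _truth, _spec = tiny_bilayer
        leaf = assign_leaflets(traj)
        for species, leaflet in (("PC", "outer"), ("PE", "inner")):
            for chain_index in (0, 1):
                prof = chain_order_parameters(traj, species, chain_index, leaf, leaflet)
                oracle = brute_force_scd(traj, species, chain_index, leaf, leaflet)
                np.testing.assert_allclose(prof.s_cd, oracle, atol=1e-12)

    def test_aligned_and_in_plane_limits(self):
        spec = BilayerSpec(
            outer=LeafletSpec({"PC": 1.0}, 5),
            inner=LeafletSpec({"PC": 1.0}, 5),
            water_count=10,
            target_scd={"default": 1.0},
            seed=3,
        )
        traj, _ = generate_bilayer_trajectory(spec, 2)
        leaf = assign_leaflets(recenter_frames(traj))
        prof = chain_order_parameters(recenter_frames(traj), "PC", 0, leaf, "outer")
        np.testing.assert_allclose(prof.s_cd, 1.0, atol=1e-9)
        spec_flat = BilayerSpec(
            outer=LeafletSpec({"PC": 1.0}, 5),
            inner=LeafletSpec({"PC": 1.0}, 5),
            water_count=10,
            target_scd={"default": -0.5},
            seed=3,
        )
        traj, _ = generate_bilayer_trajectory(spec_flat, 2)
        leaf = assign_leaflets(recenter_frames(traj))
        prof = chain_order_parameters(recenter_frames(traj), "PC", 0, leaf, "outer")
        np.testing.assert_allclose(prof.s_cd, -0.5, atol=1e-9)

    def test_magic_angle_gives_zero(self):
        spec = BilayerSpec(
            outer=LeafletSpec({"PC": 1.0}, 5),
            inner=LeafletSpec({"PC": 1.0}, 5),
            water_count=10,
            target_scd={"default": 0.0},
            seed=4,
        )
        traj, _ = generate_bilayer_trajectory(spec, 2)
        leaf = assign_leaflets(recenter_frames(traj))
        prof = chain_order_parameters(recenter_frames(traj), "PC", 0, leaf, "outer")
        np.testing.assert_allclose(prof.s_cd, 0.0, atol=1e-6)

    def test_generator_per_carbon_targets_recovered(self, bilayer200, bilayer200_leaflets):
        traj, truth, _spec = bilayer200
        for species in ("PC", "SM", "CHOL"):
            leaflet = "outer"
            for chain_index, target in enumerate(truth.scd[species]):
                prof = chain_order_parameters(
                    traj, species, chain_index, bilayer200_leaflets, leaflet
                )
                np.testing.assert_allclose(prof.s_cd, target, atol=0.01)

    def test_profile_difference_requires_matching_carbons(self, tiny_bilayer):
        traj, _truth, _spec = tiny_bilayer
        leaf = assign_leaflets(traj)
        a = chain_order_parameters(traj, "PC", 0, leaf, "outer")
        b = chain_order_parameters(traj, "PC", 1, leaf, "outer")  # longer chain
        with pytest.raises(ValueError, match="different carbons"):
            a.difference(b)
        np.testing.assert_allclose(a.difference(a), 0.0, atol=1e-15)

    def test_short_chain_is_an_error(self, tiny_bilayer):
        traj, _truth, _spec = tiny_bilayer
        leaf = assign_leaflets(traj)
        traj.topology.species_meta["PC"].chains.append(["C2A", "C3A"])
        try:
            with pytest.raises(ValueError, match="at least 3"):
                chain_order_parameters(traj, "PC", 2, leaf, "outer")
        finally:
            traj.topology.species_meta["PC"].chains.pop()
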