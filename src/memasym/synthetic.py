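"""Seeded synthetic bilayer trajectories with exact ground truth.

The generator emulates a planar two-leaflet bilayer in water without any
dynamics: every observable the analysis modules compute is *constructed*
into the coordinates, so recovery can be checked against a known answer.

Construction rules
------------------
headgroups
    Reference atoms drawn Normal(+/-headgroup_peak_z, headgroup_sigma) in z,
    on a per-leaflet lattice in x/y, redrawn every frame.  The ester
    reference shares the headgroup z (lateral offset only) so the lipid
    mass-density peak of each leaflet sits at exactly +/-headgroup_peak_z and
    the ground-truth thickness is 2 x headgroup_peak_z.
chains
    Tail carbons are placed by the recurrence C(i+1) = C(i-1) + b*u_i with
    |u_i| = 1 at the fixed polar angle theta_i* solving
    (3 cos^2 theta* - 1)/2 = target_SCD(i) and a uniformly random azimuth
    per molecule, carbon and frame.  The analysis convention measures the
    C(i-1)->C(i+1) vector, so recovered order parameters equal the targets
    to floating-point precision while the chains still look disordered.
tilt
    The molecular axis angle to the bilayer plane is drawn
    Normal(tilt_mode_deg, tilt_sd_deg); the whole chain is translated so the
    axis end-point lands where the drawn angle dictates.  Translation leaves
    segment vectors (hence S_CD) untouched.
area
    The lateral box area follows a stationary AR(1) series with the stated
    standard deviation, mimicking barostat wander.
waters, ions
    Single-site waters fill |z| > headgroup_peak_z and perform reflected
    random walks within their side, so a quiescent trajectory produces no
    membrane crossings.  Counterions neutralise anionic lipids.
charges
    Optional charge sheets (z_center, sheet density e/nm^2) are realised as
    lattices of fixed point charges, giving the electrostatic potential a
    closed form for use as an analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assembly import composition_counts
from .species import default_species_config, make_molecule_atoms, species_meta_from_config
from .topology import (
    ANION_SPECIES,
    CATION_SPECIES,
    SHEET_SPECIES,
    WATER_SPECIES,
    Topology,
)
from .trajectory import Frame, Trajectory

_BOND_STEP = 0.125  # nm, single-carbon seed step
_TWO_STEP = 0.25  # nm, |C(i-1)->C(i+1)|
_AXIS_LENGTH = {"default": 1.7, "CHOL": 0.8}  # nm, head -> terminal midpoint
_CHOL_PEAK_OFFSET = 0.4  # nm, sterol hydroxyl sits below the phosphate peak


@dataclass
class LeafletSpec:
    """Composition (species -> mole fraction) and lipid count of one leaflet."""

    composition: dict[str, float]
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("leaflet count must be >= 0")
        total = sum(self.composition.values())
        if self.count > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"leaflet fractions sum to {total}, expected 1")

    @property
    def chol_fraction(self) -> float:
        return self.composition.get("CHOL", 0.0)


def _default_outer() -> LeafletSpec:
    return LeafletSpec({"PC": 0.35, "SM": 0.35, "CHOL": 0.30}, 60)


def _default_inner() -> LeafletSpec:
    return LeafletSpec({"PE": 0.35, "PC": 0.30, "PS": 0.15, "CHOL": 0.20}, 60)


@dataclass
class BilayerSpec:
    """Everything the generator needs; defaults give a plasma-membrane-like patch.

    ``target_scd`` maps species to either a scalar (applied to every analysable
    carbon of every chain) or a list of per-chain per-carbon lists.
    ``tilt_mode_deg`` maps species to a scalar or to ``{"outer": .., "inner": ..}``.
    ``charge_profile`` is a list of ``(z_center_nm, sheet_density_e_per_nm2)``.
    """

    outer: LeafletSpec = field(default_factory=_default_outer)
    inner: LeafletSpec = field(default_factory=_default_inner)
    area_per_lipid: dict[str, float] = field(
        default_factory=lambda: {"CHOL": 0.3, "default": 0.6}
    )
    headgroup_peak_z: float = 1.95  # nm
    headgroup_sigma: float = 0.2  # nm
    target_scd: dict[str, object] = field(default_factory=lambda: {"default": 0.2})
    tilt_mode_deg: dict[str, object] = field(default_factory=lambda: {"default": 75.0})
    tilt_sd_deg: float = 4.0
    water_count: int = 1000
    charge_profile: list[tuple[float, float]] = field(default_factory=list)
    box_z: float = 10.0  # nm
    area_fluctuation_sd: float = 0.25  # nm^2
    area_ar1_phi: float = 0.9
    auto_neutralize: bool = True
    cation_count: int = 0
    anion_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.headgroup_peak_z <= 0:
            raise ValueError("headgroup_peak_z must be positive")
        if self.headgroup_peak_z + 0.5 >= self.box_z / 2:
            raise ValueError("box_z too small for the headgroup peaks plus water")
        for sp, val in self.target_scd.items():
            for v in np.ravel(np.array(val, dtype=object)):
                for x in np.ravel(np.array(v, dtype=float)):
                    if not -0.5 <= x <= 1.0:
                        raise ValueError(f"target SCD {x} for {sp} outside [-0.5, 1]")

    def apl(self, species: str) -> float:
        return self.area_per_lipid.get(species, self.area_per_lipid.get("default", 0.6))

    def base_area(self) -> float:
        """Lateral area from composition-weighted areas per lipid (mean of leaflets)."""
        areas = []
        for leaf in (self.outer, self.inner):
            counts = composition_counts(leaf.composition, leaf.count)
            areas.append(sum(n * self.apl(sp) for sp, n in counts.items()))
        return float(np.mean(areas))

    def scd_targets(self, species: str, chain_lengths: list[int]) -> list[np.ndarray]:
        """Per-chain arrays of target S_CD at the analysable carbons."""
        raw = self.target_scd.get(species, self.target_scd.get("default", 0.2))
        out = []
        for c, n_atoms in enumerate(chain_lengths):
            n_an = n_atoms - 2  # carbons with both neighbours present
            if np.isscalar(raw):
                out.append(np.full(n_an, float(raw)))
            else:
                vals = np.asarray(raw[c], dtype=float)
                if vals.size == 1:
                    out.append(np.full(n_an, float(vals)))
                elif vals.size == n_an:
                    out.append(vals.copy())
                else:
                    raise ValueError(
                        f"{species} chain {c}: {vals.size} SCD targets, need {n_an}"
                    )
        return out

    def tilt_mode(self, species: str, leaflet: str) -> float:
        raw = self.tilt_mode_deg.get(species, self.tilt_mode_deg.get("default", 75.0))
        if isinstance(raw, dict):
            return float(raw[leaflet])
        return float(raw)


@dataclass
class GroundTruth:
    """What the generator built in, for recovery tests."""

    thickness: float  # nm, 2 x headgroup_peak_z
    scd: dict[str, list[np.ndarray]]  # species -> per-chain target arrays
    tilt_modes: dict[tuple[str, str], float]  # (species, leaflet) -> degrees
    area_sd: float  # nm^2, realised population SD of the area series
    area_series: np.ndarray
    charge_sheets: list[tuple[float, float]]
    events: list[dict] = field(default_factory=list)
    tail_extent: tuple[float, float] = (0.0, 0.0)  # (inner |z| edge, outer |z| edge)


def _theta_from_scd(scd: np.ndarray) -> np.ndarray:
    """Polar angle (rad) with (3 cos^2 theta - 1)/2 = scd."""
    return np.arccos(np.sqrt((2.0 * np.asarray(scd) + 1.0) / 3.0))


def _build_chain(
    rng: np.random.Generator,
    n_mol: int,
    n_atoms: int,
    thetas: np.ndarray,
    sign: int,
) -> np.ndarray:
    """Chain skeletons (n_mol, n_atoms, 3) built from the two-step recurrence."""
    p = np.zeros((n_mol, n_atoms, 3))
    phi0 = rng.uniform(0, 2 * np.pi, n_mol)
    th0 = thetas[0] if thetas.size else math.radians(30.0)
    p[:, 1, 0] = _BOND_STEP * np.sin(th0) * np.cos(phi0)
    p[:, 1, 1] = _BOND_STEP * np.sin(th0) * np.sin(phi0)
    p[:, 1, 2] = -sign * _BOND_STEP * np.cos(th0)
    for j in range(1, n_atoms - 1):
        th = thetas[j - 1]
        phi = rng.uniform(0, 2 * np.pi, n_mol)
        u = np.stack(
            [
                np.sin(th) * np.cos(phi),
                np.sin(th) * np.sin(phi),
                np.full(n_mol, -sign * np.cos(th)),
            ],
            axis=1,
        )
        p[:, j + 1] = p[:, j - 1] + _TWO_STEP * u
    return p


def generate_bilayer_trajectory(
    spec: BilayerSpec,
    n_frames: int,
    dt: float = 100.0,
    species_config: dict | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a seeded bilayer trajectory plus its ground truth.

    ``dt`` is the frame spacing in ps.  All randomness comes from
    ``spec.seed``; identical specs give bit-identical trajectories.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    cfg = species_config or default_species_config()
    rng = np.random.default_rng(spec.seed)

    A0 = spec.base_area()
    L0 = math.sqrt(A0)
    Lz = spec.box_z
    peak = spec.headgroup_peak_z

    # ---- molecule bookkeeping --------------------------------------------
    groups = []  # (leaflet, species, molecule ids, lattice site indices)
    atoms = []
    molecules: dict[int, str] = {}
    mol_id = 0
    atom_id = 1
    coord_slices: dict[int, slice] = {}

    def add_molecule(species: str, charge_overrides=None) -> int:
        nonlocal mol_id, atom_id
        mol_id += 1
        mol_atoms = make_molecule_atoms(species, mol_id, atom_id, cfg, charge_overrides)
        coord_slices[mol_id] = slice(atom_id - 1, atom_id - 1 + len(mol_atoms))
        atom_id += len(mol_atoms)
        atoms.extend(mol_atoms)
        molecules[mol_id] = species
        return mol_id

    for leaflet, leaf in (("outer", spec.outer), ("inner", spec.inner)):
        counts = composition_counts(leaf.composition, leaf.count)
        n_leaf = sum(counts.values())
        m = math.ceil(math.sqrt(n_leaf)) if n_leaf else 1
        if m * m < n_leaf:
            raise ValueError("lattice overflow: counts inconsistent with box")
        site = 0
        for sp in sorted(counts):
            ids = []
            sites = []
            for _ in range(counts[sp]):
                ids.append(add_molecule(sp))
                sites.append(site)
                site += 1
            if ids:
                groups.append((leaflet, sp, ids, np.array(sites), m))

    water_ids = [add_molecule(WATER_SPECIES) for _ in range(spec.water_count)]

    n_cat = spec.cation_count
    n_ani = spec.anion_count
    if spec.auto_neutralize:
        q_lipid = sum(
            cfg[sp]["headgroup_charge"] * 1
            for sp in (molecules[m] for m in molecules)
            if sp in cfg and cfg[sp].get("chains")
        )
        # integer counterions for integer lipid charges
        n_cat += int(round(max(0.0, -q_lipid)))
        n_ani += int(round(max(0.0, q_lipid)))
    cation_ids = [add_molecule(CATION_SPECIES) for _ in range(n_cat)]
    anion_ids = [add_molecule(ANION_SPECIES) for _ in range(n_ani)]

    sheet_ids: list[list[int]] = []
    n_carrier = 25
    for z_c, sigma in spec.charge_profile:
        q_each = sigma * A0 / n_carrier
        ids = [
            add_molecule(SHEET_SPECIES, charge_overrides={"Q": q_each})
            for _ in range(n_carrier)
        ]
        sheet_ids.append(ids)

    meta = species_meta_from_config(cfg)
    top = Topology(atoms=atoms, molecules=molecules, species_meta=meta)
    n_atoms_total = len(atoms)

    # ---- area series ------------------------------------------------------
    sd = spec.area_fluctuation_sd
    phi = spec.area_ar1_phi
    areas = np.empty(n_frames)
    a = rng.normal(0.0, sd) if sd > 0 else 0.0
    innov_sd = sd * math.sqrt(1 - phi * phi) if sd > 0 else 0.0
    for k in range(n_frames):
        areas[k] = A0 + a
        a = phi * a + (rng.normal(0.0, innov_sd) if sd > 0 else 0.0)

    # ---- static per-molecule data ----------------------------------------
    # chain atom layout per species: index of P/E/O1 and chain atom indices
    layout: dict[str, dict] = {}
    for sp in {g[1] for g in groups}:
        names = [a["name"] for a in cfg[sp]["atoms"]]
        chains = cfg[sp]["chains"]
        layout[sp] = {
            "is_sterol": cfg[sp]["is_sterol"],
            "ref": names.index("O1" if cfg[sp]["is_sterol"] else "P"),
            "ester": names.index("E") if "E" in names else None,
            "chains": [[names.index(nm) for nm in ch] for ch in chains],
        }

    # water state (reflected walk within a side slab)
    w_lo, w_hi = peak + 0.3, Lz / 2 - 0.1
    n_w = len(water_ids)
    half = n_w // 2
    water_sign = np.array([1] * half + [-1] * (n_w - half))
    water_xy = rng.uniform(0, L0, (n_w, 2))
    water_z = rng.uniform(w_lo, w_hi, n_w) * water_sign

    ion_ids = cation_ids + anion_ids
    n_i = len(ion_ids)
    ion_sign = np.where(np.arange(n_i) % 2 == 0, 1, -1)
    ion_xy = rng.uniform(0, L0, (n_i, 2))
    ion_z = rng.uniform(w_lo, w_hi, n_i) * ion_sign

    def reflect(z, lo, hi):
        rng_width = hi - lo
        z = np.mod(z - lo, 2 * rng_width)
        z = np.where(z > rng_width, 2 * rng_width - z, z)
        return z + lo

    tail_abs_z: list[float] = []
    frames = []
    for k in range(n_frames):
        s = math.sqrt(areas[k] / A0)
        L = L0 * s
        coords = np.zeros((n_atoms_total, 3))

        for leaflet, sp, ids, sites, m in groups:
            sgn = 1 if leaflet == "outer" else -1
            lay = layout[sp]
            n_mol = len(ids)
            spacing = L / m
            gx = (sites % m + 0.5) * spacing
            gy = (sites // m + 0.5) * spacing
            jit = rng.normal(0.0, 0.03, (n_mol, 2))
            peak_sp = peak - (_CHOL_PEAK_OFFSET if lay["is_sterol"] else 0.0)
            head = np.stack(
                [
                    gx + jit[:, 0],
                    gy + jit[:, 1],
                    sgn * rng.normal(peak_sp, spec.headgroup_sigma, n_mol),
                ],
                axis=1,
            )
            alpha = np.clip(
                rng.normal(spec.tilt_mode(sp, leaflet), spec.tilt_sd_deg, n_mol),
                1.0,
                89.0,
            )
            alpha_r = np.radians(alpha)
            phi_a = rng.uniform(0, 2 * np.pi, n_mol)
            axis = np.stack(
                [
                    np.cos(alpha_r) * np.cos(phi_a),
                    np.cos(alpha_r) * np.sin(phi_a),
                    -sgn * np.sin(alpha_r),
                ],
                axis=1,
            )
            ell = _AXIS_LENGTH["CHOL"] if lay["is_sterol"] else _AXIS_LENGTH["default"]
            target_mid = head + ell * axis

            chain_lengths = [len(c) for c in lay["chains"]]
            scd = spec.scd_targets(sp, chain_lengths)
            chains_xyz = []
            for c_idx, idxs in enumerate(lay["chains"]):
                thetas = _theta_from_scd(scd[c_idx])
                chains_xyz.append(_build_chain(rng, n_mol, len(idxs), thetas, sgn))
            terminals = np.mean([ch[:, -1] for ch in chains_xyz], axis=0)
            shift = target_mid - terminals

            for mol_k, mol in enumerate(ids):
                sl = coord_slices[mol]
                block = coords[sl]
                block[lay["ref"]] = head[mol_k]
                if lay["ester"] is not None:
                    block[lay["ester"]] = head[mol_k] + np.array([0.1, 0.0, 0.0])
                for c_idx, idxs in enumerate(lay["chains"]):
                    block[idxs] = chains_xyz[c_idx][mol_k] + shift[mol_k]
            if k == 0:
                for c_idx, idxs in enumerate(lay["chains"]):
                    tail_abs_z.extend(
                        np.abs((chains_xyz[c_idx] + shift[:, None, :])[:, :, 2]).ravel()
                    )

        # waters: reflected walk in |z|, periodic drift in xy
        water_xy = np.mod(water_xy + rng.normal(0, 0.05, (n_w, 2)), L0)
        wz_abs = reflect(np.abs(water_z) + rng.normal(0, 0.05, n_w), w_lo, w_hi)
        water_z = wz_abs * water_sign
        for wi, mol in enumerate(water_ids):
            coords[coord_slices[mol].start] = (water_xy[wi, 0] * s, water_xy[wi, 1] * s, water_z[wi])

        if n_i:
            ion_xy = np.mod(ion_xy + rng.normal(0, 0.05, (n_i, 2)), L0)
            iz_abs = reflect(np.abs(ion_z) + rng.normal(0, 0.05, n_i), w_lo, w_hi)
            ion_z = iz_abs * ion_sign
            for ii, mol in enumerate(ion_ids):
                coords[coord_slices[mol].start] = (ion_xy[ii, 0] * s, ion_xy[ii, 1] * s, ion_z[ii])

        for (z_c, _sigma), ids in zip(spec.charge_profile, sheet_ids):
            grid = math.ceil(math.sqrt(len(ids)))
            for q_k, mol in enumerate(ids):
                coords[coord_slices[mol].start] = (
                    (q_k % grid + 0.5) * L0 / grid,
                    (q_k // grid + 0.5) * L0 / grid,
                    z_c,
                )

        frames.append(Frame(time=k * dt, box=np.array([L, L, Lz]), coords=coords))

    traj = Trajectory(topology=top, frames=frames, dt=dt)

    tilt_modes = {
        (sp, leaflet): spec.tilt_mode(sp, leaflet)
        for leaflet, sp, _ids, _sites, _m in groups
    }
    scd_truth = {
        sp: spec.scd_targets(sp, [len(c) for c in layout[sp]["chains"]])
        for sp in layout
    }
    tail_arr = np.array(tail_abs_z) if tail_abs_z else np.array([0.0])
    truth = GroundTruth(
        thickness=2 * peak,
        scd=scd_truth,
        tilt_modes=tilt_modes,
        area_sd=float(np.std(areas)),
        area_series=areas,
        charge_sheets=list(spec.charge_profile),
        tail_extent=(float(tail_arr.min()), float(tail_arr.max())),
    )
    return traj, truth


# ---------------------------------------------------------------------------
# permeation-event injection
# ---------------------------------------------------------------------------


def inject_permeation_events(
    traj: Trajectory,
    events: list[tuple[int, str, int, int]],
    bounds: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[Trajectory, list[dict]]:
    """Rewrite chosen waters' z-paths into clean membrane crossings.

    ``events`` entries are ``(water molecule_id, direction, entry_frame,
    dwell_frames)`` with direction ``outer_to_inner`` (enters from z > upper
    bound) or ``inner_to_outer``.  The rewritten path is monotone in z,
    strictly inside the bounds for exactly ``dwell_frames`` frames, and sits
    well outside before entry and after exit.  Returns the new trajectory and
    the injected ground-truth event records.
    """
    if bounds is None:
        peak = max(abs(fr.coords[:, 2]).max() for fr in traj.frames[:1])
        bounds = (-0.75 * peak, 0.75 * peak)
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("bounds must satisfy lower < upper")
    rng = np.random.default_rng(seed)
    n_frames = traj.n_frames
    water_set = set(traj.topology.water_molecule_ids())
    windows: dict[int, list[tuple[int, int]]] = {}
    truth = []

    mol_atoms = traj.topology.molecule_atom_indices()
    new_frames = [
        Frame(time=fr.time, box=fr.box.copy(), coords=fr.coords.copy())
        for fr in traj.frames
    ]

    margin = 0.8
    delta = 0.05 * (hi - lo)
    per_water: dict[int, list[tuple[int, str, int]]] = {}
    for water_id, direction, entry, dwell in events:
        if water_id not in water_set:
            raise ValueError(f"molecule {water_id} is not a water")
        if direction not in ("outer_to_inner", "inner_to_outer"):
            raise ValueError(f"unknown direction {direction!r}")
        if entry < 1:
            raise ValueError("entry frame must be >= 1 (need one frame outside first)")
        if dwell < 1:
            raise ValueError("dwell must be at least one frame")
        if entry + dwell >= n_frames:
            raise ValueError("dwell frames exceed the remaining frames")
        for a, b in windows.get(water_id, []):
            if not (entry + dwell < a or entry - 1 > b):
                raise ValueError(f"overlapping event windows for water {water_id}")
        windows.setdefault(water_id, []).append((entry - 1, entry + dwell))
        per_water.setdefault(water_id, []).append((entry, direction, dwell))

    def side_z(side: str) -> float:
        return hi + margin if side == "above" else lo - margin

    for water_id, evts in per_water.items():
        evts.sort()
        atom = mol_atoms[water_id][0]
        z_path = np.empty(n_frames)
        # frames before the first event sit on its entry side
        first_side = "above" if evts[0][1] == "outer_to_inner" else "below"
        cursor = 0
        side = first_side
        for entry, direction, dwell in evts:
            z_path[cursor:entry] = side_z(
                "above" if direction == "outer_to_inner" else "below"
            ) + rng.normal(0, 0.02, entry - cursor)
            if direction == "outer_to_inner":
                inside = np.linspace(hi - delta, lo + delta, dwell)
                side = "below"
            else:
                inside = np.linspace(lo + delta, hi - delta, dwell)
                side = "above"
            z_path[entry : entry + dwell] = inside
            cursor = entry + dwell
            truth.append(
                {
                    "water_id": water_id,
                    "direction": direction,
                    "entry_frame": entry,
                    "exit_frame": entry + dwell,
                    "dwell_frames": dwell,
                    "dwell_time": dwell * traj.dt,
                }
            )
        z_path[cursor:] = side_z(side) + rng.normal(0, 0.02, n_frames - cursor)
        # clamp jitter away from the bounds
        outside = np.ones(n_frames, dtype=bool)
        for entry, _d, dwell in evts:
            outside[entry : entry + dwell] = False
        z_path[outside & (z_path > lo) & (z_path < hi)] = np.sign(
            z_path[outside & (z_path > lo) & (z_path < hi)]
        ) * (hi + margin)
        for k in range(n_frames):
            new_frames[k].coords[atom, 2] = z_path[k]
            new_frames[k].coords[atom, 0:2] += rng.normal(0, 0.01, 2)
    truth.sort(key=lambda e: (e["entry_frame"], e["water_id"]))
    return Trajectory(topology=traj.topology, frames=new_frames, dt=traj.dt), truth


# ---------------------------------------------------------------------------
# assembly realisation (planner bridge)
# ---------------------------------------------------------------------------


def realize_assembly(plan, spec: BilayerSpec, n_frames: int = 1):
    """Build a starting structure for an assembly plan.

    Single-bilayer plans delegate straight to the generator.  Double-bilayer
    plans generate one bilayer, mirror it in z and stack the two so both
    inner leaflets face the interior compartment, then add the per-compartment
    ions.  Returns ``(Trajectory, manifest)``.
    """
    from .topology import AtomRecord

    if plan.double_bilayer:
        # the plan's compartment ions and counterions are authoritative; the
        # generator must not add its own
        spec.auto_neutralize = False
    else:
        spec.cation_count += plan.ions.get("exterior", {}).get("cation", 0)
        spec.anion_count += plan.ions.get("exterior", {}).get("anion", 0)
        if plan.extra_cations:
            # counterions already booked by the plan supersede auto-neutralisation
            spec.auto_neutralize = False
            spec.cation_count += sum(plan.extra_cations.values())
    traj, _truth = generate_bilayer_trajectory(spec, n_frames=n_frames)
    manifest = {
        "label": plan.label,
        "double_bilayer": plan.double_bilayer,
        "leaflets": {
            "outer": dict(plan.outer.counts),
            "inner": dict(plan.inner.counts),
        },
        "ions": {k: dict(v) for k, v in plan.ions.items()},
        "extra_cations": dict(plan.extra_cations),
    }
    if not plan.double_bilayer:
        manifest["box"] = [float(x) for x in traj.frames[0].box]
        return traj, manifest

    top = traj.topology
    cfg = default_species_config()
    Lz_single = spec.box_z
    z_shift = Lz_single / 2 + 0.5  # bilayer centres at +/- z_shift
    Lz_total = 2 * Lz_single + 2.0

    atoms: list[AtomRecord] = []
    molecules: dict[int, str] = {}
    next_mol, next_atom = 1, 1

    def clone_atoms(offset_mol: int):
        nonlocal next_mol, next_atom
        mapping = {}
        for a in top.atoms:
            mol = a.molecule_id + offset_mol
            if mol not in mapping:
                mapping[a.molecule_id] = mol
            atoms.append(
                AtomRecord(
                    atom_id=next_atom,
                    name=a.name,
                    species=a.species,
                    molecule_id=mol,
                    mass=a.mass,
                    charge=a.charge,
                    role=a.role,
                    chain=a.chain,
                    tail_index=a.tail_index,
                )
            )
            molecules[mol] = a.species
            next_atom += 1
        next_mol = max(molecules) + 1

    n_mol_single = max(top.molecules)
    clone_atoms(0)  # upper bilayer (kept orientation, centred at +z_shift)
    clone_atoms(n_mol_single)  # lower bilayer (z-mirrored, centred at -z_shift)

    # per-compartment ions
    ion_records = []
    for comp, counts in plan.ions.items():
        for _ in range(counts.get("cation", 0) + plan.extra_cations.get(comp, 0)):
            ion_records.append((comp, CATION_SPECIES))
        for _ in range(counts.get("anion", 0)):
            ion_records.append((comp, ANION_SPECIES))
    for comp, sp in ion_records:
        for rec in make_molecule_atoms(sp, next_mol, next_atom, cfg):
            atoms.append(rec)
        molecules[next_mol] = sp
        next_mol += 1
        next_atom += 1

    meta = species_meta_from_config(cfg)
    big_top = Topology(atoms=atoms, molecules=molecules, species_meta=meta)

    rng = np.random.default_rng(spec.seed + 1)
    n_single = top.n_atoms
    new_frames = []
    for fr in traj.frames:
        L = fr.box[0]
        coords = np.zeros((len(atoms), 3))
        upper = fr.coords.copy()
        upper[:, 2] += z_shift
        lower = fr.coords.copy()
        lower[:, 2] = -lower[:, 2] - z_shift
        coords[:n_single] = upper
        coords[n_single : 2 * n_single] = lower
        # ions: interior waters live between the bilayers, exterior outside
        k = 2 * n_single
        int_hw = z_shift - spec.headgroup_peak_z - 0.3
        for comp, _sp in ion_records:
            xy = rng.uniform(0, L, 2)
            if comp == "interior":
                z = rng.uniform(-int_hw, int_hw)
            else:
                side = rng.choice([-1, 1])
                z = side * rng.uniform(z_shift + spec.headgroup_peak_z + 0.3, Lz_total / 2 - 0.1)
            coords[k] = (xy[0], xy[1], z)
            k += 1
        new_frames.append(
            Frame(time=fr.time, box=np.array([L, L, Lz_total]), coords=coords)
        )
    big = Trajectory(topology=big_top, frames=new_frames, dt=traj.dt)
    manifest["box"] = [float(x) for x in new_frames[0].box]
    return big, manifest
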