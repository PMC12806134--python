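"""Frames, trajectories, recentring and leaflet assignment.

The membrane normal is fixed to the z axis throughout: the systems this
package handles are planar bilayers.  Frames are recentred so the lipid
centre of mass sits at z = 0, which makes leaflet membership a sign test
on the reference atom's z coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .topology import Topology


@dataclass
class Frame:
    """One configuration: time (ps), orthorhombic box (nm) and coordinates (nm)."""

    time: float
    box: np.ndarray  # (3,) Lx, Ly, Lz
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,):
            raise ValueError("box must be (Lx, Ly, Lz)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")

    @property
    def area(self) -> float:
        """Lateral area Lx*Ly in nm^2."""
        return float(self.box[0] * self.box[1])


@dataclass
class Trajectory:
    """An ordered sequence of frames bound to a topology; dt is the frame spacing in ps."""

    topology: Topology
    frames: list[Frame]
    dt: float

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise ValueError(
                    f"frame {k}: {fr.coords.shape[0]} atoms, topology has {n}"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise ValueError("frame spacing must be constant")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def coords_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass
class LeafletAssignment:
    """Molecule → leaflet map ('outer' above the midplane, 'inner' below)."""

    assignment: dict[int, str]
    midplane_z: float = 0.0
    per_frame: list[dict[int, str]] = field(default_factory=list, repr=False)

    def molecule_ids(self, leaflet: str) -> set[int]:
        return {m for m, l in self.assignment.items() if l == leaflet}

    def n_flips(self) -> int:
        """Frame-to-frame assignment changes (flip-flop indicator)."""
        flips = 0
        for a, b in zip(self.per_frame, self.per_frame[1:]):
            flips += sum(1 for m in a if a[m] != b.get(m, a[m]))
        return flips


def recenter_frames(traj: Trajectory, molecule_ids=None) -> Trajectory:
    """Translate each frame along z so the selection's centre of mass is at z = 0.

    ``molecule_ids`` defaults to all lipid molecules.  x and y are untouched,
    so all pairwise distances are preserved.
    """
    if molecule_ids is None:
        molecule_ids = traj.topology.lipid_molecule_ids()
    molecule_ids = set(molecule_ids)
    if not molecule_ids:
        raise ValueError("recentring selection is empty")
    idx = traj.topology.atom_indices(molecule_ids=molecule_ids)
    if idx.size == 0:
        raise ValueError("recentring selection matches no atoms")
    masses = traj.topology.masses()[idx]
    new_frames = []
    for fr in traj.frames:
        com_z = float(np.average(fr.coords[idx, 2], weights=masses))
        shifted = fr.coords.copy()
        shifted[:, 2] -= com_z
        new_frames.append(Frame(time=fr.time, box=fr.box.copy(), coords=shifted))
    return Trajectory(topology=traj.topology, frames=new_frames, dt=traj.dt)


def _reference_index(top: Topology, mol_atoms: list[int], is_sterol: bool) -> int:
    want = "hydroxyl_ref" if is_sterol else "headgroup_ref"
    for i in mol_atoms:
        if top.atoms[i].role == want:
            return i
    raise ValueError(
        f"molecule {top.atoms[mol_atoms[0]].molecule_id}: no {want} atom"
    )


def assign_leaflets(traj: Trajectory, frames: list[int] | None = None) -> LeafletAssignment:
    """Assign every lipid molecule to the outer (z > 0) or inner (z < 0) leaflet.

    Requires recentred frames.  Phospholipids are classified by the sign of
    their headgroup reference atom's z, sterols by their hydroxyl reference.
    The per-trajectory assignment is the modal per-frame assignment; frames
    where a molecule deviates from its mode indicate flip-flop and are kept
    in ``per_frame``.
    """
    top = traj.topology
    mol_atoms = top.molecule_atom_indices()
    lipids = top.lipid_molecule_ids()
    if not lipids:
        raise ValueError("no lipid molecules to assign")
    refs = {
        m: _reference_index(top, mol_atoms[m], top.species_meta[top.molecules[m]].is_sterol)
        for m in lipids
    }
    which = range(traj.n_frames) if frames is None else frames
    per_frame: list[dict[int, str]] = []
    for k in which:
        coords = traj.frames[k].coords
        per_frame.append(
            {m: ("outer" if coords[refs[m], 2] > 0 else "inner") for m in lipids}
        )
    modal = {
        m: Counter(fr[m] for fr in per_frame).most_common(1)[0][0] for m in lipids
    }
    return LeafletAssignment(assignment=modal, midplane_z=0.0, per_frame=per_frame)
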