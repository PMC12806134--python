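"""Coordinate I/O: fixed-column GRO and PDB (ATOM/HETATM, CRYST1, MODEL).

Coordinates are stored internally in nm; the PDB dialect converts Å↔nm at
this boundary.  Velocities in GRO files are ignored.  Topologies are bound
either from an explicit :class:`~memasym.topology.Topology` (e.g. the
manifest sidecar) or resolved from a species-metadata config by residue
name and atom name.
"""

from __future__ import annotations

import numpy as np

from .species import default_species_config, make_molecule_atoms, species_meta_from_config
from .topology import Topology
from .trajectory import Frame, Trajectory


class ParseError(ValueError):
    """A malformed record in a coordinate file; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# raw frame parsing: (resids, resnames, atomnames, coords, box, time) tuples
# ---------------------------------------------------------------------------


def _parse_gro(path) -> list[tuple]:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                time = None
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(path, i + 2, "expected atom count")
        if i + 2 + natoms >= n_lines + 1:
            raise ParseError(path, i + 2, f"file truncated: {natoms} atoms declared")
        resids, resnames, names = [], [], []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            ln = lines[i + 2 + k].rstrip("\n")
            lineno = i + 3 + k
            if len(ln) < 44:
                raise ParseError(path, lineno, "GRO atom line shorter than 44 columns")
            try:
                resids.append(int(ln[0:5]))
                resnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
                coords[k] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
            except ValueError as e:
                raise ParseError(path, lineno, f"malformed GRO atom line: {e}")
        box_idx = i + 2 + natoms
        if box_idx >= n_lines:
            raise ParseError(path, box_idx + 1, "missing box line")
        try:
            box_vals = [float(x) for x in lines[box_idx].split()]
            box = np.array(box_vals[:3])
        except (ValueError, IndexError):
            raise ParseError(path, box_idx + 1, "malformed box line")
        if len(box_vals) < 3:
            raise ParseError(path, box_idx + 1, "missing box line")
        frames.append((resids, resnames, names, coords, box, time))
        i = box_idx + 1
    if not frames:
        raise ParseError(path, 1, "no frames found")
    return frames


def _parse_pdb(path) -> list[tuple]:
    frames = []
    box = None
    cur: list | None = None
    in_model = False

    def flush(lineno):
        nonlocal cur
        if cur is None or not cur[0]:
            return
        if box is None:
            raise ParseError(path, lineno, "no CRYST1 record (missing box)")
        resids, resnames, names, xyz, times = cur
        frames.append((resids, resnames, names, np.array(xyz) / 10.0, box / 10.0, times))
        cur = None

    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            rec = ln[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array([float(ln[6:15]), float(ln[15:24]), float(ln[24:33])])
                except ValueError:
                    raise ParseError(path, lineno, "malformed CRYST1 record")
            elif rec == "MODEL":
                flush(lineno)
                cur = [[], [], [], [], None]
                in_model = True
            elif rec == "ENDMDL":
                flush(lineno)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                if cur is None:
                    cur = [[], [], [], [], None]
                try:
                    cur[0].append(int(ln[22:26]))
                    cur[1].append(ln[17:21].strip())
                    cur[2].append(ln[12:16].strip())
                    cur[3].append([float(ln[30:38]), float(ln[38:46]), float(ln[46:54])])
                except ValueError as e:
                    raise ParseError(path, lineno, f"malformed ATOM record: {e}")
    flush(-1)
    if not frames:
        raise ParseError(path, 1, "no ATOM/HETATM records found")
    return frames


# ---------------------------------------------------------------------------
# topology binding
# ---------------------------------------------------------------------------


def _build_topology(resids, resnames, names, cfg: dict) -> Topology:
    """Group atoms into molecules by residue-id change and resolve per-atom metadata."""
    meta = species_meta_from_config(cfg)
    atoms = []
    molecules: dict[int, str] = {}
    mol = 0
    prev_key = None
    for k, (rid, rname, aname) in enumerate(zip(resids, resnames, names)):
        key = (rid, rname)
        if key != prev_key:
            mol += 1
            molecules[mol] = rname
            prev_key = key
        if rname not in cfg:
            raise KeyError(f"residue {rname!r} not in species config")
        rec = next((a for a in cfg[rname]["atoms"] if a["name"] == aname), None)
        if rec is None:
            raise KeyError(f"atom {aname!r} not defined for species {rname!r}")
        atoms.extend(
            make_molecule_atoms(rname, mol, k + 1, {rname: {"atoms": [rec]}})
        )
    return Topology(atoms=atoms, molecules=molecules, species_meta=meta)


def read_coordinates(
    path,
    dialect: str,
    topology: Topology | None = None,
    species_config: dict | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Read a GRO or PDB file into a Trajectory.

    If ``topology`` is given (e.g. loaded from a manifest sidecar) atoms are
    bound to it positionally; otherwise a topology is resolved from residue
    and atom names via ``species_config`` (package defaults if omitted).
    ``dt`` (ps) is used when the file carries no time stamps.
    """
    if dialect == "gro":
        raw = _parse_gro(path)
    elif dialect == "pdb":
        raw = _parse_pdb(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    n0 = len(raw[0][0])
    for k, fr in enumerate(raw):
        if len(fr[0]) != n0:
            raise ParseError(path, 0, f"frame {k} has {len(fr[0])} atoms, frame 0 has {n0}")

    if topology is None:
        resids, resnames, names = raw[0][0], raw[0][1], raw[0][2]
        topology = _build_topology(resids, resnames, names, species_config or default_species_config())
    elif topology.n_atoms != n0:
        raise ValueError(f"topology has {topology.n_atoms} atoms, file has {n0}")

    times = [fr[5] for fr in raw]
    if any(t is None for t in times) or len(set(times)) != len(times):
        times = [k * dt for k in range(len(raw))]
    elif len(times) > 1:
        dt = times[1] - times[0]

    frames = [
        Frame(time=t, box=fr[4], coords=fr[3]) for t, fr in zip(times, raw)
    ]
    return Trajectory(topology=topology, frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_coordinates(traj: Trajectory, path, dialect: str) -> None:
    """Write a trajectory as GRO (nm, 3 decimals) or PDB (Å, MODEL/ENDMDL)."""
    if not traj.frames:
        raise ValueError("cannot write an empty trajectory")
    top = traj.topology
    if dialect == "gro":
        with open(path, "w") as fh:
            for fr in traj.frames:
                fh.write(f"memasym t= {fr.time:.4f}\n{top.n_atoms}\n")
                for a, xyz in zip(top.atoms, fr.coords):
                    fh.write(
                        f"{a.molecule_id % 100000:5d}{a.species:<5.5s}{a.name:>5.5s}"
                        f"{a.atom_id % 100000:5d}"
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n"
                    )
                fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")
    elif dialect == "pdb":
        with open(path, "w") as fh:
            b = traj.frames[0].box * 10.0
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            for k, fr in enumerate(traj.frames, start=1):
                fh.write(f"MODEL     {k:4d}\n")
                for a, xyz in zip(top.atoms, fr.coords):
                    x, y, z = xyz * 10.0
                    fh.write(
                        f"ATOM  {a.atom_id % 100000:5d} {a.name:<4.4s} "
                        f"{a.species:<4.4s}A{a.molecule_id % 10000:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
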