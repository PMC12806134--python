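"""Structural observables: lateral area, density profiles, thickness,
tilt distributions and acyl-chain order parameters.

Conventions
-----------
- The membrane normal is z; profiles are binned along z on a uniform grid.
- Membrane thickness is the distance between the maximum-density bin of
  each leaflet (z < 0 vs z > 0), with three-point parabolic refinement so
  the estimate is not pinned to bin centres.
- The tilt angle is measured between the molecular axis and the bilayer
  *plane*: 90 deg means perpendicular to the plane (upright lipid), 0 deg
  in-plane.  Axes: sterols run hydroxyl -> last chain carbon; phospholipids
  run headgroup -> midpoint of the two terminal chain carbons.
- S_CD(i) = <(3 cos^2 theta - 1)/2> where theta is the angle between the
  C(i-1)->C(i+1) vector and z, averaged over molecules and frames.  The
  two-neighbour vector stands in for the C-H bond direction on chains
  without explicit hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import LeafletAssignment, Trajectory


# ---------------------------------------------------------------------------
# lateral area
# ---------------------------------------------------------------------------


@dataclass
class AreaStats:
    """Per-frame lateral area series with mean, population SD and per-leaflet APL."""

    series: np.ndarray  # nm^2 per frame
    mean: float
    sd: float  # population standard deviation
    area_per_lipid: dict[str, float]  # leaflet -> nm^2


def lateral_area_stats(traj: Trajectory, leaflets: LeafletAssignment) -> AreaStats:
    """Monitor the lateral box area and derive per-leaflet area per lipid."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    series = np.array([fr.area for fr in traj.frames])
    mean = float(series.mean())
    apl = {}
    for leaflet in ("outer", "inner"):
        n = len(leaflets.molecule_ids(leaflet))
        if n == 0:
            raise ValueError(f"no lipids assigned to the {leaflet} leaflet")
        apl[leaflet] = mean / n
    return AreaStats(series=series, mean=mean, sd=float(series.std()), area_per_lipid=apl)


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Binned density along z: mass (amu/nm^3) or charge (e/nm^3)."""

    bin_edges: np.ndarray  # nm, uniform
    values: np.ndarray
    weight: str  # "mass" or "charge"
    label: str = ""
    mean_area: float = 0.0  # nm^2, used for the bin volume

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def integral(self) -> float:
        """Integral of the profile over z times the mean area = total weight."""
        return float(self.values.sum() * self.bin_width * self.mean_area)


def density_profile(
    traj: Trajectory,
    atom_indices,
    bin_width: float = 0.1,
    weight: str = "mass",
    label: str = "",
    z_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Frame-averaged density of the selected atoms along z.

    Each frame's selected z coordinates are histogrammed with the chosen
    weights (atom masses or partial charges), divided by the bin volume
    (mean lateral area x bin width) and averaged over frames.  Atoms outside
    the range are wrapped back in along z so the profile conserves the total
    selected mass or charge for every selection and bin width.
    """
    atom_indices = np.asarray(atom_indices, dtype=int)
    if atom_indices.size == 0:
        raise ValueError("empty selection")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if weight == "mass":
        w = traj.topology.masses()[atom_indices]
    elif weight == "charge":
        w = traj.topology.charges()[atom_indices]
    else:
        raise ValueError(f"unknown weight {weight!r}")

    if z_range is None:
        lz = max(float(fr.box[2]) for fr in traj.frames)
        z_range = (-lz / 2, lz / 2)
    lo, hi = z_range
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    hist = np.zeros(n_bins)
    mean_area = float(np.mean([fr.area for fr in traj.frames]))
    for fr in traj.frames:
        z = fr.coords[atom_indices, 2]
        z = lo + np.mod(z - lo, n_bins * bin_width)  # wrap into range
        idx = np.minimum((z - lo) / bin_width, n_bins - 1).astype(int)
        hist += np.bincount(idx, weights=w, minlength=n_bins)
    values = hist / (traj.n_frames * mean_area * bin_width)
    return DensityProfile(
        bin_edges=edges, values=values, weight=weight, label=label, mean_area=mean_area
    )


def _parabolic_peak(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Refine the maximum at index k by a three-point parabola."""
    if k == 0 or k == len(y) - 1:
        return float(x[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[k])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[k] + delta * (x[1] - x[0]))


def _windowed_quadratic_peak(x: np.ndarray, y: np.ndarray, k: int, half_window: int = 3) -> float:
    """Apex of a least-squares parabola over +/-half_window bins around the maximum.

    More robust than the three-point rule when individual bins are noisy
    (finite-sample histograms); falls back to the bin centre at the edges.
    """
    lo, hi = max(0, k - half_window), min(len(y), k + half_window + 1)
    if hi - lo < 3:
        return float(x[k])
    coeff = np.polyfit(x[lo:hi], y[lo:hi], 2)
    if coeff[0] >= 0:  # not concave: noisy plateau, keep the bin centre
        return float(x[k])
    apex = -coeff[1] / (2 * coeff[0])
    lo_x, hi_x = x[lo], x[hi - 1]
    return float(np.clip(apex, lo_x, hi_x))


def membrane_thickness(profile: DensityProfile) -> float:
    """Peak-to-peak distance between the two leaflets' density maxima (nm).

    The maximum-density bin is located separately for z < 0 and z > 0 and
    refined by parabolic interpolation.  A side with no interior peak (a
    monotone profile) raises an error.
    """
    z = profile.bin_centers
    v = profile.values
    out = []
    for mask in (z < 0, z > 0):
        if not np.any(mask):
            raise ValueError("profile does not cover both leaflets")
        zi, vi = z[mask], v[mask]
        k = int(np.argmax(vi))
        interior = 0 < k < len(vi) - 1
        if not interior or vi[k] <= 0:
            raise ValueError("no leaflet peak on one side of the midplane")
        out.append(_parabolic_peak(zi, vi, k))
    return float(out[1] - out[0])


# ---------------------------------------------------------------------------
# tilt distributions
# ---------------------------------------------------------------------------


@dataclass
class TiltDistribution:
    """Normalised histogram of axis-to-plane angles with the refined mode."""

    species: str
    leaflet: str
    bin_edges: np.ndarray  # degrees over [0, 90]
    density: np.ndarray  # sums to 1
    mode_deg: float
    angles_mean: float
    angles_sem: float


def _molecule_axes(traj: Trajectory, species: str, molecule_ids: list[int]):
    """(n_frames, n_mol, 3) molecular axis vectors for one species."""
    top = traj.topology
    meta = top.species_meta[species]
    mol_atoms = top.molecule_atom_indices()
    starts, end_a, end_b = [], [], []
    for m in molecule_ids:
        idxs = mol_atoms[m]
        by_name = {top.atoms[i].name: i for i in idxs}
        chains = meta.chains
        if meta.is_sterol:
            starts.append(by_name["O1"])
            end_a.append(by_name[chains[0][-1]])
            end_b.append(by_name[chains[0][-1]])
        else:
            starts.append(by_name["P"])
            end_a.append(by_name[chains[0][-1]])
            end_b.append(by_name[chains[1][-1]])
    starts = np.array(starts)
    end_a = np.array(end_a)
    end_b = np.array(end_b)
    axes = np.empty((traj.n_frames, len(molecule_ids), 3))
    for k, fr in enumerate(traj.frames):
        tip = 0.5 * (fr.coords[end_a] + fr.coords[end_b])
        axes[k] = tip - fr.coords[starts]
    return axes


def tilt_distribution(
    traj: Trajectory,
    species: str,
    leaflets: LeafletAssignment,
    leaflet: str = "outer",
    bin_width_deg: float = 1.0,
) -> TiltDistribution:
    """Distribution of the molecular axis angle to the bilayer plane.

    angle = arcsin(|axis_z| / |axis|), in [0, 90] degrees; the mode is the
    maximal histogram bin centre refined parabolically.  Zero-length axes are
    skipped with a warning; an error is raised if every molecule is skipped.
    """
    mols = [
        m
        for m in sorted(leaflets.molecule_ids(leaflet))
        if traj.topology.molecules[m] == species
    ]
    if not mols:
        raise ValueError(f"species {species!r} absent from the {leaflet} leaflet")
    axes = _molecule_axes(traj, species, mols)
    norms = np.linalg.norm(axes, axis=2)
    ok = norms > 1e-12
    if not np.any(ok):
        raise ValueError("all molecular axes are degenerate")
    if not np.all(ok):
        import warnings

        warnings.warn(f"{np.sum(~ok)} degenerate axes skipped", stacklevel=2)
    angles = np.degrees(np.arcsin(np.abs(axes[:, :, 2][ok]) / norms[ok]))
    n_bins = int(round(90.0 / bin_width_deg))
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    density = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = _windowed_quadratic_peak(centers, density.astype(float), int(np.argmax(density)))
    per_frame = np.degrees(
        np.arcsin(np.clip(np.abs(axes[:, :, 2]) / np.maximum(norms, 1e-12), 0, 1))
    ).mean(axis=1)
    sem = float(per_frame.std(ddof=1) / np.sqrt(len(per_frame))) if len(per_frame) > 1 else 0.0
    return TiltDistribution(
        species=species,
        leaflet=leaflet,
        bin_edges=edges,
        density=density,
        mode_deg=float(np.clip(mode, 0.0, 90.0)),
        angles_mean=float(angles.mean()),
        angles_sem=sem,
    )


# ---------------------------------------------------------------------------
# chain order parameters
# ---------------------------------------------------------------------------


@dataclass
class OrderParameterProfile:
    """Per-carbon S_CD with standard errors across frames."""

    species: str
    chain_index: int
    leaflet: str
    carbons: np.ndarray  # carbon indices (3 .. N-1)
    s_cd: np.ndarray
    sem: np.ndarray

    def difference(self, other: "OrderParameterProfile") -> np.ndarray:
        """Elementwise S_CD difference against a matching profile."""
        if not np.array_equal(self.carbons, other.carbons):
            raise ValueError("profiles cover different carbons")
        return self.s_cd - other.s_cd


def chain_order_parameters(
    traj: Trajectory,
    species: str,
    chain_index: int,
    leaflets: LeafletAssignment,
    leaflet: str = "outer",
) -> OrderParameterProfile:
    """S_CD(i) from the C(i-1)->C(i+1) vector, per leaflet.

    The average runs over molecules and frames; the standard error is across
    frame means.
    """
    top = traj.topology
    meta = top.species_meta[species]
    if chain_index >= len(meta.chains):
        raise ValueError(f"species {species!r} has no chain {chain_index}")
    chain_names = meta.chains[chain_index]
    if len(chain_names) < 3:
        raise ValueError("chain must have at least 3 carbons")
    mols = [
        m
        for m in sorted(leaflets.molecule_ids(leaflet))
        if top.molecules[m] == species
    ]
    if not mols:
        raise ValueError(f"species {species!r} absent from the {leaflet} leaflet")
    mol_atoms = top.molecule_atom_indices()
    rows = []
    for m in mols:
        by_name = {top.atoms[i].name: i for i in mol_atoms[m]}
        rows.append([by_name[nm] for nm in chain_names])
    idx = np.array(rows)  # (n_mol, n_chain)

    per_frame = np.empty((traj.n_frames, idx.shape[1] - 2))
    for k, fr in enumerate(traj.frames):
        pos = fr.coords[idx]  # (n_mol, n_chain, 3)
        vec = pos[:, 2:] - pos[:, :-2]  # C(i-1) -> C(i+1)
        cos2 = vec[:, :, 2] ** 2 / np.einsum("mcx,mcx->mc", vec, vec)
        per_frame[k] = ((3.0 * cos2 - 1.0) / 2.0).mean(axis=0)
    s_cd = per_frame.mean(axis=0)
    sem = (
        per_frame.std(axis=0, ddof=1) / np.sqrt(traj.n_frames)
        if traj.n_frames > 1
        else np.zeros_like(s_cd)
    )
    carbons = np.arange(3, 3 + s_cd.size)
    return OrderParameterProfile(
        species=species,
        chain_index=chain_index,
        leaflet=leaflet,
        carbons=carbons,
        s_cd=s_cd,
        sem=sem,
    )
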