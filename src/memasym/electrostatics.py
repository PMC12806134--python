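"""Transmembrane electrostatic potential from charge-density profiles.

The potential follows from the one-dimensional Poisson equation: the
binned charge density rho_q(z) (explicit charges, relative permittivity 1)
is integrated twice from the lower box edge with psi = 0 and dpsi/dz = 0
there,

    psi(z) = -(1/eps0) int_z0^z dz' int_z0^{z'} rho_q(z'') dz''.

Reported quantities are region *differences* (exterior minus interior), so
the reference choice is cosmetic; no periodic dipole correction is applied
(it cancels for the symmetric double-bilayer setups this targets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .structure import DensityProfile
from .units import E_PER_NM2_OVER_EPS0_V_PER_NM


@dataclass
class RegionSpec:
    """Aqueous-region bounds: interior |z| < interior_bound, exterior |z| > exterior_bound."""

    interior_bound: float = 3.0  # nm
    exterior_bound: float = 11.0  # nm

    def __post_init__(self) -> None:
        if self.interior_bound >= self.exterior_bound:
            raise ValueError("interior bound must be smaller than exterior bound")


@dataclass
class PotentialProfile:
    """psi(z) in mV on the charge-density grid, referenced to the lower box edge."""

    z: np.ndarray  # bin centres, nm
    psi_mv: np.ndarray
    charge_density: np.ndarray  # e/nm^3
    reference: str = "psi=0, dpsi/dz=0 at lower box edge"


def potential_profile(charge_density: DensityProfile) -> PotentialProfile:
    """Double-integrate a charge-weighted density profile into psi(z) (mV)."""
    if charge_density.weight != "charge":
        raise ValueError("potential_profile needs a charge-weighted profile")
    z = charge_density.bin_centers
    widths = np.diff(charge_density.bin_edges)
    if not np.allclose(widths, widths[0], rtol=0, atol=1e-9):
        raise ValueError("charge-density grid must be uniform")
    rho = charge_density.values  # e/nm^3
    # field E(z) = (1/eps0) int rho dz', in V/nm
    field = cumulative_trapezoid(rho, z, initial=0.0) * E_PER_NM2_OVER_EPS0_V_PER_NM
    psi_v = -cumulative_trapezoid(field, z, initial=0.0)
    return PotentialProfile(z=z.copy(), psi_mv=psi_v * 1e3, charge_density=rho.copy())


def region_potential_difference(profile: PotentialProfile, regions: RegionSpec) -> float:
    """Mean psi over the exterior minus mean psi over the interior, mV.

    Positive when the exterior potential is the higher one.
    """
    interior = np.abs(profile.z) < regions.interior_bound
    exterior = np.abs(profile.z) > regions.exterior_bound
    for name, mask in (("interior", interior), ("exterior", exterior)):
        if np.count_nonzero(mask) < 3:
            raise ValueError(f"{name} region contains fewer than 3 grid points")
    return float(profile.psi_mv[exterior].mean() - profile.psi_mv[interior].mean())


def sheet_potential(z, sheets) -> np.ndarray:
    """Closed-form psi(z) in mV for ideal charge sheets (z_j, sigma_j e/nm^2).

    With the same lower-edge reference as :func:`potential_profile`:
    psi(z) = -(1/eps0) sum_j sigma_j max(0, z - z_j).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    psi = np.zeros_like(z)
    for z_j, sigma in sheets:
        psi -= sigma * E_PER_NM2_OVER_EPS0_V_PER_NM * np.maximum(0.0, z - z_j)
    return psi * 1e3


def sheet_region_difference(sheets, regions: RegionSpec, lz: float, n_grid: int = 2001) -> float:
    """Analytic exterior-minus-interior potential difference for charge sheets, mV."""
    z = np.linspace(-lz / 2, lz / 2, n_grid)
    psi = sheet_potential(z, sheets)
    interior = np.abs(z) < regions.interior_bound
    exterior = np.abs(z) > regions.exterior_bound
    return float(psi[exterior].mean() - psi[interior].mean())
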