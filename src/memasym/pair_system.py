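"""Toy pair-interaction configurations with exact virial bookkeeping.

These systems validate the pressure-profile machinery without molecular
dynamics: particle positions are sampled (not propagated), pair forces come
from a truncated 12-6 potential, and the exact global virial pressure

    P = (N kB T + (1/3) sum_pairs r_ij . f_ij) / V

is computed by direct summation and stored alongside each configuration.
The slab-resolved profile must reproduce it exactly when volume-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KB_KJ_PER_MOL_K, KJ_PER_MOL_NM3_TO_BAR


@dataclass
class PairSystem:
    """One configuration: coordinates, pair interaction, exact forces and pressure."""

    coords: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm
    epsilon: float  # kJ/mol
    sigma: float  # nm
    cutoff: float  # nm
    temperature: float  # K
    interacting: bool = True
    # unique pairs within cutoff: indices, minimum-image r_ij = r_i - r_j, f_ij on i
    pair_i: np.ndarray = field(default=None, repr=False)
    pair_j: np.ndarray = field(default=None, repr=False)
    pair_rij: np.ndarray = field(default=None, repr=False)
    pair_fij: np.ndarray = field(default=None, repr=False)
    virial_pressure: float = 0.0  # bar, exact

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


def _lj_force_factor(r2: np.ndarray, epsilon: float, sigma: float) -> np.ndarray:
    """f_ij = factor * r_ij with factor = 24 eps (2 (s/r)^12 - (s/r)^6) / r^2."""
    sr2 = sigma * sigma / r2
    sr6 = sr2**3
    return 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r2


def compute_pairs(
    coords: np.ndarray, box: np.ndarray, epsilon: float, sigma: float, cutoff: float
):
    """All unique pairs within the cutoff (minimum image), with LJ forces."""
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    d = coords[ii] - coords[jj]
    d -= box * np.round(d / box)
    r2 = np.einsum("ij,ij->i", d, d)
    keep = r2 < cutoff * cutoff
    ii, jj, d, r2 = ii[keep], jj[keep], d[keep], r2[keep]
    f = _lj_force_factor(r2, epsilon, sigma)[:, None] * d
    return ii, jj, d, f


def finalize_system(sys: PairSystem) -> PairSystem:
    """Fill in pair lists and the exact global virial pressure."""
    if sys.interacting and sys.n_particles > 1:
        ii, jj, rij, fij = compute_pairs(
            sys.coords, sys.box, sys.epsilon, sys.sigma, sys.cutoff
        )
    else:
        ii = jj = np.empty(0, dtype=int)
        rij = fij = np.empty((0, 3))
    sys.pair_i, sys.pair_j, sys.pair_rij, sys.pair_fij = ii, jj, rij, fij
    kinetic = sys.n_particles * KB_KJ_PER_MOL_K * sys.temperature
    virial = float(np.einsum("ij,ij->", rij, fij)) / 3.0
    sys.virial_pressure = (kinetic + virial) / sys.volume * KJ_PER_MOL_NM3_TO_BAR
    return sys


def generate_pair_system(
    n_particles: int,
    box,
    arrangement: str,
    seed: int = 0,
    epsilon: float = 1.0,
    sigma: float = 0.34,
    cutoff: float = 1.0,
    temperature: float = 300.0,
    pair_positions: np.ndarray | None = None,
    min_separation: float | None = None,
) -> PairSystem:
    """One seeded configuration.

    ``arrangement``:
      - ``ideal_gas``: interactions disabled; z density-stratified (one
        particle per equal z-stratum) so the kinetic pressure is exactly
        uniform, x/y uniform random;
      - ``bulk_fluid``: uniform positions with the pair potential active;
        particles closer than ``min_separation`` (default 0.8 sigma, floor
        0.1 sigma) are resampled, error after 1000 sweeps;
      - ``single_pair``: exactly two particles, at ``pair_positions`` if given,
        otherwise separated by 2.5 nm along z at the box centre (the cutoff
        is widened to cover the pair if needed).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)

    if arrangement == "single_pair":
        if pair_positions is None:
            c = box / 2
            pair_positions = np.array([c - [0, 0, 1.25], c + [0, 0, 1.25]])
        coords = np.asarray(pair_positions, dtype=float)
        d = coords[0] - coords[1]
        d -= box * np.round(d / box)
        cutoff = max(cutoff, float(np.linalg.norm(d)) + 0.1)
        interacting = True
    elif arrangement in ("ideal_gas", "bulk_fluid"):
        coords = rng.uniform(0, 1, (n_particles, 3)) * box
        interacting = arrangement == "bulk_fluid"
        if not interacting:
            coords[:, 2] = (np.arange(n_particles) + 0.5) * box[2] / n_particles
        if interacting:
            min_d = max(min_separation or 0.8 * sigma, 0.1 * sigma)
            for _attempt in range(1000):
                ii, jj = np.triu_indices(n_particles, k=1)
                d = coords[ii] - coords[jj]
                d -= box * np.round(d / box)
                r2 = np.einsum("ij,ij->i", d, d)
                bad = np.unique(jj[r2 < min_d * min_d])
                if bad.size == 0:
                    break
                coords[bad] = rng.uniform(0, 1, (bad.size, 3)) * box
            else:
                raise RuntimeError("could not place particles without overlaps")
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    sys = PairSystem(
        coords=coords,
        box=box,
        epsilon=epsilon,
        sigma=sigma,
        cutoff=cutoff,
        temperature=temperature,
        interacting=interacting,
    )
    return finalize_system(sys)


def generate_ensemble(
    n_configs: int,
    n_particles: int,
    box,
    arrangement: str,
    seed: int = 0,
    **kwargs,
) -> list[PairSystem]:
    """Independent seeded configurations (a static stand-in for an ensemble)."""
    return [
        generate_pair_system(n_particles, box, arrangement, seed=seed + k, **kwargs)
        for k in range(n_configs)
    ]
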