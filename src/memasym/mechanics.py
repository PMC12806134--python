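"""Slab-resolved pressure tensor profiles and surface tension.

The profile decomposes the pressure tensor along the membrane normal (z)
into uniform slabs.  Each slab receives

- a kinetic term, rho(z) kB T, from local particle counts (an equipartition
  substitute for velocities, which static configurations do not carry), and
- a virial term: each pair's tensor r_ij (x) f_ij is spread along the
  straight line between the two particles (the Irving-Kirkwood contour),
  every slab the segment crosses receiving the tensor scaled by the fraction
  of the segment's z-extent inside that slab.

P_N is the zz component, P_L = (P_xx + P_yy)/2, and the lateral pressure
profile is pi(z) = P_L(z) - P_N(z).  Because the per-pair slab fractions
sum to one, the slab-volume-weighted mean of (P_N + 2 P_L)/3 equals the
global virial pressure identically - the decomposition's defining check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pair_system import PairSystem
from .units import BAR_NM_TO_MN_PER_M, KB_KJ_PER_MOL_K, KJ_PER_MOL_NM3_TO_BAR


@dataclass
class PressureProfile:
    """Per-slab normal/lateral pressures (bar) with kinetic/virial split."""

    slab_edges: np.ndarray  # (n_slabs + 1,) nm
    p_normal: np.ndarray  # zz, bar
    p_lateral: np.ndarray  # (xx + yy)/2, bar
    kinetic: np.ndarray  # isotropic kinetic contribution, bar
    virial_normal: np.ndarray
    virial_lateral: np.ndarray
    box: np.ndarray

    @property
    def slab_centers(self) -> np.ndarray:
        return 0.5 * (self.slab_edges[:-1] + self.slab_edges[1:])

    @property
    def slab_width(self) -> float:
        return float(self.slab_edges[1] - self.slab_edges[0])

    @property
    def lateral_minus_normal(self) -> np.ndarray:
        """pi(z) = P_L - P_N, the lateral pressure profile, bar."""
        return self.p_lateral - self.p_normal

    def mean_pressure(self) -> float:
        """Slab-volume-weighted mean of (P_N + 2 P_L)/3, bar."""
        return float(np.mean((self.p_normal + 2 * self.p_lateral) / 3.0))


def _segment_slab_fractions(z0: float, dz: float, lz: float, n_slabs: int):
    """Fractions of the z-interval [z0, z0+dz] in each periodic slab.

    Returns (slab indices, fractions).  ``dz`` may be negative; the interval
    is wrapped into [0, Lz).  Fractions sum to exactly 1.
    """
    h = lz / n_slabs
    if dz == 0.0:
        k = int((z0 % lz) / h) % n_slabs
        return np.array([k]), np.array([1.0])
    a, b = (z0, z0 + dz) if dz > 0 else (z0 + dz, z0)
    length = b - a
    a_mod = a % lz
    b_shift = a_mod + length
    k0 = int(a_mod / h)
    k1 = int(np.nextafter(b_shift, a_mod) / h)  # slab of the interval's top end
    idx, frac = [], []
    for k in range(k0, k1 + 1):
        lo = max(a_mod, k * h)
        hi = min(b_shift, (k + 1) * h)
        if hi > lo:
            idx.append(k % n_slabs)
            frac.append((hi - lo) / length)
    idx_arr = np.array(idx, dtype=int)
    frac_arr = np.array(frac)
    # guarantee exact normalisation so the global identity is exact
    frac_arr /= frac_arr.sum()
    return idx_arr, frac_arr


def pressure_profile(systems: list[PairSystem] | PairSystem, n_slabs: int) -> PressureProfile:
    """Ensemble-averaged Irving-Kirkwood pressure profile over z-slabs."""
    if isinstance(systems, PairSystem):
        systems = [systems]
    if not systems:
        raise ValueError("empty ensemble")
    if n_slabs < 2:
        raise ValueError("n_slabs must be >= 2")
    box = systems[0].box
    lz = float(box[2])
    h = lz / n_slabs
    if h < 0.01:
        raise ValueError("slab width below 0.01 nm")
    v_slab = float(box[0] * box[1]) * h

    kin = np.zeros(n_slabs)
    vir_xx = np.zeros(n_slabs)
    vir_yy = np.zeros(n_slabs)
    vir_zz = np.zeros(n_slabs)

    for sys in systems:
        if not np.allclose(sys.box, box):
            raise ValueError("all configurations must share one box")
        z = sys.coords[:, 2] % lz
        counts = np.bincount((z / h).astype(int) % n_slabs, minlength=n_slabs)
        kin += counts * KB_KJ_PER_MOL_K * sys.temperature
        for p in range(sys.pair_i.size):
            rij = sys.pair_rij[p]
            fij = sys.pair_fij[p]
            zi = sys.coords[sys.pair_i[p], 2]
            idx, frac = _segment_slab_fractions(zi - rij[2], rij[2], lz, n_slabs)
            wxx = rij[0] * fij[0]
            wyy = rij[1] * fij[1]
            wzz = rij[2] * fij[2]
            np.add.at(vir_xx, idx, frac * wxx)
            np.add.at(vir_yy, idx, frac * wyy)
            np.add.at(vir_zz, idx, frac * wzz)

    n_cfg = len(systems)
    conv = KJ_PER_MOL_NM3_TO_BAR / (v_slab * n_cfg)
    kinetic = kin * conv
    virial_normal = vir_zz * conv
    virial_lateral = 0.5 * (vir_xx + vir_yy) * conv
    return PressureProfile(
        slab_edges=np.linspace(0.0, lz, n_slabs + 1),
        p_normal=kinetic + virial_normal,
        p_lateral=kinetic + virial_lateral,
        kinetic=kinetic,
        virial_normal=virial_normal,
        virial_lateral=virial_lateral,
        box=box.copy(),
    )


def surface_tension(profile: PressureProfile) -> float:
    """gamma = integral of (P_N - P_L) dz over the box, in mN/m.

    The profile is piecewise constant over slabs, so the integral is the
    exact Riemann sum slab_width * sum(P_N - P_L).
    """
    diff = profile.p_normal - profile.p_lateral
    return float(np.sum(diff) * profile.slab_width * BAR_NM_TO_MN_PER_M)


def profile_difference(a: PressureProfile, b: PressureProfile) -> PressureProfile:
    """Elementwise a - b on identical slab grids."""
    if a.slab_edges.shape != b.slab_edges.shape or not np.allclose(
        a.slab_edges, b.slab_edges
    ):
        raise ValueError("profiles are on different slab grids")
    return PressureProfile(
        slab_edges=a.slab_edges.copy(),
        p_normal=a.p_normal - b.p_normal,
        p_lateral=a.p_lateral - b.p_lateral,
        kinetic=a.kinetic - b.kinetic,
        virial_normal=a.virial_normal - b.virial_normal,
        virial_lateral=a.virial_lateral - b.virial_lateral,
        box=a.box.copy(),
    )


def profile_to_frame(profile: PressureProfile):
    """Tidy DataFrame: slab centre, P_N, P_L, pi, kinetic, virial columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "z": profile.slab_centers,
            "p_normal": profile.p_normal,
            "p_lateral": profile.p_lateral,
            "pi": profile.lateral_minus_normal,
            "kinetic": profile.kinetic,
            "virial_normal": profile.virial_normal,
            "virial_lateral": profile.virial_lateral,
        }
    )
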