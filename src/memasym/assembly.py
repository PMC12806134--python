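"""Membrane-construction arithmetic: leaflet plans, area matching, stress
variants, cholesterol asymmetry and double-bilayer compartment systems.

The planner turns target compositions and measured leaflet areas into exact
integer lipid counts.  Asymmetric bilayers are built by *area matching*: the
two leaflets of a planar bilayer share one lateral box area, so the leaflet
lipid counts must be offset until the sum of per-lipid areas agrees between
leaflets.  Cholesterol occupies roughly half the area of a phospholipid
(defaults 0.3 vs 0.6 nm^2), which is why cholesterol-rich leaflets need more
molecules for the same area.

Plan families
-------------
- symmetric leaflet plans at a chosen sterol fraction,
- area-matched asymmetric bilayers (outer and inner compositions differ),
- lipid-number mismatch ("stress") variants that scale one leaflet's count,
- sterol-asymmetric combinations of two leaflet plans,
- double-bilayer systems: two mirror-image bilayers stacked so their inner
  leaflets face a shared interior compartment, giving two separated aqueous
  regions whose ion contents can differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import MM_TO_PER_NM3

DEFAULT_AREA_PER_LIPID = {"CHOL": 0.3}
DEFAULT_PHOSPHOLIPID_AREA = 0.6  # nm^2, used for any species not listed


def _apl(species: str, apl: dict[str, float] | None) -> float:
    table = dict(DEFAULT_AREA_PER_LIPID)
    if apl:
        table.update(apl)
    return table.get(species, DEFAULT_PHOSPHOLIPID_AREA)


@dataclass
class LeafletPlan:
    """Integer lipid counts for one leaflet plus its expected lateral area."""

    counts: dict[str, int]
    area_per_lipid: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for sp, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {sp}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def chol_fraction(self) -> float:
        t = self.total
        return self.counts.get("CHOL", 0) / t if t else 0.0

    @property
    def expected_area(self) -> float:
        """Sum of count x area-per-lipid over species, nm^2."""
        return sum(n * _apl(sp, self.area_per_lipid) for sp, n in self.counts.items())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {sp: n / t for sp, n in self.counts.items()} if t else {}

    def mean_apl(self) -> float:
        t = self.total
        if t == 0:
            raise ValueError("empty leaflet has no mean area per lipid")
        return self.expected_area / t


@dataclass
class AssemblyPlan:
    """A full membrane model: two leaflet plans, box, label and ion bookkeeping."""

    outer: LeafletPlan
    inner: LeafletPlan
    box: tuple[float, float, float]
    label: str = ""
    double_bilayer: bool = False
    # ion pair counts per compartment; single-bilayer plans use only "exterior"
    ions: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"exterior": {"cation": 0, "anion": 0}}
    )
    extra_cations: dict[str, int] = field(default_factory=dict)
    headgroup_charge: dict[str, float] = field(default_factory=dict)

    def lipid_charge(self) -> float:
        mult = 2 if self.double_bilayer else 1
        q = 0.0
        for leaf in (self.outer, self.inner):
            for sp, n in leaf.counts.items():
                q += n * self.headgroup_charge.get(sp, 0.0)
        return q * mult

    def net_charge(self) -> float:
        q = self.lipid_charge()
        for comp in self.ions.values():
            q += comp.get("cation", 0) - comp.get("anion", 0)
        for n in self.extra_cations.values():
            q += n
        return q


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def composition_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` molecules across species by largest remainder.

    Counts sum to exactly ``n``; ties go to the larger fraction, then to the
    lexically smaller species name, so results are fully deterministic.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    for sp, f in fractions.items():
        if f < 0:
            raise ValueError(f"negative fraction for {sp}")
    total = sum(fractions.values())
    if n > 0 and not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions sum to {total}, expected 1")
    quotas = {sp: f * n for sp, f in fractions.items()}
    counts = {sp: math.floor(q) for sp, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(
        fractions, key=lambda sp: (-(quotas[sp] - counts[sp]), -fractions[sp], sp)
    )
    for sp in order[:short]:
        counts[sp] += 1
    return counts


def area_match_offsets(
    area_outer: float,
    area_inner: float,
    leaflet_to_adjust: str,
    fractions: dict[str, float],
    apl: dict[str, float] | None = None,
    base_counts: dict[str, int] | None = None,
) -> tuple[int, LeafletPlan]:
    """Lipid-count offset that matches the adjusted leaflet's area to the other's.

    The offset is ``round(|area difference| / composition-weighted mean
    area-per-lipid)``, signed so the adjusted leaflet's area moves toward the
    opposite leaflet's.  The offset is spread over species by largest-remainder
    apportionment on the target total.  Returns (signed offset applied to the
    adjusted leaflet, adjusted LeafletPlan).
    """
    if area_outer <= 0 or area_inner <= 0:
        raise ValueError("leaflet areas must be positive")
    if leaflet_to_adjust not in ("outer", "inner"):
        raise ValueError("leaflet_to_adjust must be 'outer' or 'inner'")
    mean_apl = sum(f * _apl(sp, apl) for sp, f in fractions.items())
    if mean_apl <= 0:
        raise ValueError("composition-weighted mean area per lipid is zero")
    delta = area_outer - area_inner
    n_offset = round(abs(delta) / mean_apl)
    # shrink the adjusted leaflet if it is the larger one, grow it otherwise
    own_area = area_outer if leaflet_to_adjust == "outer" else area_inner
    other_area = area_inner if leaflet_to_adjust == "outer" else area_outer
    signed = -n_offset if own_area > other_area else n_offset

    if base_counts is not None:
        base_total = sum(base_counts.values())
    else:
        base_total = round(own_area / mean_apl)
    new_total = base_total + signed
    if new_total < 0:
        raise ValueError("offset would make the leaflet count negative")
    plan = LeafletPlan(counts=composition_counts(fractions, new_total), area_per_lipid=apl)
    return signed, plan


def stress_variant(plan: AssemblyPlan, percent: float) -> AssemblyPlan:
    """Scale the outer leaflet's lipid count by (1 + percent/100).

    The inner leaflet is untouched; the outer composition is re-apportioned
    so species fractions are preserved within rounding.
    """
    new_total = round(plan.outer.total * (1 + percent / 100.0))
    if new_total < 1:
        raise ValueError(f"stress of {percent}% empties the outer leaflet")
    outer = LeafletPlan(
        counts=composition_counts(plan.outer.fractions(), new_total),
        area_per_lipid=plan.outer.area_per_lipid,
    )
    label = plan.label + f"{percent:+g}%"
    return AssemblyPlan(
        outer=outer,
        inner=plan.inner,
        box=plan.box,
        label=label,
        double_bilayer=plan.double_bilayer,
        ions={k: dict(v) for k, v in plan.ions.items()},
        extra_cations=dict(plan.extra_cations),
        headgroup_charge=dict(plan.headgroup_charge),
    )


def combine_asymchol(
    outer_plan: LeafletPlan,
    inner_plan: LeafletPlan,
    apl: dict[str, float] | None = None,
    box: tuple[float, float, float] | None = None,
    label: str = "",
    headgroup_charge: dict[str, float] | None = None,
) -> AssemblyPlan:
    """Combine two leaflet plans with different sterol fractions.

    The inner leaflet is kept fixed; the outer leaflet's count is adjusted by
    :func:`area_match_offsets` until its expected area matches the inner's.
    """
    inner_counts_before = dict(inner_plan.counts)
    _, outer_adj = area_match_offsets(
        area_outer=outer_plan.expected_area,
        area_inner=inner_plan.expected_area,
        leaflet_to_adjust="outer",
        fractions=outer_plan.fractions(),
        apl=apl if apl is not None else outer_plan.area_per_lipid,
        base_counts=outer_plan.counts,
    )
    assert inner_plan.counts == inner_counts_before
    if box is None:
        side = math.sqrt(inner_plan.expected_area)
        box = (side, side, 10.0)
    return AssemblyPlan(
        outer=outer_adj,
        inner=inner_plan,
        box=box,
        label=label,
        headgroup_charge=dict(headgroup_charge or {}),
    )


def plan_physiol_system(
    bilayer_plan: AssemblyPlan,
    interior_conc_mm: float,
    exterior_conc_mm: float,
    interior_volume_nm3: float,
    exterior_volume_nm3: float,
    cation_valence: int = 1,
    anion_valence: int = -1,
) -> AssemblyPlan:
    """Stack a bilayer with its z-mirror into a two-compartment system.

    Both inner leaflets face the interior compartment.  Each compartment gets
    ``round(c * N_A * V)`` ion pairs, and one extra monovalent cation per unit
    of negative lipid charge is added to the compartment the charged lipids
    face, so the whole system is exactly neutral.
    """
    if interior_conc_mm < 0 or exterior_conc_mm < 0:
        raise ValueError("concentrations must be >= 0")
    if interior_volume_nm3 <= 0 or exterior_volume_nm3 <= 0:
        raise ValueError("compartment volumes must be positive")
    if cation_valence != 1 or anion_valence != -1:
        raise ValueError("only monovalent ions supported by default valences")

    ions = {
        "interior": {"cation": round(interior_conc_mm * MM_TO_PER_NM3 * interior_volume_nm3),
                     "anion": round(interior_conc_mm * MM_TO_PER_NM3 * interior_volume_nm3)},
        "exterior": {"cation": round(exterior_conc_mm * MM_TO_PER_NM3 * exterior_volume_nm3),
                     "anion": round(exterior_conc_mm * MM_TO_PER_NM3 * exterior_volume_nm3)},
    }
    plan = AssemblyPlan(
        outer=bilayer_plan.outer,
        inner=bilayer_plan.inner,
        box=(bilayer_plan.box[0], bilayer_plan.box[1], 2 * bilayer_plan.box[2] + 4.0),
        label=(bilayer_plan.label + "-physiol") if bilayer_plan.label else "physiol",
        double_bilayer=True,
        ions=ions,
        headgroup_charge=dict(bilayer_plan.headgroup_charge),
    )
    q_lipid = plan.lipid_charge()
    extra: dict[str, int] = {}
    if q_lipid < 0:
        # charged species sit in the leaflets; counterions go to the side
        # those leaflets face (inner leaflets -> interior, outer -> exterior)
        q_inner = 2 * sum(
            n * plan.headgroup_charge.get(sp, 0.0) for sp, n in plan.inner.counts.items()
        )
        q_outer = 2 * sum(
            n * plan.headgroup_charge.get(sp, 0.0) for sp, n in plan.outer.counts.items()
        )
        extra = {"interior": int(round(-q_inner)), "exterior": int(round(-q_outer))}
    elif q_lipid > 0:
        raise ValueError("positive lipid charge: neutrality scheme expects anionic lipids")
    plan.extra_cations = {k: v for k, v in extra.items() if v}
    if abs(plan.net_charge()) > 1e-9:
        raise ValueError("neutrality unreachable with monovalent counterions")
    return plan


def realize_plan(plan: AssemblyPlan, seed: int = 0, n_frames: int = 1, **spec_kwargs):
    """Emit a starting structure (single- or double-bilayer) for a plan.

    Delegates placement to the synthetic generator and returns
    ``(Trajectory, manifest)`` where the manifest records the exact species
    counts per leaflet per compartment plus ion counts.
    """
    from .synthetic import BilayerSpec, LeafletSpec, realize_assembly

    outer = LeafletSpec(composition=plan.outer.fractions(), count=plan.outer.total)
    inner = LeafletSpec(composition=plan.inner.fractions(), count=plan.inner.total)
    apl = dict(DEFAULT_AREA_PER_LIPID)
    if plan.outer.area_per_lipid:
        apl.update(plan.outer.area_per_lipid)
    spec = BilayerSpec(
        outer=outer,
        inner=inner,
        area_per_lipid=apl,
        seed=seed,
        **spec_kwargs,
    )
    return realize_assembly(plan, spec, n_frames=n_frames)
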