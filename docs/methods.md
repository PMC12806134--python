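# Methods

This note documents the models, conventions and numerical choices behind
`memasym`, and what its synthetic data can and cannot say about real
membranes.

## Scope and units

The package targets planar two-leaflet bilayers with the membrane normal
fixed to the z axis; no normal fitting or curvature analysis is attempted.
Internal units are nm (length), ps (time), amu (mass), elementary charge e,
kJ/mol (energy), bar (pressure) and mV (potential). PDB Å↔nm conversion
happens only at the I/O boundary. Fixed constants: k_B = 0.0083144626
kJ mol⁻¹ K⁻¹; 1 kJ mol⁻¹ nm⁻³ = 16.6054 bar; (1 e/nm²)/ε₀ = 18.0951 V/nm;
1 bar·nm = 0.1 mN/m.

Topology (per-atom mass, charge, role; per-species chain sequences and
sterol flags) is delivered as a structured-text manifest or resolved from a
species config by residue/atom name, keeping the package independent of any
force-field file format. Frame spacing dt is always a required input — it is
never inferred from file contents beyond explicit time stamps.

## Leaflet assignment and recentring

Frames are translated along z so the lipid centre of mass sits at z = 0
(x, y untouched, so the operation is a pure translation). Leaflet membership
is then a sign test on the headgroup reference atom (hydroxyl for sterols):
exact for planar, non-porated bilayers. The per-trajectory assignment is the
per-frame mode; frame-to-frame changes are surfaced separately as a
flip-flop count rather than silently averaged.

## Structural observables

**Area.** A(t) = Lx·Ly per frame; the fluctuation statistic is the
*population* standard deviation (a descriptive statistic of the full
series). Area per lipid divides the mean area by the leaflet's lipid count.

**Density profiles.** Per-frame histograms of selected atoms' z, weighted by
mass or charge, divided by (mean lateral area × bin width) and averaged over
frames. Out-of-range z values are wrapped back in, so the integral times the
mean area equals the selected total mass/charge for every selection and bin
width (asserted to 1e-6 relative in tests). Default bin width 0.1 nm.

**Thickness** is the distance between the maximum-density bins of the two
leaflets (z < 0, z > 0), each refined by a three-point parabola so the
estimate decouples from bin placement. A side whose maximum sits at the
profile edge has no peak and raises an error rather than returning a number.

**Tilt** is the angle between the molecular axis and the bilayer *plane*
(arcsin(|a_z|/|a|) ∈ [0°, 90°]; 90° = perpendicular to the plane). Axis
definitions, configurable per species: sterols, hydroxyl → last chain
carbon; phospholipids, headgroup → midpoint of the two terminal chain
carbons. The reported mode is the apex of a least-squares parabola over a
±3-bin window around the maximal 1° histogram bin — markedly more stable
than the three-point rule on finite-sample histograms (the "most probable"
angle is a histogram mode, not a fitted-distribution parameter).

**Order parameters.** S_CD(i) = ⟨(3cos²θ − 1)/2⟩ over molecules and frames,
with θ the angle between the C(i−1)→C(i+1) vector and z. The two-neighbour
vector is the standard hydrogen-free approximation to the C–H convention;
on chains without explicit hydrogens it is exact by construction. The
standard error is across frame means. Profile differences between models
are plain elementwise subtractions on matching carbon grids.

## Synthetic bilayer generator

The generator's purpose is sharp recovery testing, so every target is built
in *exactly*:

- **Headgroups** are drawn Normal(±d/2, σ) in z on per-leaflet lattices
  (defaults d/2 = 1.95 nm, σ = 0.2 nm), redrawn each frame. The ester
  pseudo-atom shares the headgroup z (lateral offset only). The mass model —
  lumped head (270 amu) + ester (160 amu) at the headgroup position, 14 amu
  chain carbons, a light six-site sterol body — is chosen so each leaflet's
  lipid mass-density peak falls at ±d/2; thickness ground truth is then
  exactly d. This trades some mass realism (a real sterol weighs ~387 amu,
  not ~227) for an exact oracle.
- **Chains** follow the recurrence C(i+1) = C(i−1) + b·u_i, b = 0.25 nm,
  with u_i at the fixed polar angle θ*ᵢ solving (3cos²θ* − 1)/2 = S_CD(i)
  and a fresh uniform azimuth per molecule, carbon and frame. Because the
  analysis measures exactly the C(i−1)→C(i+1) vector, recovery is exact to
  floating point while the chains remain visually disordered. A fixed-angle
  construction was preferred over sampling an orientation distribution
  because it makes the recovery test sharp rather than statistical.
- **Tilt**: the axis-to-plane angle is drawn Normal(mode, 4°), clipped to
  [1°, 89°], and the whole chain is rigidly translated so the axis endpoint
  lands accordingly — translation cannot change segment vectors, so S_CD
  and tilt targets are simultaneously exact. With ~10–40 molecules × 200
  frames per (species, leaflet) cell, the recovered histogram mode lands
  within ~0.6° of the target across seeds (tolerance 1°).
- **Area** follows a stationary AR(1) series (φ = 0.9) with the stated SD,
  mimicking barostat wander without dynamics; lateral coordinates scale with
  √(A/A₀). The ground truth records the *realised* series SD, which the
  analysis recovers identically.
- **Waters** are single sites filling |z| > d/2 + 0.3, performing reflected
  random walks within their side — continuity for the permeation detector,
  zero crossings on quiescent trajectories, and a stationary uniform density.
- **Charges.** Anionic lipids (PS, −1 e) are neutralised by monovalent
  cations placed in the water slabs. Optional charge sheets (z_c, σ) are
  realised as 25-point lattices of fixed charges, giving ψ(z) a closed form
  (the parallel-plate capacitor) for use as an analytic oracle.
- **Injected permeation events** rewrite a chosen water's z-path to enter
  through one boundary, spend exactly `dwell` frames strictly inside, and
  exit through the opposite boundary, with windows stitched per water so
  multiple events per molecule coexist.

Default composition (Table-style ratios are config-overridable): outer
35% PC / 35% SM / 30% CHOL, inner 35% PE / 30% PC / 15% PS / 20% CHOL,
60 lipids per leaflet (~120 total, the scale of small all-atom membrane
patches), 1000 waters, 10 nm box.

**What the generator does not emulate:** force-field energetics, realistic
chain torsion statistics, lipid diffusion and flip-flop dynamics,
water orientation (waters are single sites), or ensemble correlations
between observables. Passing recovery tests therefore demonstrates that the
*estimators* are correct and sharp, not that force-field trajectories would
give any particular value.

## Pressure profiles

Computed only on toy pair-interaction ensembles (truncated 12-6 potential,
minimum-image convention), never on force-field trajectories: reproducing
all-atom lateral-pressure curves is an MD-engine task. Per slab,

- kinetic term: ρ(z)·k_B·T from particle counts with a supplied temperature
  (the equipartition substitute — static configurations carry no
  velocities);
- virial term: each pair's tensor r_ij ⊗ f_ij is distributed along the
  straight line between the particles (Irving–Kirkwood contour; the
  Harasima variant is out of scope), each slab receiving the fraction of
  the segment's z-extent it contains, with periodic wrapping. Fractions are
  renormalised to sum to exactly 1 per pair, making the conservation
  identity — slab-volume-weighted mean of (P_N + 2P_L)/3 equals the global
  virial pressure — hold to machine precision, which the tests assert at
  1e-9 relative.

Surface tension integrates γ = ∫(P_N − P_L)dz as the Riemann sum
(slab width × Σ) — the exact integral of the piecewise-constant slab
representation, and the form under which a constant 100 bar difference over
1 nm gives exactly 10 mN/m.

Generator arrangements: `ideal_gas` (interactions off; z density-stratified
so the kinetic term is exactly uniform per slab), `bulk_fluid` (uniform
random positions with a minimum separation, default 0.8σ — plain uniform
sampling admits r ≈ 0.1σ contacts whose r⁻¹² virials, ~10¹², swamp every
statistic of the static ensemble; positions are samples, not Boltzmann
configurations, so the exclusion is a sampling choice, not physics), and
`single_pair` (two particles at stated positions; the cutoff widens to
cover them). The isotropy check γ ≈ 0 is statistical (3 standard errors
across configurations); all other pressure checks are exact.

## Electrostatic potential

ψ(z) = −(1/ε₀)∫∫ρ_q dz′dz″, double cumulative trapezoid from the lower box
edge with ψ = 0 and dψ/dz = 0 there; relative permittivity 1 (explicit
charges); output in mV. No periodic dipole correction is applied: the
reported quantity is the interior/exterior *difference*, and the correction
cancels for the mirror-symmetric double-bilayer layouts this targets — a
documented approximation, not an oversight. Region bounds default to
|z| < 3 nm (interior) and |z| > 11 nm (exterior) for double-bilayer boxes,
config-overridable; the sign convention makes Δψ positive when the exterior
potential is higher.

Symmetry facts used by the tests (both provable from the reference choice,
since a globally neutral density has zero edge field): an even ρ_q gives an
even ψ — but *not* a zero compartment difference; the membrane dipole
contribution survives mirroring, which is precisely why mirrored
double-bilayer systems exhibit a nonzero Δψ. The configuration with an
exactly zero difference over symmetric regions is the antisymmetric (odd,
neutral) density, asserted at 1e-9 mV. A binned ideal sheet falls entirely
within one bin, so the capacitor step σd/ε₀ is reproduced to ≪0.5% at
0.05 nm bins provided sheets sit on bin centres.

## Permeation detection

A per-water finite-state machine over frame-discrete positions: entering
the hydrophobic slab from side s and leaving through the opposite bound
emits an event (direction from s); leaving through the same bound resets
silently (the "no stop events" outcome is a finding of the detector, never
an assumption). Dwell counts frames *strictly inside* the open interval
times dt, making the injected-event invariant exact. A frame-to-frame jump
|Δz| > Lz/2 is a periodic wrap: wraps on the water side never traverse the
membrane and emit nothing; wraps into or inside the region discard the
candidate crossing with a warning. Side changes with no inside sample are
unresolvable at frame resolution and are not counted — at stride 2, an
injected dwell of 2k frames is recovered as k frames (degradation is
predictable and tested by construction). Ion selections run through the
same machinery; the expected zero count is a test, not an assumption.

Hydrophobic bounds come either from explicit config values or from the
tail-carbon mass-density profile: the outermost z where the (lightly
smoothed) density exceeds 50% of its maximum, with above-threshold runs
merged across the smallest gaps until the expected number of membranes
remains (two for double-bilayer systems; an error if they are not
separable). The 50%-plateau rule is this package's documented operational
choice.

## Assembly planner

Apportionment is largest-remainder with deterministic tie-breaks (larger
fraction first, then lexical species order), so counts sum exactly and
per-species error stays below one lipid. Area matching computes
offset = round(|ΔA|/⟨APL⟩) with the composition-weighted mean area per
lipid, signed to move the adjusted leaflet toward the other's area; which
leaflet is adjusted is an explicit argument, since either choice is
legitimate per model. Defaults: 0.6 nm² per phospholipid, 0.3 nm² per
CHOL; measured per-model areas supersede defaults when provided. Stress
variants scale one leaflet's total by (1 ± p%) and re-apportion. The
double-bilayer planner stacks a bilayer with its z-mirror (inner leaflets
facing the interior), computes round(c·N_A·V) ion pairs per compartment,
and adds one monovalent cation per unit of anionic-lipid charge on the
compartment those leaflets face; only monovalent ions are supported by
default and neutrality is asserted, not assumed. Realised structures are
audited against their manifests species-by-species.

## Pipeline and determinism

One seed governs a run; each stage derives a sub-seed deterministically.
Summaries are JSON with sorted keys and profiles/tables are CSV, so
identical configs produce byte-identical outputs (asserted in tests).
A failed stage leaves its partial outputs next to a `FAILED` marker.

## Problem sizes

Test and acceptance workloads use 200-frame bilayers with ~120 lipids and
a few hundred waters, 50-configuration × 500-particle pair ensembles and
100 injected-event trials — sizes chosen so the whole suite runs in well
under a minute while every tolerance above remains comfortably resolved.

## Known limitations

- GRO/PDB only; no binary trajectory formats, no velocity handling.
- Pressure profiles exclude three-body and long-range electrostatic
  virials; they exist to validate the decomposition, not to model bilayer
  mechanics.
- The electrostatics module assumes explicit charges (ε_r = 1) on uniform
  grids; no Poisson–Boltzmann or dielectric profiles.
- Permeation counting stops at event statistics; no permeability-coefficient
  conversion or free-energy profiles.
- The generator's geometry is kinematic, not mechanical: observables are
  independent knobs, so cross-observable correlations seen in real
  simulations (e.g. thickness–order coupling) are absent by design.
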