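"""Atom-level domain types: atoms, species metadata, topologies.

A :class:`Topology` binds every atom of a system to a molecule and a
species, carrying the masses, partial charges and role labels that the
observable calculations need.  Species metadata records which species are
sterols, their acyl-chain atom sequences, and their headgroup charge.

Roles
-----
``headgroup_ref``
    The phosphate-region reference atom used for leaflet assignment and
    as the head end of the molecular axis.
``ester_ref``
    Glycerol/ester-region reference (the water/lipid interface anchor).
``tail_carbon``
    An acyl-chain carbon; carries a chain label and a carbon index that
    counts consecutively from 2 (the first chain carbon).
``hydroxyl_ref``
    Sterol hydroxyl oxygen, the sterol leaflet/axis reference.
``water_oxygen``
    The single interaction site of a water molecule.
``other``
    Anything else (ions, charge carriers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

VALID_ROLES = {
    "headgroup_ref",
    "ester_ref",
    "tail_carbon",
    "hydroxyl_ref",
    "water_oxygen",
    "other",
}

#: Species names with fixed meaning.
WATER_SPECIES = "WAT"
CATION_SPECIES = "CAT"
ANION_SPECIES = "ANI"
SHEET_SPECIES = "QSH"  # synthetic charge-sheet carrier


@dataclass
class AtomRecord:
    """One atom: identity, molecule membership, mass, charge and role."""

    atom_id: int
    name: str
    species: str
    molecule_id: int
    mass: float  # amu
    charge: float  # e
    role: str = "other"
    chain: str | None = None  # chain label for tail carbons
    tail_index: int | None = None  # carbon index, first chain carbon = 2

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_id}: mass must be > 0")
        if self.role not in VALID_ROLES:
            raise ValueError(f"atom {self.atom_id}: unknown role {self.role!r}")
        if self.role == "tail_carbon" and self.tail_index is None:
            raise ValueError(f"atom {self.atom_id}: tail_carbon needs tail_index")


@dataclass
class SpeciesMeta:
    """Per-species metadata: sterol flag, chain atom-name sequences, headgroup charge."""

    is_sterol: bool = False
    chains: list[list[str]] = field(default_factory=list)
    headgroup_charge: float = 0.0

    @property
    def is_lipid(self) -> bool:
        return self.is_sterol or bool(self.chains)


@dataclass
class Topology:
    """All atoms of a system plus molecule → species and species metadata maps."""

    atoms: list[AtomRecord]
    molecules: dict[int, str]
    species_meta: dict[str, SpeciesMeta]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for atom in self.atoms:
            if atom.molecule_id not in self.molecules:
                raise ValueError(
                    f"atom {atom.atom_id}: molecule {atom.molecule_id} not declared"
                )
        # tail carbons of each molecule must be consecutive from 2 per chain
        per_chain: dict[tuple[int, str], list[int]] = {}
        for atom in self.atoms:
            if atom.role == "tail_carbon":
                per_chain.setdefault((atom.molecule_id, atom.chain or ""), []).append(
                    atom.tail_index  # type: ignore[arg-type]
                )
        for (mol, chain), idx in per_chain.items():
            idx_sorted = sorted(idx)
            if idx_sorted != list(range(2, 2 + len(idx_sorted))):
                raise ValueError(
                    f"molecule {mol} chain {chain!r}: tail carbon indices "
                    f"{idx_sorted} are not consecutive from 2"
                )

    # -- convenience views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self):
        import numpy as np

        return np.array([a.mass for a in self.atoms], dtype=float)

    def charges(self):
        import numpy as np

        return np.array([a.charge for a in self.atoms], dtype=float)

    def atom_indices(
        self,
        species: str | set[str] | None = None,
        role: str | set[str] | None = None,
        chain: str | None = None,
        molecule_ids: set[int] | None = None,
    ):
        """Indices (into the atom list) matching the given filters."""
        import numpy as np

        def as_set(x):
            if x is None:
                return None
            return {x} if isinstance(x, str) else set(x)

        sp, rl = as_set(species), as_set(role)
        out = [
            i
            for i, a in enumerate(self.atoms)
            if (sp is None or a.species in sp)
            and (rl is None or a.role in rl)
            and (chain is None or a.chain == chain)
            and (molecule_ids is None or a.molecule_id in molecule_ids)
        ]
        return np.array(out, dtype=int)

    def lipid_molecule_ids(self) -> list[int]:
        return [
            m
            for m, sp in sorted(self.molecules.items())
            if self.species_meta.get(sp, SpeciesMeta()).is_lipid
        ]

    def water_molecule_ids(self) -> list[int]:
        return [m for m, sp in sorted(self.molecules.items()) if sp == WATER_SPECIES]

    def molecule_atom_indices(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.molecule_id, []).append(i)
        return out

    def species_charge_check(self) -> None:
        """Verify each lipid species' total charge matches its metadata."""
        totals: dict[str, dict[int, float]] = {}
        for a in self.atoms:
            totals.setdefault(a.species, {}).setdefault(a.molecule_id, 0.0)
            totals[a.species][a.molecule_id] += a.charge
        for sp, meta in self.species_meta.items():
            if not meta.is_lipid or sp not in totals:
                continue
            for mol, q in totals[sp].items():
                if abs(q - meta.headgroup_charge) > 1e-6:
                    raise ValueError(
                        f"species {sp} molecule {mol}: total charge {q:.6f} != "
                        f"declared {meta.headgroup_charge:.6f}"
                    )


# ---------------------------------------------------------------------------
# Topology manifest (structured-text sidecar)
# ---------------------------------------------------------------------------


def topology_to_manifest(top: Topology) -> dict:
    """Serialisable manifest of a topology (per-atom and per-species data)."""
    return {
        "species_meta": {
            sp: {
                "is_sterol": m.is_sterol,
                "chains": [list(c) for c in m.chains],
                "headgroup_charge": m.headgroup_charge,
            }
            for sp, m in top.species_meta.items()
        },
        "molecules": {int(k): v for k, v in top.molecules.items()},
        "atoms": [
            {
                "atom_id": a.atom_id,
                "name": a.name,
                "species": a.species,
                "molecule_id": a.molecule_id,
                "mass": a.mass,
                "charge": a.charge,
                "role": a.role,
                "chain": a.chain,
                "tail_index": a.tail_index,
            }
            for a in top.atoms
        ],
    }


def topology_from_manifest(doc: dict) -> Topology:
    meta = {
        sp: SpeciesMeta(
            is_sterol=d.get("is_sterol", False),
            chains=[list(c) for c in d.get("chains", [])],
            headgroup_charge=float(d.get("headgroup_charge", 0.0)),
        )
        for sp, d in doc.get("species_meta", {}).items()
    }
    molecules = {int(k): v for k, v in doc["molecules"].items()}
    atoms = [
        AtomRecord(
            atom_id=int(a["atom_id"]),
            name=a["name"],
            species=a["species"],
            molecule_id=int(a["molecule_id"]),
            mass=float(a["mass"]),
            charge=float(a["charge"]),
            role=a.get("role", "other"),
            chain=a.get("chain"),
            tail_index=a.get("tail_index"),
        )
        for a in doc["atoms"]
    ]
    return Topology(atoms=atoms, molecules=molecules, species_meta=meta)


def save_topology(top: Topology, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(topology_to_manifest(top), fh, sort_keys=True)


def load_topology(path) -> Topology:
    with open(path) as fh:
        return topology_from_manifest(yaml.safe_load(fh))
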