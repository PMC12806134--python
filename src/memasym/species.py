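"""Built-in species definitions for synthetic plasma-membrane-like bilayers.

The default lipid set mirrors a typical mammalian plasma membrane: the
outer leaflet is built from PC and SM, the inner leaflet from PE, PC and
PS, with cholesterol (CHOL) in either leaflet.  Acyl chains follow one
common simplification: PE/PC/PS carry one saturated 16-carbon chain
(chain A) and one unsaturated 18-carbon chain (chain B); SM carries two
saturated 16-carbon chains.  Headgroup and ester regions are lumped into
single reference pseudo-atoms whose masses approximate the grouped heavy
atoms; chain carbons are CH2/CH-equivalent sites of 14 amu.

A species config maps species → metadata + per-atom-name records and is
what the coordinate readers use to resolve roles, masses and charges.
It can be overridden or extended via a YAML file of the same structure.
"""

from __future__ import annotations

import yaml

from .topology import (
    ANION_SPECIES,
    CATION_SPECIES,
    SHEET_SPECIES,
    WATER_SPECIES,
    AtomRecord,
    SpeciesMeta,
)

_SAT_CHAIN_LEN = 16  # carbons; chain atoms are C2..C16
_UNSAT_CHAIN_LEN = 18  # carbons; chain atoms are C2..C18
_CHOL_CHAIN_LEN = 7  # coarse sterol body, C2..C7

_HEAD_MASS = 270.0  # lumped phosphate + headgroup + glycerol, amu
_ESTER_MASS = 160.0  # lumped ester carbonyls + upper-chain heavy atoms, amu
_CH2_MASS = 14.0
_CHOL_BODY_MASS = 35.0  # per coarse sterol site
_HYDROXYL_MASS = 17.0
_WATER_MASS = 18.015


def _chain_names(label: str, n_carbons: int) -> list[str]:
    return [f"C{i}{label}" for i in range(2, n_carbons + 1)]


def _phospholipid(sn2_len: int, headgroup_charge: float) -> dict:
    atoms = [
        {"name": "P", "mass": _HEAD_MASS, "charge": headgroup_charge, "role": "headgroup_ref"},
        {"name": "E", "mass": _ESTER_MASS, "charge": 0.0, "role": "ester_ref"},
    ]
    chains = [_chain_names("A", _SAT_CHAIN_LEN), _chain_names("B", sn2_len)]
    for label, names in zip(("A", "B"), chains):
        for k, nm in enumerate(names):
            atoms.append(
                {
                    "name": nm,
                    "mass": _CH2_MASS,
                    "charge": 0.0,
                    "role": "tail_carbon",
                    "chain": label,
                    "tail_index": k + 2,
                }
            )
    return {
        "is_sterol": False,
        "chains": chains,
        "headgroup_charge": headgroup_charge,
        "atoms": atoms,
    }


def default_species_config() -> dict:
    """The package's built-in species-metadata config."""
    chol_chain = _chain_names("", _CHOL_CHAIN_LEN)
    cfg = {
        "PC": _phospholipid(_UNSAT_CHAIN_LEN, 0.0),
        "PE": _phospholipid(_UNSAT_CHAIN_LEN, 0.0),
        "PS": _phospholipid(_UNSAT_CHAIN_LEN, -1.0),
        "SM": _phospholipid(_SAT_CHAIN_LEN, 0.0),
        "CHOL": {
            "is_sterol": True,
            "chains": [chol_chain],
            "headgroup_charge": 0.0,
            "atoms": [
                {"name": "O1", "mass": _HYDROXYL_MASS, "charge": 0.0, "role": "hydroxyl_ref"}
            ]
            + [
                {
                    "name": nm,
                    "mass": _CHOL_BODY_MASS,
                    "charge": 0.0,
                    "role": "tail_carbon",
                    "chain": "",
                    "tail_index": k + 2,
                }
                for k, nm in enumerate(chol_chain)
            ],
        },
        WATER_SPECIES: {
            "is_sterol": False,
            "chains": [],
            "headgroup_charge": 0.0,
            "atoms": [
                {"name": "OW", "mass": _WATER_MASS, "charge": 0.0, "role": "water_oxygen"}
            ],
        },
        CATION_SPECIES: {
            "is_sterol": False,
            "chains": [],
            "headgroup_charge": 0.0,
            "atoms": [{"name": "NA", "mass": 22.99, "charge": 1.0, "role": "other"}],
        },
        ANION_SPECIES: {
            "is_sterol": False,
            "chains": [],
            "headgroup_charge": 0.0,
            "atoms": [{"name": "CL", "mass": 35.45, "charge": -1.0, "role": "other"}],
        },
        SHEET_SPECIES: {
            "is_sterol": False,
            "chains": [],
            "headgroup_charge": 0.0,
            "atoms": [{"name": "Q", "mass": 1.0, "charge": 0.0, "role": "other"}],
        },
    }
    return cfg


def load_species_config(path) -> dict:
    """Load a species config from YAML, layered over the built-in defaults."""
    cfg = default_species_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg.update(user)
    return cfg


def species_meta_from_config(cfg: dict) -> dict[str, SpeciesMeta]:
    return {
        sp: SpeciesMeta(
            is_sterol=d.get("is_sterol", False),
            chains=[list(c) for c in d.get("chains", [])],
            headgroup_charge=float(d.get("headgroup_charge", 0.0)),
        )
        for sp, d in cfg.items()
    }


def make_molecule_atoms(
    species: str,
    molecule_id: int,
    first_atom_id: int,
    cfg: dict,
    charge_overrides: dict[str, float] | None = None,
) -> list[AtomRecord]:
    """Instantiate the atoms of one molecule of ``species`` from the config."""
    if species not in cfg:
        raise KeyError(f"species {species!r} not in species config")
    out = []
    for k, a in enumerate(cfg[species]["atoms"]):
        charge = a["charge"]
        if charge_overrides and a["name"] in charge_overrides:
            charge = charge_overrides[a["name"]]
        out.append(
            AtomRecord(
                atom_id=first_atom_id + k,
                name=a["name"],
                species=species,
                molecule_id=molecule_id,
                mass=a["mass"],
                charge=charge,
                role=a.get("role", "other"),
                chain=a.get("chain"),
                tail_index=a.get("tail_index"),
            )
        )
    return out
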