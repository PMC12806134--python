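"""Config-driven orchestration: generation -> analysis -> tidy exports.

A pipeline run is described by a plain YAML/dict config naming an ordered
subset of stages.  Every stage writes CSV tables and/or a JSON summary into
the output directory, plus a run log (package version, seed, config echo).
One seed governs the whole run; each stage derives its own sub-seed
deterministically, so identical configs give byte-identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import (
    AssemblyPlan,
    LeafletPlan,
    area_match_offsets,
    composition_counts,
    plan_physiol_system,
    stress_variant,
)
from .electrostatics import RegionSpec, potential_profile, region_potential_difference
from .io import read_coordinates, write_coordinates
from .mechanics import pressure_profile, profile_to_frame, surface_tension
from .pair_system import generate_ensemble
from .permeation import detect_permeation_events, dwell_time_stats, hydrophobic_bounds
from .structure import (
    chain_order_parameters,
    density_profile,
    lateral_area_stats,
    membrane_thickness,
    tilt_distribution,
)
from .synthetic import BilayerSpec, LeafletSpec, generate_bilayer_trajectory
from .topology import load_topology, save_topology
from .trajectory import assign_leaflets, recenter_frames

KNOWN_STAGES = ("generate", "plan", "structure", "mechanics", "potential", "permeation")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    seed: int | None = None
    dt: float = 100.0  # ps
    outdir: str = "memasym_out"
    label: str = "run"
    options: dict = field(default_factory=dict)  # per-stage blocks

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        stages = doc.get("stages") or []
        for st in stages:
            if st not in KNOWN_STAGES:
                raise ConfigError(f"unknown stage {st!r}; known: {KNOWN_STAGES}")
        seed = doc.get("seed")
        if "generate" in stages and seed is None:
            raise ConfigError("a seed is mandatory when the generate stage is present")
        if ("structure" in stages or "potential" in stages or "permeation" in stages) and (
            "generate" not in stages
        ):
            inp = doc.get("input", {})
            traj_path = inp.get("trajectory")
            if not traj_path:
                raise ConfigError("analysis stages need a generate stage or input.trajectory")
            if not Path(traj_path).exists():
                raise ConfigError(f"input trajectory {traj_path} does not exist")
        return cls(
            stages=list(stages),
            seed=seed,
            dt=float(doc.get("dt", 100.0)),
            outdir=doc.get("outdir", "memasym_out"),
            label=doc.get("label", "run"),
            options=doc,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage_seed(base: int, stage: str) -> int:
    return (base * 10007 + KNOWN_STAGES.index(stage) + 1) % (2**31 - 1)


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _bilayer_spec_from(doc: dict, seed: int) -> BilayerSpec:
    kwargs = dict(doc)
    if "outer" in kwargs:
        kwargs["outer"] = LeafletSpec(**kwargs["outer"])
    if "inner" in kwargs:
        kwargs["inner"] = LeafletSpec(**kwargs["inner"])
    if "charge_profile" in kwargs:
        kwargs["charge_profile"] = [tuple(x) for x in kwargs["charge_profile"]]
    kwargs["seed"] = seed
    return BilayerSpec(**kwargs)


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the configured stages in order; returns {stage: outputs}.

    Partial outputs of a failed stage are kept next to a FAILED marker file.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {
        "version": __version__,
        "seed": config.seed,
        "label": config.label,
        "stages": config.stages,
        "config": {k: v for k, v in config.options.items() if k != "outdir"},
    }
    _dump_json(log, outdir / "run_log.json")

    results: dict = {}
    traj = None
    truth = None
    try:
        for stage in config.stages:
            opts = config.options.get(stage, {}) or {}
            seed = _stage_seed(config.seed or 0, stage)
            if stage == "generate":
                spec = _bilayer_spec_from(opts.get("bilayer", {}) or {}, seed=config.seed)
                n_frames = int(opts.get("n_frames", 50))
                traj, truth = generate_bilayer_trajectory(spec, n_frames, dt=config.dt)
                write_coordinates(traj, outdir / "trajectory.gro", "gro")
                save_topology(traj.topology, outdir / "topology.yaml")
                _dump_json(
                    {
                        "thickness": truth.thickness,
                        "area_sd": truth.area_sd,
                        "tilt_modes": {
                            f"{sp}/{leaf}": v for (sp, leaf), v in truth.tilt_modes.items()
                        },
                        "scd": {
                            sp: [list(map(float, c)) for c in chains]
                            for sp, chains in truth.scd.items()
                        },
                    },
                    outdir / "ground_truth.json",
                )
                results[stage] = {"trajectory": str(outdir / "trajectory.gro")}
            elif stage == "plan":
                results[stage] = _run_plan_stage(opts, outdir)
            elif stage == "structure":
                traj = traj if traj is not None else _load_input(config)
                results[stage] = _run_structure_stage(traj, opts, outdir)
            elif stage == "mechanics":
                results[stage] = _run_mechanics_stage(opts, seed, outdir)
            elif stage == "potential":
                traj = traj if traj is not None else _load_input(config)
                results[stage] = _run_potential_stage(traj, opts, outdir)
            elif stage == "permeation":
                traj = traj if traj is not None else _load_input(config)
                results[stage] = _run_permeation_stage(traj, opts, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    _dump_json({st: sorted(res) for st, res in results.items()}, outdir / "outputs.json")
    return results


def _load_input(config: PipelineConfig):
    inp = config.options.get("input", {})
    path = inp.get("trajectory")
    if not path:
        raise ConfigError("no trajectory available for analysis stage")
    top = None
    if inp.get("topology"):
        top = load_topology(inp["topology"])
    dialect = inp.get("dialect", "gro")
    return read_coordinates(path, dialect, topology=top, dt=config.dt)


def _run_plan_stage(opts: dict, outdir: Path) -> dict:
    outer = LeafletPlan(counts=composition_counts(
        opts["outer"]["fractions"], int(opts["outer"]["count"])
    ))
    inner = LeafletPlan(counts=composition_counts(
        opts["inner"]["fractions"], int(opts["inner"]["count"])
    ))
    plan = AssemblyPlan(
        outer=outer,
        inner=inner,
        box=tuple(opts.get("box", (6.5, 6.5, 10.0))),
        label=opts.get("label", "plan"),
        headgroup_charge=opts.get("headgroup_charge", {"PS": -1.0}),
    )
    if "area_match" in opts:
        am = opts["area_match"]
        offset, adjusted = area_match_offsets(
            am["area_outer"],
            am["area_inner"],
            am.get("leaflet_to_adjust", "outer"),
            outer.fractions() if am.get("leaflet_to_adjust", "outer") == "outer" else inner.fractions(),
            base_counts=outer.counts if am.get("leaflet_to_adjust", "outer") == "outer" else inner.counts,
        )
        if am.get("leaflet_to_adjust", "outer") == "outer":
            plan.outer = adjusted
        else:
            plan.inner = adjusted
    if "stress_percent" in opts:
        plan = stress_variant(plan, float(opts["stress_percent"]))
    if "physiol" in opts:
        ph = opts["physiol"]
        plan = plan_physiol_system(
            plan,
            ph.get("interior_conc_mm", 150.0),
            ph.get("exterior_conc_mm", 150.0),
            ph.get("interior_volume_nm3", 100.0),
            ph.get("exterior_volume_nm3", 100.0),
        )
    elif plan.lipid_charge() < 0:
        # one monovalent counterion per unit of anionic-lipid charge keeps
        # single-bilayer plans charge neutral too
        plan.extra_cations = {"exterior": int(round(-plan.lipid_charge()))}
    doc = {
        "label": plan.label,
        "outer": plan.outer.counts,
        "inner": plan.inner.counts,
        "ions": plan.ions,
        "extra_cations": plan.extra_cations,
        "net_charge": plan.net_charge(),
        "double_bilayer": plan.double_bilayer,
    }
    _dump_json(doc, outdir / "plan.json")
    return {"plan": str(outdir / "plan.json")}


def _run_structure_stage(traj, opts: dict, outdir: Path) -> dict:
    bin_width = float(opts.get("bin_width", 0.1))
    traj = recenter_frames(traj)
    leaflets = assign_leaflets(traj)
    stats = lateral_area_stats(traj, leaflets)
    lipid_idx = traj.topology.atom_indices(
        molecule_ids=set(traj.topology.lipid_molecule_ids())
    )
    prof = density_profile(traj, lipid_idx, bin_width=bin_width, label="lipid")
    thickness = membrane_thickness(prof)
    pd.DataFrame({"z": prof.bin_centers, "density": prof.values}).to_csv(
        outdir / "density_profile.csv", index=False
    )

    lipid_species = sorted(
        {sp for sp, m in traj.topology.species_meta.items() if m.is_lipid}
        & set(traj.topology.molecules.values())
    )
    tilt_rows, scd_rows = [], []
    summary_tilt, summary_scd = {}, {}
    for sp in lipid_species:
        meta = traj.topology.species_meta[sp]
        for leaflet in ("outer", "inner"):
            present = any(
                traj.topology.molecules[m] == sp
                for m in leaflets.molecule_ids(leaflet)
            )
            if not present:
                continue
            td = tilt_distribution(traj, sp, leaflets, leaflet=leaflet)
            summary_tilt[f"{sp}/{leaflet}"] = td.mode_deg
            tilt_rows.append(
                {"species": sp, "leaflet": leaflet, "mode_deg": td.mode_deg,
                 "mean_deg": td.angles_mean, "sem_deg": td.angles_sem}
            )
            for c_idx in range(len(meta.chains)):
                op = chain_order_parameters(traj, sp, c_idx, leaflets, leaflet=leaflet)
                summary_scd[f"{sp}/chain{c_idx}/{leaflet}"] = float(op.s_cd.mean())
                for carbon, v, se in zip(op.carbons, op.s_cd, op.sem):
                    scd_rows.append(
                        {"species": sp, "leaflet": leaflet, "chain": c_idx,
                         "carbon": int(carbon), "s_cd": float(v), "sem": float(se)}
                    )
    pd.DataFrame(tilt_rows).to_csv(outdir / "tilt_modes.csv", index=False)
    pd.DataFrame(scd_rows).to_csv(outdir / "order_parameters.csv", index=False)
    summary = {
        "area_mean": stats.mean,
        "area_sd": stats.sd,
        "area_per_lipid": stats.area_per_lipid,
        "thickness": thickness,
        "tilt_mode_deg": summary_tilt,
        "s_cd_mean": summary_scd,
    }
    _dump_json(summary, outdir / "structure_summary.json")
    return {"summary": str(outdir / "structure_summary.json")}


def _run_mechanics_stage(opts: dict, seed: int, outdir: Path) -> dict:
    ens = generate_ensemble(
        n_configs=int(opts.get("n_configs", 20)),
        n_particles=int(opts.get("n_particles", 200)),
        box=opts.get("box", (5.0, 5.0, 5.0)),
        arrangement=opts.get("arrangement", "bulk_fluid"),
        seed=seed,
        temperature=float(opts.get("temperature", 300.0)),
    )
    prof = pressure_profile(ens, n_slabs=int(opts.get("n_slabs", 25)))
    profile_to_frame(prof).to_csv(outdir / "pressure_profile.csv", index=False)
    summary = {
        "surface_tension_mn_per_m": surface_tension(prof),
        "mean_pressure_bar": prof.mean_pressure(),
        "global_virial_bar": float(np.mean([s.virial_pressure for s in ens])),
    }
    _dump_json(summary, outdir / "mechanics_summary.json")
    return {"summary": str(outdir / "mechanics_summary.json")}


def _run_potential_stage(traj, opts: dict, outdir: Path) -> dict:
    bin_width = float(opts.get("bin_width", 0.05))
    traj = recenter_frames(traj)
    all_idx = np.arange(traj.n_atoms)
    rho = density_profile(traj, all_idx, bin_width=bin_width, weight="charge", label="charge")
    prof = potential_profile(rho)
    pd.DataFrame({"z": prof.z, "rho_q": prof.charge_density, "psi_mv": prof.psi_mv}).to_csv(
        outdir / "potential_profile.csv", index=False
    )
    lz = float(traj.frames[0].box[2])
    regions = RegionSpec(
        interior_bound=float(opts.get("interior_bound", 0.25 * lz / 2)),
        exterior_bound=float(opts.get("exterior_bound", 0.85 * lz / 2)),
    )
    dpsi = region_potential_difference(prof, regions)
    _dump_json(
        {
            "delta_psi_mv": dpsi,
            "interior_bound": regions.interior_bound,
            "exterior_bound": regions.exterior_bound,
        },
        outdir / "potential_summary.json",
    )
    return {"summary": str(outdir / "potential_summary.json")}


def _run_permeation_stage(traj, opts: dict, outdir: Path) -> dict:
    traj = recenter_frames(traj)
    if "bounds" in opts:
        regions = hydrophobic_bounds(
            traj, method="explicit", explicit=[tuple(opts["bounds"])]
        )
    else:
        regions = hydrophobic_bounds(
            traj, n_membranes=int(opts.get("n_membranes", 1))
        )
    events = detect_permeation_events(traj, regions)
    stats = dwell_time_stats(events, bin_width=float(opts.get("bin_width_ps", 500.0)))
    pd.DataFrame(
        [
            {
                "molecule_id": e.molecule_id,
                "membrane": e.membrane,
                "direction": e.direction,
                "entry_frame": e.entry_frame,
                "exit_frame": e.exit_frame,
                "dwell_time_ps": e.dwell_time,
            }
            for e in events
        ]
    ).to_csv(outdir / "permeation_events.csv", index=False)
    _dump_json(
        {
            "n_events": len(events),
            "by_direction": stats.by_direction,
            "dwell_min_ps": stats.dwell_min,
            "dwell_max_ps": stats.dwell_max,
            "dwell_mode_ps": stats.dwell_mode,
            "regions": [[r.lower, r.upper] for r in regions],
        },
        outdir / "permeation_summary.json",
    )
    return {"summary": str(outdir / "permeation_summary.json")}


# ---------------------------------------------------------------------------
# cross-model comparison
# ---------------------------------------------------------------------------

_SUMMARY_FILES = (
    "structure_summary.json",
    "mechanics_summary.json",
    "potential_summary.json",
    "permeation_summary.json",
)


def _flatten(doc: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in doc.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "/"))
        else:
            out[key] = v
    return out


def compare_models(run_dirs: list, observable: str) -> pd.DataFrame:
    """Long-form table of one observable across >= 2 pipeline runs."""
    if len(run_dirs) < 2:
        raise ValueError("compare_models needs at least two runs")
    rows = []
    for d in run_dirs:
        d = Path(d)
        log_path = d / "run_log.json"
        label = d.name
        if log_path.exists():
            with open(log_path) as fh:
                label = json.load(fh).get("label", label)
        flat: dict = {}
        for name in _SUMMARY_FILES:
            p = d / name
            if p.exists():
                with open(p) as fh:
                    flat.update(_flatten(json.load(fh)))
        if observable not in flat:
            raise ValueError(f"observable {observable!r} missing from run {d}")
        rows.append({"model": label, "observable": observable, "value": flat[observable]})
    return pd.DataFrame(rows)
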