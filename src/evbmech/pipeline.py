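"""End-to-end orchestration: fixture → calibrate → map → profile → hydrate →
bind → kinetics, from one YAML configuration, with every stage seeded.

The run report carries units with every number, the seeds and the resolved
configuration, so any table it contains can be regenerated from scratch.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .energetics import (DielectricModel, LRAProtocol, hydroxide_formation_energy,
                         lra_binding, tst_convert)
from .evb import (CalibrationProtocol, apply_leg_parameters, calibrate,
                  extract_leg, measure_leg)
from .fixtures import FIXTURE_VARIANTS, make_active_site_fixture
from .hydration import CavitySpec, WaterFloodParams, coordination_shell, water_flood
from .sampling import EVBSystem, LangevinParams, MappingSchedule
from .structure import write_pdb

__all__ = ["ConfigError", "RunConfig", "validate_config", "run_pipeline",
           "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = errors if isinstance(errors, list) else [errors]
        super().__init__("; ".join(self.errors))


DEFAULT_CONFIG: dict = {
    "fixture": {"variant": "mg_b", "seed": 1, "n_waters": 24},
    "calibration": {
        # reference-reaction targets for the hydride-transfer leg in water
        "reference_barrier": 18.0,
        "reference_reaction_free_energy": -2.2,
        "windows": 55, "steps_per_window": 3000,
        "tolerance": 0.15, "max_iterations": 15, "seed": 11,
        "initial_alpha": -4.5, "initial_coupling": 6.5,
    },
    "mapping": {"windows": 55, "steps_per_window": 3000, "seeds": [1, 2, 3],
                "bin_width": 2.0},
    "langevin": {"temperature": 300.0, "friction": 10.0, "timestep": 1.0},
    "flood": {"radius": 6.0, "sweeps": 3000, "seed": 5},
    "lra": {"n_configurations": 4, "steps_per_configuration": 2000, "seed": 7},
    "kinetics": {"kcat": 12.4, "temperature": 300.0, "ph": 7.4},
    "output_dir": "results/run",
}

_SCHEMA_TYPES = {
    ("fixture", "variant"): str, ("fixture", "seed"): int, ("fixture", "n_waters"): int,
    ("calibration", "reference_barrier"): float,
    ("calibration", "reference_reaction_free_energy"): float,
    ("calibration", "windows"): int, ("calibration", "steps_per_window"): int,
    ("calibration", "tolerance"): float, ("calibration", "max_iterations"): int,
    ("calibration", "seed"): int,
    ("calibration", "initial_alpha"): float,
    ("calibration", "initial_coupling"): float,
    ("mapping", "windows"): int, ("mapping", "steps_per_window"): int,
    ("mapping", "seeds"): list, ("mapping", "bin_width"): float,
    ("langevin", "temperature"): float, ("langevin", "friction"): float,
    ("langevin", "timestep"): float,
    ("flood", "radius"): float, ("flood", "sweeps"): int, ("flood", "seed"): int,
    ("lra", "n_configurations"): int, ("lra", "steps_per_configuration"): int,
    ("lra", "seed"): int,
    ("kinetics", "kcat"): float, ("kinetics", "temperature"): float,
    ("kinetics", "ph"): float,
    ("output_dir", None): str,
}


@dataclass
class RunConfig:
    data: dict
    source: str = "<defaults>"

    def __getitem__(self, key):
        return self.data[key]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()).hexdigest()[:12]


def validate_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load, merge with defaults, and validate; all errors reported at once.

    Numeric fields must be plain numbers in the documented units (kcal/mol,
    Å, fs, K) — a value like ``"1 ps"`` is rejected rather than converted.
    """
    raw = {}
    source = "<defaults>"
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError([f"config file not found: {p}"])
        with open(p) as fh:
            raw = yaml.safe_load(fh) or {}
        source = str(p)
    if overrides:
        raw = _deep_merge(raw, overrides)

    errors = []
    merged = _deep_merge(json.loads(json.dumps(DEFAULT_CONFIG)), raw, errors=errors,
                         known=DEFAULT_CONFIG)
    # type/unit checks
    for (section, key), typ in _SCHEMA_TYPES.items():
        val = merged.get(section) if key is None else merged.get(section, {}).get(key)
        if val is None:
            errors.append(f"missing key {section}{'.' + key if key else ''}")
            continue
        if typ is float and isinstance(val, int):
            continue
        if not isinstance(val, typ):
            unit_hint = ""
            if isinstance(val, str) and any(ch.isdigit() for ch in val):
                unit_hint = " (numeric value expected — units are fixed: kcal/mol, Å, fs, K)"
            errors.append(f"{section}.{key}: expected {typ.__name__}, got {val!r}{unit_hint}")
    if not errors:
        if merged["fixture"]["variant"] not in FIXTURE_VARIANTS:
            errors.append(f"fixture.variant must be one of {FIXTURE_VARIANTS}")
        if not merged["mapping"]["seeds"]:
            errors.append("mapping.seeds must list at least one seed")
        if merged["langevin"]["timestep"] > 5.0:
            errors.append("langevin.timestep looks too large — femtoseconds expected")
    if errors:
        raise ConfigError(errors)
    return RunConfig(merged, source)


def _deep_merge(base: dict, over: dict, errors=None, known=None, prefix=""):
    out = dict(base)
    for k, v in (over or {}).items():
        if known is not None and k not in known:
            if errors is not None:
                errors.append(f"unknown key {prefix}{k}")
            continue
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v,
                                 errors=errors,
                                 known=known[k] if known and isinstance(known.get(k), dict) else None,
                                 prefix=f"{prefix}{k}.")
        else:
            out[k] = v
    return out


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "provenance": self.provenance,
                "warnings": self.warnings}


def _leg_system(fixture, alpha, coupling):
    leg = apply_leg_parameters(extract_leg(fixture.topology, 1, 2), alpha, coupling)
    return EVBSystem(leg, fixture.system.coordinates, fixture.system.boundary,
                     list(fixture.system.distance_restraints),
                     list(fixture.system.position_restraints),
                     fixture.system.mobile.copy())


def run_pipeline(config: RunConfig, progress: bool = False) -> RunReport:
    """Execute all stages in dependency order; identical config ⇒ identical
    report payload (all randomness flows from config seeds)."""
    t_start = time.time()
    report = RunReport()
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    lv = config["langevin"]
    temperature = float(lv["temperature"])

    def log(stage, **kv):
        if progress:
            msg = " ".join(f"{k}={v}" for k, v in kv.items())
            print(f"[{time.time() - t_start:7.1f}s] {stage}: {msg}", flush=True)

    # stage: fixture
    fx_cfg = config["fixture"]
    fixture = make_active_site_fixture(fx_cfg["seed"], fx_cfg["n_waters"], fx_cfg["variant"])
    write_pdb(fixture.structure, out_dir / "fixture.pdb")
    report.stages["fixture"] = {
        "variant": fx_cfg["variant"], "seed": fx_cfg["seed"],
        "n_atoms": fixture.topology.n_atoms, "n_waters": fx_cfg["n_waters"],
    }
    log("fixture", variant=fx_cfg["variant"], atoms=fixture.topology.n_atoms)

    # stage: coordination shells
    shells = {}
    for label, idx in (("Mg_A", fixture.mg_a_index), ("Mg_B", fixture.mg_b_index)):
        if idx is None:
            continue
        sh = coordination_shell(fixture.structure, idx, cutoff=2.5)
        shells[label] = {"coordination_number": sh.coordination_number,
                         "ligands": sh.ligand_names,
                         "distances_A": [round(d, 3) for d in sh.distances]}
    report.stages["coordination"] = shells
    log("coordination", shells={k: v["coordination_number"] for k, v in shells.items()})

    # stage: calibration on the water reference
    cal_cfg = config["calibration"]
    ref = make_active_site_fixture(fx_cfg["seed"], fx_cfg["n_waters"], "reference")
    sys_ref = _leg_system(ref, 0.0, 6.0)
    proto = CalibrationProtocol(
        schedule=MappingSchedule(n_windows=cal_cfg["windows"],
                                 steps_per_window=cal_cfg["steps_per_window"]),
        params=LangevinParams(temperature, lv["friction"], lv["timestep"], 0,
                              seed=cal_cfg["seed"]),
        tolerance=cal_cfg["tolerance"], max_iterations=cal_cfg["max_iterations"],
        bin_width=config["mapping"]["bin_width"])
    cal = calibrate(sys_ref, cal_cfg["reference_barrier"],
                    cal_cfg["reference_reaction_free_energy"], proto,
                    initial_alpha=cal_cfg["initial_alpha"],
                    initial_coupling=cal_cfg["initial_coupling"])
    report.stages["calibration"] = {
        "alpha_kcal_mol": round(cal.alpha, 4), "coupling_kcal_mol": round(cal.coupling, 4),
        "iterations": cal.iterations,
        "reference_barrier_kcal_mol": cal_cfg["reference_barrier"],
        "reference_dg_kcal_mol": cal_cfg["reference_reaction_free_energy"],
        "achieved_barrier_kcal_mol": round(cal.barrier, 3),
        "achieved_dg_kcal_mol": round(cal.dg_rxn, 3),
    }
    log("calibration", alpha=f"{cal.alpha:.2f}", A=f"{cal.coupling:.2f}", iters=cal.iterations)

    # stage: mapping / profile on the chosen variant (frozen parameters)
    mp = config["mapping"]
    barriers, dgs = [], []
    profile_rows = None
    for seed in mp["seeds"]:
        sysv = _leg_system(fixture, cal.alpha, cal.coupling)
        b, g, prof = measure_leg(sysv,
                                 MappingSchedule(n_windows=mp["windows"],
                                                 steps_per_window=mp["steps_per_window"]),
                                 LangevinParams(temperature, lv["friction"],
                                                lv["timestep"], 0, seed=int(seed)),
                                 bin_width=mp["bin_width"])
        barriers.append(b)
        dgs.append(g)
        profile_rows = prof
        log("mapping", seed=seed, barrier=f"{b:.2f}", dg=f"{g:.2f}")
    barrier = float(np.mean(barriers))
    report.stages["free_energy"] = {
        "barrier_kcal_mol": round(barrier, 3),
        "barrier_per_seed": [round(b, 3) for b in barriers],
        "barrier_spread_kcal_mol": round(float(np.std(barriers)), 3),
        "dg_rxn_kcal_mol": round(float(np.mean(dgs)), 3),
        "windows": mp["windows"], "steps_per_window": mp["steps_per_window"],
        "seeds": list(mp["seeds"]),
    }
    _write_profile(profile_rows, out_dir / "profile.tsv", config)

    # stage: hydration (water flooding of the fixture solute)
    fl = config["flood"]
    cavity = CavitySpec(tuple(fixture.reactive_midpoint), fl["radius"])
    flood = water_flood(fixture.pocket_structure, cavity,
                        WaterFloodParams(n_sweeps=fl["sweeps"], seed=fl["seed"],
                                         temperature=temperature))
    report.stages["hydration"] = {
        "mean_occupancy": round(flood.mean_occupancy, 2),
        "cavity_radius_A": fl["radius"], "sweeps": fl["sweeps"], "seed": fl["seed"],
    }
    log("hydration", occupancy=f"{flood.mean_occupancy:.1f}")

    # stage: binding (simplified-LRA, phosphate as the ligand)
    lra_cfg = config["lra"]
    pi_idx = [i for i, a in enumerate(fixture.structure.atoms) if a.residue_name == "PO4"]
    if pi_idx:
        est = lra_binding(fixture.system, pi_idx,
                          LRAProtocol(lra_cfg["n_configurations"],
                                      lra_cfg["steps_per_configuration"],
                                      temperature, lra_cfg["seed"]),
                          DielectricModel(), structure=fixture.structure)
        report.stages["binding"] = {
            "ligand": "PO4", "delta_g_kcal_mol": round(est.delta_g, 3),
            "label": est.label, "equilibrated": est.equilibrated,
        }
        log("binding", dg=f"{est.delta_g:.2f}")

    # stage: kinetics / pH energetics
    kin = config["kinetics"]
    obs_barrier = tst_convert("rate_to_barrier", kin["kcat"], kin["temperature"])
    report.stages["kinetics"] = {
        "kcat_s": kin["kcat"],
        "observed_barrier_kcal_mol": round(obs_barrier, 3),
        "calculated_rate_s": tst_convert("barrier_to_rate", barrier, kin["temperature"]),
        "hydroxide_formation_kcal_mol": round(
            hydroxide_formation_energy(kin["ph"]), 3),
        "temperature_K": kin["temperature"], "ph": kin["ph"],
    }

    report.provenance = {
        "package_version": __version__, "config_digest": config.digest(),
        "config": config.data, "wall_time_s": round(time.time() - t_start, 1),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return report


def _write_profile(profile, path, config):
    with open(path, "w") as fh:
        fh.write(f"# bin_width={config['mapping']['bin_width']} kcal/mol\n")
        fh.write(f"# barrier={profile.barrier:.4f} kcal/mol\n")
        fh.write(f"# dg_rxn={profile.dg_rxn:.4f} kcal/mol\n")
        fh.write("gap_kcal_mol\tdg_kcal_mol\tcount\n")
        for x, g, n in zip(profile.bin_centers, profile.dg, profile.counts):
            fh.write(f"{x:.3f}\t{g:.5f}\t{int(n)}\n")
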