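"""Configuration-driven orchestration and command-line entry points.

A YAML run config selects the lattice, the mechanical fields, model
parameter overrides, and the list of scenarios; ``run_battery`` executes
every scenario, exports final-state CSVs, heatmaps, radial profiles and
region statistics, and writes a manifest JSON listing every output file,
per-scenario convergence and boundary/interior NT ratios. One global seed
fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from .lattice import Lattice, generate_lattice
from .mechanics import FieldParams, analytic_fields, fields_from_traction_csv
from .model import ModelParams, simulate
from .quantify import radial_profile, region_stats, render_heatmap
from .scenarios import Scenario, apply_scenario, scenario_battery
from .synthetic import GeneratorParams, generate_tables

logger = logging.getLogger(__name__)

_CONFIG_SECTIONS = {"lattice", "fields", "model", "scenarios", "out_dir", "log_level"}


@dataclass
class RunConfig:
    """Validated run configuration (unknown keys are rejected)."""

    n_cells: int = 400
    seed: int = 0
    tol: float = 1e-3
    field_params: FieldParams = field(default_factory=FieldParams)
    traction_csv: str | None = None
    model_overrides: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=scenario_battery)
    out_dir: str = "results/battery"
    log_level: str = "INFO"
    t_end: float = 1000.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kw = {}
        lat = raw.get("lattice", {})
        _reject_unknown(lat, {"n_cells", "seed", "tol", "t_end"}, "lattice")
        kw.update({k: lat[k] for k in ("n_cells", "seed", "tol") if k in lat})
        fl = raw.get("fields", {})
        fp_names = {f.name for f in dc_fields(FieldParams)}
        _reject_unknown(fl, fp_names | {"traction_csv"}, "fields")
        kw["traction_csv"] = fl.pop("traction_csv", None)
        kw["field_params"] = FieldParams(**fl)
        mdl = raw.get("model", {})
        mp_names = {f.name for f in dc_fields(ModelParams)} | {"t_end"}
        _reject_unknown(mdl, mp_names, "model")
        kw["t_end"] = mdl.pop("t_end", 1000.0)
        kw["model_overrides"] = mdl
        if "scenarios" in raw:
            kw["scenarios"] = [_scenario_from_dict(s) for s in raw["scenarios"]]
        if "out_dir" in raw:
            kw["out_dir"] = raw["out_dir"]
        if "log_level" in raw:
            kw["log_level"] = raw["log_level"]
        return cls(**kw)


def _reject_unknown(d: dict, allowed: set, section: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")


def _scenario_from_dict(d: dict) -> Scenario:
    d = dict(d)
    d.setdefault("name", "unnamed")
    # YAML schema uses egf/tgfb2 as treatment keys
    if "egf" in d:
        d["egf_on"] = bool(d.pop("egf"))
    if "tgfb2" in d:
        d["tgf_on"] = bool(d.pop("tgfb2"))
    d.pop("overrides", None)
    allowed = {f.name for f in dc_fields(Scenario)}
    _reject_unknown(d, allowed, f"scenario '{d.get('name')}'")
    return Scenario(**d)


def _stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (stable across runs)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _config_hash(cfg: RunConfig) -> str:
    payload = {
        "n_cells": cfg.n_cells,
        "seed": cfg.seed,
        "tol": cfg.tol,
        "t_end": cfg.t_end,
        "field_params": asdict(cfg.field_params),
        "traction_csv": cfg.traction_csv,
        "model_overrides": cfg.model_overrides,
        "scenarios": [asdict(s) for s in cfg.scenarios],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_battery(cfg: RunConfig) -> dict:
    """Simulate every scenario in the config and write all artifacts.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    A scenario failure is recorded in the manifest; the run only fails if
    every scenario fails.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lattice = generate_lattice(cfg.n_cells, seed=_stage_seed(cfg.seed, "lattice"),
                               tol=cfg.tol)
    if cfg.traction_csv:
        fields_base = fields_from_traction_csv(lattice, cfg.traction_csv,
                                               cfg.field_params)
    else:
        fields_base = analytic_fields(lattice, cfg.field_params)
    params_base = ModelParams(**cfg.model_overrides)

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "global_seed": cfg.seed,
        "n_cells": cfg.n_cells,
        "outputs": [],
        "scenarios": {},
    }
    lattice_path = out / "lattice.json"
    lattice.to_json(lattice_path)
    manifest["outputs"].append(str(lattice_path))

    sim_seed = _stage_seed(cfg.seed, "simulate")
    n_failed = 0
    for sc in cfg.scenarios:
        entry = {"failed": False}
        try:
            p, flds = apply_scenario(params_base, fields_base, sc)
            traj = simulate(lattice, flds, p, scenario=sc, t_end=cfg.t_end,
                            seed=sim_seed)
            nt = traj.final_nt()
            state_path = out / f"{sc.name}_final.csv"
            _write_final_csv(state_path, lattice, traj)
            heat_path = out / f"{sc.name}_nt.png"
            render_heatmap(lattice, nt, heat_path, title=sc.name)
            prof_path = out / f"{sc.name}_profile.csv"
            radial_profile(nt, lattice.radius).to_frame().to_csv(prof_path,
                                                                 index=False)
            rs = region_stats(nt, lattice.radius)
            entry.update(
                converged=traj.converged,
                boundary_mean_nt=rs.boundary_mean,
                interior_mean_nt=rs.interior_mean,
                boundary_interior_ratio=rs.ratio,
                p_value=rs.p_value,
            )
            manifest["outputs"] += [str(state_path), str(heat_path), str(prof_path)]
        except Exception as exc:  # noqa: BLE001 - recorded per scenario
            logger.exception("scenario %s failed", sc.name)
            entry = {"failed": True, "error": str(exc)}
            n_failed += 1
        manifest["scenarios"][sc.name] = entry

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["outputs"].append(str(manifest_path))
    if n_failed == len(cfg.scenarios) and cfg.scenarios:
        raise RuntimeError("all scenarios failed; see manifest for errors")
    return manifest


def _write_final_csv(path, lattice: Lattice, traj) -> None:
    import pandas as pd

    from .model import SPECIES

    final = traj.final
    df = pd.DataFrame({"cell_id": np.arange(lattice.n_cells),
                       "radius": lattice.radius})
    for k, sp in enumerate(SPECIES):
        df[sp] = final[k]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level):
    """Notch-island simulation and quantification workbench."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))


@cli.command("lattice")
@click.option("--n-cells", default=400, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_lattice(n_cells, seed, out):
    """Generate a relaxed disk lattice and write it as JSON."""
    lat = generate_lattice(n_cells, seed=seed)
    lat.to_json(out)
    click.echo(f"wrote {out} ({n_cells} cells, converged={lat.converged})")


@cli.command("fields")
@click.option("--lattice-json", "lattice_json", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_fields(lattice_json, out):
    """Evaluate the analytic mechanical fields on a lattice (CSV)."""
    import pandas as pd

    lat = Lattice.from_json(lattice_json)
    flds = analytic_fields(lat)
    pd.DataFrame(
        {
            "cell_id": np.arange(lat.n_cells),
            "radius": lat.radius,
            "traction": flds.traction,
            "cellcell": flds.cellcell,
            "ecad": flds.ecad,
        }
    ).to_csv(out, index=False)
    click.echo(f"wrote {out}")


@cli.command("simulate")
@click.option("--config", required=True, type=click.Path(exists=True))
@click.option("--scenario", "scenario_name", default="wt", show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_simulate(config, scenario_name, out):
    """Simulate one named scenario from a config; write the trajectory CSV."""
    cfg = RunConfig.from_yaml(config)
    by_name = {s.name: s for s in cfg.scenarios}
    if scenario_name not in by_name:
        raise click.ClickException(f"scenario '{scenario_name}' not in config")
    lat = generate_lattice(cfg.n_cells, seed=_stage_seed(cfg.seed, "lattice"),
                           tol=cfg.tol)
    flds = analytic_fields(lat, cfg.field_params)
    p, flds = apply_scenario(ModelParams(**cfg.model_overrides), flds,
                             by_name[scenario_name])
    traj = simulate(lat, flds, p, scenario=by_name[scenario_name],
                    t_end=cfg.t_end, seed=_stage_seed(cfg.seed, "simulate"))
    traj.to_csv(out)
    click.echo(f"wrote {out} (converged={traj.converged})")


@cli.command("battery")
@click.option("--config", required=True, type=click.Path(exists=True))
def cli_battery(config):
    """Run the full scenario battery from a YAML config."""
    manifest = run_battery(RunConfig.from_yaml(config))
    click.echo(json.dumps({k: v for k, v in manifest.items() if k != "outputs"},
                          indent=2))


@cli.command("quantify")
@click.option("--cells-csv", required=True, type=click.Path(exists=True))
@click.option("--value-col", required=True)
@click.option("--out", required=True, type=click.Path())
def cli_quantify(cells_csv, value_col, out):
    """Radial profile + region stats of one column of a per-cell CSV."""
    import pandas as pd

    df = pd.read_csv(cells_csv)
    vals = df[value_col].to_numpy(float)
    radii = df["radius"].to_numpy(float)
    prof = radial_profile(vals, radii)
    prof.to_frame().to_csv(out, index=False)
    rs = region_stats(vals, radii)
    click.echo(json.dumps(asdict(rs), indent=2))


@cli.command("synthgen")
@click.option("--seed", default=0, show_default=True)
@click.option("--n-islands", default=50, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_synthgen(seed, n_islands, out):
    """Generate a synthetic per-cell island table (CSV)."""
    gp = GeneratorParams(seed=seed, n_islands=n_islands)
    generate_tables(gp).to_csv(out, index=False)
    click.echo(f"wrote {out}")


@cli.command("compare")
@click.option("--sim-csv", required=True, type=click.Path(exists=True),
              help="per-cell final-state CSV with radius and NT columns")
@click.option("--cells-csv", required=True, type=click.Path(exists=True))
def cli_compare(sim_csv, cells_csv):
    """Rank-correlate a simulated NT pattern with a synthetic OPN table."""
    import pandas as pd

    from .synthetic import model_vs_data_summary

    sim = pd.read_csv(sim_csv)
    table = pd.read_csv(cells_csv)
    rec = model_vs_data_summary(sim["NT"].to_numpy(float),
                                sim["radius"].to_numpy(float), table)
    click.echo(json.dumps(rec, indent=2))


if __name__ == "__main__":
    sys.exit(cli())
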