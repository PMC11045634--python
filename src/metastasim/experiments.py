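"""Experiment presets, orchestration and summaries.

Four canonical experiments exercise the full model:

1. **haptotaxis-flow** — EMT only (no MET, no reactions) on a directional
   ECM: the spherical epithelial tumour is progressively converted into
   solitary mesenchymal cells that migrate up the ECM gradient.
2. **cancer-cell-islands** — full dynamics on a hierarchical random ECM:
   mesenchymal cells escape the tumour, revert by MET and seed proliferating
   epithelial islands away from the primary mass.
3. **growing-merging-microtumours** — no phenotype switching: two epithelial
   spheroids grow by proliferation, interact with the heterogeneous ECM and
   merge.
4. **multiple-organ-metastasis** — four organs joined by a circulatory
   network; the full metastatic cascade from primary EMT to secondary
   micro-metastases.

Desk-scale defaults use 32 cells per axis (the printed study resolution,
64 per axis, is a config choice away) with run horizons chosen so the
dominant process of each experiment is visible.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grid import ConfigurationError, make_grid, ScalarField
from .density import DensityState, stable_dt
from .agents import CellSet
from .environment import (EcmSpec, ball_support, random_caf_ic,
                          spherical_tumor_ic, tgf_mmp_ic)
from .organism import EventLog, Organ, Organism, step_organism
from .params import ModelParams
from .transfer import Partition, cells_to_density
from . import io as _io

__all__ = ["RunConfig", "preset", "run", "validate_config", "describe",
           "summarize", "compare_island_growth", "support_volume",
           "PRESET_NAMES"]

DEFAULT_EXTENT = ((-0.05, 0.05), (-0.05, 0.05), (-0.05, 0.05))
TUMOR_RADIUS = 0.01  # cm
SUPPORT_LEVEL = 0.99  # isosurface level defining "tumour support"

PRESET_NAMES = {
    "exp1": "haptotaxis-flow",
    "exp2": "cancer-cell-islands",
    "exp3": "growing-merging-microtumours",
    "exp4": "multiple-organ-metastasis",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    experiment: str = "exp1"
    shape: tuple[int, ...] = (32, 32, 32)
    extent: tuple = DEFAULT_EXTENT
    t_end: float = 0.05           # days
    seed: int = 0
    snapshot_every: int = 10      # steps between snapshots (0 = only ends)
    coarsening: int = 1           # partition factor per axis
    n_organs: int = 1
    overrides: dict = field(default_factory=dict)
    reactions_on: bool = True
    emt_on: bool = True
    met_on: bool = True
    network_on: bool = False
    ecm_mode: str = "directional"
    ecm_levels: int | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            hints = {k: difflib.get_close_matches(k, known, n=1) for k in unknown}
            msg = "; ".join(
                f"unknown key {k!r}" + (f" (did you mean {h[0]!r}?)" if h else "")
                for k, h in hints.items())
            raise ConfigurationError(msg)
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if "extent" in raw:
            raw["extent"] = tuple(tuple(e) for e in raw["extent"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def preset(name: str, **kwargs) -> RunConfig:
    """Build the RunConfig for one of the four canonical experiments."""
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESET_NAMES)}")
    base = dict(experiment=name)
    if name == "exp1":
        # only epithelial diffusion is active; TGF-beta does not spread, so
        # EMT relies on partition cells straddling the tumour boundary --
        # hence a coarsening of 2 (partition cells of biological-cell kind,
        # coarser than the computational grid)
        base.update(ecm_mode="directional", reactions_on=False, emt_on=True,
                    met_on=False, network_on=False, t_end=0.05, coarsening=2,
                    overrides={"pde.D_F": 0.0, "pde.D_b": 0.0, "pde.D_m": 0.0,
                               "pde.chi_F": 0.0})
    elif name == "exp2":
        base.update(ecm_mode="hierarchical", reactions_on=True, emt_on=True,
                    met_on=True, network_on=False, t_end=0.05)
    elif name == "exp3":
        base.update(ecm_mode="hierarchical", reactions_on=True, emt_on=False,
                    met_on=False, network_on=False, t_end=0.05)
    else:  # exp4
        base.update(ecm_mode="hierarchical", reactions_on=True, emt_on=True,
                    met_on=True, network_on=True, n_organs=4, t_end=0.05)
    base.update(kwargs)
    return RunConfig(**base)


def _apply_overrides(params: ModelParams, overrides: dict) -> ModelParams:
    valid_groups = ("pde", "sde", "emt", "met", "network")
    for key, val in overrides.items():
        parts = key.split(".")
        if len(parts) != 2 or parts[0] not in valid_groups + ("", "model"):
            if len(parts) == 1 and hasattr(params, parts[0]):
                setattr(params, parts[0], val)
                continue
            raise ConfigurationError(f"override key {key!r} not of form group.name")
        group, name = parts
        target = getattr(params, group)
        if not hasattr(target, name):
            cands = [f.name for f in dataclasses.fields(target)]
            hint = difflib.get_close_matches(name, cands, n=1)
            extra = f"; did you mean '{group}.{hint[0]}'?" if hint else ""
            raise ConfigurationError(f"unknown parameter {key!r}{extra}")
        setattr(target, name, val)
    return params


def build_params(config: RunConfig) -> ModelParams:
    params = ModelParams()
    return _apply_overrides(params, dict(config.overrides))


def _build_organ(oid: int, config: RunConfig, params: ModelParams,
                 rng: np.random.Generator, with_tumour: bool) -> Organ:
    grid = make_grid(config.extent[: len(config.shape)], config.shape)
    part = Partition(grid, tuple(config.coarsening for _ in config.shape))

    levels = config.ecm_levels
    if levels is None and config.ecm_mode == "hierarchical":
        levels = int(round(np.log2(config.shape[0] / 8)))
    spec = EcmSpec(mode=config.ecm_mode, v_min=params.v_min, v_max=params.v_max,
                   levels=levels if levels is not None else 3)
    v = spec.build(grid, rng)

    if with_tumour:
        if config.experiment == "exp3":
            offs = 0.01 * np.array([[1.0, -1.0, -1.0], [-1.0, 1.0, 1.0]])[:, : grid.dim]
            cE = spherical_tumor_ic(grid, list(offs), TUMOR_RADIUS, density=1.0)
            support = ball_support(grid, list(offs), TUMOR_RADIUS)
        else:
            centre = [np.zeros(grid.dim)]
            cE = spherical_tumor_ic(grid, centre, TUMOR_RADIUS, density=3.0)
            support = ball_support(grid, centre, TUMOR_RADIUS)
    else:
        cE = ScalarField.zeros(grid)
        support = np.zeros(grid.shape, dtype=bool)

    cF = random_caf_ic(grid, rng)
    b, m = tgf_mmp_ic(grid, support, rng)
    state = DensityState(cE=cE, cF=cF, b=b, m=m, v=v)
    cells = CellSet(grid)
    return Organ(id=oid, grid=grid, state=state, cells=cells, partition=part)


def build_organism(config: RunConfig, params: ModelParams,
                   rng: np.random.Generator) -> Organism:
    organs = [
        _build_organ(k, config, params, rng, with_tumour=(k == 0))
        for k in range(config.n_organs)
    ]
    if config.n_organs > 1:
        conn = {o.id: [q.id for q in organs if q.id != o.id] for o in organs}
    else:
        conn = {organs[0].id: []}
    if params.pde.normalize_carrying_capacity and params.pde.carrying_capacity is None:
        cap = 0.0
        for o in organs:
            st = o.state
            tot = st.cE.values + st.cM_density.values + st.cF.values + st.v.values
            cap = max(cap, float(tot.max()))
        params.pde.carrying_capacity = cap
    return Organism(organs=organs, connectivity=conn)


def support_volume(state: DensityState, level: float = SUPPORT_LEVEL) -> float:
    """Volume (cm³) of the region where the epithelial density ≥ level."""
    return float((state.cE.values >= level).sum()) * state.grid.cell_volume


def run(config: RunConfig, params: ModelParams | None = None) -> dict:
    """Execute the composed hybrid loop and return (and optionally write) a summary.

    The loop per global step: density transport+reactions → EMT → MET →
    agent migration → intravasation/transit.  A biomass ledger is audited at
    every step; instability aborts with the last state retained.
    """
    rng = np.random.default_rng(config.seed)
    params = params if params is not None else build_params(config)
    organism = build_organism(config, params, rng)
    log = EventLog()

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        h5path = out_dir / "snapshots.h5"
        if h5path.exists():
            h5path.unlink()
    traj_rows: list = []
    audit_rows: list = []
    run_id = f"{config.experiment}-seed{config.seed}"

    initial_biomass = organism.total_biomass()
    t, step, snap_idx = 0.0, 0, 0
    if out_dir:
        _io.write_snapshot(h5path, organism, snap_idx)
        snap_idx += 1
    aborted = None
    while t < config.t_end - 1e-15:
        dt = min(stable_dt(o.state, params.pde, reactions_on=config.reactions_on)
                 for o in organism.organs)
        dt = min(dt, config.t_end - t)
        try:
            organism = step_organism(
                organism, params, dt, rng, log=log,
                reactions_on=config.reactions_on, emt_on=config.emt_on,
                met_on=config.met_on, network_on=config.network_on)
        except FloatingPointError as err:
            aborted = str(err)
            break
        t += dt
        step += 1
        booked = sum(o.state.reaction_mass + o.state.clipped_mass
                     for o in organism.organs)
        total = organism.total_biomass()
        residual = total - initial_biomass - booked + organism.ctc_death_mass
        audit_rows.append({
            "time_d": t, "step": step, "dt": dt,
            **{f"mass_{k}_organ{o.id}": v for o in organism.organs
               for k, v in o.state.field_masses().items()},
            "agents": organism.total_agents(),
            "total_biomass_g": total,
            "reaction_plus_clip_g": booked,
            "ctc_death_mass_g": organism.ctc_death_mass,
            "ledger_residual_g": residual,
        })
        if out_dir and config.snapshot_every and step % config.snapshot_every == 0:
            _io.write_snapshot(h5path, organism, snap_idx)
            snap_idx += 1
            _io.append_trajectories(traj_rows, organism, run_id)

    scale = max(initial_biomass, 1e-300)
    summary = {
        "experiment": config.experiment,
        "preset_name": PRESET_NAMES.get(config.experiment, "custom"),
        "seed": config.seed,
        "t_end": t,
        "steps": step,
        "aborted": aborted,
        "final_masses": {
            f"organ_{o.id}": {k: round(v, 15) for k, v in o.state.field_masses().items()}
            for o in organism.organs
        },
        "agent_counts": {f"organ_{o.id}": len(o.cells) for o in organism.organs},
        "in_transit": sum(1 for r in organism.transit if r.status == "in_transit"),
        "event_totals": {
            kind: log.count(kind)
            for kind in ("EMT", "MET", "intravasation", "ctc_death", "extravasation")
        },
        "support_volume_cm3": {
            f"organ_{o.id}": support_volume(o.state) for o in organism.organs
        },
        "max_ledger_residual_rel": max(
            (abs(r["ledger_residual_g"]) / scale for r in audit_rows), default=0.0),
    }

    if out_dir:
        _io.write_snapshot(h5path, organism, snap_idx)
        _io.append_trajectories(traj_rows, organism, run_id)
        _io.write_events(out_dir / "events.jsonl", log)
        _io.write_audit(out_dir / "audit.csv", audit_rows)
        import pandas as pd

        pd.DataFrame(traj_rows).to_csv(out_dir / "trajectories.csv", index=False)
        _io.write_summary(out_dir / "summary.json", summary)

    summary["_organism"] = organism
    summary["_events"] = log
    summary["_audit"] = audit_rows
    return summary


def validate_config(config: RunConfig) -> dict:
    """Schema check, parameter echo with provenance, and a dt pre-estimate."""
    params = build_params(config)
    for ax, n in enumerate(config.shape):
        if n % config.coarsening != 0:
            raise ConfigurationError(
                f"axis {ax}: coarsening factor {config.coarsening} does not divide "
                f"grid shape {n}")
    if config.ecm_mode == "hierarchical":
        levels = config.ecm_levels
        if levels is None:
            raw = np.log2(config.shape[0] / 8)
            if abs(raw - round(raw)) > 1e-9:
                raise ConfigurationError(
                    f"hierarchical ECM needs shape = 8·2^levels per axis, got {config.shape}")
    defaults = ModelParams()
    echo = {}
    for group in ("pde", "sde", "emt", "met", "network"):
        for f_ in dataclasses.fields(getattr(params, group)):
            key = f"{group}.{f_.name}"
            val = getattr(getattr(params, group), f_.name)
            dval = getattr(getattr(defaults, group), f_.name)
            echo[key] = {"value": val,
                         "provenance": "override" if val != dval else "default"}
    grid = make_grid(config.extent[: len(config.shape)], config.shape)
    state = DensityState.zeros(grid)
    state.cE.values[:] = 1.0  # worst-case mobility estimate
    dt_est = stable_dt(state, params.pde)
    return {"config": config.to_dict(), "parameters": echo,
            "dt_estimate_d": dt_est, "grid_spacing_cm": grid.spacing,
            "domain_volume_cm3": grid.volume}


def describe(config: RunConfig) -> str:
    rep = validate_config(config)
    lines = [f"experiment: {rep['config']['experiment']} "
             f"({PRESET_NAMES.get(rep['config']['experiment'], 'custom')})",
             f"grid: {rep['config']['shape']}, spacing {rep['grid_spacing_cm']} cm, "
             f"volume {rep['domain_volume_cm3']:g} cm^3",
             f"dt pre-estimate: {rep['dt_estimate_d']:.3e} d"]
    overridden = {k: v for k, v in rep["parameters"].items()
                  if v["provenance"] == "override"}
    lines.append(f"overridden parameters: {len(overridden)}")
    for k, v in sorted(overridden.items()):
        lines.append(f"  {k} = {v['value']}")
    return "\n".join(lines)


def summarize(run_dir) -> dict:
    """Metrics table for a completed run directory: CSV + JSON artefacts."""
    import pandas as pd

    run_dir = Path(run_dir)
    audit_path = run_dir / "audit.csv"
    if not audit_path.exists():
        raise FileNotFoundError(f"no audit.csv in {run_dir}; run incomplete?")
    audit = pd.read_csv(audit_path)
    events_path = run_dir / "events.jsonl"
    events = []
    if events_path.exists():
        with open(events_path) as fh:
            events = [json.loads(line) for line in fh if line.strip()]
    counts: dict[str, int] = {}
    for rec in events:
        counts[rec["kind"]] = counts.get(rec["kind"], 0) + 1
    summary_path = run_dir / "summary.json"
    summary = json.loads(summary_path.read_text()) if summary_path.exists() else {}
    metrics = {
        "n_steps": int(audit["step"].max()) if len(audit) else 0,
        "t_final_d": float(audit["time_d"].max()) if len(audit) else 0.0,
        "event_counts": counts,
        "final_agents": int(audit["agents"].iloc[-1]) if len(audit) else 0,
        "max_ledger_residual_g": float(audit["ledger_residual_g"].abs().max())
        if len(audit) else 0.0,
        "support_volume_cm3": summary.get("support_volume_cm3", {}),
    }
    audit.to_csv(run_dir / "metrics_timeseries.csv", index=False)
    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return metrics


def compare_island_growth(shape=(32, 32, 32), t_end: float = 3.0, seed: int = 0,
                          level: float = 0.5) -> dict:
    """Two separated microtumours vs one equal-mass sphere, same ECM and seed.

    Both runs use the merging-microtumours dynamics with the carrying
    capacity normalised to the initial maximum occupancy, so proliferation
    acts as surface growth.  Reported: support volumes (at the given
    epithelial level) and total epithelial masses at the matched final time.
    """
    results = {}
    shared_capacity: float | None = None
    for label, two_islands in (("two_islands", True), ("single_mass", False)):
        cfg = preset("exp3", shape=tuple(shape), t_end=t_end, seed=seed,
                     overrides={"pde.normalize_carrying_capacity": True})
        params = build_params(cfg)
        if shared_capacity is not None:
            params.pde.carrying_capacity = shared_capacity
        rng = np.random.default_rng(cfg.seed)
        organism = build_organism(cfg, params, rng)
        shared_capacity = params.pde.carrying_capacity
        organ = organism.organs[0]
        if not two_islands:
            # replace the two balls by one sphere of equal initial mass
            grid = organ.grid
            single = spherical_tumor_ic(grid, [np.zeros(grid.dim)],
                                        TUMOR_RADIUS * 2 ** (1.0 / grid.dim),
                                        density=1.0)
            target = organ.state.cE.total_mass()
            got = single.total_mass()
            if got > 0:
                single.values *= target / got  # match initial mass exactly
            organ.state.cE = single
        t = 0.0
        while t < t_end - 1e-15:
            dt = min(stable_dt(organ.state, params.pde), t_end - t)
            organism = step_organism(organism, params, dt, rng,
                                     reactions_on=True, emt_on=False,
                                     met_on=False, network_on=False)
            t += dt
        results[label] = {
            "support_volume_cm3": support_volume(organ.state, level),
            "cE_mass_g": organ.state.cE.total_mass(),
        }
    results["islands_grow_faster"] = (
        results["two_islands"]["cE_mass_g"] > results["single_mass"]["cE_mass_g"])
    return results
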