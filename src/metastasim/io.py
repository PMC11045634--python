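"""Run artefact writers: HDF5 snapshots, CSV trajectories/audits, JSONL events."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .organism import Organism

__all__ = [
    "write_snapshot",
    "append_trajectories",
    "write_events",
    "write_audit",
    "write_summary",
]


def write_snapshot(h5path, organism: Organism, idx: int) -> None:
    """Append one snapshot group per organ: /organ_<k>/t_<idx>/{cE,cF,b,m,v}."""
    with h5py.File(h5path, "a") as f:
        for organ in organism.organs:
            grp = f.require_group(f"organ_{organ.id}").create_group(f"t_{idx:05d}")
            st = organ.state
            for name in ("cE", "cF", "b", "m", "v"):
                grp.create_dataset(name, data=getattr(st, name).values)
            grp.create_dataset("cM", data=st.cM_density.values)
            grp.attrs["time"] = st.time
            grp.attrs["spacing"] = organ.grid.spacing
            grp.attrs["extent_lo"] = organ.grid.lo
            grp.attrs["extent_hi"] = organ.grid.hi


def append_trajectories(rows: list, organism: Organism, run_id: str) -> None:
    for organ in organism.organs:
        t = organ.state.time
        for cid, pos, m in zip(organ.cells.ids, organ.cells.positions,
                               organ.cells.masses):
            xyz = list(pos) + [np.nan] * (3 - len(pos))
            rows.append({
                "run_id": run_id, "time_d": t, "cell_id": int(cid),
                "organ_id": organ.id, "x": xyz[0], "y": xyz[1], "z": xyz[2],
                "mass_g": float(m),
            })


def write_events(path, log) -> None:
    with open(path, "w") as f:
        for rec in log:
            f.write(json.dumps(rec, sort_keys=True) + "\n")


def write_audit(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
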