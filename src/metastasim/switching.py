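"""Stochastic epithelial–mesenchymal plasticity.

EMT fires as a Poisson count per partition cell with intensity ζ(b̄)·τ,
where ζ is a shifted logistic in the local mean TGF-β concentration,
ζ(b) = L / (1 + exp(−k (b − b_T))), gated on the epithelial density
exceeding C_ref.  Each event converts one cell quantum m_cell of epithelial
mass into a fresh solitary mesenchymal agent at the partition-cell
barycentre.  MET is the reverse: each agent independently reverts with
probability 1 − exp(−r τ) and its mass is deposited back as epithelial
density through the cell-to-density operator.  Both directions move grams,
never create them.
"""

from __future__ import annotations

import numpy as np

from .density import DensityState
from .agents import CellSet
from .params import EmtParams, MetParams
from .transfer import Partition, cells_to_density

__all__ = [
    "emt_rate",
    "sample_emt_events",
    "apply_emt",
    "sample_met",
    "apply_met",
]


def emt_rate(b, p: EmtParams):
    """Shifted-logistic EMT rate ζ(b) in 1/d; strictly increasing, range (0, L)."""
    b = np.asarray(b, dtype=float)
    # clip the exponent to avoid overflow for the huge printed steepness values
    z = np.clip(-p.k * (b - p.b_T), -700.0, 700.0)
    out = p.L / (1.0 + np.exp(z))
    return out if out.shape else float(out)


def default_m_cell(p: EmtParams, part: Partition) -> float:
    """Mass converted per EMT event: C_ref × one partition-cell volume."""
    if p.m_cell is not None:
        return p.m_cell
    return p.C_ref * part.cell_volume


def sample_emt_events(cE, b, part: Partition, p: EmtParams, tau: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Poisson EMT event counts on the partition lattice.

    Partition cells whose mean epithelial density is below the C_ref gate
    get zero; elsewhere counts ~ Poisson(ζ(b̄_i)·τ), capped so the converted
    mass never exceeds the epithelial mass available on the cell.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    cE_bar = part.block_reduce(cE.values, np.mean)
    b_bar = part.block_reduce(b.values, np.mean)
    eligible = cE_bar >= p.C_ref
    lam = np.where(eligible, emt_rate(b_bar, p) * tau, 0.0)
    counts = rng.poisson(lam)
    m_cell = default_m_cell(p, part)
    avail = cE_bar * part.cell_volume  # epithelial mass per M cell
    cap = np.floor(avail / (p.mu_E_EMT * m_cell)).astype(np.int64)
    return np.minimum(counts, np.maximum(cap, 0)).astype(np.int64)


def apply_emt(state: DensityState, cells: CellSet, events: np.ndarray,
              p: EmtParams, part: Partition,
              log: list | None = None) -> tuple[DensityState, CellSet]:
    """Convert sampled EMT events into agents, conserving mass exactly.

    Per event on partition cell M_i: mu_E_EMT·m_cell grams of epithelial
    density are removed from M_i (proportionally to the local density, so
    non-negativity is preserved) and one agent of that mass materialises at
    the barycentre with a fresh id.
    """
    events = np.asarray(events)
    if not events.any():
        return state, cells
    new_state = state.copy()
    new_cells = cells.copy()
    m_cell = p.mu_E_EMT * default_m_cell(p, part)
    centers = part.barycenters().reshape(part.shape + (state.grid.dim,))
    cell_vol = state.grid.cell_volume
    for flat in np.flatnonzero(events):
        mi = np.unravel_index(flat, part.shape)
        a = int(events[mi])
        sl = tuple(slice(i * f, (i + 1) * f) for i, f in zip(mi, part.factor))
        block = new_state.cE.values[sl]
        avail = float(block.sum()) * cell_vol
        take = a * m_cell
        if take > avail * (1 + 1e-9):
            raise RuntimeError("EMT event count exceeds available mass after capping")
        if avail > 0:
            block *= 1.0 - take / avail
        pos = centers[mi]
        new_ids = new_cells.add(np.tile(pos, (a, 1)), np.full(a, m_cell))
        if log is not None:
            for nid in new_ids:
                log.append({"t": state.time, "kind": "EMT", "M_index": list(map(int, mi)),
                            "cell_id": int(nid), "mass": m_cell})
    return new_state, new_cells


def sample_met(cells: CellSet, p: MetParams, tau: float,
               rng: np.random.Generator) -> np.ndarray:
    """Ids of agents flagged for MET: independent Bernoulli(1 − exp(−rτ))."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(cells) == 0:
        return np.empty(0, dtype=np.int64)
    prob = 1.0 - np.exp(-p.r * tau)
    flag = rng.random(len(cells)) < prob
    return cells.ids[flag]


def apply_met(state: DensityState, cells: CellSet, ids, part: Partition,
              log: list | None = None) -> tuple[DensityState, CellSet]:
    """Remove flagged agents and deposit their mass as epithelial density."""
    ids = np.atleast_1d(np.asarray(ids, dtype=np.int64))
    if ids.size == 0:
        return state, cells
    new_state = state.copy()
    new_cells = cells.copy()
    removed = new_cells.remove(ids)
    dep = cells_to_density(removed, part)
    new_state.cE.values = new_state.cE.values + dep.values
    if log is not None:
        for cid, m in zip(removed.ids, removed.masses):
            log.append({"t": state.time, "kind": "MET", "cell_id": int(cid),
                        "mass": float(m)})
    return new_state, new_cells
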