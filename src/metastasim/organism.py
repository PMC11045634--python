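"""Multi-organ metastasis: per-organ hybrid simulations coupled by a
circulatory network.

Each organ is an independent copy of the hybrid model (density fields +
solitary mesenchymal agents) on its own cubic domain.  Agents intravasate
into the circulation as a Poisson process, become circulating tumour cells
(CTCs), survive transit with a small Bernoulli probability (default 0.1%),
and survivors extravasate into an organ drawn uniformly from those
connected to the origin, re-entering as mesenchymal agents at a random
interior position.  An event log and a biomass ledger account for every
gram and every agent ever created.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ConfigurationError, Grid
from .density import DensityState, stable_dt, step_density
from .agents import CellSet, step_cells
from .grid import gradient
from .params import ModelParams, MetastasisParams
from .switching import sample_emt_events, apply_emt, sample_met, apply_met
from .transfer import Partition, cells_to_density, footprint_indicator

__all__ = [
    "Organ",
    "Organism",
    "CtcRecord",
    "EventLog",
    "sample_intravasation",
    "resolve_transit",
    "step_organism",
]


class EventLog(list):
    """Timestamped EMT/MET/intravasation/death/extravasation records."""

    def add(self, **record) -> None:
        self.append(record)

    def first_time(self, kind: str, organ: int | None = None) -> float | None:
        for rec in self:
            if rec.get("kind") == kind and (organ is None or rec.get("organ") == organ):
                return rec["t"]
        return None

    def count(self, kind: str) -> int:
        return sum(1 for rec in self if rec.get("kind") == kind)


@dataclass
class CtcRecord:
    """One circulating tumour cell in transit through the network."""

    cell_id: int
    mass: float
    origin: int
    entry_time: float
    due_time: float
    status: str = "in_transit"  # in_transit | died | extravasated

    def resolve(self, status: str) -> None:
        if self.status != "in_transit":
            raise RuntimeError("CTC status is terminal and immutable")
        self.status = status


@dataclass
class Organ:
    """One organ: grid, density state, agents and partition."""

    id: int
    grid: Grid
    state: DensityState
    cells: CellSet
    partition: Partition


@dataclass
class Organism:
    """Organs plus the (symmetric) circulatory connectivity and CTCs in transit."""

    organs: list[Organ]
    connectivity: dict[int, list[int]] = field(default_factory=dict)
    transit: list[CtcRecord] = field(default_factory=list)
    ctc_death_mass: float = 0.0

    def __post_init__(self) -> None:
        ids = {o.id for o in self.organs}
        for a, nbrs in self.connectivity.items():
            if a not in ids:
                raise ConfigurationError(f"connectivity refers to unknown organ {a}")
            for b in nbrs:
                if b not in ids:
                    raise ConfigurationError(f"connectivity refers to unknown organ {b}")
                if a not in self.connectivity.get(b, []):
                    raise ConfigurationError("connectivity must be symmetric")

    def organ(self, oid: int) -> Organ:
        for o in self.organs:
            if o.id == oid:
                return o
        raise KeyError(oid)

    def total_biomass(self) -> float:
        """Σ densities·volume + Σ agent masses + Σ in-transit masses (g)."""
        total = 0.0
        for o in self.organs:
            masses = o.state.field_masses()
            total += masses["cE"] + masses["cF"] + masses["b"] + masses["m"] + masses["v"]
            total += o.cells.total_mass
        total += sum(r.mass for r in self.transit if r.status == "in_transit")
        return total

    def total_agents(self) -> int:
        return sum(len(o.cells) for o in self.organs)


def sample_intravasation(cells: CellSet, p: MetastasisParams, tau: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Ids of agents entering circulation: Bernoulli(1 − exp(−λ_intra·τ))."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(cells) == 0 or p.lam_intra == 0:
        return np.empty(0, dtype=np.int64)
    prob = 1.0 - np.exp(-p.lam_intra * tau)
    flag = rng.random(len(cells)) < prob
    return cells.ids[flag]


def resolve_transit(organism: Organism, p: MetastasisParams,
                    rng: np.random.Generator, now: float = np.inf,
                    log: EventLog | None = None) -> Organism:
    """Resolve every due CTC: Bernoulli survival, uniform extravasation.

    Survivors enter an organ drawn uniformly from those connected to the
    origin (the origin itself only if a self-loop exists), at a uniformly
    random interior position.  Deaths are logged and their mass booked.
    """
    for rec in organism.transit:
        if rec.status != "in_transit" or rec.due_time > now:
            continue
        dests = organism.connectivity.get(rec.origin, [])
        if not dests:
            raise ConfigurationError(
                f"organ {rec.origin} has CTCs in transit but no connections")
        if rng.random() < p.p_survive:
            dest_id = dests[int(rng.integers(len(dests)))]
            dest = organism.organ(dest_id)
            pos = np.array([rng.uniform(lo, hi) for lo, hi in zip(dest.grid.lo, dest.grid.hi)])
            new_id = dest.cells.add(pos, [rec.mass])[0]
            rec.resolve("extravasated")
            if log is not None:
                log.add(t=rec.due_time if np.isfinite(rec.due_time) else rec.entry_time,
                        kind="extravasation", organ=int(dest_id),
                        origin=int(rec.origin), cell_id=int(new_id), mass=rec.mass)
        else:
            rec.resolve("died")
            organism.ctc_death_mass += rec.mass
            if log is not None:
                log.add(t=rec.due_time if np.isfinite(rec.due_time) else rec.entry_time,
                        kind="ctc_death", origin=int(rec.origin),
                        cell_id=int(rec.cell_id), mass=rec.mass)
    return organism


def step_organ(organ: Organ, params: ModelParams, dt: float,
               rng: np.random.Generator, log: EventLog | None = None,
               reactions_on: bool = True, emt_on: bool = True,
               met_on: bool = True) -> None:
    """One split step for a single organ: density → EMT → MET → agents."""
    st = organ.state
    # refresh agent-derived fields before any reaction evaluation
    st.cM_density = cells_to_density(organ.cells, organ.partition)
    foot = footprint_indicator(organ.cells, organ.grid)

    st = step_density(st, params.pde, dt, footprint=foot, reactions_on=reactions_on)

    if emt_on:
        sub = [] if log is not None else None
        events = sample_emt_events(st.cE, st.b, organ.partition, params.emt, dt, rng)
        st, organ.cells = apply_emt(st, organ.cells, events, params.emt,
                                    organ.partition, log=sub)
        if log is not None:
            for rec in sub:
                log.add(organ=organ.id, **rec)
    if met_on:
        sub = [] if log is not None else None
        ids = sample_met(organ.cells, params.met, dt, rng)
        st, organ.cells = apply_met(st, organ.cells, ids, organ.partition, log=sub)
        if log is not None:
            for rec in sub:
                log.add(organ=organ.id, **rec)

    if len(organ.cells):
        grads = gradient(st.v)
        organ.cells = step_cells(organ.cells, st.v, params.sde, dt, rng,
                                 grad_fields=grads)
    organ.state = st


def step_organism(organism: Organism, params: ModelParams, dt: float,
                  rng: np.random.Generator, log: EventLog | None = None,
                  reactions_on: bool = True, emt_on: bool = True,
                  met_on: bool = True, network_on: bool = True) -> Organism:
    """One global step: per-organ hybrid step, intravasation, transit.

    The biomass ledger closes exactly: the total changes only through the
    (logged) reaction and clipping terms and through CTC deaths.
    """
    now = organism.organs[0].state.time if organism.organs else 0.0
    for organ in organism.organs:
        step_organ(organ, params, dt, rng, log=log, reactions_on=reactions_on,
                   emt_on=emt_on, met_on=met_on)
        # an organ with no circulatory connections cannot shed CTCs anywhere
        if network_on and len(organ.cells) and organism.connectivity.get(organ.id):
            ids = sample_intravasation(organ.cells, params.network, dt, rng)
            if ids.size:
                removed = organ.cells.remove(ids)
                for cid, m in zip(removed.ids, removed.masses):
                    organism.transit.append(CtcRecord(
                        cell_id=int(cid), mass=float(m), origin=organ.id,
                        entry_time=now + dt,
                        due_time=now + dt + params.network.transit_time))
                    if log is not None:
                        log.add(t=now + dt, kind="intravasation", organ=organ.id,
                                cell_id=int(cid), mass=float(m))
    if network_on:
        resolve_transit(organism, params.network, rng, now=now + dt, log=log)
    return organism
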