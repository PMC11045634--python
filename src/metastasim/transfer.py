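"""Mass-conservative phase transitions between density fields and agents.

Two operators couple the continuum and discrete descriptions of cancer
cells.  The density-to-cell operator B integrates the density over each
partition cell M_i (a coarsening of the computational grid, nominally the
size of one biological cell) and materialises an agent with that mass at
the barycentre.  The cell-to-density operator F spreads each agent's mass
uniformly over its cubic footprint K_p and accumulates the overlap with
each M_i.  Both directions conserve mass exactly: the agents are point
ledgers of the same grams the fields carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ConfigurationError, Grid, ScalarField
from .agents import CellSet

__all__ = [
    "Partition",
    "density_to_cells",
    "cells_to_density",
    "roundtrip_check",
    "footprint_indicator",
]


@dataclass(frozen=True)
class Partition:
    """Coarsening of a grid into partition cells M_i tiling the domain."""

    grid: Grid
    factor: tuple[int, ...] = None

    def __post_init__(self) -> None:
        factor = self.factor or tuple(1 for _ in self.grid.shape)
        factor = tuple(int(f) for f in factor)
        object.__setattr__(self, "factor", factor)
        for ax, (f, n) in enumerate(zip(factor, self.grid.shape)):
            if f < 1:
                raise ConfigurationError(f"axis {ax}: coarsening factor {f} < 1")
            if n % f != 0:
                raise ConfigurationError(
                    f"axis {ax}: factor {f} does not divide grid shape {n}")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(n // f for n, f in zip(self.grid.shape, self.factor))

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(h * f for h, f in zip(self.grid.spacing, self.factor))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def side(self) -> float:
        """Default agent footprint side: one partition-cell side (min over axes)."""
        return min(self.spacing)

    def barycenters(self) -> np.ndarray:
        """(N_M, dim) array of M-cell centres, in C order of the M lattice."""
        axes = [self.grid.lo[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
                for a in range(self.grid.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def block_reduce(self, values: np.ndarray, op=np.mean) -> np.ndarray:
        """Reduce fine-grid values to the M lattice (mean by default)."""
        a = values
        for ax, f in enumerate(self.factor):
            n = a.shape[ax]
            a = a.reshape(a.shape[:ax] + (n // f, f) + a.shape[ax + 1:])
            a = op(a, axis=ax + 1)
        return a

    def expand(self, coarse: np.ndarray) -> np.ndarray:
        """Piecewise-constant prolongation of an M-lattice array to the grid."""
        a = coarse
        for ax, f in enumerate(self.factor):
            a = np.repeat(a, f, axis=ax)
        return a


def density_to_cells(c: ScalarField, part: Partition, mass_floor: float = 0.0,
                     start_id: int = 0) -> CellSet:
    """Operator B: one agent per partition cell holding at least ``mass_floor``.

    Mass via midpoint quadrature (mean density × M-cell volume), position at
    the barycentre; the emitted masses equal the integrated masses exactly.
    """
    if np.any(c.values < 0):
        raise ValueError("density_to_cells requires a non-negative field")
    part_masses = part.block_reduce(c.values, np.mean).ravel() * part.cell_volume
    emit = part_masses >= max(mass_floor, 0.0)
    if mass_floor <= 0.0:
        emit &= part_masses > 0.0
    centers = part.barycenters()[emit]
    masses = part_masses[emit]
    ids = np.arange(start_id, start_id + masses.size, dtype=np.int64)
    return CellSet(grid=c.grid, ids=ids, positions=centers, masses=masses,
                   K=part.side, next_id=start_id + masses.size)


def _overlap_fractions(part: Partition, x: np.ndarray, K: float):
    """Per-axis M-cell index ranges and overlap lengths for a cube at x.

    The cube is clipped to the domain and the overlap weights renormalised so
    no mass is lost at the walls.
    """
    g = part.grid
    slabs = []
    for ax in range(g.dim):
        lo_dom, hi_dom = g.lo[ax], g.hi[ax]
        H = part.spacing[ax]
        a = max(x[ax] - K / 2.0, lo_dom)
        b = min(x[ax] + K / 2.0, hi_dom)
        if b <= a:  # zero-size footprint: snap to the containing M cell
            i = min(int((x[ax] - lo_dom) / H), part.shape[ax] - 1)
            slabs.append((np.array([i]), np.array([1.0])))
            continue
        i0 = max(int(np.floor((a - lo_dom) / H)), 0)
        i1 = min(int(np.ceil((b - lo_dom) / H)), part.shape[ax])
        idx = np.arange(i0, i1)
        left = lo_dom + idx * H
        right = left + H
        ov = np.minimum(right, b) - np.maximum(left, a)
        ov = np.clip(ov, 0.0, None)
        w = ov / ov.sum()
        slabs.append((idx, w))
    return slabs


def cells_to_density(cells: CellSet, part: Partition,
                     K: float | None = None) -> ScalarField:
    """Operator F: spread each agent's mass over its footprint cube K_p.

    Returns a field piecewise constant on the partition whose integral equals
    the summed agent masses exactly.
    """
    g = part.grid
    K = cells.K if K is None else K
    coarse = np.zeros(part.shape)
    for x, m in zip(cells.positions, cells.masses):
        if not g.contains(x):
            raise ValueError(f"agent at {x} lies outside the domain")
        slabs = _overlap_fractions(part, x, K)
        w = slabs[0][1]
        for _, wa in slabs[1:]:
            w = np.multiply.outer(w, wa)
        idx = np.ix_(*[s[0] for s in slabs])
        coarse[idx] += m * w
    density = coarse / part.cell_volume
    return ScalarField(g, part.expand(density))


def footprint_indicator(cells: CellSet, grid: Grid, K: float | None = None) -> ScalarField:
    """Count, per computational cell, how many agent cubes cover its centre."""
    out = np.zeros(grid.shape)
    if len(cells) == 0:
        return ScalarField(grid, out)
    K = cells.K if K is None else K
    for x in cells.positions:
        sl = []
        empty = False
        for ax in range(grid.dim):
            h = grid.spacing[ax]
            # centres at lo + (i + 1/2) h inside [x - K/2, x + K/2]
            i0 = int(np.ceil((x[ax] - K / 2.0 - grid.lo[ax]) / h - 0.5))
            i1 = int(np.floor((x[ax] + K / 2.0 - grid.lo[ax]) / h - 0.5))
            i0 = max(i0, 0)
            i1 = min(i1, grid.shape[ax] - 1)
            if i1 < i0:
                empty = True
                break
            sl.append(slice(i0, i1 + 1))
        if not empty:
            out[tuple(sl)] += 1.0
    return ScalarField(grid, out)


def roundtrip_check(c: ScalarField, part: Partition) -> dict:
    """Audit of the B∘F round trip on a density field.

    For fields already piecewise constant on the partition (with the default
    footprint K equal to the M-cell side) the round trip is the identity.
    """
    if np.any(c.values < 0):
        raise ValueError("roundtrip_check requires a non-negative field")
    cells = density_to_cells(c, part)
    back = cells_to_density(cells, part)
    mass_in = c.total_mass()
    mass_out = back.total_mass()
    denom = mass_in if mass_in > 0 else 1.0
    return {
        "mass_in": mass_in,
        "mass_out": mass_out,
        "mass_rel_error": abs(mass_out - mass_in) / denom,
        "sup_error": float(np.max(np.abs(back.values - c.values), initial=0.0)),
        "n_cells": len(cells),
    }
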