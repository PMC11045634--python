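"""Solitary mesenchymal cancer cell agents and their jump-diffusion migration.

Each mesenchymal-like cell is a point mass that drifts up the ECM gradient
with a saturated speed law mu(z) = A·arctan(z/A), A = 2 V_thr / π (so the
drift speed approaches but never exceeds the maximum cell speed V_thr), and
is kicked by compound-Poisson jump noise: in a step of length τ the cell
reorients with probability 1 − exp(−λτ), receiving one i.i.d. jump.  The
update is an Euler–Maruyama-type scheme with a hard per-step speed cap and
mirror-reflective walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, ScalarField, interp_at, gradient
from .params import SdeParams

__all__ = ["CellSet", "drift_mu", "cpp_increment", "step_cells", "reflect"]


@dataclass
class CellSet:
    """The population of solitary mesenchymal cells in one organ.

    ``ids`` are unique within a run and never reused; ``positions`` are in cm
    and strictly inside the organ's domain; ``masses`` in g; ``K`` is the
    side length of each cell's cubic footprint.
    """

    grid: Grid
    ids: np.ndarray = field(default=None)
    positions: np.ndarray = field(default=None)
    masses: np.ndarray = field(default=None)
    K: float = 0.0
    next_id: int = 0

    def __post_init__(self) -> None:
        dim = self.grid.dim
        if self.ids is None:
            self.ids = np.empty(0, dtype=np.int64)
        if self.positions is None:
            self.positions = np.empty((0, dim))
        if self.masses is None:
            self.masses = np.empty(0)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, dim)
        self.masses = np.asarray(self.masses, dtype=float)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("agent ids must be unique")
        if np.any(self.masses <= 0) and self.masses.size:
            raise ValueError("agent masses must be positive")
        if self.K == 0.0:
            self.K = min(self.grid.spacing)
        self.next_id = max(int(self.next_id), int(self.ids.max(initial=-1)) + 1)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "CellSet":
        return CellSet(self.grid, self.ids.copy(), self.positions.copy(),
                       self.masses.copy(), self.K, self.next_id)

    def add(self, positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
        """Append agents with fresh ids; returns the new ids."""
        positions = np.asarray(positions, dtype=float).reshape(-1, self.grid.dim)
        masses = np.atleast_1d(np.asarray(masses, dtype=float))
        n = len(masses)
        new_ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.ids = np.concatenate([self.ids, new_ids])
        self.positions = np.concatenate([self.positions, positions])
        self.masses = np.concatenate([self.masses, masses])
        self.next_id += n
        return new_ids

    def remove(self, ids) -> "CellSet":
        """Return the removed agents as a new CellSet and drop them here."""
        ids = np.atleast_1d(np.asarray(ids, dtype=np.int64))
        mask = np.isin(self.ids, ids)
        if mask.sum() != len(ids):
            raise KeyError("unknown agent id(s) in removal request")
        removed = CellSet(self.grid, self.ids[mask], self.positions[mask],
                          self.masses[mask], self.K, self.next_id)
        keep = ~mask
        self.ids = self.ids[keep]
        self.positions = self.positions[keep]
        self.masses = self.masses[keep]
        return removed


def drift_mu(grad_v: np.ndarray, V_thr: float, mode: str = "magnitude") -> np.ndarray:
    """Saturated haptotactic drift velocity, cm/d.

    Applies the scalar law mu(z) = A arctan(z/A), A = 2 V_thr/π, to the
    gradient magnitude and preserves the direction, so the drift speed is
    strictly below V_thr for finite gradients and tends to V_thr as the
    gradient blows up.  ``mode="componentwise"`` applies the law per axis.
    """
    grad_v = np.asarray(grad_v, dtype=float)
    A = 2.0 * V_thr / np.pi
    if mode == "componentwise":
        return A * np.arctan(grad_v / A)
    mag = np.linalg.norm(grad_v, axis=-1, keepdims=True)
    speed = A * np.arctan(mag / A)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, grad_v / np.where(mag > 0, mag, 1.0), 0.0)
    return speed * unit


def cpp_increment(p: SdeParams, tau: float, rng: np.random.Generator,
                  n: int = 1, dim: int = 3) -> np.ndarray:
    """Compound-Poisson jump displacement(s) over a step of length tau.

    With probability 1 − exp(−λτ) the cell receives one jump Y: an isotropic
    direction times a half-Gaussian magnitude with standard deviation √τ,
    scaled by σ; otherwise the zero vector.  Returns an (n, dim) array.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    out = np.zeros((n, dim))
    p_jump = 1.0 - np.exp(-p.lam_cpp * tau)
    fires = rng.random(n) < p_jump
    k = int(fires.sum())
    if k == 0:
        return out
    dirs = rng.normal(size=(k, dim))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    dirs /= norms
    mags = np.abs(rng.normal(0.0, np.sqrt(tau), size=(k, 1)))
    out[fires] = p.sigma * dirs * mags
    return out


def reflect(x: np.ndarray, grid: Grid) -> np.ndarray:
    """Mirror-fold positions back into the domain, per axis, until inside."""
    x = np.array(x, dtype=float)
    for ax in range(grid.dim):
        lo, hi = grid.lo[ax], grid.hi[ax]
        span = hi - lo
        # triangular-wave fold with period 2*span
        y = np.mod(np.asarray(x[..., ax]) - lo, 2.0 * span)
        x[..., ax] = lo + np.where(y > span, 2.0 * span - y, y)
    return x


def step_cells(cells: CellSet, v: ScalarField, p: SdeParams, tau: float,
               rng: np.random.Generator,
               grad_fields: list[ScalarField] | None = None) -> CellSet:
    """One Euler–Maruyama-type migration step for every agent.

    Per cell: evaluate ∇v at the position, add drift·τ plus one (possible)
    compound-Poisson jump, rescale the implied velocity to V_thr if the cap
    is exceeded, then reflect into the domain.  Masses are unchanged.
    """
    if len(cells) == 0:
        return cells.copy()
    new = cells.copy()
    grid = cells.grid
    gv = grad_fields if grad_fields is not None else gradient(v)
    grad_at = interp_at(gv, cells.positions)
    if grad_at.ndim == 1:
        grad_at = grad_at[:, None]
    drift = drift_mu(grad_at, p.V_thr, p.drift_mode)
    noise = cpp_increment(p, tau, rng, n=len(cells), dim=grid.dim)
    dx = drift * tau + noise
    speed = np.linalg.norm(dx, axis=1) / tau
    over = speed > p.V_thr
    if np.any(over):
        dx[over] *= (p.V_thr / speed[over])[:, None]
    proposed = cells.positions + dx
    if p.boundary == "last_position":
        inside = grid.contains(proposed)
        proposed[~inside] = cells.positions[~inside]
    else:
        proposed = reflect(proposed, grid)
    if not np.all(np.isfinite(proposed)):
        bad = cells.ids[~np.all(np.isfinite(proposed), axis=1)]
        raise FloatingPointError(f"non-finite position for agent id(s) {bad.tolist()}")
    # keep strictly inside: nudge off the walls by a tiny margin
    eps = 1e-12
    lo = np.asarray(grid.lo) + eps
    hi = np.asarray(grid.hi) - eps
    new.positions = np.clip(proposed, lo, hi)
    return new
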