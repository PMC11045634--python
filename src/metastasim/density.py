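"""Explicit finite-volume time stepping of the coupled density system.

Five fields evolve on one organ's grid: epithelial-like cancer cells (cE),
cancer-associated fibroblasts (cF), TGF-β (b), MMPs (m) and the ECM (v).
The cancer-cell fields move by degenerate porous-medium diffusion
(mobility D·c, so D(0) = 0 and compact supports stay compact) plus
haptotaxis along the ECM gradient; TGF-β and MMPs diffuse linearly; the ECM
neither diffuses nor advects.  Transport is discretised in conservative
face-flux form — arithmetic-mean interface mobility for the nonlinear
diffusion and first-order upwinding for haptotaxis — so the transport terms
conserve mass to round-off under the zero-flux walls.  Time integration is
forward Euler under a CFL-style stability bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, ScalarField
from .params import PdeParams

__all__ = [
    "DensityState",
    "pme_divergence",
    "heat_divergence",
    "haptotaxis_divergence",
    "reactions",
    "stable_dt",
    "step_density",
]


class BlowUpError(FloatingPointError):
    """A field became NaN/Inf during stepping."""


@dataclass
class DensityState:
    """The five scalar unknowns of one organ plus the agent-derived cM field."""

    cE: ScalarField
    cF: ScalarField
    b: ScalarField
    m: ScalarField
    v: ScalarField
    cM_density: ScalarField | None = None
    time: float = 0.0  # days
    clipped_mass: float = 0.0  # cumulative mass added by clipping negatives to 0, g
    reaction_mass: float = 0.0  # cumulative signed mass added by reactions, g

    def __post_init__(self) -> None:
        if self.cM_density is None:
            self.cM_density = ScalarField.zeros(self.grid)

    @property
    def grid(self) -> Grid:
        return self.cE.grid

    @classmethod
    def zeros(cls, grid: Grid) -> "DensityState":
        return cls(*[ScalarField.zeros(grid) for _ in range(5)])

    def copy(self) -> "DensityState":
        return DensityState(
            self.cE.copy(), self.cF.copy(), self.b.copy(), self.m.copy(),
            self.v.copy(), self.cM_density.copy(), self.time,
            self.clipped_mass, self.reaction_mass,
        )

    def field_masses(self) -> dict[str, float]:
        return {
            "cE": self.cE.total_mass(),
            "cF": self.cF.total_mass(),
            "b": self.b.total_mass(),
            "m": self.m.total_mass(),
            "v": self.v.total_mass(),
            "cM": self.cM_density.total_mass(),
        }


def _axis_pad(a: np.ndarray, ax: int) -> np.ndarray:
    return np.pad(a, [(1, 1) if d == ax else (0, 0) for d in range(a.ndim)], mode="edge")


def pme_divergence(c: ScalarField, D: float) -> ScalarField:
    """∇·(D c ∇c) in finite-volume form with arithmetic-mean face mobility.

    Interior face flux = D * (c_i + c_{i+1})/2 * (c_{i+1} - c_i)/h; boundary
    faces carry zero flux.  Because the mobility vanishes with c, a zero
    field stays exactly zero and compact supports spread at finite speed.
    """
    a = c.values
    if np.any(a < 0):
        raise ValueError("pme_divergence requires a non-negative field")
    g = c.grid
    out = np.zeros_like(a)
    for ax in range(g.dim):
        h = g.spacing[ax]
        n = a.shape[ax]
        lo = np.take(a, range(0, n - 1), axis=ax)
        hi = np.take(a, range(1, n), axis=ax)
        flux = D * 0.5 * (lo + hi) * (hi - lo) / h  # interior faces, (n-1) long
        dflux = np.diff(
            np.pad(flux, [(1, 1) if d == ax else (0, 0) for d in range(a.ndim)],
                   mode="constant"), axis=ax)
        out += dflux / h
    return ScalarField(g, out)


def heat_divergence(c: ScalarField, D: float) -> ScalarField:
    """Linear-diffusion validation variant: D Δc with Neumann walls."""
    from .grid import laplacian

    lap = laplacian(c)
    return ScalarField(c.grid, D * lap.values)


def haptotaxis_divergence(c: ScalarField, v: ScalarField, chi: float,
                          sign: int = 1) -> ScalarField:
    """Rate contribution of haptotactic advection of c along ∇v.

    ``sign=+1`` advects up the ECM gradient (epithelial cells), ``sign=-1``
    down it (fibroblasts).  Face velocity u = sign·chi·(central difference of
    v across the face); the advected value is taken from the upwind cell;
    boundary faces are closed.  Returns ∂c/∂t = -∇·(c u), which sums to zero
    over the domain.
    """
    a = c.values
    g = c.grid
    out = np.zeros_like(a)
    for ax in range(g.dim):
        h = g.spacing[ax]
        n = a.shape[ax]
        vlo = np.take(v.values, range(0, n - 1), axis=ax)
        vhi = np.take(v.values, range(1, n), axis=ax)
        u = sign * chi * (vhi - vlo) / h  # face-normal velocity
        clo = np.take(a, range(0, n - 1), axis=ax)
        chi_ = np.take(a, range(1, n), axis=ax)
        upwind = np.where(u > 0, clo, chi_)
        flux = u * upwind
        dflux = np.diff(
            np.pad(flux, [(1, 1) if d == ax else (0, 0) for d in range(a.ndim)],
                   mode="constant"), axis=ax)
        out -= dflux / h
    return ScalarField(g, out)


def reactions(state: DensityState, p: PdeParams,
              emt_sink: ScalarField | None = None,
              met_source: ScalarField | None = None,
              footprint: ScalarField | None = None) -> dict[str, ScalarField]:
    """Pointwise reaction rates d(field)/dt for all five fields.

    ``emt_sink`` / ``met_source`` are mass-rate densities handed over by the
    phenotype-switching module (zero by default: in the composed loop those
    exchanges are applied as discrete, exactly conservative mass moves).
    ``footprint`` is the agent-cube indicator field entering ECM degradation.
    """
    g = state.grid
    cE, cF, b, m, v = (state.cE.values, state.cF.values, state.b.values,
                       state.m.values, state.v.values)
    cM = state.cM_density.values
    total = cE + cM + cF + v
    if p.normalize_carrying_capacity:
        cap = p.carrying_capacity
        if cap is None or cap <= 0:
            raise ValueError("normalize_carrying_capacity needs a positive carrying_capacity")
        competition = 1.0 - total / cap
    else:
        competition = 1.0 - total

    d_cE = p.rho_cE * cE * competition
    if emt_sink is not None:
        d_cE = d_cE - emt_sink.values
    if met_source is not None:
        d_cE = d_cE + met_source.values

    d_cF = p.rho_cF * cF * (1.0 + cE) * competition - p.lambda_F * cF
    d_b = p.rho_bF * cF - p.lambda_b * b
    d_m = p.rho_mF * cF + p.rho_mE * cE - p.lambda_m * m

    foot = footprint.values if footprint is not None else 0.0
    d_v = p.rho_vF * cF - (p.lambda_vM * foot + p.lambda_vE * m * cE) * v

    return {
        "cE": ScalarField(g, d_cE),
        "cF": ScalarField(g, d_cF),
        "b": ScalarField(g, d_b),
        "m": ScalarField(g, d_m),
        "v": ScalarField(g, d_v),
    }


def stable_dt(state: DensityState, p: PdeParams,
              footprint: ScalarField | None = None,
              reactions_on: bool = True) -> float:
    """Stability-controlled explicit time step (days).

    dt = safety * min( h²/(2·dim·D_max), h/u_max, 1/r_max ) over the
    diffusion mobilities, face advection speeds and reaction depletion
    rates currently present; returns ``dt_max`` for an all-zero state.
    Production into a (near-)empty field poses no explicit-Euler stability
    risk, so only depleting rates enter the reaction constraint.
    """
    g = state.grid
    h = min(g.spacing)
    dim = g.dim

    D_cands = [
        p.D_E * (1.0 if p.linear_diffusion else float(state.cE.values.max(initial=0.0))),
        p.D_F * (1.0 if p.linear_diffusion else float(state.cF.values.max(initial=0.0))),
        p.D_b,
        p.D_m,
    ]
    D_max = max(D_cands)

    grad_mag = 0.0
    for ax in range(dim):
        dv = np.diff(state.v.values, axis=ax) / g.spacing[ax]
        if dv.size:
            grad_mag = max(grad_mag, float(np.abs(dv).max()))
    u_max = max(p.chi_E, p.chi_F) * grad_mag

    r_max = 0.0
    if reactions_on:
        rates = reactions(state, p, footprint=footprint)
        for name in ("cE", "cF", "b", "m", "v"):
            vals = getattr(state, name).values
            depletion = np.maximum(-rates[name].values, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                local = np.where(vals > 0, depletion / np.maximum(vals, 1e-300), 0.0)
            if local.size:
                r_max = max(r_max, float(local.max()))

    cands = []
    if D_max > 0:
        cands.append(h**2 / (2.0 * dim * D_max))
    if u_max > 0:
        cands.append(h / u_max)
    if r_max > 0:
        cands.append(1.0 / r_max)
    if not cands:
        return p.dt_max
    return min(p.dt_safety * min(cands), p.dt_max)


def _check_finite(name: str, arr: np.ndarray, t: float) -> None:
    if not np.all(np.isfinite(arr)):
        raise BlowUpError(f"field {name} became non-finite at t={t:.6g} d")


def step_density(state: DensityState, p: PdeParams, dt: float,
                 emt_sink: ScalarField | None = None,
                 met_source: ScalarField | None = None,
                 footprint: ScalarField | None = None,
                 reactions_on: bool = True) -> DensityState:
    """One forward-Euler step of the full density system.

    Negative values produced by round-off are clipped to zero and the
    clipped mass is accumulated on the returned state.  The signed mass
    added by reactions is also accumulated, which lets callers audit the
    conservation of the transport terms exactly.
    """
    g = state.grid
    new = state.copy()
    diffuse = heat_divergence if p.linear_diffusion else pme_divergence

    rate_cE = diffuse(state.cE, p.D_E).values \
        + haptotaxis_divergence(state.cE, state.v, p.chi_E, sign=+1).values
    rate_cF = diffuse(state.cF, p.D_F).values \
        + haptotaxis_divergence(state.cF, state.v, p.chi_F, sign=-1).values
    from .grid import laplacian

    D_mmp = p.D_E if p.mmp_uses_DE else p.D_m
    rate_b = p.D_b * laplacian(state.b).values
    rate_m = D_mmp * laplacian(state.m).values
    rate_v = np.zeros(g.shape)

    if reactions_on:
        rx = reactions(state, p, emt_sink, met_source, footprint)
        rate_cE = rate_cE + rx["cE"].values
        rate_cF = rate_cF + rx["cF"].values
        rate_b = rate_b + rx["b"].values
        rate_m = rate_m + rx["m"].values
        rate_v = rate_v + rx["v"].values
        new.reaction_mass += float(
            (rx["cE"].values + rx["cF"].values + rx["b"].values
             + rx["m"].values + rx["v"].values).sum()
        ) * g.cell_volume * dt

    for name, rate in (("cE", rate_cE), ("cF", rate_cF), ("b", rate_b),
                       ("m", rate_m), ("v", rate_v)):
        fld = getattr(new, name)
        fld.values = getattr(state, name).values + dt * rate
        _check_finite(name, fld.values, state.time)
        neg = fld.values < 0
        if np.any(neg):
            new.clipped_mass += float(-fld.values[neg].sum()) * g.cell_volume
            fld.values[neg] = 0.0

    new.time = state.time + dt
    return new
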