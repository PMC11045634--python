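"""Synthetic tumour microenvironments and initial conditions.

Two ECM constructions: a *directional* matrix whose density increases
linearly towards one corner of the domain (so haptotactic migration has an
unambiguous target direction), and a *hierarchical* random matrix built by
refining an 8-per-axis standard-normal lattice, doubling the resolution at
each level by interpolation plus shrinking additive Gaussian noise — the
coarse structure survives refinement, giving reproducible "patchy" tissue.
Both are min–max normalised and mapped affinely onto the biological range
[v_min, v_max].

Tumour initial conditions are unions of balls indicated on cell centres;
fibroblasts occupy a random 30% of the domain with U(0, 0.001) densities;
TGF-β is seeded only outside the tumour (U(0, 0.01)); MMPs everywhere
(U(0, 0.0001)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ConfigurationError, Grid, ScalarField

__all__ = [
    "EcmSpec",
    "directional_ecm",
    "hierarchical_ecm",
    "spherical_tumor_ic",
    "random_caf_ic",
    "tgf_mmp_ic",
]

V_MAX_DEFAULT = 1.06
V_MIN_DEFAULT = 0.9 * 1.06


@dataclass
class EcmSpec:
    """Recipe for a synthetic ECM field."""

    mode: str = "directional"  # or "hierarchical"
    v_min: float = V_MIN_DEFAULT
    v_max: float = V_MAX_DEFAULT
    base_size: int = 8
    levels: int = 3
    noise_sd: float = 0.1  # level-1 additive noise SD; halves per level

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_min <= self.v_max:
            raise ConfigurationError("need 0 <= v_min <= v_max")
        if self.mode not in ("directional", "hierarchical"):
            raise ConfigurationError(f"unknown ECM mode {self.mode!r}")

    def build(self, grid: Grid, rng: np.random.Generator | None = None) -> ScalarField:
        if self.mode == "directional":
            return directional_ecm(grid, self.v_min, self.v_max)
        if rng is None:
            raise ConfigurationError("hierarchical ECM needs an rng")
        return hierarchical_ecm(grid, self, rng)


def _affine_map(raw: np.ndarray, v_min: float, v_max: float) -> np.ndarray:
    rng_ = raw.max() - raw.min()
    if rng_ == 0:
        if v_min != v_max:
            raise ConfigurationError("constant raw field cannot be min-max normalised")
        return np.full_like(raw, v_min)
    hat = (raw - raw.min()) / rng_
    return v_min + (v_max - v_min) * hat


def directional_ecm(grid: Grid, v_min: float = V_MIN_DEFAULT,
                    v_max: float = V_MAX_DEFAULT) -> ScalarField:
    """ECM increasing linearly along the main diagonal: v̄(x) = Σ coordinates.

    After min–max normalisation and affine mapping the field attains exactly
    v_min and v_max at the two opposite corners.
    """
    raw = sum(grid.meshgrid())
    if v_min == v_max:
        return ScalarField(grid, np.full(grid.shape, v_min))
    return ScalarField(grid, _affine_map(raw, v_min, v_max))


def hierarchical_ecm(grid: Grid, spec: EcmSpec, rng: np.random.Generator) -> ScalarField:
    """Hierarchical random ECM: refine a base_size^dim N(0,1) lattice.

    Each refinement doubles the per-axis resolution by linear interpolation
    of the coarser lattice and adds Gaussian noise whose SD halves per
    level; the final lattice must match the grid shape exactly.
    """
    target = spec.base_size * 2**spec.levels
    for n in grid.shape:
        if n != target:
            raise ConfigurationError(
                f"grid shape {grid.shape} incompatible with base {spec.base_size} "
                f"x 2^{spec.levels} = {target} per axis")
    a = rng.normal(size=(spec.base_size,) * grid.dim)
    sd = spec.noise_sd
    for _ in range(spec.levels):
        a = ndimage.zoom(a, 2, order=1, mode="nearest", grid_mode=True)
        if sd > 0:
            a = a + rng.normal(0.0, sd, size=a.shape)
        sd *= 0.5
    if a.max() == a.min():  # interpolation preserved a constant base lattice
        return ScalarField(grid, np.full(grid.shape, spec.v_min))
    return ScalarField(grid, _affine_map(a, spec.v_min, spec.v_max))


def ball_support(grid: Grid, centres, radius: float) -> np.ndarray:
    """Boolean field: cell centres inside the union of balls."""
    mesh = grid.meshgrid()
    mask = np.zeros(grid.shape, dtype=bool)
    for c in centres:
        r2 = sum((m - ci) ** 2 for m, ci in zip(mesh, c))
        mask |= r2 < radius**2
    return mask


def spherical_tumor_ic(grid: Grid, centres, radius: float = 0.01,
                       density: float = 3.0, warn=None) -> ScalarField:
    """Epithelial tumour IC: uniform density on a union of balls.

    Membership is tested at cell centres, so balls much smaller than a cell
    may quantise to an empty field.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    centres = [np.asarray(c, dtype=float) for c in centres]
    for c in centres:
        nearest = np.clip(c, grid.lo, grid.hi)
        if np.linalg.norm(c - nearest) >= radius:
            import warnings

            warnings.warn(f"tumour ball at {c} lies entirely outside the domain")
    mask = ball_support(grid, centres, radius)
    return ScalarField(grid, np.where(mask, float(density), 0.0))


def random_caf_ic(grid: Grid, rng: np.random.Generator, fraction: float = 0.30,
                  hi: float = 0.001) -> ScalarField:
    """Fibroblast IC: exactly round(fraction·N) cells get U(0, hi), rest 0."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    n = int(np.prod(grid.shape))
    k = int(round(fraction * n))
    vals = np.zeros(n)
    if k:
        chosen = rng.choice(n, size=k, replace=False)
        vals[chosen] = rng.uniform(0.0, hi, size=k)
    return ScalarField(grid, vals.reshape(grid.shape))


def tgf_mmp_ic(grid: Grid, tumour_support: np.ndarray,
               rng: np.random.Generator, b_hi: float = 0.01,
               m_hi: float = 0.0001) -> tuple[ScalarField, ScalarField]:
    """TGF-β and MMP ICs.

    TGF-β is zero on the tumour support and U(0, b_hi) elsewhere — EMT can
    therefore first fire only at the tumour periphery.  MMPs are U(0, m_hi)
    everywhere.
    """
    tumour_support = np.asarray(tumour_support, dtype=bool)
    b = rng.uniform(0.0, b_hi, size=grid.shape)
    b[tumour_support] = 0.0
    m = rng.uniform(0.0, m_hi, size=grid.shape)
    return ScalarField(grid, b), ScalarField(grid, m)
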