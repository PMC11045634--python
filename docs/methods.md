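# Methods

## Model structure

The simulator couples three descriptions of one tumour system:

1. **Continuum.** Five cell-centred density fields per organ (epithelial
   cancer cells, fibroblasts, TGF-β, MMPs, ECM) on a uniform Cartesian grid
   over a cubic domain (default [−0.05, 0.05]³ cm, volume 10⁻³ cm³), with
   homogeneous Neumann boundaries.  Cancer-cell transport is degenerate
   porous-medium diffusion with mobility D·c (so D(0)=0) plus haptotactic
   advection along the ECM gradient — up-gradient for epithelial cells,
   down-gradient for fibroblasts, which remodel low-density matrix.
2. **Discrete.** Solitary mesenchymal cells as point masses moved by an
   Euler–Maruyama-type update of a jump-diffusion SDE: arctan-saturated
   drift (speed < V_thr always), compound-Poisson reorientation noise, hard
   per-step speed cap, mirror-reflective walls.
3. **Exchange.**  A partition of the domain into cells M_i (a configurable
   integer coarsening of the grid; the partition cell stands for one
   biological cell) carries the two mass-exact operators: density→cells
   (integrate over M_i, emit an agent at the barycentre) and cells→density
   (spread each agent's mass uniformly over its cubic footprint K_p and
   accumulate overlaps).  EMT and MET are built from these operators, so
   epithelial + mesenchymal mass is invariant under any switching sequence.

## Parameters

Defaults (units: cm, g, days) follow the published parameterisation of this
model family:

| symbol | meaning | default |
|---|---|---|
| D_E | epithelial PME mobility coefficient | 8.64e-8 cm²/d |
| D_F, D_b, D_m | fibroblast / TGF-β / MMP diffusion | 10·D_E, 10³·D_E, 10³·D_E |
| χ_E, χ_F | haptotaxis coefficients | 1e-3 cm²/d |
| ρ_c^E, ρ_c^F | proliferation rates | 1.2/d, 1e-3/d |
| ρ_b^F, ρ_m^F, ρ_m^E, ρ_v^F | production rates | 1e-3 |
| λ_F, λ_b, λ_m | decay rates | 2.62e-2/d |
| λ_v^M, λ_v^E | ECM degradation channels | 1.8383 (both) |
| L, k, b_T | EMT logistic (simulation defaults) | 5e-3/d, 1e6, 1e-3 |
| r | MET rate | 0.1/d |
| V_thr | maximum mesenchymal cell speed | 2.16 cm/d |
| σ | jump scale | 30 cm·d^(−1/2) |
| v_max, v_min | ECM density bounds | 1.06, 0.9·v_max |
| p_survive | CTC survival probability | 0.001 |

Quantities the source literature leaves open carry package defaults, stated
prominently and configurable:

- **λ_cpp = 50/d** — compound-Poisson event rate (several reorientations per
  day, consistent with a persistent random walk).
- **C_ref = 0.5 g/cm³** — epithelial density gate for EMT (half the logistic
  carrying-capacity scale).
- **m_cell = C_ref·|M_i|** — mass converted per EMT event; makes agents
  partition-cell-sized and the EMT sink dimensionally a density rate.
- **λ_intra = 0.1/d** — intravasation rate (same order as MET).
- **jump law** — isotropic direction × half-Gaussian magnitude of SD √τ,
  scaled by σ; family configurable.
- A literature "drift coefficient" μ_v = 100 cm²/d has no slot in the
  saturated drift law (which V_thr determines completely); it is kept as an
  inert config field.
- The printed MMP equation reuses D_E in its diffusion term while the
  parameter table defines a separate D_m; D_m is presumed intended and used
  by default (`mmp_uses_DE` restores the printed form).  Likewise the table
  prints one ECM degradation rate λ_v where the equation distinguishes two
  channels; both default to the printed value, individually overridable.
- Two EMT parameterisations circulate: the simulation defaults above and a
  reference curve (L=0.05, k=10³, b_T=0.01) used by the rate-law
  demonstrations; both are exposed.  The printed units of k (cm³/d) do not
  make k(b−b_T) dimensionless; k is applied numerically as printed.

## Numerics

- **Scheme.** Explicit forward Euler on a conservative finite-volume
  discretisation: arithmetic-mean interface mobility for the PME flux,
  first-order upwinding for haptotaxis, central five/seven-point Laplacian
  with ghost-cell mirroring.  Every transport operator telescopes to zero
  total flux, so transport conserves mass to round-off (verified at 1e-10
  over 100 steps; the PME front also provably moves ≤ 1 cell/step).
- **Time step.** dt = 0.4·min(h²/(2·dim·D_max), h/u_max, 1/r_max) over
  current mobilities, face speeds, and reaction *depletion* rates
  (production into an empty field is not a stability risk), capped at
  dt_max = 1e-2 d.
- **Splitting order** per global step, fixed for reproducibility:
  transport+reactions → EMT → MET → agent migration → intravasation →
  transit resolution.  The agent-derived mesenchymal density and footprint
  indicator are refreshed from the agent set before each density step.
- **Negativity.** Round-off negatives are clipped to zero and the clipped
  mass is accumulated and reported; reaction mass changes are likewise
  integrated, so every run audits a biomass ledger
  (Δtotal = reactions + clipping − CTC deaths) that must close to 1e-10
  relative (observed: ~1e-16).
- **Degenerate inputs.** Zero fields are absorbing for all operators; an
  all-zero state returns dt_max; empty agent sets are inert; NaN/Inf aborts
  the run naming the offending field, retaining the last good snapshot.
- **RNG.** One `numpy.random.Generator` seeded from the run config is
  threaded through every stochastic operation; identical (config, seed)
  runs are byte-identical.

## Design choices where the design was open

- **Super-capacity initial data.**  The canonical initial conditions put
  c^E = 3 inside the tumour while the logistic competition uses capacity 1
  and the ECM sits near 1; the competition factor is then negative
  (overcrowding death), which is reproduced as given.  The optional
  `normalize_carrying_capacity` flag instead evaluates the competition as
  1 − (total occupancy)/Θ with Θ fixed at the initial maximum occupancy, so
  1 becomes the carrying capacity and growth concentrates on the tumour
  surface.  The island-growth comparison uses this mode (with one shared Θ
  for both arms) because surface-dominated growth is the regime the
  comparison is about.
- **EMT mass removal** within a partition cell is proportional to the local
  fine-grid density (identical to uniform removal at the default
  coarsening of 1; preserves non-negativity at coarser partitions).
- **Reflective boundary** is mirror reflection; the alternative reading
  (return to last position) is available via `boundary="last_position"`.
- **Extravasation destination** excludes the origin organ (no self-loops by
  default); transit resolves at the next global step (`transit_time = 0`).
- **One agent per EMT event**, each of mass m_cell, capped by the mass
  available on the partition cell.
- 1-D and 2-D grids are supported throughout (used by the convergence
  studies); production experiments are 3-D.

## Synthetic environments

- **Directional ECM**: v̄(x) = x+y+z, min–max normalised and affinely
  mapped to [v_min, v_max]; the bounds are attained exactly at two opposite
  corners, giving haptotaxis an unambiguous target.
- **Hierarchical ECM**: an 8-per-axis standard-normal lattice is refined by
  repeated resolution doubling (multilinear interpolation + additive
  Gaussian noise whose SD halves per level, level-1 default 0.1), then
  mapped to [v_min, v_max].  The 8³ block means of the result correlate
  with the base lattice (r > 0.5 at default noise), i.e. the coarse patch
  structure survives refinement.
- **Initial conditions**: spherical tumours (radius 0.01 cm; density 3 for
  the single-tumour experiments, two density-1 spheroids offset by
  ±0.01·(1,−1,−1) for the merging experiment), fibroblasts on a random 30%
  of cells ~ U(0, 0.001), TGF-β ~ U(0, 0.01) only outside the tumour (so
  EMT first fires at the periphery), MMPs ~ U(0, 1e-4) everywhere.

What these generators emulate is the *statistical structure* of tumour
microenvironments — graded or patchy matrix, sparse stromal seeding — not
any imaged tissue: there is no anisotropic fibre tracking, no vasculature,
no organ geometry (organs are equal cubes).  Tests passing on these
environments validate the operators and their couplings, not organ-level
anatomical prediction.

## Problem sizes

Experiments default to 32 cells per axis (partition coarsening 1; the
haptotaxis-flow preset uses coarsening 2 so that partition cells straddle
the tumour boundary, where its non-diffusing TGF-β field meets the density
gate).  The study-scale resolution, 64³ with three hierarchical-ECM
refinement levels, is a config choice.  The test suite runs its PDE checks
at 8–32 cells per axis and 1-D refinement studies up to 400 cells; the
island-growth comparison runs two 32³ simulations for 1–2 simulated days.
At desk partition resolutions the printed EMT intensity (5e-3/d per
eligible partition cell) fires rarely; mechanism tests therefore raise the
switching and network rates well above the defaults — the properties they
assert (ordering, conservation, gating) are rate-independent.

## Known limitations

- Forward Euler and first-order upwinding are diffusive at fronts; no
  IMEX/higher-order limiters.
- Agents do not interact mechanically with each other.
- The circulatory network has no blood-flow directionality, residence-time
  distribution, organ-specific seeding propensity, or CTC dormancy.
- The legacy linear-diffusion model exists only as a validation mode of the
  diffusion operator, not as a runnable historical configuration.
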