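# metastasim

A hybrid discrete–continuum simulator of 3-D cancer invasion and multi-organ
metastasis, for mathematical oncologists studying how epithelial–mesenchymal
plasticity couples collective tumour growth to solitary-cell dissemination.

## The model

Each organ is a cube Ω = [−0.05, 0.05]³ cm carrying five density fields —
epithelial-like cancer cells c^E, cancer-associated fibroblasts c^F, TGF-β b,
matrix metalloproteinases m, and the extracellular matrix v — evolved by

```
∂t c^E = ∇·(D_E c^E ∇c^E) − χ_E ∇·(c^E ∇v) + ρ_c^E c^E (1 − c^E − c^M − c^F − v) − EMT + MET
∂t c^F = ∇·(D_F c^F ∇c^F) + χ_F ∇·(c^F ∇v) + ρ_c^F c^F (1 + c^E)(1 − …) − λ_F c^F
∂t b   = D_b Δb + ρ_b^F c^F − λ_b b
∂t m   = D_m Δm + ρ_m^F c^F + ρ_m^E c^E − λ_m m
∂t v   = ρ_v^F c^F − (λ_v^M Σ_p 𝟙_{K_p} + λ_v^E m c^E) v
```

with homogeneous Neumann walls.  The cancer-cell mobilities D·c are
*degenerate* (porous-medium type): compact tumour fronts stay compact and
propagate at finite speed, unlike linear diffusion.

Mesenchymal-like cells are discrete point masses (x_p, m_p) driven by the
jump-diffusion SDE

```
dX_t = μ(∇v(X_t)) dt + σ dC_t,     μ(z) = A arctan(z/A),  A = 2 V_thr/π,
```

where C_t is a compound Poisson process (rate λ, i.i.d. isotropic jumps): the
drift saturates below the maximum cell speed V_thr = 2.16 cm/d and the noise
models discrete re-orientation events rather than Brownian jitter.
Per step, displacements exceeding V_thr·τ are rescaled and walls reflect.

The two phases exchange mass exactly.  EMT fires per partition cell as a
Poisson count with intensity ζ(b)τ, ζ(b) = L/(1+e^{−k(b−b_T)}), gated on
c^E ≥ C_ref; each event converts one cell quantum of epithelial density into
an agent.  MET reverts each agent independently with probability 1−e^{−rτ}.
Organs are joined by a symmetric circulatory graph: agents intravasate as a
Poisson process, survive circulation with probability 0.1%, and survivors
extravasate into a uniformly chosen connected organ.

## Worked example

Run the haptotaxis-flow experiment (EMT only, directional ECM) for two days:

```bash
metastasim run --preset exp1 --seed 1 --out runs/exp1 --t-end 2.0
```

which prints (abridged):

```json
{
  "steps": 200,
  "event_totals": {"EMT": 1, "MET": 0, "intravasation": 0},
  "agent_counts": {"organ_0": 1},
  "final_masses": {"organ_0": {"cE": 1.2329101563e-05, "cM": 1.22070313e-07,
                               "v": 0.001007, "b": 4.982136025e-06}},
  "support_volume_cm3": {"organ_0": 4.5166015625e-06},
  "max_ledger_residual_rel": 2.1e-16
}
```

One EMT event converted 1.2e-7 g of epithelial density (one cell quantum at
this partition resolution) into a single solitary mesenchymal agent, now
migrating up the ECM gradient; every gram is accounted for — the biomass
ledger closes to round-off (`max_ledger_residual_rel ≈ 2e-16`).  Snapshots
(HDF5), agent trajectories (CSV), the event log (JSONL) and the mass-audit
time series (CSV) are in `runs/exp1/`; `metastasim summarize runs/exp1`
tabulates them.  The other presets are `exp2` (cancer-cell islands on a
hierarchical random ECM), `exp3` (growing and merging microtumours) and
`exp4` (four-organ metastasis).  `metastasim preset exp2 --out cfg.yaml`
writes an editable config; `metastasim validate cfg.yaml` echoes every
parameter with its provenance and a stability pre-estimate of the time step.

From Python, `metastasim.compare_island_growth()` runs the matched-mass
comparison of two separated microtumours against a single sphere on the same
ECM and seed and reports which configuration gains epithelial mass faster.

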