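"""Model parameters with literature defaults.

All rates are per day; lengths in cm; densities in g·cm⁻³.  The defaults are
the published parameterisation of the hybrid invasion model (EC diffusion
8.64e-8 cm²/d with CAF/TGF-β/MMP diffusivities scaled from it, logistic
proliferation 1.2/d, MET rate 0.1/d, maximum mesenchymal cell speed
2.16 cm/d, ECM bounds v_max = 1.06 g·cm⁻³ and v_min = 0.9 v_max).  A handful
of quantities the literature leaves open (compound-Poisson reorientation
rate, EMT density gate C_ref, intravasation rate, EMT mass quantum) carry
package defaults and are prominently configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

D_E_DEFAULT = 8.64e-8  # cm^2/d, EC diffusion coefficient

# Fig.-3 parameterisation of the EMT logistic switch (used by the rate-curve
# demos); Table-1 prints separate simulation defaults, kept in EmtParams.
FIG3_EMT = dict(L=0.05, k=1.0e3, b_T=0.01)


@dataclass
class PdeParams:
    """Coefficients of the five coupled density equations."""

    D_E: float = D_E_DEFAULT          # EC (porous-medium) diffusion, cm^2/d
    D_F: float = 10.0 * D_E_DEFAULT   # CAF diffusion
    D_b: float = 1.0e3 * D_E_DEFAULT  # TGF-beta diffusion
    D_m: float = 1.0e3 * D_E_DEFAULT  # MMP diffusion
    chi_E: float = 1.0e-3             # EC haptotaxis, cm^2/d (up ECM gradient)
    chi_F: float = 1.0e-3             # CAF haptotaxis (down ECM gradient)
    rho_cE: float = 1.2               # EC proliferation rate, 1/d
    rho_cF: float = 1.0e-3            # CAF proliferation rate, 1/d
    rho_bF: float = 1.0e-3            # TGF-beta production by CAFs
    rho_mF: float = 1.0e-3            # MMP production by CAFs
    rho_mE: float = 1.0e-3            # MMP production by ECs
    rho_vF: float = 1.0e-3            # ECM production by CAFs
    lambda_F: float = 2.62e-2         # CAF apoptosis rate, 1/d
    lambda_b: float = 2.62e-2         # TGF-beta decay rate, 1/d
    lambda_m: float = 2.62e-2         # MMP decay rate, 1/d
    # Table 1 prints a single ECM degradation rate lambda_v; the ECM equation
    # distinguishes an agent-footprint channel (M) and an EC-MMP-complex
    # channel (E).  Both default to the printed value, individually overridable.
    lambda_vM: float = 1.8383
    lambda_vE: float = 1.8383
    # The printed MMP equation reuses D_E in its diffusion term while Table 1
    # defines a separate D_m; D_m is presumed intended and used by default.
    mmp_uses_DE: bool = False
    # Linear-diffusion validation mode (heat equation instead of PME) for the
    # finite- vs infinite-propagation comparison.
    linear_diffusion: bool = False
    # When set, the logistic competition 1 - cE - cM - cF - v is evaluated as
    # 1 - (cE + cM + cF + v)/capacity with capacity fixed at the initial
    # maximum total occupancy, so 1 is the carrying capacity even for the
    # published super-capacity initial data (cE = 3, v ~ 1).
    normalize_carrying_capacity: bool = False
    carrying_capacity: float | None = None
    dt_max: float = 1.0e-2            # fallback time step for degenerate states, d
    dt_safety: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "D_E", "D_F", "D_b", "D_m", "chi_E", "chi_F", "rho_cE", "rho_cF",
            "rho_bF", "rho_mF", "rho_mE", "rho_vF", "lambda_F", "lambda_b",
            "lambda_m", "lambda_vM", "lambda_vE",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SdeParams:
    """Solitary mesenchymal cell migration parameters."""

    V_thr: float = 2.16      # maximum cell speed, cm/d
    sigma: float = 30.0      # jump scale, cm/d^(1/2)
    lam_cpp: float = 50.0    # compound-Poisson reorientation rate, 1/d (estimate)
    # Inert literature constant: a drift coefficient slot with no role in the
    # saturated-arctan drift law; retained for config round-tripping only.
    mu_v: float = 100.0
    jump_law: str = "isotropic_half_gaussian"
    drift_mode: str = "magnitude"  # or "componentwise"
    boundary: str = "reflect"      # or "last_position"

    def __post_init__(self) -> None:
        if self.V_thr <= 0:
            raise ValueError("V_thr must be positive")
        if self.sigma < 0 or self.lam_cpp < 0:
            raise ValueError("sigma and lam_cpp must be non-negative")


@dataclass
class EmtParams:
    """TGF-β-gated Poisson EMT parameters (Table-1 simulation defaults)."""

    L: float = 5.0e-3        # maximum EMT rate, 1/d
    k: float = 1.0e6         # logistic steepness (printed units cm^3/d)
    b_T: float = 1.0e-3      # TGF-beta threshold, g/cm^3
    C_ref: float = 0.5       # EC density gate, g/cm^3 (package default)
    m_cell: float | None = None  # mass per EMT event, g; default C_ref * |M_i|
    mu_E_EMT: float = 1.0    # sink prefactor (rates live in the Poisson intensity)

    def __post_init__(self) -> None:
        if self.L < 0 or self.k < 0 or self.b_T < 0 or self.C_ref < 0:
            raise ValueError("EMT parameters must be non-negative")
        if self.m_cell is not None and self.m_cell <= 0:
            raise ValueError("m_cell must be positive")


@dataclass
class MetParams:
    """Fixed-rate Poisson MET parameters."""

    r: float = 0.1           # MET rate, 1/d
    mu_M_MET: float = 1.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("MET rate must be non-negative")


@dataclass
class MetastasisParams:
    """Circulatory-network parameters."""

    lam_intra: float = 0.1   # intravasation rate per cell, 1/d (package default)
    p_survive: float = 0.001  # CTC survival probability through circulation
    transit_time: float = 0.0  # extra days in circulation; 0 = resolve next step

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_survive <= 1.0:
            raise ValueError("p_survive must lie in [0, 1]")
        if self.lam_intra < 0:
            raise ValueError("lam_intra must be non-negative")


@dataclass
class ModelParams:
    """Bundle of every module's parameters, as used by the experiment runner."""

    pde: PdeParams = field(default_factory=PdeParams)
    sde: SdeParams = field(default_factory=SdeParams)
    emt: EmtParams = field(default_factory=EmtParams)
    met: MetParams = field(default_factory=MetParams)
    network: MetastasisParams = field(default_factory=MetastasisParams)
    v_max: float = 1.06               # maximum ECM density, g/cm^3
    v_min: float = 0.9 * 1.06         # minimum ECM density

    def to_dict(self) -> dict:
        return asdict(self)
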