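"""Finite-volume density solver: transport, reactions, stability, stepping."""

import numpy as np
import pytest

from metastasim import (DensityState, PdeParams, ScalarField, haptotaxis_divergence,
                        make_grid, pme_divergence, reactions, stable_dt, step_density)
from metastasim.density import BlowUpError, heat_divergence
from metastasim.transfer import footprint_indicator
from metastasim.agents import CellSet


def blob_state(grid, width=0.01, amp=1.0):
    mesh = grid.meshgrid()
    r2 = sum(m**2 for m in mesh)
    st = DensityState.zeros(grid)
    st.cE.values = amp * np.exp(-r2 / (2 * width**2))
    return st


class TestPmeDivergence:
    def test_zero_field_stays_zero(self, grid3):
        out = pme_divergence(ScalarField.zeros(grid3), 1.0)
        assert np.all(out.values == 0.0)

    def test_constant_field_no_flux(self, grid3):
        out = pme_divergence(ScalarField.full(grid3, 2.0), 1.0)
        assert np.allclose(out.values, 0.0)

    def test_negative_density_rejected(self, grid3):
        f = ScalarField.full(grid3, 1.0)
        f.values[0, 0, 0] = -1e-3
        with pytest.raises(ValueError):
            pme_divergence(f, 1.0)

    def test_mass_conserving(self, grid3, rng):
        f = ScalarField(grid3, rng.uniform(0, 1, grid3.shape))
        total = pme_divergence(f, 1.0).values.sum()
        scale = np.abs(pme_divergence(f, 1.0).values).sum()
        assert abs(total) <= 1e-12 * max(scale, 1.0)

    def test_barenblatt_l1_convergence(self):
        """1-D porous-medium evolution converges to the self-similar profile.

        Oracle: the closed-form Barenblatt solution of u_t = Δ(u²) for m=2,
        U(x,t) = t^(-1/3) (C - x²/(12 t^(2/3)))_+ , evolved here under the
        equivalent flux form u_t = ∇·(2u ∇u).
        """
        def barenblatt(x, t, C=0.1):
            return np.maximum(C - x**2 / (12.0 * t ** (2.0 / 3.0)), 0.0) / t ** (1.0 / 3.0)

        D = 2.0  # mobility D*u with D=2 matches u_t = (u²)_xx
        t0, t1 = 1.0, 2.0
        errs = []
        for n in (100, 200, 400):
            g = make_grid([(-3.0, 3.0)], (n,))
            x = g.centers(0)
            st = DensityState.zeros(g)
            st.cE.values = barenblatt(x, t0)
            p = PdeParams(D_E=D, D_F=0, D_b=0, D_m=0, chi_E=0, chi_F=0)
            t = t0
            while t < t1:
                dt = min(stable_dt(st, p, reactions_on=False), t1 - t)
                st = step_density(st, p, dt, reactions_on=False)
                t += dt
            err = np.abs(st.cE.values - barenblatt(x, t1)).sum() * g.cell_volume
            errs.append(err)
        assert errs[0] > errs[1] > errs[2]


class TestHaptotaxis:
    def test_uniform_ecm_inert(self, grid3, rng):
        c = ScalarField(grid3, rng.uniform(0, 1, grid3.shape))
        v = ScalarField.full(grid3, 1.0)
        out = haptotaxis_divergence(c, v, 1e-3, sign=+1)
        assert np.allclose(out.values, 0.0)

    def test_centre_of_mass_advects_up_gradient(self):
        g = make_grid([(0.0, 1.0)], (100,))
        x = g.centers(0)
        c = ScalarField(g, np.exp(-((x - 0.3) ** 2) / (2 * 0.05**2)))
        v = ScalarField(g, x.copy())
        chi, dt = 0.01, 0.05
        rate = haptotaxis_divergence(c, v, chi, sign=+1)
        new_vals = c.values + dt * rate.values
        com0 = (x * c.values).sum() / c.values.sum()
        com1 = (x * new_vals).sum() / new_vals.sum()
        assert com1 - com0 == pytest.approx(chi * dt, abs=g.spacing[0] * chi * dt * 100)
        assert com1 > com0

    def test_mass_exactly_conserved(self, grid3, rng):
        c = ScalarField(grid3, rng.uniform(0, 1, grid3.shape))
        v = ScalarField(grid3, rng.uniform(0.9, 1.1, grid3.shape))
        for sign in (+1, -1):
            out = haptotaxis_divergence(c, v, 1e-3, sign=sign)
            scale = np.abs(out.values).sum()
            assert abs(out.values.sum()) <= 1e-12 * max(scale, 1.0)


class TestReactions:
    def test_zero_state_zero_rates(self, grid3):
        st = DensityState.zeros(grid3)
        rates = reactions(st, PdeParams())
        for f in rates.values():
            assert np.all(f.values == 0.0)

    def test_logistic_closed_form(self):
        """Uniform epithelial density follows c(t) = c0/(c0+(1-c0)e^{-ρt})."""
        g = make_grid([(0.0, 1.0)], (4,))
        p = PdeParams(D_E=0, chi_E=0)
        st = DensityState.zeros(g)
        c0, rho, T = 0.1, p.rho_cE, 1.0
        st.cE.values[:] = c0
        t = 0.0
        while t < T:
            dt = min(1e-3, T - t)
            rates = reactions(st, p)
            st.cE.values += dt * rates["cE"].values
            t += dt
        exact = c0 / (c0 + (1 - c0) * np.exp(-rho * T))
        assert rho == 1.2
        assert st.cE.values[0] == pytest.approx(exact, rel=1e-3)

    def test_mmp_exponential_decay(self):
        g = make_grid([(0.0, 1.0)], (4,))
        p = PdeParams()
        st = DensityState.zeros(g)
        m0, T = 0.5, 10.0
        st.m.values[:] = m0
        t = 0.0
        while t < T:
            dt = min(5e-3, T - t)
            st.m.values += dt * reactions(st, p)["m"].values
            t += dt
        assert st.m.values[0] == pytest.approx(m0 * np.exp(-p.lambda_m * T), rel=1e-3)

    def test_ecm_decay_only_under_agent_footprint(self, grid3):
        p = PdeParams(rho_vF=0)
        st = DensityState.zeros(grid3)
        st.v.values[:] = 1.0
        centre = [grid3.centers(a)[4] for a in range(3)]  # one cell centre
        cells = CellSet(grid3, ids=[0], positions=[centre], masses=[1e-9],
                        K=grid3.spacing[0] * 0.5)
        foot = footprint_indicator(cells, grid3)
        assert foot.values.sum() == 1
        T, t = 0.5, 0.0
        while t < T:
            dt = 1e-3
            st.v.values += dt * reactions(st, p, footprint=foot)["v"].values
            t += dt
        inside = st.v.values[4, 4, 4]
        outside = np.delete(st.v.values.ravel(), np.ravel_multi_index((4, 4, 4), grid3.shape))
        assert inside == pytest.approx(np.exp(-p.lambda_vM * T), rel=1e-3)
        assert np.allclose(outside, 1.0)


class TestStableDt:
    def test_zero_state_returns_dt_max(self, grid3):
        p = PdeParams()
        assert stable_dt(DensityState.zeros(grid3), p) == p.dt_max

    def test_tgf_diffusion_limit_formula(self):
        g = make_grid([(-0.05, 0.05)] * 3, (64, 64, 64))
        p = PdeParams(dt_max=10.0)
        st = DensityState.zeros(g)
        st.b.values[:] = 1e-6  # activate only the D_b constraint
        h = g.spacing[0]
        expected = 0.4 * h**2 / (6 * p.D_b)
        got = stable_dt(st, p, reactions_on=False)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_refinement_tightens_dt(self):
        p = PdeParams(dt_max=10.0)
        dts = []
        for n in (16, 32):
            g = make_grid([(-0.05, 0.05)] * 3, (n,) * 3)
            st = DensityState.zeros(g)
            st.b.values[:] = 1.0
            dts.append(stable_dt(st, p, reactions_on=False))
        assert dts[0] / dts[1] >= 4.0 - 1e-9


class TestStepDensity:
    def test_zero_state_absorbing(self, grid3):
        st = DensityState.zeros(grid3)
        out = step_density(st, PdeParams(), 1e-3)
        for name in ("cE", "cF", "b", "m", "v"):
            assert np.all(getattr(out, name).values == 0.0)

    def test_transport_mass_conserved_100_steps(self, grid3):
        p = PdeParams()
        st = blob_state(grid3)
        st.v.values[:] = 1.0 + 0.1 * grid3.meshgrid()[0]
        m0 = st.cE.total_mass()
        for _ in range(100):
            dt = stable_dt(st, p, reactions_on=False)
            st = step_density(st, p, dt, reactions_on=False)
        assert st.cE.total_mass() == pytest.approx(m0, rel=1e-10)

    def test_finite_vs_infinite_propagation(self):
        """Porous-medium fronts stay compact; the heat variant fills space.

        Evolving the same compact blob to the same final time, the linear
        mode ends strictly positive at every cell while the degenerate mode
        keeps most of the domain at exactly zero; the porous-medium support
        also never grows by more than one cell per step.
        """
        g = make_grid([(-1.0, 1.0)], (128,))
        centre = g.shape[0] // 2

        def compact_ic():
            st = DensityState.zeros(g)
            st.cE.values[centre - 1: centre + 2] = 1.0
            return st

        D = 1e-3
        pme = PdeParams(D_E=D, chi_E=0, dt_max=1.0)
        st = compact_ic()
        for _ in range(200):
            dt = stable_dt(st, pme, reactions_on=False)
            lo, hi = np.flatnonzero(st.cE.values > 0)[[0, -1]]
            st = step_density(st, pme, dt, reactions_on=False)
            lo2, hi2 = np.flatnonzero(st.cE.values > 0)[[0, -1]]
            assert lo - lo2 <= 1 and hi2 - hi <= 1
        frac_zero = (st.cE.values == 0.0).mean()
        assert frac_zero > 0.3

        heat = PdeParams(D_E=D, chi_E=0, linear_diffusion=True, dt_max=1.0)
        st = compact_ic()
        for _ in range(200):
            st = step_density(st, heat, stable_dt(st, heat, reactions_on=False),
                              reactions_on=False)
        assert np.all(st.cE.values > 0.0)

    def test_heat_mode_matches_gaussian_kernel(self):
        """Linear mode reproduces the analytic heat-kernel widening."""
        g = make_grid([(-1.0, 1.0)], (200,))
        x = g.centers(0)
        D, s0 = 1e-3, 0.05
        st = DensityState.zeros(g)
        st.cE.values = np.exp(-(x**2) / (2 * s0**2))
        p = PdeParams(D_E=D, chi_E=0, linear_diffusion=True, dt_max=1.0)
        T, t = 1.0, 0.0
        while t < T:
            dt = min(stable_dt(st, p, reactions_on=False), T - t)
            st = step_density(st, p, dt, reactions_on=False)
            t += dt
        s2 = s0**2 + 2 * D * T
        exact = (s0 / np.sqrt(s2)) * np.exp(-(x**2) / (2 * s2))
        assert np.abs(st.cE.values - exact).max() < 5e-4

    def test_blow_up_reported_with_field_name(self, grid3):
        st = DensityState.zeros(grid3)
        st.cE.values[0, 0, 0] = np.inf
        with pytest.raises(BlowUpError, match="cE"):
            step_density(st, PdeParams(), 1e-3)

    def test_clipping_is_logged(self):
        g = make_grid([(0.0, 1.0)], (8,))
        st = DensityState.zeros(g)
        st.m.values[:] = 1e-6
        p = PdeParams()
        # a huge dt forces the decay term to overshoot below zero
        out = step_density(st, p, 100.0, reactions_on=True)
        assert np.all(out.m.values >= 0)
        assert out.clipped_mass > 0
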