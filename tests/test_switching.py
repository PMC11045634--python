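"""EMT/MET phenotype switching: rate law, Poisson sampling, mass exchange."""

import numpy as np
import pytest
from scipy import stats

from metastasim import (CellSet, DensityState, EmtParams, MetParams, Partition,
                        ScalarField, apply_emt, apply_met, emt_rate, make_grid,
                        sample_emt_events, sample_met)
from metastasim.params import FIG3_EMT
from metastasim.switching import default_m_cell
from metastasim.environment import ball_support, spherical_tumor_ic, tgf_mmp_ic

FIG3 = EmtParams(L=FIG3_EMT["L"], k=FIG3_EMT["k"], b_T=FIG3_EMT["b_T"])


class TestEmtRate:
    def test_ceiling_reached_above_threshold(self):
        assert emt_rate(FIG3.b_T + 1.0, FIG3) == pytest.approx(0.05, abs=1e-9)

    def test_midpoint_is_half_maximum(self):
        assert emt_rate(FIG3.b_T, FIG3) == pytest.approx(FIG3.L / 2)

    def test_negligible_below_threshold(self):
        # logistic tail bound: ζ(0) < L e^{-k b_T}
        assert emt_rate(0.0, FIG3) < FIG3.L * np.exp(-FIG3.k * FIG3.b_T) * 1.01
        assert emt_rate(0.0, FIG3) < 1e-4 * FIG3.L

    def test_strictly_increasing(self):
        b = np.linspace(0, 0.02, 200)
        r = emt_rate(b, FIG3)
        assert np.all(np.diff(r) > 0)
        assert np.all((r > 0) & (r < FIG3.L))


@pytest.fixture
def setup(grid3):
    part = Partition(grid3, (2, 2, 2))
    state = DensityState.zeros(grid3)
    return part, state


class TestSampleEmt:
    def test_gate_blocks_low_density(self, setup, rng):
        part, state = setup
        state.cE.values[:] = 0.4  # below C_ref = 0.5
        state.b.values[:] = 1.0
        ev = sample_emt_events(state.cE, state.b, part, EmtParams(), 1.0, rng)
        assert ev.sum() == 0

    def test_no_tgf_no_events(self, setup, rng):
        part, state = setup
        state.cE.values[:] = 1.0
        p = EmtParams(L=0.05, k=1e3, b_T=0.01)
        total = 0
        for _ in range(1000):
            total += sample_emt_events(state.cE, state.b, part, p, 1e-3, rng).sum()
        assert total == 0

    def test_poisson_moments_single_cell(self, grid3, rng):
        part = Partition(grid3, (8, 8, 8))  # one M cell
        state = DensityState.zeros(grid3)
        state.cE.values[:] = 1.0
        state.b.values[:] = 1.0
        # pick tau so the intensity is exactly 2, with a cap far away
        p = EmtParams(L=0.05, k=1e3, b_T=0.01, C_ref=0.5,
                      m_cell=1.0 * part.cell_volume / 1000)
        tau = 2.0 / emt_rate(1.0, p)
        draws = np.array([
            int(sample_emt_events(state.cE, state.b, part, p, tau, rng).sum())
            for _ in range(10_000)])
        assert draws.mean() == pytest.approx(2.0, abs=3 * np.sqrt(2.0 / len(draws)))
        assert draws.var() == pytest.approx(2.0, rel=0.1)

    def test_poisson_distribution_gof(self, grid3, rng):
        """Chi-square goodness of fit of event counts to Poisson(ζτ)."""
        part = Partition(grid3, (8, 8, 8))
        state = DensityState.zeros(grid3)
        state.cE.values[:] = 1.0
        state.b.values[:] = 1.0
        p = EmtParams(L=0.05, k=1e3, b_T=0.01, m_cell=part.cell_volume / 1000)
        lam = 2.0
        tau = lam / emt_rate(1.0, p)
        n = 10_000
        draws = np.array([
            int(sample_emt_events(state.cE, state.b, part, p, tau, rng).sum())
            for _ in range(n)])
        kmax = 8
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), lam)
        probs = np.append(probs, 1 - probs.sum())
        chi2 = ((obs - n * probs) ** 2 / (n * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=kmax)

    def test_monotone_in_tgf(self, setup, rng):
        part, state = setup
        state.cE.values[:] = 1.0
        p = EmtParams(L=0.05, k=1e3, b_T=0.01, m_cell=1e-12)
        totals = []
        for b_level in (0.005, 0.01, 0.02):
            state.b.values[:] = b_level
            rng_local = np.random.default_rng(5)
            tot = sum(sample_emt_events(state.cE, state.b, part, p, 0.5,
                                        rng_local).sum() for _ in range(200))
            totals.append(tot)
        assert totals[0] <= totals[1] <= totals[2]

    def test_cap_respects_available_mass(self, grid3, rng):
        part = Partition(grid3, (8, 8, 8))
        state = DensityState.zeros(grid3)
        state.cE.values[:] = 1.0
        p = EmtParams(L=1e3, k=1e3, b_T=0.0, m_cell=part.cell_volume / 2)
        state.b.values[:] = 1.0
        ev = sample_emt_events(state.cE, state.b, part, p, 10.0, rng)
        assert ev.max() <= 2  # available mass = 2 quanta


class TestApplyEmt:
    def test_zero_events_identity(self, setup):
        part, state = setup
        state.cE.values[:] = 1.0
        cells = CellSet(state.grid)
        s2, c2 = apply_emt(state, cells, np.zeros(part.shape, int), EmtParams(), part)
        assert np.array_equal(s2.cE.values, state.cE.values)
        assert len(c2) == 0

    def test_single_event_bookkeeping(self, setup):
        part, state = setup
        p = EmtParams()
        m_cell = default_m_cell(p, part)
        state.cE.values[:2, :2, :2] = 10 * m_cell / part.cell_volume
        events = np.zeros(part.shape, int)
        events[0, 0, 0] = 1
        cells = CellSet(state.grid)
        s2, c2 = apply_emt(state, cells, events, p, part)
        assert len(c2) == 1
        assert c2.masses[0] == pytest.approx(m_cell)
        lost = state.cE.total_mass() - s2.cE.total_mass()
        assert lost == pytest.approx(m_cell, rel=1e-12)
        assert np.allclose(c2.positions[0], part.barycenters()[0])

    def test_joint_mass_invariant(self, setup, rng):
        part, state = setup
        state.cE.values[:] = 1.0
        state.b.values[:] = 1.0
        cells = CellSet(state.grid)
        p = EmtParams(L=5.0, k=1e3, b_T=0.01)
        before = state.cE.total_mass()
        for _ in range(20):
            ev = sample_emt_events(state.cE, state.b, part, p, 0.1, rng)
            state, cells = apply_emt(state, cells, ev, p, part)
        after = state.cE.total_mass() + cells.total_mass
        assert after == pytest.approx(before, rel=1e-12)
        assert len(cells) > 0

    def test_periphery_only_when_tgf_excluded_from_tumour(self, grid3, rng):
        """With TGF-β zero inside the tumour, first EMT events are peripheral."""
        part = Partition(grid3, (2, 2, 2))
        cE = spherical_tumor_ic(grid3, [np.zeros(3)], 0.03, density=3.0)
        support = ball_support(grid3, [np.zeros(3)], 0.03)
        b, _ = tgf_mmp_ic(grid3, support, rng, b_hi=1.0)
        # steep switch so fully-interior M-cells (mean TGF-β = 0) stay silent
        p = EmtParams(L=50.0, k=1e4, b_T=0.01, C_ref=0.5)
        ev = sample_emt_events(cE, b, part, p, 1.0, rng)
        fired = ev > 0
        interior = part.block_reduce(support.astype(float), np.min) > 0.5
        touches = part.block_reduce(support.astype(float), np.max) > 0.5
        assert fired.any()
        assert not (fired & interior).any()       # fully-interior cells silent
        assert (fired <= touches).all()           # only cells meeting the tumour fire


class TestMet:
    def test_zero_rate_empty(self, grid3, rng):
        cells = CellSet(grid3, ids=np.arange(100), positions=np.zeros((100, 3)),
                        masses=np.ones(100))
        assert sample_met(cells, MetParams(r=0.0), 1.0, rng).size == 0

    def test_empty_cellset_never_fires(self, grid3, rng):
        assert sample_met(CellSet(grid3), MetParams(r=100.0), 1.0, rng).size == 0

    def test_flag_fraction_binomial(self, grid3, rng):
        n = 100_000
        cells = CellSet(grid3, ids=np.arange(n), positions=np.zeros((n, 3)),
                        masses=np.ones(n))
        tau = np.log(2) / 0.1
        flagged = sample_met(cells, MetParams(r=0.1), tau, rng)
        se = np.sqrt(0.25 / n)
        assert abs(len(flagged) / n - 0.5) < 3 * se

    def test_default_rate_small_step_count(self, grid3, rng):
        """r = 0.1/d, τ = 1e-3 d: ~1e-4 per cell-step over 1e6 cell-steps."""
        n, reps = 10_000, 100
        cells = CellSet(grid3, ids=np.arange(n), positions=np.zeros((n, 3)),
                        masses=np.ones(n))
        p = MetParams(r=0.1)
        total = sum(len(sample_met(cells, p, 1e-3, rng)) for _ in range(reps))
        expect = n * reps * (1 - np.exp(-0.1 * 1e-3))
        assert abs(total - expect) < 3 * np.sqrt(expect)

    def test_apply_met_full_overlap(self, grid3, rng):
        part = Partition(grid3, (2, 2, 2))
        state = DensityState.zeros(grid3)
        centre = part.barycenters()[0]
        m = 4e-9
        cells = CellSet(grid3, ids=[7], positions=[centre], masses=[m], K=part.side)
        s2, c2 = apply_met(state, cells, [7], part)
        assert len(c2) == 0
        assert s2.cE.total_mass() == pytest.approx(m, rel=1e-12)
        coarse = part.block_reduce(s2.cE.values)
        assert coarse.ravel()[0] == pytest.approx(m / part.cell_volume)

    def test_apply_met_empty_identity(self, grid3):
        part = Partition(grid3)
        state = DensityState.zeros(grid3)
        cells = CellSet(grid3)
        s2, c2 = apply_met(state, cells, [], part)
        assert np.array_equal(s2.cE.values, state.cE.values)
        assert len(c2) == 0


class TestJointInvariance:
    def test_emt_met_sequences_conserve_mass(self, grid3, rng):
        """Random EMT/MET interleavings keep epithelial+agent mass fixed."""
        part = Partition(grid3, (2, 2, 2))
        state = DensityState.zeros(grid3)
        state.cE.values[:] = 1.0
        state.b.values[:] = 1.0
        cells = CellSet(grid3, K=part.side)
        emt = EmtParams(L=20.0, k=1e3, b_T=0.01)
        met = MetParams(r=20.0)
        total0 = state.cE.total_mass()
        for _ in range(100):
            if rng.random() < 0.5:
                ev = sample_emt_events(state.cE, state.b, part, emt, 0.05, rng)
                state, cells = apply_emt(state, cells, ev, emt, part)
            else:
                ids = sample_met(cells, met, 0.05, rng)
                state, cells = apply_met(state, cells, ids, part)
        total = state.cE.total_mass() + cells.total_mass
        assert total == pytest.approx(total0, rel=1e-12)
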