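import numpy as np
import pytest

from flashox import (BoundarySupply, ConvergenceError, Geometry1D, GridSpec,
                     IrradiationProtocol, OxygenState, TissueParameters,
                     equilibrate, make_domain_1d, midpoint_value,
                     reaction_rate, run_protocol, run_stage,
                     steady_state_parabola_oracle, steady_state_residual,
                     step, well_mixed_ode_oracle)
from flashox.solver import STAGE_IRRADIATION, STAGE_RECOVERY

from conftest import domain_1d


class TestReactionRate:
    def test_vanishes_at_zero_oxygen(self, tissue):
        assert reaction_rate(0.0, 500.0, tissue) == 0.0

    def test_metabolism_half_saturates_at_michaelis_constant(self, tissue):
        # O = λ: Michaelis-Menten term sits at K2/2
        assert reaction_rate(3.15, 0.0, tissue) == pytest.approx(-9.45)

    def test_high_oxygen_high_rate_value(self, tissue):
        # direct evaluation: -0.5*125*1000/1000.29 - 18.9*1000/1003.15
        assert reaction_rate(1000.0, 125.0, tissue) == pytest.approx(
            -81.3225, abs=1e-3)

    def test_is_nonpositive_and_rejects_negative_oxygen(self, tissue):
        grid = np.linspace(0.0, 100.0, 41)
        assert np.all(reaction_rate(grid, 125.0, tissue) <= 0.0)
        with pytest.raises(ValueError):
            reaction_rate(-1.0, 0.0, tissue)


class TestStep:
    def test_uniform_supply_without_sinks_is_exact_steady_state(self):
        params = TissueParameters(k2_metabolism=0.0)
        domain = domain_1d(50, 50.4, dx=2.5)
        state = OxygenState(0.0, np.full(domain.n_nodes, 50.4))
        out = step(state, 1e-3, 0.0, domain.supply_values(0.0), domain, params)
        assert out.values == pytest.approx(state.values, abs=1e-12)

    def test_zeroth_order_decay_when_diffusion_disabled(self):
        # O >> λ and K3 = 0: interior node loses ~K2*dt per step
        params = TissueParameters(k3_diffusion=0.0, lambda_metabolism=1e-9)
        domain = domain_1d(50, 1000.0, dx=25.0)   # 3 nodes
        state = OxygenState(0.0, np.full(domain.n_nodes, 1000.0))
        dt = 1e-3
        out = step(state, dt, 0.0, domain.supply_values(dt), domain, params)
        assert out.values[1] == pytest.approx(1000.0 - 18.9 * dt, rel=1e-9)

    def test_mirrored_profiles_stay_mirror_images(self, tissue):
        domain = domain_1d(50, 30.0, dx=0.5)
        x = np.arange(domain.n_nodes) * 0.5
        profile = 30.0 - 0.02 * x * (50.0 - x) + 2.0 * np.sin(np.pi * x / 50.0)
        a = OxygenState(0.0, profile)
        b = OxygenState(0.0, profile[::-1].copy())
        sup = domain.supply_values(1e-3)
        out_a = step(a, 1e-3, 125.0, sup, domain, tissue)
        out_b = step(b, 1e-3, 125.0, sup, domain, tissue)
        assert out_a.values == pytest.approx(out_b.values[::-1], rel=1e-12)


class TestEquilibrate:
    def test_pure_diffusion_gives_uniform_supply_level(self):
        params = TissueParameters(k2_metabolism=0.0)
        domain = domain_1d(100, 25.0, dx=1.0)
        eq = equilibrate(domain, params, GridSpec(dx=1.0))
        assert eq.values == pytest.approx(np.full(domain.n_nodes, 25.0),
                                          abs=1e-6)

    def test_matches_constant_consumption_parabola_where_valid(self, tissue):
        domain = domain_1d(50, 50.4)
        eq = equilibrate(domain, tissue, GridSpec())
        x, oracle = steady_state_parabola_oracle(tissue, 50.0, 50.4,
                                                 n_points=101)
        mid = midpoint_value(eq, domain)
        assert mid == pytest.approx(oracle[50], rel=0.01)

    def test_residual_is_small_at_equilibrium(self, eq_50_10, tissue):
        domain, eq = eq_50_10
        assert steady_state_residual(eq.values, domain, tissue).max() < 1e-2

    def test_dirichlet_nodes_pin_to_supply(self, eq_50_10):
        domain, eq = eq_50_10
        assert eq.values[domain.dirichlet_mask] == pytest.approx(10.1)

    def test_raises_when_not_converged_in_time(self, tissue):
        domain = domain_1d(250, 50.4)
        with pytest.raises(ConvergenceError):
            equilibrate(domain, tissue,
                        GridSpec(equilibration_max_time=0.05))


class TestStages:
    def test_zero_dose_rate_preserves_equilibrium(self, eq_50_10, tissue):
        domain, eq = eq_50_10
        seg = run_stage(eq, 1.0, 150, lambda t: 0.0, domain, tissue, "hold")
        assert seg.final.values == pytest.approx(eq.values, abs=1e-3)

    def test_step_count_and_dt_partition_the_duration(self, eq_50_10, tissue):
        domain, eq = eq_50_10
        protocol = IrradiationProtocol(15.0, 125.0)
        seg = run_stage(eq, protocol.duration, 1500,
                        lambda t: protocol.dose_rate, domain, tissue,
                        STAGE_IRRADIATION)
        assert seg.dt == pytest.approx(8e-5)
        assert seg.n_steps == 1500
        assert seg.times[0] == 0.0
        assert seg.times[-1] == pytest.approx(0.12)

    def test_zero_dose_protocol_is_inert(self, eq_50_10, tissue):
        domain, eq = eq_50_10
        hist = run_protocol(domain, tissue,
                            IrradiationProtocol(0.0, 125.0), GridSpec(),
                            initial=eq)
        for stage in hist.stages:
            assert stage.values[-1] == pytest.approx(eq.values, abs=1e-12)

    def test_recovery_returns_to_equilibrium_within_one_percent(
            self, eq_50_10, tissue):
        domain, eq = eq_50_10
        hist = run_protocol(domain, tissue, IrradiationProtocol(15.0, 125.0),
                            GridSpec(), initial=eq)
        depleted = midpoint_value(hist.stage(STAGE_IRRADIATION).final, domain)
        recovered = midpoint_value(hist.stage(STAGE_RECOVERY).final, domain)
        pre = midpoint_value(eq, domain)
        assert depleted < 0.6 * pre
        assert recovered == pytest.approx(pre, rel=0.01)

    def test_maximum_principle_and_dirichlet_exactness(self, eq_50_10,
                                                       tissue):
        domain, eq = eq_50_10
        hist = run_protocol(domain, tissue, IrradiationProtocol(15.0, 125.0),
                            GridSpec(), initial=eq)
        bound = max(10.1, eq.values.max()) + 1e-9
        for stage in hist.stages:
            assert np.all(stage.values >= 0.0)
            assert np.all(stage.values <= bound)
            for t, vals in zip(stage.times, stage.values):
                assert vals[domain.dirichlet_mask] == pytest.approx(
                    domain.supply_values(t), abs=1e-12)

    def test_symmetric_supplies_keep_snapshots_symmetric(self, eq_50_10,
                                                         tissue):
        domain, eq = eq_50_10
        hist = run_protocol(domain, tissue, IrradiationProtocol(15.0, 125.0),
                            GridSpec(), initial=eq, include_recovery=False)
        vals = hist.stage(STAGE_IRRADIATION).values
        assert np.allclose(vals, vals[:, ::-1], rtol=1e-9, atol=1e-12)

    def test_midpoint_depletion_monotone_in_dose_rate(self, eq_50_10, tissue):
        domain, eq = eq_50_10
        mids = []
        for rate in (0.5, 12.5, 125.0, 285.0):
            hist = run_protocol(domain, tissue,
                                IrradiationProtocol(15.0, rate),
                                GridSpec(), initial=eq,
                                include_recovery=False)
            mids.append(midpoint_value(hist.stage(STAGE_IRRADIATION).final,
                                       domain))
        assert all(b <= a + 1e-9 for a, b in zip(mids, mids[1:]))


class TestAgainstIndependentOracles:
    def test_diffusion_free_stepper_matches_adaptive_ode(self):
        """K3 = 0 decouples the nodes; the IMEX sequence must track a
        high-accuracy adaptive integration of the reaction ODE."""
        params = TissueParameters(k3_diffusion=0.0)
        domain = domain_1d(50, 8.0, dx=25.0)  # 3 nodes, middle one isolated
        protocol = IrradiationProtocol(15.0, 125.0)
        state = OxygenState(0.0, np.full(domain.n_nodes, 8.0))
        seg = run_stage(state, protocol.duration, 1500,
                        lambda t: protocol.dose_rate, domain, params,
                        STAGE_IRRADIATION)
        _, ode = well_mixed_ode_oracle(params, protocol, 8.0,
                                       t_eval=np.array([0.0, 0.12]))
        assert seg.final.values[1] == pytest.approx(ode[-1], rel=0.005)

    def test_grid_convergence_of_end_of_irradiation_midpoint(self, tissue):
        """Halving dx and doubling the steps moves the answer < 0.5%."""
        mids = {}
        for dx, steps in ((0.5, 1500), (0.25, 3000)):
            domain = domain_1d(50, 10.1, dx=dx)
            grid = GridSpec(dx=dx, steps_per_stage=steps)
            eq = equilibrate(domain, tissue, grid)
            hist = run_protocol(domain, tissue,
                                IrradiationProtocol(15.0, 125.0), grid,
                                initial=eq, include_recovery=False)
            mids[dx] = midpoint_value(hist.stage(STAGE_IRRADIATION).final,
                                      domain)
        assert mids[0.25] == pytest.approx(mids[0.5], rel=0.005)
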