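import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.interpolate import CubicSpline

from conftest import make_channel
from maskflow.channel import (
    ChannelBC,
    ChannelSolverError,
    FabricModel,
    FluidProperties,
    ScaleGroup,
    channel_fluxes,
    darcy_jump,
    kp_momentum_ode,
    profile_u,
    profile_v,
    reference_fd_solver,
    solve_channel,
)

FLUID = FluidProperties()


def random_tapered_channel(seed):
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, 101)
    K0 = rng.uniform(0.5e-3, 4e-3)
    K = K0 * (1.0 + rng.uniform(0.05, 0.25) * np.cos(2 * np.pi * x
                                                     + rng.uniform(0, 6.28))
              + rng.uniform(-0.2, 0.2) * x)
    return make_channel(K, width=rng.uniform(0.005, 0.02),
                        length=rng.uniform(0.03, 0.06))


class TestProfiles:
    def test_u_midpoint_poiseuille(self):
        assert profile_u(0.0, 0.5) == pytest.approx(1.5)

    def test_u_no_slip_at_walls(self):
        for f in (-0.5, 0.0, 2.0):
            assert profile_u(f, 0.0) == 0.0
            assert profile_u(f, 1.0) == 0.0

    def test_u_mean_is_one_plus_f(self):
        eta = np.linspace(0, 1, 2001)
        mean = simpson(profile_u(0.2, eta), x=eta)
        assert mean == pytest.approx(1.2, abs=1e-8)

    def test_u_rejects_eta_outside_unit_interval(self):
        with pytest.raises(ValueError):
            profile_u(0.0, 1.5)

    def test_v_no_penetration_at_face(self):
        assert profile_v(1.0, 1.0, 0.0) == 0.0

    def test_v_zero_for_constant_flux(self):
        eta = np.linspace(0, 1, 11)
        assert np.all(profile_v(0.0, 1.0, eta) == 0.0)

    def test_v_top_wall_value(self):
        assert profile_v(-2.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_v_rejects_eta_outside_unit_interval(self):
        with pytest.raises(ValueError):
            profile_v(1.0, 1.0, -0.1)


class TestDarcyJump:
    def test_zero_velocity_zero_jump(self):
        assert darcy_jump(0.0, FabricModel(c_k=500.0)) == 0.0

    def test_linear_in_velocity(self):
        assert darcy_jump(1.0, FabricModel(c_k=500.0)) == pytest.approx(500.0)

    def test_linear_in_resistance(self):
        lo = darcy_jump(0.3, FabricModel(c_k=250.0))
        hi = darcy_jump(0.3, FabricModel(c_k=500.0))
        assert hi == pytest.approx(2.0 * lo)


class TestPoiseuilleLimit:
    """Constant height, effectively impermeable, low Re, no exit loss."""

    K0, Lc, W, U = 1e-3, 0.05, 0.01, 0.01

    @pytest.fixture
    def channel(self):
        return make_channel(np.full(101, self.K0), width=self.W,
                            length=self.Lc)

    @property
    def dp_analytic(self):
        Q = self.U * self.W * self.K0
        return 12.0 * FLUID.mu * self.Lc * Q / (self.W * self.K0**3)

    def test_collocation_matches_analytic(self, channel):
        sol = solve_channel(channel, self.U, FLUID, FabricModel(c_k=1e9),
                            ChannelBC())
        assert sol.p_in == pytest.approx(self.dp_analytic, rel=0.02)

    def test_fd_oracle_matches_analytic(self, channel):
        sol = reference_fd_solver(channel, self.U, FLUID,
                                  FabricModel(c_k=1e9), ChannelBC())
        assert sol.p_in == pytest.approx(self.dp_analytic, rel=0.005)

    def test_impermeable_flux_deficit_negligible(self, channel):
        sol = solve_channel(channel, self.U, FLUID, FabricModel(c_k=1e9),
                            ChannelBC())
        assert np.max(np.abs(sol.f)) < 1e-6

    def test_impermeable_keeps_all_flux(self, channel):
        sol = solve_channel(channel, self.U, FLUID, FabricModel(c_k=1e9),
                            ChannelBC())
        assert sol.Q_g == pytest.approx(sol.Q_in, rel=1e-6)
        assert abs(sol.Q_m_c) < 1e-6 * sol.Q_in


class TestSolveChannel:
    def test_porous_wall_bleeds_flux(self, uniform_channel):
        sol = solve_channel(uniform_channel, 0.5, FLUID,
                            FabricModel(c_k=500.0), ChannelBC())
        assert sol.Q_m_c > 0
        assert sol.Q_g < sol.Q_in

    def test_jet_velocity_definition(self, uniform_channel):
        sol = solve_channel(uniform_channel, 0.5, FLUID,
                            FabricModel(c_k=500.0), ChannelBC())
        K_exit = uniform_channel.heights[-1]
        assert sol.U_jet == pytest.approx(
            sol.Q_g / (uniform_channel.width * K_exit), rel=1e-12)

    def test_conservation_residual_small(self, tapered_channel):
        sol = solve_channel(tapered_channel, 0.4, FLUID,
                            FabricModel(c_k=300.0), ChannelBC(k_L=0.3))
        fx = channel_fluxes(sol, tapered_channel)
        assert fx["conservation_residual"] < 1e-6

    def test_exit_loss_raises_inlet_pressure(self, uniform_channel):
        free = solve_channel(uniform_channel, 0.5, FLUID,
                             FabricModel(c_k=500.0), ChannelBC(k_L=0.0))
        loaded = solve_channel(uniform_channel, 0.5, FLUID,
                               FabricModel(c_k=500.0), ChannelBC(k_L=10.0))
        assert loaded.p_cavity > free.p_cavity

    def test_monotone_porosity_response(self, uniform_channel):
        sols = [solve_channel(uniform_channel, 0.5, FLUID, FabricModel(c_k=ck),
                              ChannelBC()) for ck in (100.0, 500.0, 1000.0)]
        Qm = [s.Q_m_c for s in sols]
        Qg = [s.Q_g for s in sols]
        assert Qm[0] > Qm[1] > Qm[2]
        assert Qg[0] < Qg[1] < Qg[2]

    def test_exit_height_below_floor_rejected(self):
        K = np.full(101, 1e-3)
        K[-1] = 5e-6
        ch = make_channel(K)
        with pytest.raises(ChannelSolverError):
            solve_channel(ch, 0.1, FLUID, FabricModel(c_k=500.0), ChannelBC())

    def test_non_positive_velocity_rejected(self, uniform_channel):
        with pytest.raises(ChannelSolverError):
            solve_channel(uniform_channel, 0.0, FLUID, FabricModel(c_k=500.0),
                          ChannelBC())

    def test_inhale_draws_through_fabric(self, uniform_channel):
        sol = solve_channel(uniform_channel, 0.3, FLUID,
                            FabricModel(c_k=500.0),
                            ChannelBC(direction="inhale", k_L=0.5))
        assert sol.p_cavity < 0
        assert sol.Q_m_c > 0  # fabric gain on the way to the cavity


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exhale_pressure_agreement(self, seed):
        ch = random_tapered_channel(seed)
        rng = np.random.default_rng(100 + seed)
        U = float(rng.uniform(0.05, 0.6))
        ck = float(rng.uniform(100.0, 1000.0))
        a = solve_channel(ch, U, FLUID, FabricModel(c_k=ck), ChannelBC())
        b = reference_fd_solver(ch, U, FLUID, FabricModel(c_k=ck), ChannelBC())
        assert a.p_cavity == pytest.approx(b.p_cavity, rel=0.01)
        scale = np.max(np.abs(b.p))
        assert np.max(np.abs(np.interp(b.x, a.x, a.p) - b.p)) < 0.01 * scale

    def test_inhale_agreement(self, uniform_channel):
        a = solve_channel(uniform_channel, 0.3, FLUID, FabricModel(c_k=500.0),
                          ChannelBC(direction="inhale", k_L=0.5))
        b = reference_fd_solver(uniform_channel, 0.3, FLUID,
                                FabricModel(c_k=500.0),
                                ChannelBC(direction="inhale", k_L=0.5))
        assert a.p_cavity == pytest.approx(b.p_cavity, rel=0.01)

    def test_fd_grid_refinement_converged(self, tapered_channel):
        coarse = reference_fd_solver(tapered_channel, 0.4, FLUID,
                                     FabricModel(c_k=300.0), ChannelBC(),
                                     n_nodes=1001)
        fine = reference_fd_solver(tapered_channel, 0.4, FLUID,
                                   FabricModel(c_k=300.0), ChannelBC(),
                                   n_nodes=2001)
        assert fine.p_in == pytest.approx(coarse.p_in, rel=1e-3)

    def test_fd_conservation(self, tapered_channel):
        sol = reference_fd_solver(tapered_channel, 0.4, FLUID,
                                  FabricModel(c_k=300.0), ChannelBC())
        assert abs(sol.Q_in - sol.Q_g - sol.Q_m_c) < 1e-5 * sol.Q_in


class TestMomentumResidual:
    def test_converged_solution_satisfies_ode(self, tapered_channel):
        U, ck = 0.4, 300.0
        fabric = FabricModel(c_k=ck)
        sol = solve_channel(tapered_channel, U, FLUID, fabric, ChannelBC())
        scale = ScaleGroup.from_inputs(U, FLUID, fabric, tapered_channel)
        residual = kp_momentum_ode(tapered_channel, scale, FLUID, fabric)
        fp_spline = CubicSpline(sol.x, sol.fp)
        x = sol.x[5:-5]
        res = residual(x, np.interp(x, sol.x, sol.f), fp_spline(x),
                       fp_spline.derivative()(x))
        # scale by the largest individual term of the balance
        drain = np.max(np.abs(residual(x, np.interp(x, sol.x, sol.f),
                                       np.zeros_like(x), np.zeros_like(x))))
        assert np.max(np.abs(res)) < 1e-3 * drain

    def test_reversed_profile_differs_symmetric_does_not(self):
        x = np.linspace(0, 1, 101)
        sym = make_channel(2e-3 * (1.0 + 0.2 * np.cos(2 * np.pi * x)))
        asym = make_channel(2e-3 * (1.0 + 0.2 * x))
        fab = FabricModel(c_k=300.0)
        for ch, same in ((sym, True), (asym, False)):
            fwd = solve_channel(ch, 0.3, FLUID, fab, ChannelBC())
            rev_ch = make_channel(ch.heights[::-1].copy())
            rev = solve_channel(rev_ch, 0.3, FLUID, fab, ChannelBC())
            agree = fwd.p_cavity == pytest.approx(rev.p_cavity, rel=1e-6)
            assert agree == same


class TestScaleGroup:
    def test_nondimensional_groups(self, uniform_channel):
        s = ScaleGroup.from_inputs(0.5, FLUID, FabricModel(c_k=500.0),
                                   uniform_channel)
        K0 = uniform_channel.K0
        assert s.P0 == pytest.approx(FLUID.rho * 0.25)
        assert s.Re == pytest.approx(FLUID.rho * 0.5 * K0 / FLUID.mu)
        assert s.b == pytest.approx(500.0 / (FLUID.rho * 0.5))
        assert s.kappa == pytest.approx(K0 / uniform_channel.length)
        assert s.St == 0.0

    def test_rejects_non_positive_velocity(self, uniform_channel):
        with pytest.raises(ValueError):
            ScaleGroup.from_inputs(0.0, FLUID, FabricModel(c_k=500.0),
                                   uniform_channel)
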