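import numpy as np
import pytest

from conftest import make_channel
from maskflow.channel import ChannelBC, FabricModel, FluidProperties
from maskflow.gaps import GapProfileSet, mean_face_gaps
from maskflow.geometry import (
    CavitySpec,
    ChannelLayout,
    MaskSpec,
    build_channels,
)
from maskflow.network import (
    BreathSpec,
    ClipSpec,
    NetworkConvergenceError,
    SolverOptions,
    apply_clip,
    cavity_through_flux,
    solve_inhale,
    solve_network,
)

FLUID = FluidProperties()
BREATH = BreathSpec()  # 0.5 L/s exhale


def two_channel_pair(K=2e-3):
    """Mirror-identical channel pair on opposite sides of the midline."""
    left = make_channel(np.full(101, K), index=1, region="nose")
    left.exit_point = (-0.05, 0.0686)
    right = make_channel(np.full(101, K), index=2, region="nose")
    right.exit_point = (0.05, 0.0686)
    return [left, right]


def tiny_cavity():
    return CavitySpec(semi_axes=(1e-3, 1e-3))


class TestCavityThroughFlux:
    def test_zero_pressure(self):
        assert cavity_through_flux(0.0, tiny_cavity(),
                                   FabricModel(c_k=500.0)) == 0.0

    def test_darcy_value(self):
        cav = CavitySpec(semi_axes=(0.05, 0.005 / (0.05 * np.pi)))
        # area 0.005 m^2, 100 Pa, ck 500 -> v = 0.2 m/s -> 1e-3 m^3/s
        assert cav.area == pytest.approx(0.005)
        assert cavity_through_flux(100.0, cav, FabricModel(c_k=500.0)) == \
            pytest.approx(1.0e-3)

    def test_halving_ck_doubles_flux(self):
        cav = tiny_cavity()
        lo = cavity_through_flux(50.0, cav, FabricModel(c_k=250.0))
        hi = cavity_through_flux(50.0, cav, FabricModel(c_k=500.0))
        assert lo == pytest.approx(2.0 * hi)


class TestApplyClip:
    def _bcs(self, channels):
        return {c.index: ChannelBC(direction="exhale", k_L=0.0)
                for c in channels}

    def test_zero_clip_is_identity(self, small_channels):
        bcs = self._bcs(small_channels)
        out = apply_clip(bcs, small_channels, ClipSpec(k_L_clip=0.0))
        assert out == bcs

    def test_clip_targets_only_nose(self, small_channels):
        bcs = self._bcs(small_channels)
        out = apply_clip(bcs, small_channels, ClipSpec(k_L_clip=100.0))
        for ch in small_channels:
            if ch.region == "nose":
                assert out[ch.index].k_L == 100.0
            else:
                assert out[ch.index] == bcs[ch.index]

    def test_empty_target_region_rejected(self, small_channels):
        chin_only = [c for c in small_channels if c.region == "chin"]
        with pytest.raises(ValueError):
            apply_clip(self._bcs(chin_only), chin_only,
                       ClipSpec(k_L_clip=1.0, target_region="nose"))


class TestTwoChannelNetwork:
    def test_symmetric_split_and_conservation(self):
        chans = two_channel_pair()
        sol = solve_network(chans, None, FLUID, FabricModel(c_k=1e9),
                            BREATH, None, tiny_cavity(), symmetric=False)
        U = [s.U for s in sol.channel_solutions]
        assert U[0] == pytest.approx(U[1], rel=1e-9)
        assert sol.Q_g == pytest.approx(BREATH.Q_breath, rel=1e-5)
        assert sol.channel_solutions[0].Q_in == pytest.approx(
            0.5 * BREATH.Q_breath, rel=1e-4)

    def test_inhale_symmetric_split(self):
        chans = two_channel_pair()
        breath = BreathSpec(direction="inhale")
        sol = solve_inhale(chans, None, FLUID, FabricModel(c_k=1e9),
                           breath, None, tiny_cavity(), edge_k_L=0.5,
                           symmetric=False)
        U = [s.U for s in sol.channel_solutions]
        assert U[0] == pytest.approx(U[1], rel=1e-9)
        assert sol.P_cav < 0
        assert sol.Q_g == pytest.approx(breath.Q_breath, rel=1e-5)


class TestDarcyOnlyLimit:
    """Near-floor gaps: essentially everything crosses the fabric."""

    def test_exhale_floor_gaps(self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        chans = [c.with_heights(np.full(101, 1e-4)) for c in chans]
        fabric = FabricModel(c_k=1000.0)
        sol = solve_network(chans, None, FLUID, fabric, BREATH, None, cavity)
        assert sol.Q_m / BREATH.Q_breath > 0.99
        # cavity Darcy bound: P between ck Q/(A_cav + A_channel_tops) and
        # ck Q / A_cav
        A_tops = 2 * sum(c.width * c.length for c in chans)
        P_hi = fabric.c_k * BREATH.Q_breath / cavity.area
        P_lo = fabric.c_k * BREATH.Q_breath / (cavity.area + A_tops)
        assert P_lo * 0.99 < sol.P_cav < P_hi * 1.01

    def test_inhale_floor_gaps(self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        chans = [c.with_heights(np.full(101, 2.5e-4)) for c in chans]
        breath = BreathSpec(direction="inhale")
        sol = solve_inhale(chans, None, FLUID, FabricModel(c_k=1000.0),
                           breath, None, cavity, edge_k_L=0.5)
        assert sol.Q_m / breath.Q_breath > 0.97


@pytest.fixture(scope="module")
def solution(mask, cavity, small_layout):
    chans = build_channels(mask, cavity, small_layout)
    gaps = mean_face_gaps(chans, seed=7)
    return solve_network(chans, gaps, FLUID, FabricModel(c_k=500.0),
                         BREATH, None, cavity)


class TestMeanFaceNetwork:
    def test_global_conservation(self, solution):
        assert solution.mass_residual < 1e-6

    def test_pressure_equalisation(self, solution):
        tol = 1e-6 * max(abs(solution.P_cav), 1.0)
        p = np.array([s.p_cavity for s in solution.channel_solutions])
        assert np.max(np.abs(p - solution.P_cav)) < tol

    def test_positive_decomposition(self, solution):
        assert solution.P_cav > 0
        assert solution.Q_m_cav > 0
        assert solution.Q_m_c > 0
        assert all(v >= 0 for v in solution.Q_g_by_region.values())

    def test_region_totals_sum_to_Qg(self, solution):
        assert sum(solution.Q_g_by_region.values()) == pytest.approx(
            solution.Q_g, rel=1e-12)


class TestMonotonicity:
    def test_leak_fraction_grows_with_fabric_resistance(
            self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        gaps = mean_face_gaps(chans, seed=7)
        fracs = []
        for ck in (100.0, 500.0, 1000.0):
            sol = solve_network(chans, gaps, FLUID, FabricModel(c_k=ck),
                                BREATH, None, cavity)
            fracs.append(sol.Q_g / BREATH.Q_breath)
        assert fracs[0] < fracs[1] < fracs[2]

    def test_clip_reduces_nose_leak_and_redistributes(
            self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        gaps = mean_face_gaps(chans, seed=7)
        fabric = FabricModel(c_k=500.0)
        free = solve_network(chans, gaps, FLUID, fabric, BREATH, None, cavity)
        clipped = solve_network(chans, gaps, FLUID, fabric, BREATH,
                                ClipSpec(k_L_clip=1000.0), cavity)
        d_nose = free.Q_g_by_region["nose"] - clipped.Q_g_by_region["nose"]
        d_total = abs(free.Q_g - clipped.Q_g)
        assert clipped.Q_g_by_region["nose"] < free.Q_g_by_region["nose"]
        assert d_total < d_nose  # mostly redistribution, not suppression
        # other regions pick up the flow
        assert clipped.Q_g_by_region["cheek"] > free.Q_g_by_region["cheek"]

    def test_inhale_higher_edge_loss_raises_through_mask_share(
            self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        gaps = mean_face_gaps(chans, seed=7)
        breath = BreathSpec(direction="inhale")
        fabric = FabricModel(c_k=500.0)
        lo = solve_inhale(chans, gaps, FLUID, fabric, breath, None, cavity,
                          edge_k_L=0.2)
        hi = solve_inhale(chans, gaps, FLUID, fabric, breath, None, cavity,
                          edge_k_L=0.5)
        assert hi.Q_m >= lo.Q_m


class TestRobustness:
    def test_step_size_independence(self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        gaps = mean_face_gaps(chans, seed=7)
        fabric = FabricModel(c_k=500.0)
        P = []
        for a in (0.1, 0.3, 0.6):
            sol = solve_network(chans, gaps, FLUID, fabric, BREATH, None,
                                cavity, options=SolverOptions(step_a=a))
            P.append(sol.P_cav)
        assert max(P) - min(P) < 10e-6 * max(abs(p) for p in P)

    def test_unreachable_tolerance_raises(self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        gaps = mean_face_gaps(chans, seed=7)
        opts = SolverOptions(eps=1e-15, max_iter=4)
        with pytest.raises(NetworkConvergenceError):
            solve_network(chans, gaps, FLUID, FabricModel(c_k=500.0),
                          BREATH, None, cavity, options=opts)

    def test_missing_heights_rejected(self, mask, cavity, small_layout):
        chans = build_channels(mask, cavity, small_layout)
        with pytest.raises(ValueError):
            solve_network(chans, None, FLUID, FabricModel(c_k=500.0),
                          BREATH, None, cavity)


class TestMirrorSymmetry:
    def test_mirrored_gaps_give_mirrored_fluxes(self, mask, cavity):
        layout = ChannelLayout(n_nose=4, n_chin=4, n_cheek_per_side=2,
                               use_symmetry=False)
        chans = build_channels(mask, cavity, layout)
        gaps = mean_face_gaps(chans, seed=3)

        # mirror partner lookup via exit points
        def partner(i):
            ex, ey = chans[i].exit_point
            for j, c in enumerate(chans):
                if (abs(c.exit_point[0] + ex) < 1e-12
                        and abs(c.exit_point[1] - ey) < 1e-12):
                    return j
            raise AssertionError("no mirror partner")

        perm = [partner(i) for i in range(len(chans))]
        K_mirror = gaps.K.copy()
        for i, j in enumerate(perm):
            K_mirror[j] = gaps.K[i]
        mirrored = GapProfileSet(channel_ids=gaps.channel_ids,
                                 regions=gaps.regions, x=gaps.x, K=K_mirror,
                                 upper_cheek=gaps.upper_cheek)

        fabric = FabricModel(c_k=500.0)
        a = solve_network(chans, gaps, FLUID, fabric, BREATH, None, cavity,
                          symmetric=False)
        b = solve_network(chans, mirrored, FLUID, fabric, BREATH, None,
                          cavity, symmetric=False)
        Qa = np.array([s.Q_g for s in a.channel_solutions])
        Qb = np.array([s.Q_g for s in b.channel_solutions])
        assert np.allclose(Qb[perm], Qa, rtol=1e-5)
        assert b.P_cav == pytest.approx(a.P_cav, rel=1e-6)
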