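"""Cavity-coupled channel network solver.

All channels share the cavity stagnation pressure ``P_cav`` at their inner
sections.  The network iteration finds the per-channel inlet velocities
``U[i]`` and ``P_cav`` such that (i) every channel sees the same cavity
pressure and (ii) the peripheral plus through-fabric flux matches the
breathing flux.  The implementation nests an under-relaxed per-channel flux
update (step size ``a``) inside a bracketed scalar root-find on ``P_cav``,
which satisfies the same convergence contract as a flat fixed-point sweep
but is robust across the full fabric-resistance range.

Sign convention: exhale drives flow cavity -> edge with ``P_cav > 0``;
inhale reverses every flux with ``P_cav < 0``.  Totals always refer to the
full mask: when a symmetric half-model layout is detected, half of the
breathing flux is routed through the modelled half and channel totals are
mirrored back.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from maskflow.channel import (
    EXHALE,
    INHALE,
    ChannelBC,
    ChannelOptions,
    ChannelSolution,
    ChannelSolverError,
    FabricModel,
    FluidProperties,
    solve_channel,
)
from maskflow.gaps import GapProfileSet, apply_gaps
from maskflow.geometry import CavitySpec, ChannelGeometry

logger = logging.getLogger("maskflow.network")

_U_FLOOR = 1.0e-9


class NetworkConvergenceError(RuntimeError):
    """The network iteration failed to meet its convergence contract."""


@dataclass(frozen=True)
class BreathSpec:
    """Steady breathing flux (m^3/s) and direction."""

    Q_breath: float = 5.0e-4  # 0.5 L/s
    direction: str = EXHALE

    def __post_init__(self) -> None:
        if self.Q_breath <= 0:
            raise ValueError("Q_breath must be positive")
        if self.direction not in (EXHALE, INHALE):
            raise ValueError("direction must be 'exhale' or 'inhale'")


@dataclass(frozen=True)
class ClipSpec:
    """Nose-clip restriction: extra exit minor loss on targeted channels."""

    k_L_clip: float = 0.0
    target_region: str = "nose"

    def __post_init__(self) -> None:
        if self.k_L_clip < 0:
            raise ValueError("k_L_clip must be non-negative")


@dataclass(frozen=True)
class SolverOptions:
    """Network-iteration controls."""

    eps: float = 1.0e-6       # relative tolerance (pressure spread, mass)
    step_a: float = 0.3       # under-relaxed flux-update step size
    max_iter: int = 500
    init_rule: str = "conductance"
    channel_options: ChannelOptions = field(default_factory=ChannelOptions)

    def __post_init__(self) -> None:
        if not 0.0 < self.step_a <= 1.0:
            raise ValueError("step_a must lie in (0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class NetworkSolution:
    """Converged network state with the full flux decomposition."""

    direction: str
    P_cav: float                         # Pa, gauge (negative for inhale)
    channels: list[ChannelGeometry]
    channel_solutions: list[ChannelSolution]
    Q_breath: float
    Q_g: float                           # total peripheral leak, full mask
    Q_g_by_region: dict[str, float]
    Q_m_cav: float
    Q_m_c: float
    symmetric: bool
    multiplier: int
    history: list[dict] = field(default_factory=list)
    converged: bool = False

    @property
    def Q_m(self) -> float:
        return self.Q_m_cav + self.Q_m_c

    @property
    def q_g(self) -> np.ndarray:
        """Leak per unit edge width for the modelled channels (m^2/s)."""
        return np.array([s.Q_g / c.width for s, c in
                         zip(self.channel_solutions, self.channels)])

    @property
    def U_jet(self) -> np.ndarray:
        return np.array([s.U_jet for s in self.channel_solutions])

    @property
    def pressure_spread(self) -> float:
        p = np.array([s.p_cavity for s in self.channel_solutions])
        return float(p.max() - p.min())

    @property
    def mass_residual(self) -> float:
        return abs(self.Q_g + self.Q_m - self.Q_breath) / self.Q_breath


def cavity_through_flux(P_cav: float, cavity: CavitySpec,
                        fabric: FabricModel) -> float:
    """Darcy flux through the porous cavity region, sign follows P_cav."""
    return cavity.area * P_cav / fabric.c_k


def apply_clip(channel_bcs: dict[int, ChannelBC],
               channels: list[ChannelGeometry], clip: ClipSpec) -> dict[int, ChannelBC]:
    """Add the clip's minor-loss coefficient to the targeted region's exits."""
    targets = [c.index for c in channels if c.region == clip.target_region]
    if not targets:
        raise ValueError(f"no channels in target region {clip.target_region!r}")
    out = dict(channel_bcs)
    for idx in targets:
        old = out[idx]
        out[idx] = ChannelBC(direction=old.direction,
                             k_L=old.k_L + clip.k_L_clip, patm=old.patm)
    return out


def _lubrication_conductance(ch: ChannelGeometry, mu: float) -> float:
    """Poiseuille heuristic W K_exit^3 / (12 mu Lc), m^3/(s Pa)."""
    K_exit = float(ch.heights[-1])
    return ch.width * K_exit**3 / (12.0 * mu * ch.length)


class _ChannelState:
    """Per-channel matcher: invert |p_cavity(U)| = P with an a-step update."""

    def __init__(self, channel: ChannelGeometry, bc: ChannelBC,
                 fluid: FluidProperties, fabric: FabricModel,
                 options: SolverOptions):
        self.channel = channel
        self.bc = bc
        self.fluid = fluid
        self.fabric = fabric
        self.opts = options
        self.U: float | None = None
        self.solution: ChannelSolution | None = None
        self.slope: float = 1.0  # d log U / d log |p_cavity| estimate
        self.n_solves = 0

    def _solve(self, U: float) -> ChannelSolution:
        base = self.opts.channel_options
        copts = ChannelOptions(
            grid_size=base.grid_size,
            mesh_size=base.mesh_size,
            bvp_tol=base.bvp_tol,
            max_nodes=base.max_nodes,
            dense_quadrature=base.dense_quadrature,
        )
        if self.solution is not None:
            copts.warm_start = np.vstack([self.solution.f, self.solution.fp])
        self.n_solves += 1
        return solve_channel(self.channel, U, self.fluid, self.fabric,
                             self.bc, copts)

    def match(self, P_target: float, U_init: float, tol: float,
              max_iter: int) -> ChannelSolution:
        """Find U such that |p_cavity(U)| equals ``P_target`` within tol.

        Starts with the under-relaxed a-step update; once two iterates are
        available a clamped secant step in (log U, log p) accelerates the
        fixed point without changing the converged result.
        """
        a = self.opts.step_a
        U = self.U if self.U is not None else max(U_init, _U_FLOOR)
        sol = None
        U_good = None
        max_step = 1.5
        prev: tuple[float, float] | None = None  # (log U, log p)
        for it in range(max_iter):
            try:
                sol = self._solve(U)
            except (ChannelSolverError, ValueError, FloatingPointError):
                # inhale channels can blow up in finite x at large U:
                # retreat toward the last solvable velocity
                sol = None
            if sol is None:
                U = (math.sqrt(U * U_good) if U_good is not None
                     else max(0.25 * U, _U_FLOOR))
                max_step = max(0.25 * max_step, 0.05)
                prev = None
                continue
            U_good = U
            p = abs(sol.p_cavity)
            if abs(p - P_target) <= tol:
                self.U, self.solution = U, sol
                return sol
            lu, lp = math.log(U), math.log(max(p, 1e-300))
            target = math.log(P_target)
            if prev is not None and abs(lp - prev[1]) > 1e-14 and it >= 1:
                slope = (lu - prev[0]) / (lp - prev[1])  # d logU / d logp
                if slope > 0:
                    self.slope = float(slope)
                step = np.clip(slope * (target - lp), -max_step, max_step)
            elif self.U is not None:
                # reuse the local log-log slope from the previous target
                step = np.clip(self.slope * (target - lp), -max_step, max_step)
            else:
                step = np.clip(a * (target - lp), -max_step, max_step)
            prev = (lu, lp)
            U = max(U * math.exp(step), _U_FLOOR)
        # under-relaxation stalled: bracketed root-find on log U
        logger.debug("channel %d: a-step update stalled, using brentq",
                     self.channel.index)

        def h(logU):
            nonlocal sol
            sol = self._solve(math.exp(logU))
            return abs(sol.p_cavity) - P_target

        lo = hi = math.log(U)
        if h(lo) > 0:  # pressure too high: walk U down
            for _ in range(80):
                hi, lo = lo, lo - 0.7
                if h(lo) <= 0:
                    break
            else:
                raise ChannelSolverError(
                    f"channel {self.channel.index}: cannot bracket U")
        else:  # pressure too low: walk U up
            for _ in range(80):
                lo, hi = hi, hi + 0.7
                if h(hi) >= 0:
                    break
            else:
                raise ChannelSolverError(
                    f"channel {self.channel.index}: cannot bracket U")
        logU = brentq(h, lo, hi, xtol=1e-13)
        sol = self._solve(math.exp(logU))
        self.U, self.solution = math.exp(logU), sol
        return sol


def _detect_symmetric(channels: list[ChannelGeometry]) -> bool:
    return all(ch.exit_point[0] >= -1e-12 for ch in channels)


def solve_network(channels: list[ChannelGeometry],
                  gaps: GapProfileSet | None,
                  fluid: FluidProperties,
                  fabric: FabricModel,
                  breath: BreathSpec,
                  clip: ClipSpec | None,
                  cavity: CavitySpec,
                  options: SolverOptions | None = None,
                  edge_k_L: float = 0.0,
                  symmetric: bool | None = None) -> NetworkSolution:
    """Solve the coupled cavity/channel network.

    The outer scalar root-find drives the total-mass residual to zero over
    the cavity-pressure magnitude; at each trial pressure every channel's
    inlet flux is updated (step size ``a``) until its inner-section pressure
    matches.  Raises :class:`NetworkConvergenceError` if the convergence
    contract cannot be met; never returns partial results silently.
    """
    opts = options or SolverOptions()
    if gaps is not None:
        channels = apply_gaps(channels, gaps)
    if any(ch.heights is None for ch in channels):
        raise ValueError("channels must carry gap heights")
    if symmetric is None:
        symmetric = _detect_symmetric(channels)
    mult = 2 if symmetric else 1

    direction = breath.direction
    bcs = {ch.index: ChannelBC(direction=direction, k_L=edge_k_L)
           for ch in channels}
    if clip is not None and clip.k_L_clip > 0:
        bcs = apply_clip(bcs, channels, clip)

    states = [_ChannelState(ch, bcs[ch.index], fluid, fabric, opts)
              for ch in channels]

    # initial flux split: lubrication conductances against the cavity Darcy
    G_ch = np.array([_lubrication_conductance(ch, fluid.mu)
                     for ch in channels])
    G_cav = cavity.area / fabric.c_k
    P_guess = breath.Q_breath / (mult * G_ch.sum() + G_cav)
    U_init = {}
    for ch, g in zip(channels, G_ch):
        K_inlet = float(ch.heights[0 if direction == EXHALE else -1])
        U_init[ch.index] = max(g * P_guess / (ch.width * K_inlet), _U_FLOOR)

    Q_breath = breath.Q_breath
    history: list[dict] = []
    # inner tolerance must track |P_cav| so the per-channel matching noise
    # stays below the outer mass-balance tolerance
    inner_tol_of = lambda P: 0.25 * opts.eps * max(P, 1e-9)

    def mass_residual(Pm: float) -> float:
        Q_channels = 0.0
        for st in states:
            sol = st.match(Pm, U_init[st.channel.index], inner_tol_of(Pm),
                           opts.max_iter)
            if direction == EXHALE:
                Q_channels += sol.Q_in
            else:
                Q_channels += sol.Q_in + sol.Q_m_c  # delivered to the cavity
        g = mult * Q_channels + cavity.area * Pm / fabric.c_k - Q_breath
        history.append({"P_cav": Pm, "mass_residual": g / Q_breath})
        return g

    # bracket the cavity-pressure magnitude, expanding from the conductance
    # estimate (the Darcy-only ceiling c_k Q / A_cav caps the search)
    P_max = fabric.c_k * Q_breath / cavity.area
    P0 = min(max(P_guess, 1e-12), P_max)
    g0 = mass_residual(P0)
    if g0 < 0:
        P_lo, g_lo = P0, g0
        P_hi, g_hi = P_lo, g_lo
        for _ in range(80):
            P_hi = min(4.0 * P_hi, P_max)
            g_hi = mass_residual(P_hi)
            if g_hi >= 0:
                break
            if P_hi >= P_max:
                raise NetworkConvergenceError(
                    "cavity-pressure bracket failed (high end)")
            P_lo, g_lo = P_hi, g_hi
        else:
            raise NetworkConvergenceError("could not bracket the cavity pressure")
    else:
        P_hi, g_hi = P0, g0
        P_lo, g_lo = P_hi, g_hi
        for _ in range(80):
            P_lo *= 0.25
            g_lo = mass_residual(P_lo)
            if g_lo <= 0:
                break
            P_hi, g_hi = P_lo, g_lo
        else:
            raise NetworkConvergenceError("could not bracket the cavity pressure")

    # Illinois regula falsi on the bracket; stop on the mass-balance value
    Pm, resid = P_lo, g_lo
    P_prev = None
    for _ in range(opts.max_iter):
        if abs(resid) / Q_breath <= 0.5 * opts.eps:
            break
        Pm = (P_lo * g_hi - P_hi * g_lo) / (g_hi - g_lo)
        Pm = min(max(Pm, P_lo + 1e-3 * (P_hi - P_lo)),
                 P_hi - 1e-3 * (P_hi - P_lo))
        if Pm == P_prev or (P_hi - P_lo) <= 1e-13 * P_hi:
            break  # bracket exhausted to round-off; final check decides
        P_prev = Pm
        resid = mass_residual(Pm)
        if resid > 0:
            P_hi, g_hi = Pm, resid
            g_lo *= 0.5  # Illinois weighting keeps superlinear convergence
        else:
            P_lo, g_lo = Pm, resid
            g_hi *= 0.5
    resid = mass_residual(Pm)  # leave every channel state at the accepted Pm
    if abs(resid) / Q_breath > opts.eps:
        raise NetworkConvergenceError(
            f"mass balance residual {resid / Q_breath:.3e} exceeds eps "
            f"after {opts.max_iter} outer iterations")

    sols = [st.solution for st in states]
    P_cav = Pm if direction == EXHALE else -Pm
    spread = max(abs(abs(s.p_cavity) - Pm) for s in sols)
    if spread > opts.eps * max(Pm, 1.0):
        raise NetworkConvergenceError(
            f"channel inlet pressures not equalised (spread {spread:.3e} Pa)")

    Q_g_region = {"nose": 0.0, "chin": 0.0, "cheek": 0.0}
    Q_g = Q_m_c = 0.0
    for ch, s in zip(channels, sols):
        Q_g += mult * s.Q_g
        Q_m_c += mult * s.Q_m_c
        Q_g_region[ch.region] += mult * s.Q_g
    Q_m_cav = cavity.area * Pm / fabric.c_k

    sol = NetworkSolution(
        direction=direction, P_cav=P_cav, channels=list(channels),
        channel_solutions=sols, Q_breath=Q_breath, Q_g=Q_g,
        Q_g_by_region=Q_g_region, Q_m_cav=Q_m_cav, Q_m_c=Q_m_c,
        symmetric=symmetric, multiplier=mult, history=history,
        converged=True,
    )
    logger.info("network converged: P_cav=%.4g Pa, Q_g=%.3g, Q_m=%.3g "
                "(%d channel solves)", P_cav, Q_g, sol.Q_m,
                sum(st.n_solves for st in states))
    return sol


def solve_inhale(channels, gaps, fluid, fabric, breath, clip, cavity,
                 options=None, edge_k_L: float = 0.5,
                 symmetric: bool | None = None) -> NetworkSolution:
    """Inward-protection solve: flow enters at the edges and the fabric.

    ``edge_k_L`` is the sudden-contraction loss at the peripheral inlets
    (representative values 0.2 and 0.5).
    """
    if breath.direction != INHALE:
        breath = BreathSpec(Q_breath=breath.Q_breath, direction=INHALE)
    return solve_network(channels, gaps, fluid, fabric, breath, clip, cavity,
                         options=options, edge_k_L=edge_k_L,
                         symmetric=symmetric)
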