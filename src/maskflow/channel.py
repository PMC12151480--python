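"""Single-channel Karman-Pohlhausen solver with a Darcy-porous top wall.

Each channel has a solid bottom wall (the face) and a porous top wall (the
fabric).  A parabolic streamwise profile ``u = (1+f(x)) 6 eta (1-eta)`` is
assumed and the streamwise momentum equation is integrated across the channel
height, which reduces the problem to a second-order ODE for the flux
amplitude ``f(x)`` on the normalised arclength ``x in [0, 1]``::

    (dh f')' = A (1+f) f' + G (1+f) / dh^2
    A = 12 rho U Lc / (5 c_k K0),   G = 12 mu Lc^2 / (c_k K0^3)

with ``dh(x) = K(x)/K0`` the unit-mean height profile.  The continuity
equation fixes the through-fabric normal velocity as
``v_n = -U kappa d[dh (1+f)]/dx`` (``kappa = K0/Lc``), and the channel gauge
pressure follows from the dimensional Darcy jump at the top wall,
``p(x) = c_k v_n = -c_k U kappa dh(x) f'(x)``; keeping the kappa factor here
makes the pressure-flux coupling exactly Darcy-consistent.  At the ambient
end a minor-loss condition ``p = patm +/- (k_L/2) rho (U (1+f))^2`` closes
the problem.  ``f(0) = 0`` fixes U as the mean velocity at the flow inlet
(cavity end for exhale, mask edge for inhale), so the inlet/cavity pressure
is an *output* used by the network iteration.

Two independent solution routes are provided: :func:`solve_channel`
(scipy collocation with a shooting fallback) and
:func:`reference_fd_solver` (dense finite differences + damped Newton),
which serve as mutual oracles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson, solve_bvp, solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from maskflow.geometry import ChannelGeometry

logger = logging.getLogger("maskflow.channel")

#: minimum admissible channel height (m); smaller heights are clamped
HEIGHT_FLOOR = 1.0e-5

EXHALE = "exhale"
INHALE = "inhale"


class ChannelSolverError(RuntimeError):
    """Channel BVP failed to converge or violated its contract."""


@dataclass(frozen=True)
class FluidProperties:
    """Incompressible air: density rho (kg/m^3), viscosity mu (Pa s)."""

    rho: float = 1.2
    mu: float = 1.8e-5

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class FabricModel:
    """Darcy fabric: pressure jump = c_k * normal velocity."""

    c_k: float = 500.0  # kg/(m^2 s)

    def __post_init__(self) -> None:
        if self.c_k <= 0:
            raise ValueError("fabric air resistance c_k must be positive")


@dataclass(frozen=True)
class ChannelBC:
    """Flow direction and ambient-end minor-loss coefficient."""

    direction: str = EXHALE
    k_L: float = 0.0
    patm: float = 0.0  # gauge; fixed 0

    def __post_init__(self) -> None:
        if self.direction not in (EXHALE, INHALE):
            raise ValueError("direction must be 'exhale' or 'inhale'")
        if self.k_L < 0:
            raise ValueError("k_L must be non-negative")


@dataclass(frozen=True)
class ScaleGroup:
    """Nondimensional groups of one channel solve (steady: St = 0)."""

    U: float
    P0: float
    kappa: float
    Re: float
    b: float
    St: float = 0.0

    @classmethod
    def from_inputs(cls, U: float, fluid: FluidProperties, fabric: FabricModel,
                    channel: ChannelGeometry) -> "ScaleGroup":
        if U <= 0:
            raise ValueError("characteristic velocity must be positive")
        K0 = channel.K0
        return cls(U=U, P0=fluid.rho * U * U, kappa=K0 / channel.length,
                   Re=fluid.rho * U * K0 / fluid.mu,
                   b=fabric.c_k / (fluid.rho * U))


@dataclass
class ChannelOptions:
    """Numerical knobs for the channel solvers."""

    grid_size: int = 101        # output grid
    mesh_size: int = 41         # initial collocation mesh (adaptively refined)
    bvp_tol: float = 1.0e-6
    max_nodes: int = 20000
    dense_quadrature: int = 401  # nodes used for the v_n flux quadrature
    conservation_tol: float = 1.0e-6
    warm_start: np.ndarray | None = None  # (2, m) prior [f; f'] on a mesh


@dataclass
class ChannelSolution:
    """Converged per-channel solution.

    ``x`` runs from the flow inlet: the cavity end for exhale, the mask edge
    for inhale.  ``p_cavity`` is the gauge pressure at the cavity end (the
    quantity equalised by the network); ``v_n`` is the through-fabric normal
    velocity, positive out of the channel.
    """

    direction: str
    x: np.ndarray
    f: np.ndarray
    fp: np.ndarray
    p: np.ndarray          # Pa, gauge
    v_n: np.ndarray        # m/s, outward through the fabric
    U: float               # mean inlet velocity, m/s
    p_in: float            # Pa at the flow inlet
    p_cavity: float        # Pa at the cavity end
    Q_in: float            # m^3/s entering at the flow inlet
    Q_g: float             # m^3/s peripheral (edge) flux
    Q_m_c: float           # m^3/s through the channel's porous top
    U_jet: float           # m/s mean velocity at the mask-edge cross-section
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# assumed velocity profiles and Darcy closure
# ---------------------------------------------------------------------------

def profile_u(f, eta):
    """Dimensionless streamwise velocity u = (1+f) 6 eta (1-eta)."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0) or np.any(eta > 1):
        raise ValueError("eta must lie in [0, 1]")
    return (1.0 + f) * 6.0 * eta * (1.0 - eta)


def profile_v(fp, delta_h, eta):
    """Dimensionless wall-normal velocity v = -dh f' (3 eta^2 - 2 eta^3)."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0) or np.any(eta > 1):
        raise ValueError("eta must lie in [0, 1]")
    return -delta_h * fp * (3.0 * eta**2 - 2.0 * eta**3)


def darcy_jump(v_n, fabric: FabricModel):
    """Dimensional fabric pressure jump, Delta p = c_k * v_n (Pa)."""
    return fabric.c_k * np.asarray(v_n, dtype=float)


# ---------------------------------------------------------------------------
# ODE assembly
# ---------------------------------------------------------------------------

def _floored_profile(channel: ChannelGeometry):
    """Unit-mean height profile (value, derivative, is_constant) + K0.

    Heights below the floor are clamped (and logged); constant profiles get
    a spline-free fast path.
    """
    K = np.asarray(channel.heights, dtype=float)
    if np.any(K < HEIGHT_FLOOR):
        n_clamped = int(np.sum(K < HEIGHT_FLOOR))
        logger.info("channel %s: clamped %d height samples to the %g m floor",
                    channel.index, n_clamped, HEIGHT_FLOOR)
        K = np.maximum(K, HEIGHT_FLOOR)
    x = np.linspace(0.0, 1.0, len(K))
    K0 = float(np.trapezoid(K, x))
    if np.ptp(K) <= 1e-12 * K0:
        one = lambda s: np.ones_like(np.asarray(s, dtype=float))
        zero = lambda s: np.zeros_like(np.asarray(s, dtype=float))
        return K0, one, zero, True
    dh = CubicSpline(x, K / K0)
    return K0, dh, dh.derivative(), False


def _ode_params(channel: ChannelGeometry, K0: float, U: float,
                fluid: FluidProperties, fabric: FabricModel,
                k_L: float) -> tuple[float, float, float]:
    """Coefficients (A, G, C_L) of the reduced momentum ODE.

    With the Darcy-consistent pressure scale ``B = kappa b = c_k K0/(rho U
    Lc)``: A = 12/(5B) weights inertia, G = 12/(B kappa Re) = 12 mu Lc^2 /
    (c_k K0^3) the fabric drain, C_L = k_L/(2B) the minor-loss coefficient.
    """
    Lc = channel.length
    B = fabric.c_k * K0 / (fluid.rho * U * Lc)
    A = 12.0 / (5.0 * B)
    G = 12.0 * fluid.mu * Lc * Lc / (fabric.c_k * K0**3)
    C_L = k_L / (2.0 * B)
    return A, G, C_L


def kp_momentum_ode(channel: ChannelGeometry, scale: ScaleGroup,
                    fluid: FluidProperties | None = None,
                    fabric: FabricModel | None = None):
    """Residual of the integrated momentum ODE, for validation.

    Returns ``residual(x, f, fp, fpp)`` evaluating
    ``dh f'' + dh' f' - A (1+f) f' - G (1+f)/dh^2``;
    a converged solution drives it to zero pointwise.
    """
    fluid = fluid or FluidProperties()
    fabric = fabric or FabricModel(c_k=scale.b * fluid.rho * scale.U)
    K0, dh, dhp, _const = _floored_profile(channel)
    A, G, _ = _ode_params(channel, K0, scale.U, fluid, fabric, 0.0)

    def residual(x, f, fp, fpp):
        h = dh(x)
        return h * fpp + dhp(x) * fp - A * (1.0 + f) * fp - G * (1.0 + f) / h**2

    return residual


def _cosh_guess(x: np.ndarray, G: float, sign: float,
                c0: float = 0.0) -> np.ndarray:
    """Viscous-limit seed: 1+f = cosh-type solution of f'' = G (1+f)."""
    r = math.sqrt(max(G, 1.0e-12))
    if sign < 0:  # exhale: decay toward the exit, f'(1) ~ 0
        z = np.clip(r * (1.0 - x), 0.0, 350.0)
        den = math.cosh(min(r, 350.0))
        f = np.cosh(z) / den - 1.0
        fp = -np.sinh(z) * r / den
    else:  # inhale: growth from the edge inlet, f'(0) = c0
        z = np.clip(r * x, 0.0, 350.0)
        f = np.cosh(z) - 1.0 + (c0 / r) * np.sinh(z)
        fp = r * np.sinh(z) + c0 * np.cosh(z)
    return np.vstack([f, fp])


# ---------------------------------------------------------------------------
# primary solver: collocation with shooting fallback
# ---------------------------------------------------------------------------

def solve_channel(channel: ChannelGeometry, U_in: float,
                  fluid: FluidProperties, fabric: FabricModel,
                  bc: ChannelBC,
                  options: ChannelOptions | None = None) -> ChannelSolution:
    """Solve one channel for a given mean inlet velocity ``U_in``.

    For exhale the flow runs cavity -> edge and the minor-loss condition is
    applied at the exit; for inhale the channel is solved in the flow-aligned
    (edge -> cavity) coordinate with the contraction loss at the peripheral
    inlet.  The cavity-end pressure is returned, not imposed.
    """
    opts = options or ChannelOptions()
    if channel.heights is None or channel.length is None:
        raise ChannelSolverError(f"channel {channel.index}: geometry incomplete")
    if U_in <= 0:
        raise ChannelSolverError("U_in must be positive")
    K_exit = float(channel.heights[-1])
    if K_exit < HEIGHT_FLOOR:
        raise ChannelSolverError(
            f"channel {channel.index}: exit height {K_exit:g} m below floor")

    K0, dh_geom, dhp_geom, const = _floored_profile(channel)
    A, G, C_L = _ode_params(channel, K0, U_in, fluid, fabric, bc.k_L)

    inhale = bc.direction == INHALE
    if inhale and not const:
        # flow-aligned coordinate: xi = 1 - x_geometry
        dh = lambda s: dh_geom(1.0 - np.asarray(s))
        dhp = lambda s: -dhp_geom(1.0 - np.asarray(s))
    else:
        dh, dhp = dh_geom, dhp_geom

    def rhs(x, y):
        h = dh(x)
        f, fp = y
        fpp = (A * (1.0 + f) * fp + G * (1.0 + f) / h**2 - dhp(x) * fp) / h
        return np.vstack([fp, fpp])

    if const:
        def rhs_scalar(t, y):
            f, fp = y
            return (fp, A * (1.0 + f) * fp + G * (1.0 + f))
    else:
        def rhs_scalar(t, y):
            f, fp = y
            h = float(dh(t))
            return (fp, (A * (1.0 + f) * fp + G * (1.0 + f) / (h * h)
                         - float(dhp(t)) * fp) / h)

    dh0 = float(dh(0.0))
    dh1 = float(dh(1.0))
    if inhale:
        c0 = C_L / dh0  # f'(0) from the inlet contraction loss

        def bc_fun(ya, yb):
            return np.array([ya[0], dh0 * ya[1] - C_L * (1.0 + ya[0]) ** 2])
    else:
        def bc_fun(ya, yb):
            return np.array([ya[0], dh1 * yb[1] + C_L * (1.0 + yb[0]) ** 2])

    x_mesh = np.linspace(0.0, 1.0, opts.mesh_size)
    if opts.warm_start is not None and opts.warm_start.shape[1] >= 2:
        ws = opts.warm_start
        x_ws = np.linspace(0.0, 1.0, ws.shape[1])
        y_guess = np.vstack([np.interp(x_mesh, x_ws, ws[0]),
                             np.interp(x_mesh, x_ws, ws[1])])
    else:
        y_guess = _cosh_guess(x_mesh, G, +1.0 if inhale else -1.0,
                              c0=C_L / dh0 if inhale else 0.0)

    if inhale:
        # both conditions sit at the peripheral inlet: march the IVP
        method = "ivp"
        res = _shooting_fallback(rhs_scalar, dh0, dh1, C_L, inhale, opts)
        if res is None:
            raise ChannelSolverError(
                f"channel {channel.index}: inhale integration diverged "
                f"(A={A:.3g}, G={G:.3g}, C_L={C_L:.3g})")
    else:
        method = "collocation"
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            res = solve_bvp(rhs, bc_fun, x_mesh, y_guess, tol=opts.bvp_tol,
                            max_nodes=opts.max_nodes)
            if res.status != 0 or not np.all(np.isfinite(res.sol(x_mesh))):
                # retry from the analytic seed, then fall back to shooting
                res = solve_bvp(rhs, bc_fun, x_mesh,
                                _cosh_guess(x_mesh, G, -1.0),
                                tol=opts.bvp_tol, max_nodes=opts.max_nodes)
            if res.status != 0 or not np.all(np.isfinite(res.sol(x_mesh))):
                method = "shooting"
                res = _shooting_fallback(rhs_scalar, dh0, dh1, C_L, inhale,
                                         opts)
                if res is None:
                    raise ChannelSolverError(
                        f"channel {channel.index}: BVP did not converge "
                        f"(A={A:.3g}, G={G:.3g}, C_L={C_L:.3g})")

    x_out = np.linspace(0.0, 1.0, opts.grid_size)
    f, fp = res.sol(x_out)
    sol = ChannelSolution(
        direction=bc.direction, x=x_out, f=f, fp=fp,
        p=np.empty(0), v_n=np.empty(0), U=U_in,
        p_in=0.0, p_cavity=0.0, Q_in=0.0, Q_g=0.0, Q_m_c=0.0, U_jet=0.0,
        diagnostics={"method": method, "n_mesh": res.x.size,
                     "bvp_status": int(res.status),
                     "max_residual": float(np.max(res.rms_residuals))
                     if hasattr(res, "rms_residuals") and
                     np.size(res.rms_residuals) else 0.0},
    )
    _finalize(sol, res.sol, channel, K0, dh, dhp, U_in, fluid, fabric, opts)
    return sol


def _shooting_fallback(rhs_scalar, dh0, dh1, C_L, inhale,
                       opts: ChannelOptions):
    """Shoot from x = 0 (bisecting on the free initial slope for exhale)."""

    class _Shot:
        def __init__(self, spline):
            self._spline = spline
            self.status = 0
            self.x = spline.x

        def sol(self, x):
            return self._spline(x).T

    def blowup(t, y):
        return abs(y[0]) + abs(y[1]) - 1.0e10

    blowup.terminal = True

    def integrate(s0):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ivp = solve_ivp(rhs_scalar, (0.0, 1.0), [0.0, s0],
                            method="LSODA", dense_output=True,
                            rtol=1e-10, atol=1e-12, events=[blowup])
        if (not ivp.success or ivp.status == 1
                or not np.all(np.isfinite(ivp.y))):
            return None
        return ivp

    if inhale:
        ivp = integrate(C_L / dh0)
        if ivp is None:
            return None
        xs = np.linspace(0.0, 1.0, opts.grid_size)
        ys = ivp.sol(xs)
        return _Shot(CubicSpline(xs, ys.T))

    def mismatch(s0):
        ivp = integrate(s0)
        if ivp is None:
            return np.nan
        f1, fp1 = ivp.y[:, -1]
        return dh1 * fp1 + C_L * (1.0 + f1) ** 2

    # exhale slope is non-positive; expand the bracket downwards
    hi = 0.0
    g_hi = mismatch(hi)
    if not np.isfinite(g_hi):
        return None
    lo = -1.0
    for _ in range(60):
        g_lo = mismatch(lo)
        if np.isfinite(g_lo) and g_lo * g_hi <= 0:
            break
        lo *= 2.0
    else:
        return None
    s_root = brentq(mismatch, lo, hi, xtol=1e-13)
    ivp = integrate(s_root)
    xs = np.linspace(0.0, 1.0, opts.grid_size)
    ys = ivp.sol(xs)
    return _Shot(CubicSpline(xs, ys.T))


def _finalize(sol: ChannelSolution, interp, channel: ChannelGeometry,
              K0: float, dh, dhp, U: float, fluid: FluidProperties,
              fabric: FabricModel, opts: ChannelOptions) -> None:
    """Fill pressures, normal velocities and the flux partition."""
    kappa = K0 / channel.length
    x = sol.x
    h = dh(x)
    # Darcy pressure along the channel (gauge), Pa: p = c_k * v_n
    sol.p = -fabric.c_k * U * kappa * h * sol.fp
    # mass-consistent outward normal velocity: v_n = -(U K0 / Lc) d[dh(1+f)]/dx
    sol.v_n = -U * kappa * (dhp(x) * (1.0 + sol.f) + h * sol.fp)
    sol.p_in = float(sol.p[0])

    W = channel.width
    xq = np.linspace(0.0, 1.0, opts.dense_quadrature)
    fq, fpq = interp(xq)
    vq = -U * kappa * (dhp(xq) * (1.0 + fq) + dh(xq) * fpq)
    Q_fabric = W * channel.length * simpson(vq, x=xq)  # signed outward

    hq0 = float(dh(0.0))
    hq1 = float(dh(1.0))
    f1 = float(sol.f[-1])
    Q0 = U * W * K0 * hq0                 # inlet (f(0) = 0)
    Q1 = U * W * K0 * hq1 * (1.0 + f1)    # far-end flux

    if sol.direction == EXHALE:
        # the cavity holds near-stagnant air: its stagnation pressure exceeds
        # the channel-inlet static pressure by the momentum-consistent
        # dynamic head beta * rho U^2 / 2 with beta = 6/5 (parabolic profile)
        sol.p_cavity = sol.p_in + 0.6 * fluid.rho * U * U
        sol.Q_in = Q0
        sol.Q_g = Q1
        sol.Q_m_c = Q_fabric
        K_edge = K0 * hq1
        sol.U_jet = sol.Q_g / (W * K_edge)
    else:
        # flow-aligned coordinate starts at the mask edge
        sol.p_cavity = float(sol.p[-1])
        sol.Q_in = Q0            # unfiltered ambient inflow at the edge
        sol.Q_g = Q0
        sol.Q_m_c = -Q_fabric    # fabric gain along the channel (positive)
        K_edge = K0 * hq0
        sol.U_jet = Q0 / (W * K_edge)
    sol.diagnostics["Q_far"] = Q1


def channel_fluxes(sol: ChannelSolution, channel: ChannelGeometry,
                   scale: ScaleGroup | None = None,
                   tol: float = 1.0e-6) -> dict:
    """Flux summary with a per-channel conservation check.

    Exhale: ``Q_in = Q_g + Q_m_c``; inhale: edge inflow plus fabric gain
    equals the flux delivered to the cavity.
    """
    if sol.direction == EXHALE:
        residual = abs(sol.Q_in - sol.Q_g - sol.Q_m_c) / abs(sol.Q_in)
    else:
        Q_cav = sol.diagnostics.get("Q_far", sol.Q_in + sol.Q_m_c)
        residual = abs(sol.Q_in + sol.Q_m_c - Q_cav) / abs(Q_cav)
    if residual > tol:
        raise ChannelSolverError(
            f"per-channel conservation violated: residual {residual:.3e} > {tol:g}")
    return {
        "Q_in": sol.Q_in,
        "Q_g": sol.Q_g,
        "Q_m_c": sol.Q_m_c,
        "U_jet": sol.U_jet,
        "p_in": sol.p_in,
        "p_cavity": sol.p_cavity,
        "conservation_residual": residual,
    }


# ---------------------------------------------------------------------------
# independent finite-difference oracle
# ---------------------------------------------------------------------------

def reference_fd_solver(channel: ChannelGeometry, U_in: float,
                        fluid: FluidProperties, fabric: FabricModel,
                        bc: ChannelBC, n_nodes: int = 2001,
                        max_iter: int = 60) -> ChannelSolution:
    """Dense finite-difference discretization solved by damped Newton.

    Independent of :func:`solve_channel`: the conservative form
    ``(dh f')' = A (1+f) f' + G (1+f)/dh^2`` is discretized with half-node
    height coefficients on ``n_nodes`` points and the nonlinear system is
    solved with a line-searched Newton iteration.  Used as the validation
    oracle in tests and the ``validate`` CLI command.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    if channel.heights is None or channel.length is None:
        raise ChannelSolverError(f"channel {channel.index}: geometry incomplete")
    if U_in <= 0:
        raise ChannelSolverError("U_in must be positive")

    K0, dh_geom, dhp_geom, _const = _floored_profile(channel)
    A, G, C_L = _ode_params(channel, K0, U_in, fluid, fabric, bc.k_L)
    inhale = bc.direction == INHALE

    xs = np.linspace(0.0, 1.0, n_nodes)
    hgrid = 1.0 / (n_nodes - 1)
    if inhale:
        dh_n = dh_geom(1.0 - xs)
        dh_half = dh_geom(1.0 - (xs[:-1] + 0.5 * hgrid))
    else:
        dh_n = dh_geom(xs)
        dh_half = dh_geom(xs[:-1] + 0.5 * hgrid)

    f = _cosh_guess(xs, G, +1.0 if inhale else -1.0,
                    c0=C_L / dh_n[0] if inhale else 0.0)[0]

    def residual(fv):
        R = np.empty(n_nodes)
        R[0] = fv[0]
        interior = slice(1, n_nodes - 1)
        fj = fv[interior]
        fjm = fv[:-2]
        fjp = fv[2:]
        diff = (dh_half[1:] * (fjp - fj) - dh_half[:-1] * (fj - fjm)) / hgrid**2
        adv = A * (1.0 + fj) * (fjp - fjm) / (2.0 * hgrid)
        drain = G * (1.0 + fj) / dh_n[interior] ** 2
        R[1:-1] = diff - adv - drain
        if inhale:
            # both conditions sit at the inlet; last row carries the
            # inlet-slope (contraction-loss) condition
            R[-1] = (dh_n[0] * (-3.0 * fv[0] + 4.0 * fv[1] - fv[2])
                     / (2.0 * hgrid) - C_L * (1.0 + fv[0]) ** 2)
        else:
            R[-1] = (dh_n[-1] * (3.0 * fv[-1] - 4.0 * fv[-2] + fv[-3])
                     / (2.0 * hgrid) + C_L * (1.0 + fv[-1]) ** 2)
        return R

    def jacobian(fv):
        J = lil_matrix((n_nodes, n_nodes))
        J[0, 0] = 1.0
        for j in range(1, n_nodes - 1):
            fj = fv[j]
            J[j, j - 1] = dh_half[j - 1] / hgrid**2 + A * (1.0 + fj) / (2 * hgrid)
            J[j, j] = (-(dh_half[j] + dh_half[j - 1]) / hgrid**2
                       - A * (fv[j + 1] - fv[j - 1]) / (2 * hgrid)
                       - G / dh_n[j] ** 2)
            J[j, j + 1] = dh_half[j] / hgrid**2 - A * (1.0 + fj) / (2 * hgrid)
        if inhale:
            J[-1, :] = 0.0
            J[-1, 0] = -3.0 * dh_n[0] / (2 * hgrid) - 2.0 * C_L * (1.0 + fv[0])
            J[-1, 1] = 4.0 * dh_n[0] / (2 * hgrid)
            J[-1, 2] = -dh_n[0] / (2 * hgrid)
        else:
            J[-1, -1] = (3.0 * dh_n[-1] / (2 * hgrid)
                         + 2.0 * C_L * (1.0 + fv[-1]))
            J[-1, -2] = -4.0 * dh_n[-1] / (2 * hgrid)
            J[-1, -3] = dh_n[-1] / (2 * hgrid)
        return J.tocsr()

    R = residual(f)
    norm = np.linalg.norm(R)
    # residual entries scale like 1/h^2; accept the rounding floor
    floor = 1.0e-15 * math.sqrt(n_nodes) / hgrid**2
    tol_hard = max(1.0e-10 * norm, 10.0 * floor)
    for _ in range(max_iter):
        if norm <= tol_hard:
            break
        step = spsolve(jacobian(f), -R)
        t = 1.0
        improved = False
        for _ in range(40):
            f_try = f + t * step
            R_try = residual(f_try)
            n_try = np.linalg.norm(R_try)
            if n_try < norm:
                f, R, norm = f_try, R_try, n_try
                improved = True
                break
            t *= 0.5
        if not improved:
            if norm <= 1.0e4 * floor:
                break  # stalled at the rounding floor
            raise ChannelSolverError(
                f"FD oracle: Newton line search stalled (|R| = {norm:.3e})")
    else:
        if norm > 1.0e4 * floor:
            raise ChannelSolverError(
                f"FD oracle: Newton did not converge (|R| = {norm:.3e})")

    fp = np.gradient(f, xs, edge_order=2)
    spline = CubicSpline(xs, np.vstack([f, fp]).T)

    class _Wrap:
        def __init__(self, s):
            self._s = s

        def __call__(self, x):
            return self._s(x).T

    if inhale:
        dh = lambda s: dh_geom(1.0 - np.asarray(s))
        dhp = lambda s: -dhp_geom(1.0 - np.asarray(s))
    else:
        dh, dhp = dh_geom, dhp_geom

    opts = ChannelOptions(grid_size=min(n_nodes, 1001), dense_quadrature=2001)
    x_out = np.linspace(0.0, 1.0, opts.grid_size)
    fo, fpo = _Wrap(spline)(x_out)
    sol = ChannelSolution(
        direction=bc.direction, x=x_out, f=fo, fp=fpo,
        p=np.empty(0), v_n=np.empty(0), U=U_in,
        p_in=0.0, p_cavity=0.0, Q_in=0.0, Q_g=0.0, Q_m_c=0.0, U_jet=0.0,
        diagnostics={"method": "fd-newton", "n_mesh": n_nodes,
                     "newton_residual": float(norm)},
    )
    _finalize(sol, _Wrap(spline), channel, K0, dh, dhp, U_in, fluid, fabric,
              opts)
    return sol
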