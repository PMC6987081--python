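"""Desk-scale laminar flow of a Casson fluid in straight channels and tubes.

The solver targets fully developed unidirectional flow: the velocity has a
single axial component ``u`` varying across the lumen (and in time), the
pressure gradient is uniform along the vessel, and continuity holds exactly.
This captures the physics the elongation-index mapping needs -- the
cross-lumen shear-stress distribution and its modulation over the cardiac
cycle -- while remaining cheap and verifiable against a semi-analytic
Casson-Poiseuille oracle (`casson_tube_profile`).

The momentum balance solved is

    rho * du/dt = G(t) + d/dn( mu(gamma_dot) * du/dn )        (channel)
    rho * du/dt = G(t) + (1/r) d/dr( r * mu(gamma_dot) * du/dr )   (tube)

with no-slip walls and the axial pressure gradient G(t) = -dp/dx determined at
every instant so that the mean velocity across the lumen equals the prescribed
inlet velocity (flow-rate-driven forcing).  Diffusion is discretized with a
second-order finite-volume scheme on cross-stream nodes and advanced with
backward Euler; the Casson viscosity enters through Picard iteration.

For pulsatile inlets the time-periodic state is computed directly: within each
Picard sweep the affine one-period map of the implicit scheme is propagated
(monodromy matrix) and the cyclic fixed point solved exactly, so the reported
solution is periodic to solver tolerance rather than relying on transients to
decay (the viscous time scale of a ~6 mm vessel is several pulse periods).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConfigurationError, GeometryError, SolverError
from .rheology import (
    CassonParams,
    apparent_viscosity,
    casson_shear_rate_from_stress,
    derive_params,
)

# --------------------------------------------------------------------------- #
# Problem description
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Channel:
    """Plane channel: full width 2*half_height, axial length (meters)."""

    half_height: float = 0.00315
    length: float = 0.06

    def __post_init__(self):
        if self.half_height <= 0 or self.length <= 0:
            raise ConfigurationError("channel dimensions must be positive")


@dataclass(frozen=True)
class Tube:
    """Circular tube: radius and axial length (meters)."""

    radius: float = 0.00315
    length: float = 0.06

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ConfigurationError("tube dimensions must be positive")


@dataclass(frozen=True)
class PulseProfile:
    """Sinusoidal inlet velocity: v(t) = mean + amp * sin(2*pi*t/period).

    Defaults are a physiological carotid pulse: 0.1 (diastolic) to 0.5
    (systolic) m/s at 120 beats/min (period 0.5 s).  Phase zero is at the
    ascending mean crossing.
    """

    v_min: float = 0.1
    v_max: float = 0.5
    period: float = 0.5
    shape: str = "sinusoid"

    def __post_init__(self):
        if not (self.v_max > self.v_min > 0):
            raise ConfigurationError("require v_max > v_min > 0")
        if self.period <= 0:
            raise ConfigurationError("period must be positive")
        if self.shape != "sinusoid":
            raise ConfigurationError(f"unsupported pulse shape {self.shape!r}")

    @property
    def mean(self) -> float:
        return 0.5 * (self.v_min + self.v_max)

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.v_max - self.v_min)

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        out = self.mean + self.amplitude * np.sin(2.0 * np.pi * t / self.period)
        return float(out) if out.ndim == 0 else out


@dataclass
class FlowProblem:
    """A straight-vessel flow problem.

    ``ny`` cells span the lumen (wall to wall for a channel, axis to wall for
    a tube); ``nx`` cells span the axial length (the developed solution is
    uniform along it, but the exported fields are 2-D).  ``dt`` defaults to
    0.45 * dx / v_max (advective CFL 0.45); an explicit ``dt`` violating
    CFL <= 0.5 is rejected before time stepping.
    """

    geometry: Channel | Tube = dc_field(default_factory=Channel)
    inlet: PulseProfile | float = dc_field(default_factory=PulseProfile)
    outlet_gauge_pressure: float = 13332.0  # Pa, mean arterial pressure
    rho: float = 1060.0  # kg/m^3, whole blood
    rheology: CassonParams = dc_field(default_factory=CassonParams)
    nx: int = 256
    ny: int = 64
    dt: float | None = None
    n_periods: int = 2
    n_store: int = 20

    def __post_init__(self):
        if self.rho <= 0:
            raise ConfigurationError("density must be positive")
        if self.nx < 2 or self.ny < 4:
            raise ConfigurationError("grid too coarse: need nx >= 2, ny >= 4")
        if isinstance(self.inlet, (int, float)) and self.inlet < 0:
            raise ConfigurationError("steady inlet velocity must be >= 0")
        if self.n_periods < 2:
            raise ConfigurationError("n_periods must be >= 2")
        if self.n_store < 2:
            raise ConfigurationError("n_store must be >= 2")

    @property
    def v_max(self) -> float:
        if isinstance(self.inlet, PulseProfile):
            return self.inlet.v_max
        return float(self.inlet)

    def resolved_dt(self) -> float:
        """Time step honoring the advective CFL contract (<= 0.5 at v_max)."""
        dx = self.geometry.length / self.nx
        vmax = max(self.v_max, 1e-12)
        cfl_dt = 0.5 * dx / vmax
        if self.dt is not None:
            if self.dt > cfl_dt * (1.0 + 1e-12):
                raise ConfigurationError(
                    f"dt={self.dt:g} violates advective CFL <= 0.5 "
                    f"(max allowed {cfl_dt:g} at v_max={vmax:g})"
                )
            return self.dt
        return 0.9 * cfl_dt  # CFL number 0.45


@dataclass
class FlowField:
    """Velocity/pressure/shear fields on a structured grid at one instant.

    Arrays have shape ``(len(y), len(x))``; ``y`` is the cross-stream
    coordinate (signed distance from the centerline for a channel, radius for
    a tube).  ``tau = mu * gamma_dot`` is the local shear-stress magnitude.
    """

    time: float
    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    gamma_dot: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    mask: np.ndarray
    geometry: Channel | Tube
    rheology: CassonParams
    pressure_gradient: float  # G = -dp/dx, Pa/m
    v_mean: float             # lumen-average axial velocity, m/s


@dataclass
class WSSProfile:
    """Wall shear stress along the vessel wall at one instant."""

    positions: np.ndarray  # arc length along the wall, m
    wss: np.ndarray        # Pa, per position
    time: float


@dataclass
class PulsatileResult:
    """Time series of a pulsatile solve plus periodicity diagnostics."""

    fields: list
    period_change: float        # max |u_this_period - u_previous| over the cycle, m/s
    mean_inlet_velocity: float  # time average of the imposed inlet over one period
    sweeps: int

    def __iter__(self):
        return iter(self.fields)

    def __len__(self):
        return len(self.fields)


# --------------------------------------------------------------------------- #
# Semi-analytic tube oracle
# --------------------------------------------------------------------------- #


@dataclass
class TubeProfile:
    """Radial profiles of the analytic Casson-Poiseuille solution."""

    r: np.ndarray
    u: np.ndarray
    tau: np.ndarray
    gamma_dot: np.ndarray
    v_mean: float
    flow_rate: float
    no_flow: bool = False


def casson_tube_profile(
    wall_shear: float, radius: float, rheology: CassonParams, n_points: int = 1000
) -> TubeProfile:
    """Fully developed Casson flow in a tube at imposed wall shear stress.

    Momentum balance gives tau(r) = wall_shear * r / R exactly; the shear rate
    follows by inverting the constitutive law (zero inside the plug r <
    R*tau_y/wall_shear for the uncapped law) and the velocity by integrating
    the shear rate inward from the no-slip wall.  If the rheology carries a
    viscosity cap the same capped law as the numerical solver is inverted, so
    oracle and solver share one constitutive relation.

    Returns a no-flow profile (u = 0) when wall_shear <= yield stress for the
    uncapped law.
    """
    if wall_shear < 0 or radius <= 0:
        raise ConfigurationError("wall_shear must be >= 0 and radius > 0")
    d = derive_params(rheology)
    r = np.linspace(0.0, radius, n_points)
    tau = wall_shear * r / radius
    if rheology.mu_cap is None and wall_shear <= d.yield_stress:
        z = np.zeros_like(r)
        return TubeProfile(r=r, u=z, tau=tau, gamma_dot=z.copy(),
                           v_mean=0.0, flow_rate=0.0, no_flow=True)
    gamma = casson_shear_rate_from_stress(tau, rheology)
    # u(r) = integral_r^R gamma dr'  (no-slip at the wall, monotone toward the axis)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (gamma[1:] + gamma[:-1]) * np.diff(r))))
    u = cum[-1] - cum
    flow_rate = 2.0 * np.pi * np.trapezoid(u * r, r)
    v_mean = flow_rate / (np.pi * radius**2)
    return TubeProfile(r=r, u=u, tau=tau, gamma_dot=gamma,
                       v_mean=float(v_mean), flow_rate=float(flow_rate))


# --------------------------------------------------------------------------- #
# Cross-section discretization
# --------------------------------------------------------------------------- #


class _CrossSection:
    """Second-order finite-volume diffusion operator on cross-stream nodes.

    Channel: nodes y_0..y_ny spanning [-h, h]; free nodes are the interior.
    Tube: nodes r_0..r_ny spanning [0, R]; the axis node is free (symmetry),
    the wall node is Dirichlet zero.
    """

    def __init__(self, geometry, ny: int):
        self.geometry = geometry
        self.ny = ny
        if isinstance(geometry, Channel):
            h = geometry.half_height
            self.coords = np.linspace(-h, h, ny + 1)
            self.dh = 2.0 * h / ny
            self.face_weight = np.ones(ny)          # metric factor at faces
            self.vol = np.full(ny + 1, self.dh)     # control-volume measure
            self.vol[0] = self.vol[-1] = 0.5 * self.dh
            self.free = np.arange(1, ny)
        elif isinstance(geometry, Tube):
            R = geometry.radius
            self.coords = np.linspace(0.0, R, ny + 1)
            self.dh = R / ny
            r_face = self.coords[:-1] + 0.5 * self.dh
            self.face_weight = r_face
            r_lo = np.maximum(self.coords - 0.5 * self.dh, 0.0)
            r_hi = np.minimum(self.coords + 0.5 * self.dh, R)
            self.vol = 0.5 * (r_hi**2 - r_lo**2)    # annular measure / (2*pi)
            self.free = np.arange(0, ny)
        else:
            raise ConfigurationError(f"unsupported geometry {geometry!r}")
        # Mean-velocity weights over all nodes (wall nodes carry zero velocity).
        self.mean_w = self.vol / self.vol.sum()

    def mean_velocity(self, u: np.ndarray) -> float:
        return float(self.mean_w @ u)

    def face_shear_rate(self, u: np.ndarray) -> np.ndarray:
        return np.abs(np.diff(u)) / self.dh

    def banded_matrix(self, mu_face: np.ndarray, alpha: float) -> np.ndarray:
        """(alpha*I - L) restricted to free nodes, in solve_banded (1,1) form."""
        k = self.face_weight * mu_face / self.dh**2  # face conductances
        n = len(self.free)
        ab = np.zeros((3, n))
        for idx, j in enumerate(self.free):
            west = k[j - 1] / self.vol[j] * self.dh if j > 0 else 0.0
            east = k[j] / self.vol[j] * self.dh if j < self.ny else 0.0
            ab[1, idx] = alpha + west + east
            if idx > 0 and self.free[idx - 1] == j - 1:
                ab[2, idx - 1] = -west  # sub-diagonal entry for column idx-1
            if idx < n - 1 and self.free[idx + 1] == j + 1:
                ab[0, idx + 1] = -east  # super-diagonal entry for column idx+1
        return ab

    def solve(self, ab: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        return solve_banded((1, 1), ab, rhs)

    def embed(self, u_free: np.ndarray) -> np.ndarray:
        u = np.zeros(self.ny + 1)
        u[self.free] = u_free
        return u


def _nodal_shear_rate(cs: _CrossSection, u: np.ndarray) -> np.ndarray:
    return np.abs(np.gradient(u, cs.coords, edge_order=2))


def _steady_profile(cs: _CrossSection, rheology: CassonParams, v_target: float,
                    tol: float = 1e-11, max_iter: int = 500):
    """Picard iteration for the steady developed profile at a target mean velocity.

    Returns (u_nodes, G, mu_face, iterations).
    """
    if v_target == 0.0:
        return np.zeros(cs.ny + 1), 0.0, np.full(cs.ny, rheology.mu_fallback), 0

    mu_face = np.full(cs.ny, apparent_viscosity(1.0, rheology))
    u = np.zeros(cs.ny + 1)
    G = 0.0
    for it in range(1, max_iter + 1):
        ab = cs.banded_matrix(mu_face, alpha=0.0)
        w = cs.embed(cs.solve(ab, np.ones(len(cs.free))))
        G = v_target / cs.mean_velocity(w)
        u_new = G * w
        du = np.max(np.abs(u_new - u)) / max(np.max(np.abs(u_new)), 1e-300)
        u = u_new
        mu_new = apparent_viscosity(cs.face_shear_rate(u), rheology)
        mu_face = 0.7 * mu_new + 0.3 * mu_face
        if du < tol and it > 2:
            return u, float(G), mu_face, it
    raise SolverError(
        f"steady Picard iteration did not converge in {max_iter} iterations "
        f"(last relative change {du:.3e})"
    )


def _make_field(problem: FlowProblem, cs: _CrossSection, u_nodes: np.ndarray,
                G: float, time: float) -> FlowField:
    nx = problem.nx
    L = problem.geometry.length
    x = np.linspace(0.0, L, nx + 1)
    gamma = _nodal_shear_rate(cs, u_nodes)
    mu = apparent_viscosity(gamma, problem.rheology)
    tau = mu * gamma
    ones_x = np.ones_like(x)
    p_line = problem.outlet_gauge_pressure + G * (L - x)
    shape = (len(cs.coords), len(x))
    return FlowField(
        time=time,
        x=x,
        y=cs.coords.copy(),
        u=np.outer(u_nodes, ones_x),
        v=np.zeros(shape),
        p=np.outer(np.ones(len(cs.coords)), p_line),
        gamma_dot=np.outer(gamma, ones_x),
        mu=np.outer(mu, ones_x),
        tau=np.outer(tau, ones_x),
        mask=np.ones(shape, dtype=bool),
        geometry=problem.geometry,
        rheology=problem.rheology,
        pressure_gradient=float(G),
        v_mean=cs.mean_velocity(u_nodes),
    )


# --------------------------------------------------------------------------- #
# Solvers
# --------------------------------------------------------------------------- #


def solve_steady(problem: FlowProblem) -> FlowField:
    """Steady developed flow at the problem's (scalar) inlet velocity."""
    if isinstance(problem.inlet, PulseProfile):
        raise ConfigurationError("solve_steady requires a steady (scalar) inlet")
    cs = _CrossSection(problem.geometry, problem.ny)
    u, G, _, _ = _steady_profile(cs, problem.rheology, float(problem.inlet))
    return _make_field(problem, cs, u, G, time=0.0)


def solve_pulsatile(problem: FlowProblem) -> PulsatileResult:
    """Time-periodic developed flow driven by the sinusoidal inlet pulse.

    Backward-Euler time stepping with the viscosity treated by Picard sweeps
    over whole periods; within each sweep the affine one-period map is
    propagated and its cyclic fixed point solved exactly, so the returned
    cycle is periodic to solver tolerance.  Fields are stored at ``n_store``
    equispaced phases of the converged period.
    """
    if not isinstance(problem.inlet, PulseProfile):
        raise ConfigurationError("solve_pulsatile requires a PulseProfile inlet")
    pulse = problem.inlet
    dt = problem.resolved_dt()
    n_steps = max(int(np.ceil(pulse.period / dt)), 4 * problem.n_store)
    dt = pulse.period / n_steps
    cs = _CrossSection(problem.geometry, problem.ny)
    nf = len(cs.free)
    alpha = problem.rho / dt
    m_free = cs.mean_w[cs.free]
    t_grid = dt * (np.arange(n_steps) + 1.0)       # step n advances to t_grid[n]
    v_grid = pulse.velocity(t_grid)

    # Initialize the viscosity history from the steady profile at the mean.
    _, _, mu0, _ = _steady_profile(cs, problem.rheology, pulse.mean)
    mu_cycle = np.tile(mu0, (n_steps, 1))

    u_cycle = np.zeros((n_steps, cs.ny + 1))
    G_cycle = np.zeros(n_steps)
    prev_cycle = None
    change = np.inf
    max_sweeps = max(problem.n_periods, 40)
    sweeps = 0
    for sweep in range(1, max_sweeps + 1):
        sweeps = sweep
        # Propagate the affine period map: state -> M state + c.
        P = np.eye(nf)
        c = np.zeros(nf)
        for n in range(n_steps):
            ab = cs.banded_matrix(mu_cycle[n], alpha=alpha)
            rhs = np.concatenate([alpha * P, (alpha * c)[:, None], np.ones((nf, 1))], axis=1)
            Z = cs.solve(ab, rhs)
            BP, Bc, w = Z[:, :nf], Z[:, nf], Z[:, nf + 1]
            mw = float(m_free @ w)
            P = BP - np.outer(w, m_free @ BP) / mw
            c = Bc - w * float(m_free @ Bc) / mw + v_grid[n] * w / mw
        u0 = np.linalg.solve(np.eye(nf) - P, c)

        # March one period from the periodic state, storing and updating mu.
        u_free = u0.copy()
        for n in range(n_steps):
            ab = cs.banded_matrix(mu_cycle[n], alpha=alpha)
            Z = cs.solve(ab, np.stack([alpha * u_free, np.ones(nf)], axis=1))
            Bu, w = Z[:, 0], Z[:, 1]
            G = (v_grid[n] - float(m_free @ Bu)) / float(m_free @ w)
            u_free = Bu + G * w
            u_cycle[n] = cs.embed(u_free)
            G_cycle[n] = G
            mu_new = apparent_viscosity(cs.face_shear_rate(u_cycle[n]), problem.rheology)
            mu_cycle[n] = 0.7 * mu_new + 0.3 * mu_cycle[n]

        if prev_cycle is not None:
            change = float(np.max(np.abs(u_cycle - prev_cycle)))
            if change < 1e-7 * pulse.v_max and sweep >= problem.n_periods:
                break
        prev_cycle = u_cycle.copy()
    else:
        if change > 1e-3 * pulse.v_max:
            raise SolverError(
                f"pulsatile Picard sweeps did not reach periodicity "
                f"(period-to-period change {change:.3e} m/s after {max_sweeps} sweeps)"
            )

    store_idx = np.round(np.linspace(0, n_steps, problem.n_store, endpoint=False)).astype(int)
    fields = []
    for k in store_idx:
        n = (k - 1) % n_steps  # state after step n is at time t_grid[n]
        t = float(t_grid[n] % pulse.period)
        fields.append(_make_field(problem, cs, u_cycle[n], G_cycle[n], time=t))
    fields.sort(key=lambda f: f.time)
    return PulsatileResult(
        fields=fields,
        period_change=change if np.isfinite(change) else 0.0,
        mean_inlet_velocity=float(np.mean(v_grid)),
        sweeps=sweeps,
    )


def wall_shear_stress(field: FlowField) -> WSSProfile:
    """WSS = mu_wall * |du/dn| at the wall, one-sided second-order differences.

    For a channel the two walls are averaged (they are identical by symmetry
    of the developed solution); for a tube the single wall at r = R is used.
    """
    if not np.any(field.mask):
        raise GeometryError("field has no fluid cells")
    u = field.u[:, 0]
    y = field.y
    dh = y[1] - y[0]
    if len(u) < 3:
        raise GeometryError("too few cross-stream nodes for a wall gradient")

    def one_sided(uw, u1, u2):
        return (-3.0 * uw + 4.0 * u1 - u2) / (2.0 * dh)

    grads = [abs(one_sided(u[-1], u[-2], u[-3]))]
    if isinstance(field.geometry, Channel):
        grads.append(abs(one_sided(u[0], u[1], u[2])))
    gamma_w = float(np.mean(grads))
    mu_w = apparent_viscosity(gamma_w, field.rheology)
    wss = mu_w * gamma_w
    return WSSProfile(
        positions=field.x.copy(),
        wss=np.full_like(field.x, wss),
        time=field.time,
    )
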