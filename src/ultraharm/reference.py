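"""Independent numerical oracles.

Two validation routes that do not share code with the production solvers:

* a fixed-step time-domain integrator for the periodically forced microbubble
  volume ODE, whose steady-state Fourier coefficients check the harmonic
  algebra (the transfer coefficients α_m and the quadratic harmonic transfer);
* a manufactured-solution suite for the modified Helmholtz kernel, checking
  the expected O(h²) convergence of the P1 discretization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .fem import FemOperators, assemble_operators
from .helmholtz import harmonic_problem, solve_harmonic
from .mesh import generate_disk_mesh
from .physics import DerivedParams, PrimitiveParams

__all__ = [
    "OdeTrajectory",
    "ode_periodic_steady_state",
    "manufactured_helmholtz_suite",
]


@dataclass
class OdeTrajectory:
    """Time-domain trajectory of the volume oscillator with steady-state window."""

    times: np.ndarray
    v: np.ndarray
    v_t: np.ndarray
    periods_integrated: int
    steady_state_window: int  # number of final periods analyzed
    fourier: dict[int, complex]  # m -> extracted coefficient of exp(i m ω t)
    periodicity_defect: float


def _fourier_coefficients(
    t: np.ndarray, y: np.ndarray, omega: float, n_periods: int, m_max: int
) -> dict[int, complex]:
    """Extract coefficients u_m of Re{Σ u_m e^{imωt}} over an integer window.

    Uses the FFT over uniform samples covering exactly ``n_periods`` periods;
    harmonic m sits in bin m * n_periods.
    """
    n = y.size
    spec = np.fft.fft(y) / n
    out: dict[int, complex] = {0: complex(spec[0].real)}
    for m in range(1, m_max + 1):
        # Re{u e^{imωt}} contributes (u/2) e^{imωt}; with samples starting at
        # t[0], the forward FFT (kernel e^{-2πikn/N}) puts it in bin
        # m·n_periods with an extra phase e^{imωt[0]}.
        out[m] = 2.0 * spec[(m * n_periods) % n] * np.exp(-1j * m * omega * t[0])
    return out


def ode_periodic_steady_state(
    der: DerivedParams,
    omega: float,
    forcing: Sequence[tuple[int, complex]],
    *,
    nonlinear: bool = False,
    pressure_forcing: bool = False,
    steps_per_period: int = 1024,
    n_periods: int | None = None,
    analysis_periods: int = 4,
    m_max: int = 8,
) -> OdeTrajectory:
    """Integrate the volume ODE to its periodic steady state and Fourier-analyze it.

    The oscillator is v'' + δω0 v' + ω0² v = f(t) with, in the nonlinear case,
    the right-hand side ζ v² + ξ(2 v v'' + v'²) − μ p resolved through the
    algebraic rewriting

        v'' = [−δω0 v' − ω0² v + ζ v² + ξ v'² − μ p] / (1 − 2 ξ v),

    valid while 2|ξ||v| < 1 (the small-oscillation regime).  ``forcing`` lists
    complex amplitudes (m, F_m) of f(t) = Re{Σ F_m e^{imωt}}; with
    ``pressure_forcing`` they describe the pressure p instead and the forcing
    enters as −μ p.  Integration uses classical RK4 with a fixed step,
    transients are discarded and the final ``analysis_periods`` periods are
    Fourier-analyzed.
    """
    if der.delta * der.omega0 <= 0:
        raise ValueError("need positive damping δω0 for transient decay")
    T = 2.0 * np.pi / omega
    if n_periods is None:
        # transients decay at rate ~min root of s² + δω0 s + ω0²; the slow
        # root for strong damping is ≈ ω0/δ
        slow_rate = min(der.delta * der.omega0 / 2.0, der.omega0 / max(der.delta, 1e-12))
        n_periods = max(50, int(np.ceil(10.0 / (slow_rate * T))))
    dt = T / steps_per_period

    forcing = list(forcing)

    def f_ext(t: float) -> float:
        tot = 0.0
        for m, F in forcing:
            tot += (F * np.exp(1j * m * omega * t)).real
        return tot

    mu = der.mu

    def accel(t: float, v: float, vt: float) -> float:
        if not nonlinear:
            ext = -mu * f_ext(t) if pressure_forcing else f_ext(t)
            return ext - der.delta * der.omega0 * vt - der.omega0**2 * v
        denom = 1.0 - 2.0 * der.xi * v
        if denom <= 0.0 or 2.0 * abs(der.xi) * abs(v) >= 1.0:
            raise RuntimeError(
                f"amplitude left the small-solution regime: |v| = {abs(v):.3e}, "
                f"2|ξ||v| = {2 * abs(der.xi) * abs(v):.3e}"
            )
        p = f_ext(t)
        num = (
            -der.delta * der.omega0 * vt
            - der.omega0**2 * v
            + der.zeta * v**2
            + der.xi * vt**2
            - mu * p
        )
        return num / denom

    # RK4 from zero data
    n_store = analysis_periods * steps_per_period
    total_steps = n_periods * steps_per_period
    v, vt = 0.0, 0.0
    ts = np.empty(n_store)
    vs = np.empty(n_store)
    vts = np.empty(n_store)
    store_from = total_steps - n_store
    # also track one period earlier for the periodicity defect
    v_prev_period = np.empty(steps_per_period)
    for i in range(total_steps):
        t = i * dt
        if i >= store_from:
            j = i - store_from
            ts[j], vs[j], vts[j] = t, v, vt
        if store_from - steps_per_period <= i < store_from:
            v_prev_period[i - (store_from - steps_per_period)] = v
        k1v = vt
        k1a = accel(t, v, vt)
        k2v = vt + 0.5 * dt * k1a
        k2a = accel(t + 0.5 * dt, v + 0.5 * dt * k1v, vt + 0.5 * dt * k1a)
        k3v = vt + 0.5 * dt * k2a
        k3a = accel(t + 0.5 * dt, v + 0.5 * dt * k2v, vt + 0.5 * dt * k2a)
        k4v = vt + dt * k3a
        k4a = accel(t + dt, v + dt * k3v, vt + dt * k3a)
        v += (dt / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        vt += (dt / 6.0) * (k1a + 2 * k2a + 2 * k3a + k4a)

    scale = float(np.max(np.abs(vs))) or 1.0
    defect = float(np.max(np.abs(vs[:steps_per_period] - v_prev_period))) / scale
    fourier = _fourier_coefficients(ts, vs, omega, analysis_periods, m_max)
    return OdeTrajectory(
        times=ts,
        v=vs,
        v_t=vts,
        periods_integrated=n_periods,
        steady_state_window=analysis_periods,
        fourier=fourier,
        periodicity_defect=defect,
    )


def manufactured_helmholtz_suite(
    h_values: Sequence[float],
    m: int,
    omega: float,
    prim: PrimitiveParams,
    der: DerivedParams,
    solution: Callable[[np.ndarray], np.ndarray] | None = None,
    gradient: Callable[[np.ndarray], np.ndarray] | None = None,
    laplacian: Callable[[np.ndarray], np.ndarray] | None = None,
    radius: float = 0.2,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Convergence table for the Helmholtz kernel on a family of disk meshes.

    A smooth manufactured field u is substituted into the strong form to get
    the interior load f = −D Δu + R u and the inhomogeneous Robin datum
    g = ρ u + ∇u·n (evaluated with the boundary polygon's own edge geometry,
    so only the O(h²) domain approximation remains).  Returns columns
    (h, error, order) where error is the discrete L²(Ω) norm of u_h − I_h u.
    """
    if solution is None:
        q = 20.0  # spatial frequency of the default manufactured field (1/m)

        def solution(x):  # noqa: F811
            return np.cos(q * x[..., 0]) * np.cos(q * x[..., 1]) + 0.3j * np.sin(
                q * x[..., 0]
            ) * np.cos(q * x[..., 1])

        def gradient(x):  # noqa: F811
            gx = -q * np.sin(q * x[..., 0]) * np.cos(q * x[..., 1]) + 0.3j * q * np.cos(
                q * x[..., 0]
            ) * np.cos(q * x[..., 1])
            gy = -q * np.cos(q * x[..., 0]) * np.sin(q * x[..., 1]) - 0.3j * q * np.sin(
                q * x[..., 0]
            ) * np.sin(q * x[..., 1])
            return np.stack([gx, gy], axis=-1)

        def laplacian(x):  # noqa: F811
            return -2.0 * q**2 * solution(x)

    errors: list[float] = []
    for h in h_values:
        mesh = generate_disk_mesh(radius, h, seed=seed)
        ops = assemble_operators(mesh)
        dummy = np.zeros(mesh.n_nodes, dtype=complex)
        prob = harmonic_problem(m, omega, prim, der, rhs=dummy)
        # interior load at P1 accuracy: f interpolated nodally
        f_nodal = -prob.diffusion * laplacian(mesh.nodes) + prob.reaction * solution(mesh.nodes)
        rhs = ops.M @ f_nodal.astype(complex)
        # Robin datum integrated edge by edge with 2-point Gauss and the
        # polygon edge normal
        be = mesh.boundary_edges
        p0 = mesh.nodes[be[:, 0]]
        p1 = mesh.nodes[be[:, 1]]
        tang = p1 - p0
        lengths = np.hypot(tang[:, 0], tang[:, 1])
        normals = np.column_stack([tang[:, 1], -tang[:, 0]]) / lengths[:, None]
        gauss = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
        bload = np.zeros(mesh.n_nodes, dtype=complex)
        for s in gauss:
            pts = (1 - s) * p0 + s * p1
            g = prob.robin * solution(pts) + np.einsum(
                "ed,ed->e", gradient(pts), normals
            )
            w = 0.5 * lengths * g
            np.add.at(bload, be[:, 0], w * (1 - s))
            np.add.at(bload, be[:, 1], w * s)
        prob.rhs = rhs + prob.diffusion * bload
        u_h = solve_harmonic(prob, ops)
        err = u_h - solution(mesh.nodes)
        errors.append(ops.l2_norm(err))

    orders = [float("nan")]
    for i in range(1, len(h_values)):
        dh = np.log(h_values[i - 1] / h_values[i])
        orders.append(float(np.log(errors[i - 1] / errors[i]) / dh) if dh else float("nan"))
    if any(e2 >= e1 for e1, e2 in zip(errors, errors[1:])):
        import warnings

        warnings.warn("non-monotone manufactured-solution error sequence", stacklevel=2)
    return {"h": list(h_values), "error": errors, "order": orders}
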