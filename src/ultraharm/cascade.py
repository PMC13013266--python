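"""Multiharmonic cascade algorithms for the Westervelt–microbubble system.

Five solution algorithms are provided, all operating on the truncated Fourier
representation p(x,t) ≈ Σ_m exp(i m ω t) p_m(x) (with the real part taken in
the real-field variants):

* ``complex-linearized`` — successive levels N' = 1..N; at each level the
  quadratic couplings are evaluated at the previous level, giving a triangular
  sequence of modified Helmholtz solves (sum-frequency convolutions only).
* ``complex-coupled`` — one sweep m = 1..N where the right-hand side of
  harmonic m references only lower harmonics of the same solution; solved by
  direct substitution.
* ``real-linearized`` — the real-field cascade carrying both sum-frequency and
  difference-frequency (conjugate) convolutions, with the zeroth volume
  harmonic updated algebraically at each level.
* ``real-linearized-zero0`` — same with v_0 pinned to zero.
* ``two-harmonic`` — the N = 2 scheme with bubble-modified effective sound
  speeds c̃_m and added nonlinearity β̃_a.

In every variant the m-th volume harmonic is eliminated algebraically,
v_m = α_m (−μ p_m + f_v), so that only Helmholtz problems in the pressure
remain; matrices depend on m but not on the level, so each harmonic's LU
factorization is computed once and reused across levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fem import FemOperators, SourceSpec, assemble_load
from .helmholtz import HarmonicFactor, harmonic_problem
from .mesh import Mesh
from .physics import (
    DerivedParams,
    PrimitiveParams,
    derive_params,
    effective_two_harmonic,
    harmonic_coefficients,
)

__all__ = [
    "HarmonicField",
    "SolverConfig",
    "run_cascade",
    "run_complex_linearized",
    "run_complex_coupled",
    "run_real_linearized",
    "run_two_harmonic",
    "recover_volume_harmonics",
    "residual_coupled_real",
]

VARIANTS = (
    "complex-linearized",
    "complex-coupled",
    "real-linearized",
    "real-linearized-zero0",
    "two-harmonic",
)


@dataclass
class HarmonicField:
    """Multiharmonic state: nodal coefficient vectors p_m, v_m for m = 0..N."""

    N: int
    omega: float
    p: list[np.ndarray]
    v: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.p) != self.N + 1 or len(self.v) != self.N + 1:
            raise ValueError("need exactly N + 1 harmonic coefficient vectors")

    @property
    def n_nodes(self) -> int:
        return self.p[0].shape[0]

    @staticmethod
    def zeros(N: int, omega: float, n_nodes: int) -> "HarmonicField":
        return HarmonicField(
            N=N,
            omega=omega,
            p=[np.zeros(n_nodes, dtype=complex) for _ in range(N + 1)],
            v=[np.zeros(n_nodes, dtype=complex) for _ in range(N + 1)],
        )


@dataclass
class SolverConfig:
    """Cascade configuration.

    ``with_bubbles=False`` forces n0 = 0 regardless of the parameter set.  The
    ``two-harmonic`` variant always uses N = 2.
    """

    variant: str = "complex-linearized"
    N: int = 10
    omega: float | None = None  # None: drive at the bubble resonance ω0
    with_bubbles: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.variant == "two-harmonic":
            self.N = 2
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def period(self) -> float:
        if self.omega is None:
            raise ValueError("omega not resolved yet")
        return 2.0 * np.pi / self.omega


@dataclass
class _Workspace:
    prim: PrimitiveParams
    der: DerivedParams
    omega: float
    factors: list  # index m (0 unused)
    loads: list  # assembled source loads per m
    ops: FemOperators
    n_nodes: int
    audit: list | None = dc_field(default=None)


def _setup(
    cfg: SolverConfig,
    mesh: Mesh,
    ops: FemOperators,
    src: SourceSpec,
    prim: PrimitiveParams,
    der: DerivedParams | None = None,
) -> _Workspace:
    if not cfg.with_bubbles:
        prim = prim.without_bubbles()
    if der is None:
        der = derive_params(prim)
    omega = cfg.omega if cfg.omega is not None else der.omega0
    factors: list = [None]
    loads: list = [None]
    for m in range(1, cfg.N + 1):
        q = assemble_load(mesh, ops, src, m)
        prob = harmonic_problem(m, omega, prim, der, rhs=np.zeros(mesh.n_nodes, dtype=complex))
        factors.append(HarmonicFactor(prob, ops))
        loads.append(q)
    return _Workspace(
        prim=prim, der=der, omega=omega, factors=factors, loads=loads, ops=ops,
        n_nodes=mesh.n_nodes,
    )


def _rhs(ws: _Workspace, m: int, s_p: np.ndarray | float, f_v: np.ndarray | float) -> np.ndarray:
    """Canonical right-hand side −k² q_m + M(k² s_p − m²ω²ρ0 n0 α_m f_v).

    ``s_p`` is the pressure-convolution term exactly as it appears on the
    right-hand side of the m-th pressure equation (sign included); ``f_v`` the
    volume-convolution term of the algebraic equation.
    """
    coeffs = harmonic_coefficients(m, ws.omega, ws.prim, ws.der)
    k2 = coeffs.k**2
    b = -k2 * ws.loads[m]
    interior = np.zeros(ws.n_nodes, dtype=complex)
    if np.any(s_p != 0):
        interior = interior + k2 * s_p
    if np.any(f_v != 0):
        interior = interior - (m * ws.omega) ** 2 * ws.prim.rho0 * ws.prim.n0 * coeffs.alpha_m * f_v
    if np.any(interior != 0):
        b = b + ws.ops.M @ interior
    return b


def recover_volume_harmonics(
    p_m: np.ndarray,
    f_v: np.ndarray | float,
    coeffs,
    der: DerivedParams,
) -> np.ndarray:
    """Volume harmonic from the eliminated algebraic equation:
    v_m = −α_m μ p_m + α_m f_v (m ≥ 1)."""
    return coeffs.alpha_m * (-der.mu * p_m + f_v)


def _record(ws: _Workspace, level: int, m: int, reads: list[tuple[int, int]]) -> None:
    if ws.audit is not None:
        ws.audit.append({"level": level, "m": m, "reads": sorted(set(reads))})


def run_complex_linearized(
    cfg: SolverConfig,
    mesh: Mesh,
    ops: FemOperators,
    src: SourceSpec,
    prim: PrimitiveParams,
    audit: list | None = None,
    der: DerivedParams | None = None,
) -> list[HarmonicField]:
    """Linearized complex cascade; returns the fields of all levels 1..N."""
    ws = _setup(cfg, mesh, ops, src, prim, der)
    ws.audit = audit
    zeta, xi, eta = ws.der.zeta, ws.der.xi, ws.der.eta
    w2 = ws.omega**2
    prev = HarmonicField.zeros(cfg.N, ws.omega, ws.n_nodes)
    levels: list[HarmonicField] = []
    for level in range(1, cfg.N + 1):
        cur = HarmonicField.zeros(cfg.N, ws.omega, ws.n_nodes)
        for m in range(1, level + 1):
            reads = []
            f_p = np.zeros(ws.n_nodes, dtype=complex)
            f_v = np.zeros(ws.n_nodes, dtype=complex)
            for l in range(1, m):
                f_p += prev.p[l] * prev.p[m - l]
                f_v += (zeta - xi * w2 * (m - l) * (2 * m - l)) * prev.v[l] * prev.v[m - l]
                reads += [(level - 1, l), (level - 1, m - l)]
            coeffs = harmonic_coefficients(m, ws.omega, ws.prim, ws.der)
            b = _rhs(ws, m, -eta * f_p, f_v)
            cur.p[m] = ws.factors[m].solve(b)
            cur.v[m] = recover_volume_harmonics(cur.p[m], f_v, coeffs, ws.der)
            _record(ws, level, m, reads)
        levels.append(cur)
        prev = cur
    return levels


def run_complex_coupled(
    cfg: SolverConfig,
    mesh: Mesh,
    ops: FemOperators,
    src: SourceSpec,
    prim: PrimitiveParams,
    audit: list | None = None,
    der: DerivedParams | None = None,
) -> HarmonicField:
    """Coupled complex system solved by substitution in increasing m."""
    ws = _setup(cfg, mesh, ops, src, prim, der)
    ws.audit = audit
    zeta, xi, eta = ws.der.zeta, ws.der.xi, ws.der.eta
    w2 = ws.omega**2
    cur = HarmonicField.zeros(cfg.N, ws.omega, ws.n_nodes)
    for m in range(1, cfg.N + 1):
        reads = []
        f_p = np.zeros(ws.n_nodes, dtype=complex)
        f_v = np.zeros(ws.n_nodes, dtype=complex)
        for l in range(1, m):
            f_p += cur.p[l] * cur.p[m - l]
            f_v += (zeta - xi * w2 * (m - l) * (2 * m - l)) * cur.v[l] * cur.v[m - l]
            reads += [(0, l), (0, m - l)]
        coeffs = harmonic_coefficients(m, ws.omega, ws.prim, ws.der)
        b = _rhs(ws, m, -eta * f_p, f_v)
        cur.p[m] = ws.factors[m].solve(b)
        cur.v[m] = recover_volume_harmonics(cur.p[m], f_v, coeffs, ws.der)
        _record(ws, 0, m, reads)
    return cur


def _real_s_p(prev: HarmonicField, m: int, level: int, eta: float, reads: list) -> np.ndarray:
    """Pressure convolution term of the real-field cascade at level ``level``.

    Combines the sum-frequency convolution Σ p_l p_{m−l} (with the same weight
    η as in the complex-field cascade, so that dropping the conjugate sums
    recovers the complex variant exactly) with the difference-frequency
    (conjugate) convolution over the stride-2 range
    k = m+2, m+4, ..., 2(level−1) − m.
    """
    n = prev.n_nodes
    s = np.zeros(n, dtype=complex)
    if m == 1:
        for k in range(3, 2 * level - 3 + 1, 2):
            s -= eta * np.conj(prev.p[(k - 1) // 2]) * prev.p[(k + 1) // 2]
            reads += [(level - 1, (k - 1) // 2), (level - 1, (k + 1) // 2)]
        return s
    conv = np.zeros(n, dtype=complex)
    for l in range(1, m):
        conv += prev.p[l] * prev.p[m - l]
        reads += [(level - 1, l), (level - 1, m - l)]
    for k in range(m + 2, 2 * (level - 1) - m + 1, 2):
        conv -= 2.0 * np.conj(prev.p[(k - m) // 2]) * prev.p[(k + m) // 2]
        reads += [(level - 1, (k - m) // 2), (level - 1, (k + m) // 2)]
    return -eta * conv


def _real_f_v(
    prev: HarmonicField, m: int, level: int, zeta: float, xi: float, w2: float, reads: list
) -> np.ndarray:
    """Volume convolution term of the real-field cascade (sum + conjugate parts)."""
    n = prev.n_nodes
    f = np.zeros(n, dtype=complex)
    if m == 1:
        f += (zeta - xi * w2) * prev.v[0] * prev.v[1]
        for k in range(1, 2 * level - 3 + 1, 2):
            f += (zeta - xi * w2 * (k**2 + 3) / 4.0) * np.conj(prev.v[(k - 1) // 2]) * prev.v[
                (k + 1) // 2
            ]
            reads += [(level - 1, (k - 1) // 2), (level - 1, (k + 1) // 2)]
        return f
    for l in range(0, m + 1):
        f += (zeta - xi * w2 * (m - l) * (2 * m - l)) * prev.v[l] * prev.v[m - l]
        reads += [(level - 1, l), (level - 1, m - l)]
    for k in range(m, 2 * (level - 1) - m + 1, 2):
        f += (zeta - xi * w2 * (k**2 + 3 * m**2) / 4.0) * np.conj(prev.v[(k - m) // 2]) * prev.v[
            (k + m) // 2
        ]
        reads += [(level - 1, (k - m) // 2), (level - 1, (k + m) // 2)]
    return f


def run_real_linearized(
    cfg: SolverConfig,
    mesh: Mesh,
    ops: FemOperators,
    src: SourceSpec,
    prim: PrimitiveParams,
    audit: list | None = None,
    der: DerivedParams | None = None,
) -> list[HarmonicField]:
    """Linearized real-field cascade (variants with free or pinned v_0)."""
    pin_v0 = cfg.variant == "real-linearized-zero0"
    ws = _setup(cfg, mesh, ops, src, prim, der)
    ws.audit = audit
    zeta, xi = ws.der.zeta, ws.der.xi
    w2 = ws.omega**2
    w0sq = ws.der.omega0**2
    prev = HarmonicField.zeros(cfg.N, ws.omega, ws.n_nodes)
    levels: list[HarmonicField] = []
    for level in range(1, cfg.N + 1):
        cur = HarmonicField.zeros(cfg.N, ws.omega, ws.n_nodes)
        if not pin_v0:
            reads = [(level - 1, j) for j in range(0, level)]
            v0 = (zeta / 2.0) * prev.v[0] ** 2
            for j in range(0, level):
                v0 = v0 + (zeta / 2.0 - (xi * w2 / 2.0) * j**2) * np.abs(prev.v[j]) ** 2
            cur.v[0] = v0 / w0sq
            _record(ws, level, 0, reads)
        for m in range(1, level + 1):
            reads: list[tuple[int, int]] = []
            s_p = _real_s_p(prev, m, level, ws.der.eta, reads)
            f_v = _real_f_v(prev, m, level, zeta, xi, w2, reads)
            coeffs = harmonic_coefficients(m, ws.omega, ws.prim, ws.der)
            b = _rhs(ws, m, s_p, f_v)
            cur.p[m] = ws.factors[m].solve(b)
            cur.v[m] = recover_volume_harmonics(cur.p[m], f_v, coeffs, ws.der)
            _record(ws, level, m, reads)
        levels.append(cur)
        prev = cur
    return levels


def run_two_harmonic(
    cfg: SolverConfig,
    mesh: Mesh,
    ops: FemOperators,
    src: SourceSpec,
    prim: PrimitiveParams,
) -> HarmonicField:
    """Two-harmonic scheme with effective sound speeds and nonlinearity.

    Solves the pressure pair

        (ω²/c̃₁²) p₁ + (1 + i bω/c²) Δp₁ = (ω²/c²) h₁,
        (4ω²/c̃₂²) p₂ + (1 + i 2bω/c²) Δp₂ = (4ω²/c²) h₂
            + (4ω²/(ρ0 c⁴)) (β_a + β̃_a) p₁²,

    then recovers v₁ = −α₁ μ p₁ and v₂ = α₂[−μ p₂ + (ζ − 3ξω²) α₁² μ² p₁²].
    """
    if cfg.variant != "two-harmonic":
        raise ValueError("cfg.variant must be 'two-harmonic'")
    ws = _setup(cfg, mesh, ops, src, prim)
    prim_eff, der = ws.prim, ws.der
    omega = ws.omega
    c1t, c2t, beta_t = effective_two_harmonic(prim_eff, der, omega)
    cur = HarmonicField.zeros(2, omega, ws.n_nodes)
    coeffs1 = harmonic_coefficients(1, omega, prim_eff, der)
    coeffs2 = harmonic_coefficients(2, omega, prim_eff, der)

    prob1 = harmonic_problem(
        1, omega, prim_eff, der,
        rhs=-(coeffs1.k**2) * ws.loads[1],
        reaction=-(omega**2) / c1t**2,
    )
    f1 = HarmonicFactor(prob1, ops)
    cur.p[1] = f1.solve(prob1.rhs)
    cur.v[1] = -coeffs1.alpha_m * der.mu * cur.p[1]

    quad = (
        (4.0 * omega**2 / (prim_eff.rho0 * prim_eff.c**4))
        * (prim_eff.beta_a + beta_t)
        * cur.p[1] ** 2
    )
    rhs2 = -(coeffs2.k**2) * ws.loads[2] - ops.M @ quad
    prob2 = harmonic_problem(
        2, omega, prim_eff, der, rhs=rhs2, reaction=-(4.0 * omega**2) / c2t**2
    )
    f2 = HarmonicFactor(prob2, ops)
    cur.p[2] = f2.solve(prob2.rhs)
    f_v2 = (der.zeta - 3.0 * der.xi * omega**2) * coeffs1.alpha_m**2 * der.mu**2 * cur.p[1] ** 2
    cur.v[2] = recover_volume_harmonics(cur.p[2], f_v2, coeffs2, der)
    return cur


def run_cascade(
    cfg: SolverConfig,
    mesh: Mesh,
    ops: FemOperators,
    src: SourceSpec,
    prim: PrimitiveParams,
):
    """Dispatch on ``cfg.variant``.

    Returns a list of per-level fields for the linearized variants and a single
    field for ``complex-coupled`` and ``two-harmonic``.
    """
    if cfg.variant == "complex-linearized":
        return run_complex_linearized(cfg, mesh, ops, src, prim)
    if cfg.variant == "complex-coupled":
        return run_complex_coupled(cfg, mesh, ops, src, prim)
    if cfg.variant in ("real-linearized", "real-linearized-zero0"):
        return run_real_linearized(cfg, mesh, ops, src, prim)
    if cfg.variant == "two-harmonic":
        return run_two_harmonic(cfg, mesh, ops, src, prim)
    raise ValueError(f"unknown variant {cfg.variant!r}")


def residual_coupled_real(
    field: HarmonicField,
    mesh: Mesh,
    ops: FemOperators,
    src: SourceSpec,
    prim: PrimitiveParams,
    with_bubbles: bool = True,
    der: DerivedParams | None = None,
) -> dict[str, list[float]]:
    """Residual norms of the full (non-linearized) real coupled system.

    Evaluates the coupled same-level system at the supplied field and returns
    discrete L²(Ω) norms of the residual per harmonic, separately for the PDE
    rows (weak form, lumped-mass Riesz representative) and the algebraic ODE
    rows.  The PDE rows are additionally reported normalized by the norm of
    the m = 1 source load.
    """
    if not with_bubbles:
        prim = prim.without_bubbles()
    if der is None:
        der = derive_params(prim)
    omega = field.omega
    N = field.N
    zeta, xi, eta = der.zeta, der.xi, der.eta
    w2 = omega**2
    w0sq = der.omega0**2
    lumped = np.asarray(ops.M.sum(axis=1)).ravel()

    def _norm_weak(R: np.ndarray) -> float:
        rho = R / lumped
        return float(np.sqrt(np.real(np.vdot(rho, ops.M @ rho))))

    def _norm_nodal(R: np.ndarray) -> float:
        return float(np.sqrt(np.real(np.vdot(R, ops.M @ R))))

    pde: list[float] = []
    ode: list[float] = []
    # m = 0 rows: p_0 = 0 and the algebraic v_0 equation
    pde.append(_norm_nodal(field.p[0]))
    r0 = w0sq * field.v[0] - zeta * field.v[0] ** 2
    for j in range(1, N + 1):
        r0 = r0 - (zeta / 2.0 - (xi / 2.0) * w2 * j**2) * np.abs(field.v[j]) ** 2
    ode.append(_norm_nodal(r0))

    for m in range(1, N + 1):
        coeffs = harmonic_coefficients(m, omega, prim, der)
        C = (prim.c**2 + 1j * m * prim.b * omega) / (m**2 * w2)
        robin = 1j * omega * m * prim.beta_bc + prim.gamma_bc
        q_m = assemble_load(mesh, ops, src, m)
        # pressure convolution, same level, as printed in the coupled system
        if m == 1:
            conv_p = np.zeros(field.n_nodes, dtype=complex)
            for k in range(3, 2 * N - 1 + 1, 2):
                conv_p += eta * np.conj(field.p[(k - 1) // 2]) * field.p[(k + 1) // 2]
        else:
            conv_p = np.zeros(field.n_nodes, dtype=complex)
            for l in range(1, m):
                conv_p += field.p[l] * field.p[m - l]
            for k in range(m + 2, 2 * N - m + 1, 2):
                conv_p -= 2.0 * np.conj(field.p[(k - m) // 2]) * field.p[(k + m) // 2]
            conv_p *= eta
        # weak form of −C Δp: +C (K p + robin M_bnd p) after integration by
        # parts with the Robin condition
        R = (
            -(ops.M @ field.p[m])
            + C * (ops.K @ field.p[m] + robin * (ops.M_bnd @ field.p[m]))
            + prim.c**2 * prim.rho0 * prim.n0 * (ops.M @ field.v[m])
            + q_m
            + ops.M @ conv_p
        )
        pde.append(_norm_weak(R))

        if m == 1:
            f_v = (zeta - xi * w2) * field.v[0] * field.v[1]
            for k in range(1, 2 * N - 1 + 1, 2):
                f_v += (zeta - xi * w2 * (k**2 + 3) / 4.0) * np.conj(
                    field.v[(k - 1) // 2]
                ) * field.v[(k + 1) // 2]
        else:
            f_v = np.zeros(field.n_nodes, dtype=complex)
            for l in range(0, m + 1):
                f_v += (zeta - xi * w2 * (m - l) * (2 * m - l)) * field.v[
                    l
                ] * field.v[m - l]
            for k in range(m, 2 * N - m + 1, 2):
                f_v += (zeta - xi * w2 * (k**2 + 3 * m**2) / 4.0) * np.conj(
                    field.v[(k - m) // 2]
                ) * field.v[(k + m) // 2]
        r_ode = (1.0 / coeffs.alpha_m) * field.v[m] + der.mu * field.p[m] - f_v
        ode.append(_norm_nodal(r_ode))
    return {"pde": pde, "ode": ode}
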