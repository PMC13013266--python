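"""Physical parameters of the bubbly-liquid acoustic model and derived coefficients.

The time-domain model couples a strongly damped Westervelt equation for the
acoustic pressure fluctuation ``p`` with a volume-based Rayleigh–Plesset-type
oscillator for the microbubble volume perturbation ``v``::

    p_tt - c^2 Δp - b Δp_t = η (p^2)_tt + c^2 ρ0 n0 v_tt + h
    v_tt + δ ω0 v_t + ω0^2 v = ζ v^2 + ξ (2 v v_tt + v_t^2) - μ p

All quantities are SI.  Frequencies are angular (rad/s) throughout.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass, fields
from math import pi, sqrt

__all__ = [
    "PrimitiveParams",
    "DerivedParams",
    "HarmonicCoefficients",
    "TABLE_PRESET",
    "derive_params",
    "harmonic_coefficients",
    "effective_two_harmonic",
]


@dataclass(frozen=True)
class PrimitiveParams:
    """Primitive physical constants of the mixture, the bubbles and the boundary.

    Attributes
    ----------
    c : float
        Speed of sound in the mixture (m/s).
    b : float
        Diffusivity of sound (m^2/s); coefficient of the strong damping -b Δp_t.
    rho0 : float
        Equilibrium mass density of the mixture (kg/m^3).
    beta_a : float
        Dimensionless nonlinearity parameter of the medium.
    R0 : float
        Equilibrium bubble radius (m).
    n0 : float
        Bubble number density (1/m^3); ``n0 = 0`` encodes a bubble-free medium.
    P0 : float
        Ambient (vapor) pressure in the mixture (Pa).
    kappa : float
        Adiabatic exponent of the bubble gas.
    nu : float
        Kinematic viscosity (m^2/s).
    beta_bc : float
        Absorbing-boundary coefficient β in β p_t + γ p + ∇p·n = 0 (s/m).
    gamma_bc : float
        Absorbing-boundary coefficient γ (1/m).
    """

    c: float = 1500.0
    b: float = 1.0e-3
    rho0: float = 1000.0
    beta_a: float = 3.5
    R0: float = 2.0e-6
    n0: float = 1.0e12
    P0: float = 100.0
    kappa: float = 1.4
    nu: float = 8.9e-6
    beta_bc: float = 1.0 / 1500.0
    gamma_bc: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "n0":
                if value < 0:
                    raise ValueError(f"parameter 'n0' must be >= 0, got {value!r}")
            elif not value > 0:
                raise ValueError(
                    f"parameter {f.name!r} must be strictly positive, got {value!r}"
                )

    def without_bubbles(self) -> "PrimitiveParams":
        """Return a copy with the bubble density switched off (``n0 = 0``)."""
        return replace_n0(self, 0.0)


def replace_n0(prim: PrimitiveParams, n0: float) -> PrimitiveParams:
    from dataclasses import replace

    return replace(prim, n0=n0)


@dataclass(frozen=True)
class DerivedParams:
    """Coefficients derived from the primitive constants.

    ``omega0 = sqrt(3 κ P0 / (ρ0 R0^2))`` is the natural (angular) frequency of
    the bubble oscillator, ``delta = 4 ν / (ω0 R0^2)`` its viscous damping,
    ``v0 = (4π/3) R0^3`` the equilibrium bubble volume, ``mu = 4π R0 / ρ0`` the
    pressure-coupling coefficient, ``zeta = (κ+1) ω0^2 / (2 v0)`` the quadratic
    stiffness, ``xi = 1/(6 v0)`` the inertial nonlinearity and
    ``eta = β_a / (ρ0 c^2)`` the Westervelt nonlinearity coefficient.
    """

    omega0: float
    delta: float
    v0: float
    mu: float
    zeta: float
    xi: float
    eta: float


def derive_params(prim: PrimitiveParams) -> DerivedParams:
    """Compute all derived coefficients from the primitive parameters."""
    omega0 = sqrt(3.0 * prim.kappa * prim.P0 / (prim.rho0 * prim.R0**2))
    delta = 4.0 * prim.nu / (omega0 * prim.R0**2)
    v0 = (4.0 * pi / 3.0) * prim.R0**3
    mu = 4.0 * pi * prim.R0 / prim.rho0
    zeta = (prim.kappa + 1.0) * omega0**2 / (2.0 * v0)
    xi = 1.0 / (6.0 * v0)
    eta = prim.beta_a / (prim.rho0 * prim.c**2)
    return DerivedParams(omega0=omega0, delta=delta, v0=v0, mu=mu, zeta=zeta, xi=xi, eta=eta)


@dataclass(frozen=True)
class HarmonicCoefficients:
    """Per-harmonic coefficients of the frequency-domain pressure equation.

    For harmonic index ``m`` at driving frequency ``omega``:

    * ``alpha_m = 1 / (-m^2 ω^2 + i m δ ω0 ω + ω0^2)`` — complex transfer
      coefficient of the damped linear volume oscillator at frequency m ω (s^2);
    * ``k = m ω / c`` — acoustic wavenumber (1/m);
    * ``frak_a``/``frak_b`` — real wavenumber shift and bubble-induced
      dissipation (1/m^2), both proportional to ``n0``:

      frak_a = μ ρ0 n0 m^2ω^2 (ω0^2 - m^2ω^2) / [(ω0^2 - m^2ω^2)^2 + (m δ ω0 ω)^2]
      frak_b = μ ρ0 n0 m^3ω^3 δ ω0       / [(ω0^2 - m^2ω^2)^2 + (m δ ω0 ω)^2]

    The modified Helmholtz reaction coefficient is ``-(k^2 + frak_a) + i frak_b``,
    equal to ``-(k^2 + m^2 ω^2 ρ0 n0 μ alpha_m)``.
    """

    m: int
    omega: float
    alpha_m: complex
    k: float
    frak_a: float
    frak_b: float


def harmonic_coefficients(
    m: int, omega: float, prim: PrimitiveParams, der: DerivedParams
) -> HarmonicCoefficients:
    """Coefficients of the m-th harmonic pressure equation (m >= 1)."""
    if m < 1:
        raise ValueError(
            "harmonic index m must be >= 1; the zeroth harmonic is handled algebraically"
        )
    if not omega > 0:
        raise ValueError(f"omega must be positive, got {omega!r}")
    w0sq = der.omega0**2
    mw = m * omega
    denom_c = -(mw**2) + 1j * m * der.delta * der.omega0 * omega + w0sq
    alpha_m = 1.0 / denom_c
    k = mw / prim.c
    d = (w0sq - mw**2) ** 2 + (m * der.delta * der.omega0 * omega) ** 2
    pref = der.mu * prim.rho0 * prim.n0
    frak_a = pref * mw**2 * (w0sq - mw**2) / d
    frak_b = pref * mw**3 * der.delta * der.omega0 / d
    return HarmonicCoefficients(m=m, omega=omega, alpha_m=alpha_m, k=k, frak_a=frak_a, frak_b=frak_b)


def effective_two_harmonic(
    prim: PrimitiveParams, der: DerivedParams, omega: float
) -> tuple[complex, complex, complex]:
    """Effective sound speeds and added nonlinearity of the two-harmonic scheme.

    Returns ``(c_tilde_1, c_tilde_2, beta_tilde_a)`` with

        1/c̃_m^2 = 1/c^2 + ρ0 n0 μ α_m,
        β̃_a     = c^4 ρ0^2 n0 (ζ - 3 ξ ω^2) μ^2 α_1^2 α_2.

    The effective (generally complex) wavenumber is ``k̃_m = m ω / c̃_m``; its
    imaginary part encodes bubble-induced attenuation.  For ``n0 = 0`` the
    scheme reduces to the plain two-harmonic Westervelt expansion
    (``c̃_m = c``, ``β̃_a = 0``).
    """
    a1 = harmonic_coefficients(1, omega, prim, der).alpha_m
    a2 = harmonic_coefficients(2, omega, prim, der).alpha_m
    inv_c1_sq = 1.0 / prim.c**2 + prim.rho0 * prim.n0 * der.mu * a1
    inv_c2_sq = 1.0 / prim.c**2 + prim.rho0 * prim.n0 * der.mu * a2
    c1 = 1.0 / cmath.sqrt(inv_c1_sq)
    c2 = 1.0 / cmath.sqrt(inv_c2_sq)
    beta_tilde = (
        prim.c**4
        * prim.rho0**2
        * prim.n0
        * (der.zeta - 3.0 * der.xi * omega**2)
        * der.mu**2
        * a1**2
        * a2
    )
    return c1, c2, beta_tilde


#: Primitive parameters as used in the simulations (ultrasound contrast imaging
#: regime).  The bubble number density is stored per cubic metre.
TABLE_PRESET = PrimitiveParams()
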