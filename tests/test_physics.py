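"""Derived coefficients, per-harmonic transfer algebra and effective media."""

import math
from dataclasses import replace

import numpy as np
import pytest

import ultraharm as uh


class TestDeriveParams:
    def test_natural_frequency_matches_closed_form(self, prim, der):
        # omega0 = sqrt(3 kappa P0 / (rho0 R0^2)), approx 0.324 Mrad/s for the
        # contrast-imaging parameter set
        expected = math.sqrt(3 * 1.4 * 100.0 / (1000.0 * (2e-6) ** 2))
        assert der.omega0 == pytest.approx(expected, rel=1e-14)
        assert der.omega0 == pytest.approx(0.324e6, rel=2e-3)

    def test_direct_arithmetic_oracles(self, prim, der):
        # independent evaluation of each closed formula
        assert der.v0 == pytest.approx(4.0 * math.pi / 3.0 * prim.R0**3, rel=1e-14)
        assert der.mu == pytest.approx(4.0 * math.pi * prim.R0 / prim.rho0, rel=1e-14)
        assert der.delta == pytest.approx(4 * prim.nu / (der.omega0 * prim.R0**2), rel=1e-14)
        assert der.zeta == pytest.approx(
            (prim.kappa + 1) * der.omega0**2 / (2 * der.v0), rel=1e-14
        )
        assert der.xi == pytest.approx(1.0 / (6 * der.v0), rel=1e-14)
        assert der.eta == pytest.approx(prim.beta_a / (prim.rho0 * prim.c**2), rel=1e-14)

    def test_defining_relation(self, prim, der):
        assert der.omega0**2 * prim.rho0 * prim.R0**2 == pytest.approx(
            3 * prim.kappa * prim.P0, rel=1e-12
        )

    @pytest.mark.parametrize("field", ["c", "rho0", "R0", "P0", "kappa", "nu"])
    def test_nonpositive_primitive_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            uh.PrimitiveParams(**{field: -1.0})

    def test_negative_density_rejected_but_zero_allowed(self):
        with pytest.raises(ValueError, match="n0"):
            uh.PrimitiveParams(n0=-1.0)
        assert uh.PrimitiveParams(n0=0.0).n0 == 0.0

    @pytest.mark.parametrize(
        "field,factor,powers",
        [
            # scaling laws: coefficient -> its power of the rescaled primitive
            ("R0", 4.0, {"omega0": -1, "v0": 3, "mu": 1, "xi": -3}),
            ("rho0", 9.0, {"omega0": -0.5, "mu": -1, "eta": -1}),
            ("P0", 16.0, {"omega0": 0.5, "v0": 0}),
        ],
    )
    def test_dimensional_power_laws(self, prim, der, field, factor, powers):
        scaled = uh.derive_params(replace(prim, **{field: getattr(prim, field) * factor}))
        for name, power in powers.items():
            assert getattr(scaled, name) == pytest.approx(
                getattr(der, name) * factor**power, rel=1e-11
            ), name


class TestHarmonicCoefficients:
    def test_resonant_fundamental_purely_imaginary(self, prim, der):
        c = uh.harmonic_coefficients(1, der.omega0, prim, der)
        assert c.alpha_m.real == pytest.approx(0.0, abs=1e-30)
        assert c.alpha_m == pytest.approx(-1j / (der.delta * der.omega0**2), rel=1e-14)
        assert c.frak_a == pytest.approx(0.0, abs=1e-20)

    def test_undamped_off_resonance_real(self, prim, der):
        der0 = replace(der, delta=1e-300)  # delta -> 0 limit
        c = uh.harmonic_coefficients(3, 0.7 * der.omega0, prim, der0)
        w0sq, mw = der.omega0**2, 3 * 0.7 * der.omega0
        assert c.alpha_m == pytest.approx(1.0 / (w0sq - mw**2), rel=1e-12)
        assert abs(c.alpha_m.imag) < 1e-12 * abs(c.alpha_m.real)

    def test_bubble_free_coefficients_vanish(self, der):
        prim0 = uh.PrimitiveParams(n0=0.0)
        for m in (1, 2, 7):
            c = uh.harmonic_coefficients(m, der.omega0, prim0, der)
            assert c.frak_a == 0.0 and c.frak_b == 0.0

    @pytest.mark.parametrize("m", range(1, 21))
    def test_alpha_defining_identity(self, prim, der, m):
        for omega in np.linspace(0.1, 3.0, 7) * der.omega0:
            c = uh.harmonic_coefficients(m, omega, prim, der)
            lhs = c.alpha_m * (
                -(m**2) * omega**2 + 1j * m * der.delta * der.omega0 * omega + der.omega0**2
            )
            assert lhs == pytest.approx(1.0, rel=1e-13)
            assert c.k == m * omega / prim.c

    def test_frak_a_sign_flips_at_resonance_and_frak_b_positive(self, prim, der):
        for m in (1, 2, 5):
            below = uh.harmonic_coefficients(m, 0.999 * der.omega0 / m, prim, der)
            above = uh.harmonic_coefficients(m, 1.001 * der.omega0 / m, prim, der)
            assert below.frak_a > 0 > above.frak_a
            assert below.frak_b > 0 and above.frak_b > 0

    def test_m_zero_rejected(self, prim, der):
        with pytest.raises(ValueError):
            uh.harmonic_coefficients(0, der.omega0, prim, der)


class TestEffectiveTwoHarmonic:
    def test_bubble_free_reduction(self, der):
        prim0 = uh.PrimitiveParams(n0=0.0)
        c1, c2, bt = uh.effective_two_harmonic(prim0, der, der.omega0)
        assert c1 == pytest.approx(prim0.c) and c2 == pytest.approx(prim0.c)
        assert bt == 0.0

    def test_complex_effective_wavenumber(self, prim, der):
        c1, c2, _ = uh.effective_two_harmonic(prim, der, der.omega0)
        for m, ct in ((1, c1), (2, c2)):
            k_eff_sq = (m * der.omega0 / ct) ** 2
            assert abs(k_eff_sq.imag) > 0

    def test_real_part_identity(self, prim, der):
        omega = 0.8 * der.omega0
        c1, _, _ = uh.effective_two_harmonic(prim, der, omega)
        alpha1 = uh.harmonic_coefficients(1, omega, prim, der).alpha_m
        lhs = (1.0 / c1**2).real - 1.0 / prim.c**2
        assert lhs == pytest.approx(prim.rho0 * prim.n0 * der.mu * alpha1.real, rel=1e-12)

    def test_effective_reaction_equals_modified_helmholtz_reaction(self, prim, der):
        # (m omega / c_tilde_m)^2 == (k^2 + frak_a) - i frak_b, the identity that
        # makes the two-harmonic scheme and the coupled complex system coincide
        omega = der.omega0
        c1, c2, _ = uh.effective_two_harmonic(prim, der, omega)
        for m, ct in ((1, c1), (2, c2)):
            c = uh.harmonic_coefficients(m, omega, prim, der)
            assert (m * omega / ct) ** 2 == pytest.approx(
                (c.k**2 + c.frak_a) - 1j * c.frak_b, rel=1e-12
            )


class TestPropertyBased:
    """Randomized invariants of the per-harmonic algebra (seeded/derandomized)."""

    def test_alpha_identity_and_dissipation_randomized(self, prim, der):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            m=st.integers(min_value=1, max_value=20),
            w_rel=st.floats(min_value=0.05, max_value=5.0),
        )
        def check(m, w_rel):
            omega = w_rel * der.omega0
            c = uh.harmonic_coefficients(m, omega, prim, der)
            assert c.alpha_m * (
                -(m**2) * omega**2 + 1j * m * der.delta * der.omega0 * omega + der.omega0**2
            ) == pytest.approx(1.0, rel=1e-12)
            assert c.frak_b >= 0.0
            # reaction identity: k^2 + frak_a - i frak_b == m^2 w^2 (1/c^2 + rho0 n0 mu alpha_m)
            lhs = c.k**2 + c.frak_a - 1j * c.frak_b
            rhs = (m * omega) ** 2 * (1 / prim.c**2 + prim.rho0 * prim.n0 * der.mu * c.alpha_m)
            assert lhs == pytest.approx(rhs, rel=1e-12)

        check()
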