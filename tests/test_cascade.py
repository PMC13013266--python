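"""Cascade algorithms: triangularity, homogeneity, variant equivalences."""

from dataclasses import replace

import numpy as np
import pytest

import ultraharm as uh
from conftest import rel

N0_MODERATE = 1.0e9  # a density with visible but non-dominant bubble coupling


@pytest.fixture(scope="module")
def bubbly_prim():
    return replace(uh.TABLE_PRESET, n0=N0_MODERATE)


class TestComplexCascades:
    def test_linear_medium_kills_higher_harmonics(
        self, coarse_mesh, coarse_ops, source, prim, linear_der
    ):
        cfg = uh.SolverConfig(variant="complex-linearized", N=4)
        levels = uh.run_complex_linearized(
            cfg, coarse_mesh, coarse_ops, source, prim, der=linear_der
        )
        final = levels[-1]
        assert np.max(np.abs(final.p[1])) > 0
        for m in range(2, 5):
            assert not np.any(final.p[m])
            assert not np.any(final.v[m])

    def test_amplitude_homogeneity(self, coarse_mesh, coarse_ops, bubbly_prim):
        # scaling the source amplitude by s scales p_m by s^m exactly
        cfg = uh.SolverConfig(variant="complex-linearized", N=3)
        s = 10.0
        lev_a = uh.run_complex_linearized(
            cfg, coarse_mesh, coarse_ops, uh.SourceSpec(a=1e3, r_delta=0.004),
            bubbly_prim,
        )
        lev_b = uh.run_complex_linearized(
            cfg, coarse_mesh, coarse_ops, uh.SourceSpec(a=1e4, r_delta=0.004),
            bubbly_prim,
        )
        for m in range(1, 4):
            assert rel(lev_b[-1].p[m], s**m * lev_a[-1].p[m]) < 1e-11

    def test_harmonics_stabilize_at_their_own_level(
        self, coarse_mesh, coarse_ops, source, bubbly_prim
    ):
        # p_m no longer changes after level m (triangular structure)
        cfg = uh.SolverConfig(variant="complex-linearized", N=5)
        levels = uh.run_complex_linearized(cfg, coarse_mesh, coarse_ops, source, bubbly_prim)
        for m in range(1, 6):
            for lvl in range(m, 5):
                assert rel(levels[lvl].p[m], levels[m - 1].p[m]) < 1e-12

    def test_coupled_equals_stabilized_linearized(
        self, coarse_mesh, coarse_ops, source, bubbly_prim
    ):
        cfg_l = uh.SolverConfig(variant="complex-linearized", N=4)
        cfg_c = uh.SolverConfig(variant="complex-coupled", N=4)
        levels = uh.run_complex_linearized(cfg_l, coarse_mesh, coarse_ops, source, bubbly_prim)
        coupled = uh.run_complex_coupled(cfg_c, coarse_mesh, coarse_ops, source, bubbly_prim)
        for m in range(1, 5):
            assert rel(levels[-1].p[m], coupled.p[m]) < 1e-10
            assert rel(levels[-1].v[m], coupled.v[m]) < 1e-10

    def test_coupled_first_harmonic_volume_identity(
        self, coarse_mesh, coarse_ops, source, bubbly_prim
    ):
        # v_1 = -alpha_1 mu p_1 exactly (no lower harmonics feed m = 1)
        der = uh.derive_params(bubbly_prim)
        cfg = uh.SolverConfig(variant="complex-coupled", N=2)
        out = uh.run_complex_coupled(cfg, coarse_mesh, coarse_ops, source, bubbly_prim)
        alpha1 = uh.harmonic_coefficients(1, der.omega0, bubbly_prim, der).alpha_m
        assert np.allclose(out.v[1], -alpha1 * der.mu * out.p[1], rtol=1e-13)

    def test_linear_medium_single_solve(self, coarse_mesh, coarse_ops, source, prim, linear_der):
        # eta = zeta = xi = 0: p_1 equals one bubble-modified Helmholtz solve
        from ultraharm.helmholtz import harmonic_problem

        der = linear_der
        cfg = uh.SolverConfig(variant="complex-coupled", N=3)
        out = uh.run_complex_coupled(cfg, coarse_mesh, coarse_ops, source, prim, der=der)
        q = uh.assemble_load(coarse_mesh, coarse_ops, source, 1)
        c1 = uh.harmonic_coefficients(1, der.omega0, prim, der)
        prob = harmonic_problem(1, der.omega0, prim, der, rhs=-(c1.k**2) * q)
        u = uh.solve_harmonic(prob, coarse_ops)
        assert rel(out.p[1], u) < 1e-12
        assert not np.any(out.p[2]) and not np.any(out.p[3])


class TestRealCascade:
    def test_level_one_matches_complex(self, coarse_mesh, coarse_ops, source, bubbly_prim):
        # N = 1: every convolution range is empty
        lev_r = uh.run_real_linearized(
            uh.SolverConfig(variant="real-linearized", N=1),
            coarse_mesh, coarse_ops, source, bubbly_prim,
        )
        lev_c = uh.run_complex_linearized(
            uh.SolverConfig(variant="complex-linearized", N=1),
            coarse_mesh, coarse_ops, source, bubbly_prim,
        )
        assert rel(lev_r[0].p[1], lev_c[0].p[1]) < 1e-13
        assert rel(lev_r[0].v[1], lev_c[0].v[1]) < 1e-13

    def test_zero0_variant_pins_v0(self, coarse_mesh, coarse_ops, source, bubbly_prim):
        levels = uh.run_real_linearized(
            uh.SolverConfig(variant="real-linearized-zero0", N=3),
            coarse_mesh, coarse_ops, source, bubbly_prim,
        )
        for lvl in levels:
            assert not np.any(lvl.v[0]) and not np.any(lvl.p[0])

    def test_free_v0_is_real_valued(self, coarse_mesh, coarse_ops, source, bubbly_prim):
        levels = uh.run_real_linearized(
            uh.SolverConfig(variant="real-linearized", N=3),
            coarse_mesh, coarse_ops, source, bubbly_prim,
        )
        v0 = levels[-1].v[0]
        assert np.any(v0)
        assert np.max(np.abs(v0.imag)) < 1e-16 * np.max(np.abs(v0.real))

    def test_triangularity_audit(self, coarse_mesh, coarse_ops, source, bubbly_prim):
        # complex variants read only lower harmonics; linearized variants read
        # only previous-level data
        audit_c: list = []
        uh.run_complex_coupled(
            uh.SolverConfig(variant="complex-coupled", N=4),
            coarse_mesh, coarse_ops, source, bubbly_prim, audit=audit_c,
        )
        for record in audit_c:
            assert all(idx < record["m"] for _, idx in record["reads"])
        audit_r: list = []
        uh.run_real_linearized(
            uh.SolverConfig(variant="real-linearized", N=4),
            coarse_mesh, coarse_ops, source, bubbly_prim, audit=audit_r,
        )
        for record in audit_r:
            assert all(lvl == record["level"] - 1 for lvl, _ in record["reads"])


class TestTwoHarmonic:
    def test_equals_coupled_n2(self, coarse_mesh, coarse_ops, source, bubbly_prim):
        th = uh.run_two_harmonic(
            uh.SolverConfig(variant="two-harmonic"), coarse_mesh, coarse_ops, source,
            bubbly_prim,
        )
        c2 = uh.run_complex_coupled(
            uh.SolverConfig(variant="complex-coupled", N=2), coarse_mesh, coarse_ops,
            source, bubbly_prim,
        )
        for m in (1, 2):
            assert rel(th.p[m], c2.p[m]) < 1e-10
            assert rel(th.v[m], c2.v[m]) < 1e-10

    def test_volume_recovery_identities(self, coarse_mesh, coarse_ops, source, bubbly_prim):
        der = uh.derive_params(bubbly_prim)
        w = der.omega0
        th = uh.run_two_harmonic(
            uh.SolverConfig(variant="two-harmonic"), coarse_mesh, coarse_ops, source,
            bubbly_prim,
        )
        a1 = uh.harmonic_coefficients(1, w, bubbly_prim, der).alpha_m
        a2 = uh.harmonic_coefficients(2, w, bubbly_prim, der).alpha_m
        assert np.allclose(th.v[1], -a1 * der.mu * th.p[1], rtol=1e-13)
        v2 = a2 * (
            -der.mu * th.p[2]
            + (der.zeta - 3 * der.xi * w**2) * a1**2 * der.mu**2 * th.p[1] ** 2
        )
        assert np.allclose(th.v[2], v2, rtol=1e-12)

    def test_bubble_free_reduces_to_westervelt(self, coarse_mesh, coarse_ops, source):
        th = uh.run_two_harmonic(
            uh.SolverConfig(variant="two-harmonic", with_bubbles=False),
            coarse_mesh, coarse_ops, source, uh.TABLE_PRESET,
        )
        west = uh.run_complex_coupled(
            uh.SolverConfig(variant="complex-coupled", N=2, with_bubbles=False),
            coarse_mesh, coarse_ops, source, uh.TABLE_PRESET,
        )
        for m in (1, 2):
            assert rel(th.p[m], west.p[m]) < 1e-11


class TestVolumeRecovery:
    def test_algebraic_identities(self, prim, der):
        c2 = uh.harmonic_coefficients(2, der.omega0, prim, der)
        p = np.array([1 + 2j, -0.5j, 3.0])
        fv = np.array([0.1, 0.0, -2j])
        out = uh.recover_volume_harmonics(p, fv, c2, der)
        assert np.allclose(out, c2.alpha_m * (-der.mu * p + fv), rtol=1e-15)
        assert np.allclose(
            uh.recover_volume_harmonics(p, 0.0, c2, der), -c2.alpha_m * der.mu * p
        )
        assert np.allclose(
            uh.recover_volume_harmonics(np.zeros(3), fv, c2, der), c2.alpha_m * fv
        )
        assert not np.any(uh.recover_volume_harmonics(np.zeros(3), 0.0, c2, der))


class TestResiduals:
    def test_linear_solution_has_tiny_residual(
        self, coarse_mesh, coarse_ops, source, prim, linear_der
    ):
        cfg = uh.SolverConfig(variant="complex-coupled", N=2)
        out = uh.run_complex_coupled(cfg, coarse_mesh, coarse_ops, source, prim, der=linear_der)
        res = uh.residual_coupled_real(
            out, coarse_mesh, coarse_ops, source, prim, der=linear_der
        )
        zero = uh.HarmonicField.zeros(2, out.omega, coarse_mesh.n_nodes)
        res0 = uh.residual_coupled_real(
            zero, coarse_mesh, coarse_ops, source, prim, der=linear_der
        )
        assert res["pde"][1] < 1e-8 * res0["pde"][1]
        assert res["ode"][1] < 1e-20

    def test_zero_field_residual_is_source_norm(
        self, coarse_mesh, coarse_ops, source, bubbly_prim
    ):
        zero = uh.HarmonicField.zeros(
            3, uh.derive_params(bubbly_prim).omega0, coarse_mesh.n_nodes
        )
        res = uh.residual_coupled_real(zero, coarse_mesh, coarse_ops, source, bubbly_prim)
        assert res["pde"][1] > 0
        assert res["pde"][2] == 0.0  # only m = 1 carries the source
        assert all(r == 0 for r in res["ode"])

    def test_real_iterates_residual_decreases_to_stagnation(
        self, medium_mesh, medium_ops, prim
    ):
        # bubble-free, moderate amplitude: each level reduces the coupled
        # residual until the difference-frequency floor
        src = uh.SourceSpec(a=1e4, r_delta=0.004)
        levels = uh.run_real_linearized(
            uh.SolverConfig(variant="real-linearized", N=4, with_bubbles=False),
            medium_mesh, medium_ops, src, prim,
        )
        totals = []
        for lvl in levels:
            res = uh.residual_coupled_real(
                lvl, medium_mesh, medium_ops, src, prim, with_bubbles=False
            )
            totals.append(sum(res["pde"][1:]))
        assert totals[1] < totals[0]
        assert totals[2] < totals[1] * 1.05  # stagnation tolerated
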