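"""Unit and property tests for the shell mechanics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize

from corneashell.core_model import (
    CornealGeometry,
    GeometryError,
    InvalidModulusError,
    InvalidPoissonError,
    Loads,
    ModelValidityWarning,
    NormalizedState,
    SingularGeometryError,
    ThinShellWarning,
    assemble_full_system,
    bending_terms,
    deflection_breakdown,
    derived_shell_params,
    dimple_deflection,
    dimple_volume,
    equilibrium_force,
    forward_deflection,
    make_loads,
    pressure_drag,
    reduced_system,
    solve_reduced,
    solve_volume_conserving,
    stretch_energy,
    total_deflection,
    total_potential,
)


def geom(R=7.17, t=0.5431, alpha=math.pi / 6, nu=0.49) -> CornealGeometry:
    return CornealGeometry(R=R, t=t, alpha=alpha, nu=nu)


def tied_loads(g: CornealGeometry, E_mpa: float, p_bar: float) -> Loads:
    """Physical loads consistent with the small-deformation force tie."""
    E_pa = E_mpa * 1e6
    t_m = g.t * 1e-3
    R_m = g.R * 1e-3
    p = p_bar * E_pa * t_m**2 / R_m**2
    P = equilibrium_force(g.alpha, p_bar) * E_pa * t_m**2
    return make_loads(g, P, p, E_mpa)


# --------------------------------------------------------------------------
# elementary geometry and energy components


class TestShellParameters:
    def test_factor_collapses_for_zero_poisson(self):
        g = geom(R=10.0, t=math.sqrt(12.0), alpha=0.4, nu=0.0)
        c, lam = derived_shell_params(g)
        assert c == pytest.approx(1.0, abs=1e-14)
        assert lam == pytest.approx(10.0, rel=1e-14)

    def test_clinical_values(self):
        g = geom(t=0.55)
        c, lam = derived_shell_params(g)
        # direct arithmetic: c = t / sqrt(12 (1 - nu^2))
        assert c == pytest.approx(0.55 / math.sqrt(12 * (1 - 0.49**2)), rel=1e-12)
        assert c == pytest.approx(0.18213, abs=1e-5)
        assert lam == pytest.approx(39.37, abs=0.01)

    @pytest.mark.parametrize("nu", [0.55, 0.5, -1.0, -1.3])
    def test_invalid_poisson_rejected(self, nu):
        with pytest.raises(InvalidPoissonError):
            geom(nu=nu)

    def test_thinness_and_kink_warnings(self):
        with pytest.warns(ThinShellWarning):
            geom(R=7.0, t=0.55, alpha=0.3)
        with pytest.warns(ModelValidityWarning):
            geom(R=20.0, t=0.55, alpha=math.pi / 5)


class TestDimple:
    @pytest.mark.parametrize(
        "R, alpha, expected",
        [
            (7.0, 1e-9, 0.0),
            (7.0, math.pi / 3, 7.0),  # 1 - cos 60 deg = 1/2
            (7.0, math.pi / 6, 1.87564),
        ],
    )
    def test_inversion_travel(self, R, alpha, expected):
        g = geom(R=R, t=0.2, alpha=max(alpha, 1e-9))
        assert dimple_deflection(g) == pytest.approx(expected, abs=2e-5)

    def test_volume_matches_solid_of_revolution_oracle(self):
        # independent oracle: minus twice the cap volume, integrated as a
        # solid of revolution of the mirrored cap
        g = geom(R=7.0, t=0.2, alpha=math.pi / 6)
        d1 = dimple_deflection(g)
        h = d1 / 2.0
        cap, _ = integrate.quad(lambda y: math.pi * (g.R**2 - y**2), g.R - h, g.R)
        assert dimple_volume(g, d1) == pytest.approx(-2.0 * cap, rel=1e-8)
        assert dimple_volume(g, d1) == pytest.approx(-36.955, abs=2e-3)

    def test_zero_depth_zero_volume(self):
        assert dimple_volume(geom(), 0.0) == 0.0

    def test_cubic_length_scaling(self):
        g1, g2 = geom(R=7.0, t=0.2), geom(R=14.0, t=0.4)
        assert dimple_volume(g2) == pytest.approx(8.0 * dimple_volume(g1), rel=1e-12)

    def test_overdeep_dimple_rejected(self):
        with pytest.raises(GeometryError):
            dimple_volume(geom(R=7.0, t=0.2), 15.0)


class TestMembraneTerms:
    def test_zero_state_zero_energy(self):
        st0 = NormalizedState(0.0, 0.0, 0.0)
        assert stretch_energy(geom(), 0.2, st0) == 0.0

    def test_direct_arithmetic_transcription(self):
        # independent transcription of the stretch energy at stated values
        E, t, R, nu, a = 0.2, 0.55, 7.17, 0.49, math.pi / 6
        st1 = NormalizedState(0.01, 0.005, 0.0)
        expected_j = (
            2.0 * math.pi * (E * 1e6) * (t * 1e-3) * (R * 1e-3) ** 2 / (1 - nu)
            * (0.01**2 * (1 - math.cos(a)) + 0.005**2 * math.cos(a))
        )
        got = stretch_energy(geom(R=R, t=t, alpha=a, nu=nu), E, st1)
        assert got == pytest.approx(expected_j * 1e6, rel=1e-12)
        assert got >= 0.0

    def test_linear_in_modulus(self):
        st1 = NormalizedState(0.01, 0.005, 0.0)
        assert stretch_energy(geom(), 0.4, st1) == pytest.approx(
            2.0 * stretch_energy(geom(), 0.2, st1), rel=1e-12
        )

    def test_pressure_drag_arithmetic(self):
        g = geom(R=7.0, t=0.2, alpha=math.pi / 6)
        st1 = NormalizedState(0.01, 0.005, 0.0)
        d2, dv2, dv3 = pressure_drag(g, st1)
        ca = math.cos(math.pi / 6)
        assert d2 == pytest.approx(7.0 * (0.01 * (1 - ca) - 0.005 * ca), rel=1e-12)
        assert d2 == pytest.approx(-0.020933, abs=2e-6)
        assert dv2 == pytest.approx(-2 * math.pi * 49.0 * d2 * (1 - ca), rel=1e-12)
        assert dv3 == pytest.approx(2 * math.pi * 343.0 * 0.005 * ca, rel=1e-12)

    def test_pressure_drag_zero_state(self):
        assert pressure_drag(geom(), NormalizedState(0, 0, 0)) == (0.0, 0.0, 0.0)


class TestBendingTerms:
    def test_apex_term_vanishes_without_outer_strain(self):
        _, d4, dv4 = bending_terms(geom(), 0.2, NormalizedState(0.01, 0.0, 0.0))
        assert d4 == 0.0 and dv4 == 0.0

    def test_linear_in_modulus(self):
        st1 = NormalizedState(-0.008, 0.03, 1.5)
        ub1, _, _ = bending_terms(geom(), 0.2, st1)
        ub2, _, _ = bending_terms(geom(), 0.4, st1)
        assert ub2 == pytest.approx(2.0 * ub1, rel=1e-12)

    def test_apex_term_forms(self):
        g = geom()
        st1 = NormalizedState(0.0, 0.02, 0.0)
        _, d4_lam, _ = bending_terms(g, 0.2, st1, "lam_scaled")
        _, d4_plain, _ = bending_terms(g, 0.2, st1, "unscaled")
        assert d4_lam == pytest.approx(-g.R * g.lam * math.sqrt(2) / 4 * 0.02**2)
        assert d4_plain == pytest.approx(d4_lam / g.lam, rel=1e-12)


# --------------------------------------------------------------------------
# equilibrium: closed forms, energy-route agreement, structure


class TestForceTie:
    @given(
        alpha=st.floats(0.0, math.pi / 2 - 1e-9),
        p_bar=st.floats(0.0, 50.0),
    )
    def test_closed_form_exact(self, alpha, p_bar):
        assert equilibrium_force(alpha, p_bar) == 2.0 * math.pi * (
            1.0 - math.cos(alpha)
        ) * p_bar

    def test_limit_values(self):
        assert equilibrium_force(0.0, 3.0) == 0.0
        assert equilibrium_force(math.pi / 3, 1.0) == pytest.approx(math.pi, rel=1e-14)


def _fd_newton_minimize_potential(g, E_mpa, p_bar, iters=20):
    """Independent energy oracle: finite-difference Newton stationarisation
    of the physical total potential over (w_i_bar, w_o_bar)."""
    loads = tied_loads(g, E_mpa, p_bar)

    def pi_of(w):
        st1 = NormalizedState(float(w[0]), float(w[1]), p_bar)
        return total_potential(g, E_mpa, loads, st1).Pi_total

    w = np.zeros(2)
    hg, hh = 1e-7, 1e-5
    for _ in range(iters):
        grad = np.array(
            [
                (pi_of(w + [hg, 0]) - pi_of(w - [hg, 0])) / (2 * hg),
                (pi_of(w + [0, hg]) - pi_of(w - [0, hg])) / (2 * hg),
            ]
        )
        H = np.zeros((2, 2))
        for i in range(2):
            e = np.zeros(2)
            e[i] = hh
            gp = np.array(
                [
                    (pi_of(w + e + [hg, 0]) - pi_of(w + e - [hg, 0])) / (2 * hg),
                    (pi_of(w + e + [0, hg]) - pi_of(w + e - [0, hg])) / (2 * hg),
                ]
            )
            gm = np.array(
                [
                    (pi_of(w - e + [hg, 0]) - pi_of(w - e - [hg, 0])) / (2 * hg),
                    (pi_of(w - e + [0, hg]) - pi_of(w - e - [0, hg])) / (2 * hg),
                ]
            )
            H[:, i] = (gp - gm) / (2 * hh)
        w = w - np.linalg.solve(H, grad)
    return w


class TestReducedEquilibrium:
    def test_agrees_with_energy_minimisation_oracle(self):
        """Stationary points of the reconstructed potential coincide with
        the algebraic solve on a (lam, alpha, p_bar) grid."""
        nu = 0.49
        for lam in (25.0, 40.0, 60.0):
            for alpha in (0.30, 0.45, 0.52):
                for p_bar in (0.5, 1.5, 3.0):
                    R = 7.0
                    c = R / lam
                    t = c * math.sqrt(12 * (1 - nu**2))
                    g = geom(R=R, t=t, alpha=alpha, nu=nu)
                    st1 = solve_reduced(g, p_bar)
                    w_oracle = _fd_newton_minimize_potential(g, 0.25, p_bar)
                    assert st1.w_i_bar == pytest.approx(
                        w_oracle[0], rel=1e-6, abs=1e-9
                    )
                    assert st1.w_o_bar == pytest.approx(
                        w_oracle[1], rel=1e-6, abs=1e-9
                    )

    def test_stationarity_by_finite_differences(self, typical_geom):
        st1 = solve_reduced(typical_geom, 1.65)
        loads = tied_loads(typical_geom, 0.207, 1.65)

        def pi_of(wi, wo):
            return total_potential(
                typical_geom, 0.207, loads, NormalizedState(wi, wo, 1.65)
            ).Pi_total

        h = 1e-7
        g1 = (pi_of(st1.w_i_bar + h, st1.w_o_bar) - pi_of(st1.w_i_bar - h, st1.w_o_bar)) / (2 * h)
        g2 = (pi_of(st1.w_i_bar, st1.w_o_bar + h) - pi_of(st1.w_i_bar, st1.w_o_bar - h)) / (2 * h)
        scale = abs(pi_of(st1.w_i_bar, st1.w_o_bar)) + 1.0
        assert abs(g1) / scale < 1e-6
        assert abs(g2) / scale < 1e-6

    def test_nondimensional_invariance(self):
        g1 = geom(R=7.17, t=0.5431, alpha=0.5)
        s = 2.7
        g2 = geom(R=7.17 * s, t=0.5431 * s, alpha=0.5)
        st1, st2 = solve_reduced(g1, 1.3), solve_reduced(g2, 1.3)
        assert st1.w_i_bar == pytest.approx(st2.w_i_bar, rel=1e-12)
        assert st1.w_o_bar == pytest.approx(st2.w_o_bar, rel=1e-12)

    def test_deflection_monotone_in_pressure(self, typical_geom):
        """Higher normalised pressure swells the outer shell and lifts the
        ridge, so the apex deflection strictly decreases with p_bar."""
        deltas = [
            total_deflection(typical_geom, solve_reduced(typical_geom, pb))
            for pb in np.linspace(0.2, 4.0, 12)
        ]
        assert all(b < a for a, b in zip(deltas, deltas[1:]))

    def test_singular_alpha_guarded(self):
        g = geom(alpha=5e-4)
        with pytest.raises(SingularGeometryError):
            solve_reduced(g, 1.0)

    def test_physical_strain_pattern(self, typical_geom):
        # the inverted cap is compressed, the outer shell swells
        st1 = solve_reduced(typical_geom, 1.65)
        assert st1.w_i_bar < 0 < st1.w_o_bar
        assert abs(st1.w_o_bar) < 0.1  # strains stay small


class TestSymbolicStructure:
    def test_reconstructed_potential_gradient_matches_system(self):
        """Symbolic-differentiation oracle: an independent sympy
        transcription of the reconstructed potential, differentiated and
        scaled, reproduces the assembled 2x2 system including the
        sqrt(2*lam)/(1-nu) diagonal families, the -1/2 off-diagonals, the
        equal-and-opposite ridge forcing and the pressure forcing confined
        to the outer-shell equation."""
        import sympy as sp

        wi, wo, pb = sp.symbols("wi wo pb")
        E, t, R, a, nu = sp.symbols("E t R a nu", positive=True)
        c = t / sp.sqrt(12 * (1 - nu**2))
        lam = R / c
        mu = sp.sqrt(lam / 2)
        US = 2 * sp.pi * E * t * R**2 / (1 - nu) * (
            wi**2 * (1 - sp.cos(a)) + wo**2 * sp.cos(a)
        )
        dw = wo - wi
        UB = sp.pi * E * t * R**2 * sp.sin(a) / 2 * (
            dw**2 / mu - 2 * a * dw / mu**2 + 2 * a**2 / mu**3
        ) + sp.pi * E * t * R**2 / mu * wo**2
        D1 = 2 * R * (1 - sp.cos(a))
        D2 = R * (wi * (1 - sp.cos(a)) - wo * sp.cos(a))
        D4 = -R * lam * sp.sqrt(2) / 4 * wo**2
        V1 = -sp.pi * R * D1**2 * (6 - D1 / R) / 12
        V2 = -2 * sp.pi * R**2 * D2 * (1 - sp.cos(a))
        V3 = 2 * sp.pi * R**3 * wo * sp.cos(a)
        V4 = -2 * sp.pi * R**2 * D4 * (1 - sp.cos(a))
        p = pb * E * t**2 / R**2
        P = 2 * sp.pi * (1 - sp.cos(a)) * pb * E * t**2
        Pi = US + UB - P * (D1 + D2 + D4) - p * (V1 + V2 + V3 + V4)
        norm = 2 * sp.pi * E * t * R**2 * sp.sin(a) * sp.sqrt(2 / lam)
        g1 = sp.diff(Pi, wi) / norm
        g2 = sp.diff(Pi, wo) / norm

        rng = np.random.default_rng(0)
        f1 = sp.lambdify((wi, wo, pb, E, t, R, a, nu), g1)
        f2 = sp.lambdify((wi, wo, pb, E, t, R, a, nu), g2)
        for _ in range(5):
            Rv = rng.uniform(6, 9)
            tv = rng.uniform(0.3, 0.7)
            av = rng.uniform(0.2, 0.6)
            nuv = 0.49
            pbv = rng.uniform(0.1, 3.0)
            wv = rng.uniform(-0.05, 0.05, size=2)
            g = geom(R=Rv, t=tv, alpha=av, nu=nuv)
            M, b = reduced_system(g, pbv)
            expected = M @ wv - b
            got = np.array(
                [
                    f1(wv[0], wv[1], pbv, 0.2, tv, Rv, av, nuv),
                    f2(wv[0], wv[1], pbv, 0.2, tv, Rv, av, nuv),
                ]
            )
            np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)


class TestFullSystem:
    def test_shapes_and_symmetric_coupling(self, typical_geom):
        st1 = solve_reduced(typical_geom, 1.65)
        loads = tied_loads(typical_geom, 0.207, 1.65)
        A, BL, BNL = assemble_full_system(typical_geom, loads, st1)
        assert A.shape == (5, 5) and BL.shape == (5,) and BNL.shape == (5,)
        assert A[0][1] == pytest.approx(-0.5)
        assert A[1][0] == pytest.approx(-0.5)

    def test_volume_row_structure(self, typical_geom):
        st1 = NormalizedState(0.0, 0.0, 0.0)
        loads = make_loads(typical_geom, 0.0, 0.0, 0.2)
        A, _, _ = assemble_full_system(typical_geom, loads, st1)
        ca = math.cos(typical_geom.alpha)
        # the membrane-sweep factor cos(a)(2 - cos(a)) sits in the w_o column
        assert A[2][1] == pytest.approx(ca * (2.0 - ca), rel=1e-12)
        assert A[2][0] == pytest.approx(-((1.0 - ca) ** 2), rel=1e-12)

    def test_residual_vanishes_at_reduced_solution(self, typical_geom):
        p_bar = 1.65
        st1 = solve_reduced(typical_geom, p_bar)
        loads = tied_loads(typical_geom, 0.207, p_bar)
        A, BL, BNL = assemble_full_system(typical_geom, loads, st1)
        Z = np.array([st1.w_i_bar, st1.w_o_bar, p_bar, 0.0, 0.0])
        resid = A @ Z - BL - BNL
        assert abs(resid[0]) < 1e-8
        assert abs(resid[1]) < 1e-8
        # edge-unknown rows vanish identically under the force tie
        assert abs(resid[3]) < 1e-12 and abs(resid[4]) < 1e-12

    def test_near_singular_geometry_rejected(self):
        g = geom(alpha=5e-4)
        with pytest.raises(SingularGeometryError):
            assemble_full_system(g, make_loads(g, 0.0, 0.0, 0.2), NormalizedState(0, 0, 0))


# --------------------------------------------------------------------------
# assembled deflection, potential, forward model


class TestDeflection:
    def test_rigid_state_reduces_to_inversion_travel(self, typical_geom):
        st0 = NormalizedState(0.0, 0.0, 0.0)
        assert total_deflection(typical_geom, st0) == pytest.approx(
            dimple_deflection(typical_geom), rel=1e-14
        )

    def test_component_sum_identity(self, typical_geom):
        st1 = solve_reduced(typical_geom, 1.65)
        br = deflection_breakdown(typical_geom, st1)
        assert br.total == pytest.approx(br.d1 + br.d2 + br.d4, rel=1e-14)

    def test_golden_regression_value(self, typical_geom):
        # frozen after verification against the finite-difference energy
        # oracle: E = 0.207 MPa, IOP 15 mmHg, typical geometry
        delta = forward_deflection(typical_geom, 0.207, 15.0 * 133.322)
        assert delta == pytest.approx(1.614789, abs=1e-5)


class TestTotalPotential:
    def test_sum_identity_and_unloaded_terms(self, typical_geom):
        st1 = NormalizedState(-0.008, 0.03, 0.0)
        loads0 = make_loads(typical_geom, 0.0, 0.0, 0.207)
        eb = total_potential(typical_geom, 0.207, loads0, st1)
        assert eb.UP == 0.0 and eb.Upr == 0.0
        assert eb.Pi_total == pytest.approx(eb.US + eb.UB, rel=1e-14)

    def test_force_work_linear_in_load(self, typical_geom):
        st1 = NormalizedState(-0.008, 0.03, 0.0)
        l1 = make_loads(typical_geom, 0.1, 0.0, 0.207)
        l2 = make_loads(typical_geom, 0.2, 0.0, 0.207)
        e1 = total_potential(typical_geom, 0.207, l1, st1)
        e2 = total_potential(typical_geom, 0.207, l2, st1)
        assert e2.UP == pytest.approx(2.0 * e1.UP, rel=1e-12)


class TestForwardModel:
    def test_strictly_monotone_in_modulus(self, typical_geom):
        p_pa = 15.0 * 133.322
        es = np.linspace(0.05, 1.0, 12)
        deltas = [forward_deflection(typical_geom, e, p_pa) for e in es]
        assert all(b > a for a, b in zip(deltas, deltas[1:]))

    def test_stiff_limit_is_zero_pressure_equilibrium(self, typical_geom):
        """As E grows the pressure forcing vanishes and the deflection
        approaches the E-independent kink-only equilibrium, which lies just
        below the rigid inversion travel Delta_1 (the ridge kink strains the
        shell by pure geometry, so Delta_1 is an upper bound, not the
        limit)."""
        d = forward_deflection(typical_geom, 1e4, 15.0 * 133.322)
        limit = total_deflection(typical_geom, solve_reduced(typical_geom, 0.0))
        assert d == pytest.approx(limit, abs=1e-4)
        assert d < dimple_deflection(typical_geom)

    def test_invalid_modulus_rejected(self, typical_geom):
        with pytest.raises(InvalidModulusError):
            forward_deflection(typical_geom, 0.0, 2000.0)


class TestVolumeConservingMode:
    def test_volume_is_conserved(self, typical_geom):
        P_bar = 2.0
        st1 = solve_volume_conserving(typical_geom, P_bar)
        br = deflection_breakdown(typical_geom, st1)
        assert abs(br.volume_residual) / abs(br.dv1) < 1e-6

    def test_pressure_is_solved_positive(self, typical_geom):
        st1 = solve_volume_conserving(typical_geom, 2.0)
        assert st1.p_bar > 0
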