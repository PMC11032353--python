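"""Scalar energy terms: printed constants, limits, derivatives, continuity."""

import math

import numpy as np
import pytest

from dropletmd.constants import COULOMB
from dropletmd.forcefield import (
    FlexibleAngleSpline,
    FlexibleDihedralSpline,
    angle_energy,
    angle_modulation,
    bond_energy,
    debye_huckel_energy,
    debye_length,
    dihedral_energy,
    excluded_volume_energy,
    go_contact_energy,
    hps_pair_energy,
    morse_components,
    relative_permittivity,
)
from dropletmd.params import FlexTable

TWO16 = 2.0 ** (1.0 / 6.0)


def central_diff(f, x, h=1e-6):
    return (f(x + h) - f(x - h)) / (2.0 * h)


def assert_deriv(f, x, analytic, h=1e-6, tol=1e-5):
    num = central_diff(f, x, h)
    assert analytic == pytest.approx(num, rel=tol, abs=1e-8)


class TestBond:
    def test_harmonic_zero_at_reference(self):
        assert bond_energy(3.8, "harmonic", (2.39, 3.8))[0] == 0.0

    def test_default_constant_at_one_angstrom_stretch(self):
        """k_b (b-b0)^2 with the default 2.39 kcal/mol/Å^2 at 1 Å."""
        e, _ = bond_energy(4.8, "harmonic", (2.39, 3.8))
        assert e == pytest.approx(2.39, abs=1e-12)

    def test_quartic_matches_polynomial_and_derivative(self, rng):
        for _ in range(20):
            b, k2, k4, b0 = rng.uniform(0.5, 6.0, 4)
            e, de = bond_energy(b, "quartic", (k2, k4, b0))
            d = b - b0
            assert e == pytest.approx(k2 * d**2 + k4 * d**4, rel=1e-12)
            assert_deriv(lambda x: bond_energy(x, "quartic",
                                               (k2, k4, b0))[0], b, de)

    def test_unknown_style(self):
        with pytest.raises(ValueError, match="unknown bond style"):
            bond_energy(1.0, "fene", (1.0, 1.0))


class TestAngles:
    def test_gaussian_13_minimum(self):
        e, de = angle_energy(5.5, "gaussian_13", (2.0, 5.5, 0.4))
        assert e == pytest.approx(-2.0) and de == 0.0

    def test_harmonic_zero_at_reference(self):
        assert angle_energy(1.9, "harmonic", (40.0, 1.9))[0] == 0.0

    def test_flexible_uniform_table_is_flat(self):
        """P(theta) proportional to sin(theta) cancels exactly: constant
        energy and zero force everywhere on the grid interior."""
        grid = np.linspace(0.1, math.pi - 0.1, 73)
        p = np.sin(grid) / np.trapezoid(np.sin(grid), grid)
        spline = FlexibleAngleSpline(FlexTable(grid, p), kT=0.6)
        thetas = np.linspace(0.15, math.pi - 0.15, 40)
        e, de = spline(thetas)
        assert np.ptp(e) < 1e-12
        assert np.abs(de).max() < 1e-12

    def test_flexible_derivative_matches_spline(self, rng):
        grid = np.linspace(0.1, math.pi - 0.1, 73)
        p = np.exp(-((grid - 1.8) ** 2) / 0.18) * np.sin(grid) + 1e-3
        p /= np.trapezoid(p, grid)
        spline = FlexibleAngleSpline(FlexTable(grid, p), kT=0.6)
        for theta in rng.uniform(0.3, 2.7, 10):
            e, de = angle_energy(theta, "flexible", spline)
            assert_deriv(lambda x: spline(x)[0], theta, de)


class TestDihedrals:
    def test_periodic_zero_opposite_reference(self):
        e, _ = dihedral_energy(1.0 + math.pi, "periodic", (2.0, 1.0, 1))
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_minimum(self):
        e, de = dihedral_energy(0.7, "gaussian", (1.5, 0.7, 0.3))
        assert e == pytest.approx(-1.5) and de == 0.0

    def test_gaussian_uses_minimum_image_difference(self):
        e1, _ = dihedral_energy(math.pi - 0.05, "gaussian",
                                (1.5, -math.pi + 0.05, 0.3))
        e2, _ = dihedral_energy(0.05, "gaussian", (1.5, -0.05, 0.3))
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_two_harmonic_sum_and_derivative(self, rng):
        terms = ((1.2, 0.4, 1), (0.7, -0.9, 3))
        for phi in rng.uniform(-math.pi, math.pi, 10):
            e, de = dihedral_energy(phi, "periodic", terms)
            expected = sum(k * (1 + math.cos(n * (phi - p0)))
                           for k, p0, n in terms)
            assert e == pytest.approx(expected, rel=1e-12)
            assert_deriv(lambda x: dihedral_energy(x, "periodic", terms)[0],
                         phi, de)

    def test_flexible_periodic_table(self, rng):
        grid = np.linspace(-math.pi, math.pi, 121)
        p = np.exp(0.8 * np.cos(grid - 0.5))
        p[-1] = p[0]
        p /= np.trapezoid(p, grid)
        spline = FlexibleDihedralSpline(FlexTable(grid, p, periodic=True), 0.6)
        for phi in rng.uniform(-3 * math.pi, 3 * math.pi, 10):
            e, de = spline(phi)
            ew, _ = spline((phi + math.pi) % (2 * math.pi) - math.pi)
            assert e == pytest.approx(ew, rel=1e-10)
            assert_deriv(lambda x: spline(x)[0], phi, de)


class TestGoContact:
    def test_minimum_at_sigma(self):
        e, de = go_contact_energy(5.0, 5.0, 0.3)
        assert e == pytest.approx(-0.3) and de == pytest.approx(0.0)

    def test_decays_to_zero_from_below(self):
        es = [go_contact_energy(r, 5.0, 0.3)[0] for r in (8.0, 12.0, 20.0)]
        assert all(e < 0 for e in es)
        assert es[0] < es[1] < es[2] < 0 or abs(es[2]) < 1e-4

    def test_compressed_value(self):
        e, _ = go_contact_energy(0.9 * 5.0, 5.0, 1.0)
        assert e == pytest.approx(5 * (1 / 0.9) ** 12 - 6 * (1 / 0.9) ** 10,
                                  rel=1e-12)

    def test_derivative(self, rng):
        for _ in range(10):
            r, s, eps = rng.uniform(2, 8), rng.uniform(3, 7), rng.uniform(0.1, 2)
            _, de = go_contact_energy(r, s, eps)
            assert_deriv(lambda x: go_contact_energy(x, s, eps)[0], r, de)


class TestExcludedVolume:
    def test_aicg_vanishes_at_twice_sigma(self):
        e, de = excluded_volume_energy(10.0, "aicg", 0.6, 5.0)
        assert e == 0.0 and de == 0.0
        e_in, _ = excluded_volume_energy(10.0 - 1e-7, "aicg", 0.6, 5.0)
        assert abs(e_in) < 1e-10

    def test_dna_vanishes_at_sigma(self):
        e_in, _ = excluded_volume_energy(5.0 - 1e-7, "dna", 1.0, 5.0)
        assert abs(e_in) < 1e-10
        assert excluded_volume_energy(5.0, "dna", 1.0, 5.0)[0] == 0.0

    def test_aicg_value_at_sigma(self):
        e, _ = excluded_volume_energy(5.0, "aicg", 0.6, 5.0)
        assert e == pytest.approx(0.6 * (1 - 0.5**12), rel=1e-12)

    def test_derivatives(self, rng):
        for style in ("aicg", "dna"):
            for _ in range(10):
                s = rng.uniform(3, 7)
                r = rng.uniform(0.5 * s, 0.95 * s)
                _, de = excluded_volume_energy(r, style, 0.6, s)
                assert_deriv(lambda x: excluded_volume_energy(
                    x, style, 0.6, s)[0], r, de, tol=1e-4)


class TestHPSPair:
    def test_full_hydropathy_minimum_depth(self):
        """At lambda = 1 the well depth is the default 0.2 kcal/mol."""
        e, _ = hps_pair_energy(TWO16 * 6.0, 6.0, 1.0, 0.2)
        assert e == pytest.approx(-0.2, rel=1e-12)

    def test_zero_hydropathy_tail_vanishes(self):
        assert hps_pair_energy(9.0, 6.0, 0.0, 0.2)[0] == 0.0

    def test_branch_continuity(self, rng):
        for _ in range(20):
            s, lam = rng.uniform(4, 7), rng.uniform(0, 1.2)
            r0 = TWO16 * s
            e_in, _ = hps_pair_energy(r0 * (1 - 1e-9), s, lam, 0.2)
            e_out, _ = hps_pair_energy(r0 * (1 + 1e-9), s, lam, 0.2)
            assert abs(e_in - e_out) < 1e-10

    def test_derivative_both_branches(self, rng):
        for r in (5.0, 6.2, 7.5, 9.0):
            _, de = hps_pair_energy(r, 6.0, 0.7, 0.2)
            assert_deriv(lambda x: hps_pair_energy(x, 6.0, 0.7, 0.2)[0],
                         r, de)


class TestEnvironment:
    def test_printed_value(self):
        assert relative_permittivity(300.0, 0.15) == pytest.approx(
            74.911, abs=5e-4)

    def test_pure_water_limit(self):
        t = 321.0
        e_t = 249.4 - 0.788 * t + 7.20e-4 * t * t
        assert relative_permittivity(t, 0.0) == pytest.approx(e_t, rel=1e-12)

    def test_product_form(self):
        t, c = 298.0, 0.1
        e_t = 249.4 - 0.788 * t + 7.20e-4 * t**2
        a_c = 1 - 0.2551 * c + 5.151e-2 * c**2 - 6.889e-3 * c**3
        assert relative_permittivity(t, c) == pytest.approx(e_t * a_c,
                                                            rel=1e-12)

    @pytest.mark.parametrize("t,c", [(150.0, 0.1), (450.0, 0.1), (300.0, -1.0)])
    def test_out_of_range_rejected(self, t, c):
        with pytest.raises(ValueError):
            relative_permittivity(t, c)

    def test_debye_length_sqrt_scaling(self):
        lam1 = debye_length(300.0, 0.15, 74.911)
        lam4 = debye_length(300.0, 0.60, 74.911)
        assert lam4 == pytest.approx(lam1 / 2.0, rel=1e-12)

    def test_debye_length_closed_form(self):
        """Independent SI evaluation with CODATA constants."""
        t, i, er = 300.0, 0.15, 74.911
        expect = math.sqrt(1.380649e-23 * t * 8.8541878128e-12 * er
                           / (2 * 6.02214076e23 * 1.602176634e-19**2
                              * i * 1000)) * 1e10
        assert debye_length(t, i, er) == pytest.approx(expect, rel=1e-12)

    def test_debye_length_monotone_in_ionic_strength(self):
        lams = [debye_length(300.0, i, 74.911)
                for i in np.linspace(0.01, 1.0, 12)]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_zero_ionic_strength_rejected(self):
        with pytest.raises(ValueError, match="infinite screening"):
            debye_length(300.0, 0.0, 74.911)


class TestDebyeHuckel:
    def test_neutral_pair(self):
        assert debye_huckel_energy(5.0, 0.0, 1.0, 75.0, 8.0) == (0.0, 0.0)

    def test_unscreened_limit_is_coulomb(self):
        e, _ = debye_huckel_energy(7.0, 1.0, -1.0, 75.0, 1e12)
        assert e == pytest.approx(-COULOMB / (75.0 * 7.0), rel=1e-9)

    def test_derivative(self, rng):
        for _ in range(10):
            r = rng.uniform(2, 30)
            q1, q2 = rng.uniform(-2, 2, 2)
            lam = rng.uniform(3, 20)
            _, de = debye_huckel_energy(r, q1, q2, 75.0, lam)
            assert_deriv(lambda x: debye_huckel_energy(
                x, q1, q2, 75.0, lam)[0], r, de)

    def test_cutoff(self):
        assert debye_huckel_energy(40.0, 1.0, 1.0, 75.0, 8.0,
                                   r_cut=35.0) == (0.0, 0.0)


class TestMorseSplit:
    def test_at_reference(self):
        (rep, _), (attr, _) = morse_components(4.0, 2.0, 3.0, 4.0)
        assert rep == 0.0 and attr == pytest.approx(-2.0)

    def test_far_limit(self):
        (rep, _), (attr, _) = morse_components(50.0, 2.0, 3.0, 4.0)
        assert rep == 0.0 and attr == pytest.approx(0.0, abs=1e-9)

    def test_split_reconstructs_full_morse(self, rng):
        for _ in range(30):
            eps, alpha, r0 = rng.uniform(0.5, 5), rng.uniform(1, 4), \
                rng.uniform(3, 7)
            r = rng.uniform(0.5 * r0, 2.5 * r0)
            (rep, drep), (attr, dattr) = morse_components(r, eps, alpha, r0)
            full = eps * (1 - math.exp(-alpha * (r - r0))) ** 2 - eps
            assert rep + attr == pytest.approx(full, rel=1e-12, abs=1e-12)
            assert_deriv(lambda x: sum(
                v[0] for v in morse_components(x, eps, alpha, r0)), r,
                drep + dattr)

    def test_split_continuity_at_reference(self):
        for delta in (1e-8, 1e-10):
            lo = morse_components(4.0 - delta, 2.0, 3.0, 4.0)
            hi = morse_components(4.0 + delta, 2.0, 3.0, 4.0)
            assert abs(lo[0][0] - hi[0][0]) < 1e-10
            assert abs(lo[1][0] - hi[1][0]) < 1e-10


class TestAngleModulation:
    def test_plateau_and_cutoff(self):
        g = 0.3
        assert angle_modulation(0.0, g)[0] == 1.0
        assert angle_modulation(2 * g, g)[0] == pytest.approx(0.0, abs=1e-12)
        assert angle_modulation(-2.5 * g, g)[0] == 0.0

    def test_half_height_point(self):
        f, _ = angle_modulation(1.5 * 0.3, 0.3)
        assert f == pytest.approx(0.5, rel=1e-12)

    def test_continuity_at_both_knots(self):
        g = 0.25
        for knot in (g, 2 * g):
            for sgn in (1, -1):
                lo = angle_modulation(sgn * (knot - 1e-9), g)[0]
                hi = angle_modulation(sgn * (knot + 1e-9), g)[0]
                assert abs(lo - hi) < 1e-10

    def test_derivative(self, rng):
        g = 0.3
        for d in rng.uniform(-2.5 * g, 2.5 * g, 20):
            if min(abs(abs(d) - g), abs(abs(d) - 2 * g)) < 1e-4:
                continue
            _, df = angle_modulation(d, g)
            assert_deriv(lambda x: angle_modulation(x, g)[0], d, df)
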