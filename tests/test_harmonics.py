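"""Unit and property tests for the solid-harmonic term fields.

Gradients are checked against finite differences of the scalar potential
and against fully symbolic differentiation (sympy), both independent of the
recurrence-based implementation.
"""

import math

import numpy as np
import pytest

from opmsss import (
    HarmonicIndex,
    associated_legendre,
    external_term_field,
    internal_term_field,
    real_spherical_harmonic,
)
from opmsss.exceptions import SingularPointError
from opmsss.harmonics import iter_indices, n_terms


@pytest.mark.parametrize(
    "l, m, x, expected",
    [
        (1, 0, 0.5, 0.5),  # P_1^0(x) = x
        (1, 1, 0.0, -1.0),  # P_1^1(x) = -sqrt(1-x^2), Condon-Shortley sign
        # frozen from a symbolic Rodrigues-formula evaluation: P_4^2(3/10) = -10101/4000
        (4, 2, 0.3, -10101 / 4000),
    ],
)
def test_associated_legendre_values(l, m, x, expected):
    assert associated_legendre(l, m, x) == pytest.approx(expected, rel=1e-12)


def test_associated_legendre_rejects_bad_arguments():
    with pytest.raises(ValueError):
        associated_legendre(2, 3, 0.5)  # m > l
    with pytest.raises(ValueError):
        associated_legendre(2, -1, 0.5)  # negative order
    with pytest.raises(ValueError):
        associated_legendre(2, 1, 1.5)  # |x| > 1


def test_harmonic_index_invariants():
    with pytest.raises(ValueError):
        HarmonicIndex(0, 0)  # no monopole term
    with pytest.raises(ValueError):
        HarmonicIndex(2, 3)
    assert len(list(iter_indices(3))) == n_terms(3) == 15


@pytest.mark.parametrize(
    "idx, theta, phi, expected",
    [
        (HarmonicIndex(1, 0), 0.0, 1.234, math.sqrt(3 / (4 * math.pi))),
        (HarmonicIndex(2, 0), math.pi / 2, 0.0, -0.5 * math.sqrt(5 / (4 * math.pi))),
    ],
)
def test_real_harmonic_closed_forms(idx, theta, phi, expected):
    assert real_spherical_harmonic(idx, theta, phi) == pytest.approx(expected, rel=1e-12)


def test_real_harmonics_orthonormal_over_sphere():
    """Gauss-Legendre x uniform-azimuth quadrature of all pairwise products
    up to degree 4 reproduces the identity matrix."""
    l_max = 4
    n_theta, n_phi = 40, 81
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = np.linspace(0.0, 2 * math.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    weights = (w[:, None] * (2 * math.pi / n_phi)).repeat(n_phi, axis=1)
    vals = np.stack(
        [real_spherical_harmonic(idx, tt, pp) for idx in iter_indices(l_max)]
    )
    gram = np.einsum("iab,jab,ab->ij", vals, vals, weights)
    assert np.allclose(gram, np.eye(n_terms(l_max)), atol=1e-3)


def _numeric_gradient(f, p, h=1e-6):
    return np.array([(f(p + h * e) - f(p - h * e)) / (2 * h) for e in np.eye(3)])


def _potential(idx, kind):
    def f(p):
        r = np.linalg.norm(p)
        theta = math.acos(p[2] / r)
        phi = math.atan2(p[1], p[0])
        y = real_spherical_harmonic(idx, theta, phi)
        return y / r ** (idx.l + 1) if kind == "internal" else r**idx.l * y

    return f


@pytest.mark.parametrize("kind", ["internal", "external"])
@pytest.mark.parametrize("idx", [HarmonicIndex(*lm) for lm in [(1, 0), (2, -1), (3, 2), (5, -4), (7, 0), (8, 8)]])
def test_term_fields_match_potential_gradient(idx, kind, rng):
    """The analytic field equals minus the finite-difference gradient of the
    corresponding solid-harmonic potential at random points."""
    field = internal_term_field if kind == "internal" else external_term_field
    for _ in range(4):
        p = rng.normal(size=3)
        p *= (0.5 + rng.uniform()) / np.linalg.norm(p)
        g = _numeric_gradient(_potential(idx, kind), p)
        b = field(idx, p)
        assert np.linalg.norm(b + g) <= 1e-5 * np.linalg.norm(g)


def test_term_fields_match_symbolic_gradient():
    """Cross-check against fully symbolic differentiation of the real solid
    harmonics (independent of the Legendre recurrences used internally)."""
    sympy = pytest.importorskip("sympy")
    x, y, z = sympy.symbols("x y z", real=True)
    r = sympy.sqrt(x**2 + y**2 + z**2)
    theta = sympy.acos(z / r)
    phi = sympy.atan2(y, x)
    pts = np.random.default_rng(3).normal(size=(3, 3))
    for l, m in [(1, 1), (2, -2), (3, 0), (4, 3)]:
        ylm = sympy.Znm(l, m, theta, phi)  # sympy's real spherical harmonic
        for kind, pot in [("internal", ylm / r ** (l + 1)), ("external", r**l * ylm)]:
            grad = [sympy.diff(sympy.expand_func(pot), v) for v in (x, y, z)]
            fn = sympy.lambdify((x, y, z), grad, "numpy")
            field = internal_term_field if kind == "internal" else external_term_field
            for p in pts:
                expected = -np.real(np.array(fn(*p), dtype=complex))
                got = field(HarmonicIndex(l, m), p)
                # sympy's Znm uses (-1)^m relative sign for m<0 in some versions;
                # compare up to the overall sign of the whole term
                s = 1.0 if np.dot(expected, got) >= 0 else -1.0
                assert np.allclose(s * got, expected, rtol=1e-8, atol=1e-12)


@pytest.mark.parametrize("idx", [HarmonicIndex(1, 0), HarmonicIndex(3, -2), HarmonicIndex(6, 5)])
@pytest.mark.parametrize("kind", ["internal", "external"])
def test_term_fields_divergence_and_curl_free(idx, kind, rng):
    """Central-difference divergence and curl vanish at random points."""
    field = internal_term_field if kind == "internal" else external_term_field
    h = 1e-6
    for _ in range(3):
        p = rng.normal(size=3)
        p *= (0.8 + rng.uniform()) / np.linalg.norm(p)
        jac = np.empty((3, 3))
        for j, e in enumerate(np.eye(3)):
            jac[:, j] = (field(idx, p + h * e) - field(idx, p - h * e)) / (2 * h)
        # floor guards the uniform-field case (zero Jacobian up to rounding)
        tol = 1e-5 * np.linalg.norm(jac) + 1e-9 * np.linalg.norm(field(idx, p))
        assert abs(np.trace(jac)) <= tol  # divergence
        curl = np.array([jac[2, 1] - jac[1, 2], jac[0, 2] - jac[2, 0], jac[1, 0] - jac[0, 1]])
        assert np.linalg.norm(curl) <= tol


def test_internal_field_power_law_decay(rng):
    """Internal term magnitudes fall as r^-(l+2): for l=1 the ratio between
    r and 2r is exactly 8; log-log slopes match over a decade for higher l."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    b1 = np.linalg.norm(internal_term_field(HarmonicIndex(1, 0), 0.3 * u))
    b2 = np.linalg.norm(internal_term_field(HarmonicIndex(1, 0), 0.6 * u))
    assert b1 / b2 == pytest.approx(8.0, rel=1e-6)
    for idx in [HarmonicIndex(3, 1), HarmonicIndex(5, -3)]:
        radii = np.logspace(-1, 0, 8)
        mags = [np.linalg.norm(internal_term_field(idx, r * u)) for r in radii]
        slope = np.polyfit(np.log(radii), np.log(mags), 1)[0]
        assert slope == pytest.approx(-(idx.l + 2), abs=1e-8)


def test_external_field_power_law_growth(rng):
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    for idx in [HarmonicIndex(2, 0), HarmonicIndex(2, -2), HarmonicIndex(4, 3)]:
        b1 = np.linalg.norm(external_term_field(idx, 0.4 * u))
        b2 = np.linalg.norm(external_term_field(idx, 0.8 * u))
        assert b2 / b1 == pytest.approx(2.0 ** (idx.l - 1), rel=1e-10)


def test_external_degree_one_terms_are_uniform_fields(rng):
    """l=1 external terms are constant fields along z, x and y."""
    pts = rng.normal(size=(5, 3))
    for m, axis in [(0, 2), (1, 0), (-1, 1)]:
        b = external_term_field(HarmonicIndex(1, m), pts)
        assert np.allclose(b, b[0], rtol=0, atol=1e-12 * np.linalg.norm(b[0]))
        direction = np.abs(b[0]) / np.linalg.norm(b[0])
        assert direction[axis] == pytest.approx(1.0, abs=1e-12)


def test_internal_degree_one_matches_point_dipole_direction(rng):
    """The (l=1, m=0) internal pattern is the field of a z-oriented point
    magnetic dipole at the origin (checked directionally at random points)."""
    from opmsss import DipoleSource, dipole_field

    src = DipoleSource(position=np.zeros(3), moment=[0, 0, 1.0], frequency=10, kind="internal")
    for _ in range(5):
        p = rng.normal(size=3)
        b_term = internal_term_field(HarmonicIndex(1, 0), p)
        b_dip = dipole_field(src, p)
        cos = np.dot(b_term, b_dip) / (np.linalg.norm(b_term) * np.linalg.norm(b_dip))
        assert abs(cos) == pytest.approx(1.0, abs=1e-10)


def test_internal_field_singular_at_origin():
    with pytest.raises(SingularPointError):
        internal_term_field(HarmonicIndex(1, 0), np.zeros(3))


def test_on_axis_evaluation_is_finite_and_smooth():
    """Points on the z-axis (degenerate spherical coordinates) still get the
    correct field, matching a point nudged slightly off-axis."""
    for idx in [HarmonicIndex(2, 1), HarmonicIndex(3, 0), HarmonicIndex(4, -1)]:
        on = internal_term_field(idx, [0.0, 0.0, 0.5])
        near = internal_term_field(idx, [1e-7, 0.0, 0.5])
        assert np.all(np.isfinite(on))
        assert np.allclose(on, near, rtol=1e-4, atol=1e-4 * np.linalg.norm(near))
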