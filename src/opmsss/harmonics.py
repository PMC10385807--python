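"""Real solid harmonics and the magnetic field pattern of each multipole term.

In a source-free region the magnetic scalar potential obeys Laplace's
equation and decomposes into *internal* terms, proportional to
``Y_lm(theta, phi) / r**(l+1)`` (singular at the expansion origin, hence
describing sources inside the array), and *external* terms, proportional to
``r**l * Y_lm(theta, phi)`` (divergent at infinity, hence describing distant
sources).  The field of each term is the (negative) gradient of that
potential.

Conventions used throughout the package
---------------------------------------
* Associated Legendre functions carry the Condon-Shortley phase ``(-1)**m``
  (this is what :func:`scipy.special.lpmv` returns).
* Harmonics are *real valued*: the ``m = 0`` harmonic is unchanged, and for
  ``m != 0`` the usual ``sqrt(2) * cos/sin`` combinations of the complex
  pair are used (``cos`` for ``m > 0``, ``sin`` for ``m < 0``).  The set is
  orthonormal over the unit sphere.
* Physical constants (``mu_0`` and the overall minus sign of
  ``B = -mu_0 grad V``) are dropped: basis columns are normalised later, so
  only the *shape* of each term field matters.  The functions below return
  ``-grad`` of the solid harmonic itself.
* Angular derivatives are evaluated analytically through Legendre
  recurrences; finite differences appear only in the test suite as an
  independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.special import lpmv

from .exceptions import SingularPointError

__all__ = [
    "HarmonicIndex",
    "iter_indices",
    "n_terms",
    "associated_legendre",
    "real_spherical_harmonic",
    "internal_term_field",
    "external_term_field",
]


@dataclass(frozen=True, order=True)
class HarmonicIndex:
    """Degree/order pair ``(l, m)`` of one multipole term.

    ``l >= 1`` (there is no magnetic monopole term) and ``|m| <= l``.
    """

    l: int
    m: int

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError(f"degree l must be >= 1, got {self.l}")
        if abs(self.m) > self.l:
            raise ValueError(f"order m must satisfy |m| <= l, got (l={self.l}, m={self.m})")


def iter_indices(l_max: int) -> Iterator[HarmonicIndex]:
    """All indices up to degree ``l_max`` in l-major order, m from -l to +l."""
    if l_max < 1:
        raise ValueError(f"l_max must be >= 1, got {l_max}")
    for l in range(1, l_max + 1):
        for m in range(-l, l + 1):
            yield HarmonicIndex(l, m)


def n_terms(l_max: int) -> int:
    """Number of (l, m) terms with 1 <= l <= l_max, i.e. ``(l_max+1)**2 - 1``."""
    return (l_max + 1) ** 2 - 1


def associated_legendre(l: int, m: int, x):
    """Associated Legendre function ``P_l^m(x)`` with Condon-Shortley phase.

    Parameters
    ----------
    l, m
        Degree and (non-negative) order, ``0 <= m <= l``.
    x
        Argument(s) in ``[-1, 1]``; scalars or arrays.
    """
    if not (0 <= m <= l):
        raise ValueError(f"need 0 <= m <= l, got (l={l}, m={m})")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-15):
        raise ValueError("argument of P_l^m must lie in [-1, 1]")
    out = lpmv(m, l, np.clip(x, -1.0, 1.0))
    return out if out.ndim else float(out)


def _norm_constant(l: int, m_abs: int) -> float:
    """Full normalisation so the real harmonics integrate to 1 over the sphere."""
    return math.sqrt(
        (2 * l + 1) / (4.0 * math.pi) * math.factorial(l - m_abs) / math.factorial(l + m_abs)
    )


def real_spherical_harmonic(idx: HarmonicIndex, theta, phi):
    """Real, fully normalised spherical harmonic ``Y_lm(theta, phi)``.

    ``theta`` is the polar angle (radians, ``[0, pi]``), ``phi`` the azimuth.
    Scalars or broadcastable arrays are accepted.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > math.pi + 1e-12):
        raise ValueError("polar angle theta must lie in [0, pi]")
    l, m = idx.l, idx.m
    m_abs = abs(m)
    p = lpmv(m_abs, l, np.cos(theta))
    c = _norm_constant(l, m_abs)
    if m == 0:
        out = c * p
    elif m > 0:
        out = math.sqrt(2.0) * c * p * np.cos(m_abs * phi)
    else:
        out = math.sqrt(2.0) * c * p * np.sin(m_abs * phi)
    return out if np.ndim(out) else float(out)


# --- analytic gradients ----------------------------------------------------

def _to_spherical(vec: np.ndarray):
    """Cartesian offsets -> (r, theta, phi) plus the local unit vectors.

    Points lying numerically on the +-z axis are nudged off the axis by a
    relative 1e-7 in x so the spherical-coordinate frame stays defined (a
    smaller offset would be rounded away inside cos(theta)); the relative
    error this introduces is O(1e-7), far below every tolerance used
    downstream — the field itself is smooth across the axis, only the
    coordinates degenerate there.
    """
    vec = np.array(vec, dtype=float, copy=True)
    r = np.linalg.norm(vec, axis=-1)
    rho = np.hypot(vec[..., 0], vec[..., 1])
    on_axis = (rho < 1e-7 * r) & (r > 0)
    if np.any(on_axis):
        vec[..., 0] = np.where(on_axis, vec[..., 0] + 1e-7 * r, vec[..., 0])
        r = np.linalg.norm(vec, axis=-1)
    theta = np.arccos(np.clip(vec[..., 2] / np.where(r == 0, 1.0, r), -1.0, 1.0))
    phi = np.arctan2(vec[..., 1], vec[..., 0])
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    r_hat = np.stack([st * cp, st * sp, ct], axis=-1)
    th_hat = np.stack([ct * cp, ct * sp, -st], axis=-1)
    ph_hat = np.stack([-sp, cp, np.zeros_like(sp)], axis=-1)
    return r, theta, phi, r_hat, th_hat, ph_hat


def _angular_factors(idx: HarmonicIndex, theta: np.ndarray, phi: np.ndarray):
    """Return ``(Y, dY/dtheta, (1/sin theta) dY/dphi)`` for the real harmonic.

    ``dP/dtheta`` uses the recurrence
    ``sin(theta) * dP_l^m/dtheta = l*x*P_l^m - (l+m)*P_{l-1}^m`` with
    ``x = cos(theta)``; the ``m P_l^m / sin(theta)`` factor is regular for
    ``m >= 1`` because ``P_l^m ~ sin(theta)**m`` near the poles.
    """
    l, m = idx.l, idx.m
    m_abs = abs(m)
    x = np.cos(theta)
    st = np.sin(theta)
    st_safe = np.where(st < 1e-300, 1.0, st)
    p = lpmv(m_abs, l, x)
    p_lm1 = lpmv(m_abs, l - 1, x) if l - 1 >= m_abs else np.zeros_like(x)
    dp_dtheta = (l * x * p - (l + m_abs) * p_lm1) / st_safe
    c = _norm_constant(l, m_abs) * (math.sqrt(2.0) if m != 0 else 1.0)
    if m == 0:
        trig, dtrig = np.ones_like(phi), np.zeros_like(phi)
    elif m > 0:
        trig, dtrig = np.cos(m_abs * phi), -m_abs * np.sin(m_abs * phi)
    else:
        trig, dtrig = np.sin(m_abs * phi), m_abs * np.cos(m_abs * phi)
    y = c * p * trig
    dy_dtheta = c * dp_dtheta * trig
    dy_dphi_over_st = c * (p / st_safe) * dtrig
    return y, dy_dtheta, dy_dphi_over_st


def internal_term_field(idx: HarmonicIndex, point, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Field pattern ``-grad[ Y_lm / r**(l+1) ]`` of one internal term.

    ``point`` may be a single 3-vector or a ``(..., 3)`` stack of points
    (metres); the result has the same shape.  Amplitude scale is arbitrary.
    Raises :class:`SingularPointError` at the expansion origin, where the
    internal potential diverges.
    """
    vec = np.asarray(point, dtype=float) - np.asarray(origin, dtype=float)
    single = vec.ndim == 1
    vec = np.atleast_2d(vec)
    r, theta, phi, r_hat, th_hat, ph_hat = _to_spherical(vec)
    if np.any(r == 0):
        raise SingularPointError("internal term field requested at the expansion origin")
    y, dy_dth, dy_dph_st = _angular_factors(idx, theta, phi)
    l = idx.l
    scale = r ** -(l + 2)
    b = (
        ((l + 1) * y * scale)[..., None] * r_hat
        - (dy_dth * scale)[..., None] * th_hat
        - (dy_dph_st * scale)[..., None] * ph_hat
    )
    return b[0] if single else b


def external_term_field(idx: HarmonicIndex, point, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Field pattern ``-grad[ r**l * Y_lm ]`` of one external term.

    For ``l = 1`` the result is spatially uniform (the homogeneous background
    field along z, x or y for ``m = 0, +1, -1``).
    """
    vec = np.asarray(point, dtype=float) - np.asarray(origin, dtype=float)
    single = vec.ndim == 1
    vec = np.atleast_2d(vec)
    r, theta, phi, r_hat, th_hat, ph_hat = _to_spherical(vec)
    y, dy_dth, dy_dph_st = _angular_factors(idx, theta, phi)
    l = idx.l
    scale = r ** (l - 1)
    b = (
        -(l * y * scale)[..., None] * r_hat
        - (dy_dth * scale)[..., None] * th_hat
        - (dy_dph_st * scale)[..., None] * ph_hat
    )
    return b[0] if single else b
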