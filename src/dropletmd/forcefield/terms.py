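"""Scalar energy terms with analytic derivatives.

Every function returns ``(energy, d_energy_d_coordinate)`` so forces can be
assembled by the chain rule.  These scalar forms are the reference
implementations; the engine evaluates vectorized versions of the same
expressions over term and pair lists.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.interpolate import CubicSpline

from ..constants import COULOMB, KB
from ..params import FlexTable

log = logging.getLogger(__name__)

TWO_16 = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# bonds
# ---------------------------------------------------------------------------

def bond_energy(b: float, style: str, params: tuple) -> tuple[float, float]:
    """Bond energy: harmonic k(b-b0)^2 or quartic k2(b-b0)^2 + k4(b-b0)^4."""
    if b <= 0:
        raise ValueError("bond length must be positive")
    if style == "harmonic":
        k, b0 = params
        d = b - b0
        return k * d * d, 2.0 * k * d
    if style == "quartic":
        k2, k4, b0 = params
        d = b - b0
        return k2 * d * d + k4 * d**4, 2.0 * k2 * d + 4.0 * k4 * d**3
    raise ValueError(f"unknown bond style {style!r}")


# ---------------------------------------------------------------------------
# statistical flexible tables
# ---------------------------------------------------------------------------

class FlexibleAngleSpline:
    """Energy spline for a statistical bond-angle table.

    The tabulated energy -kB T ln(P(theta)/sin theta) is interpolated with a
    clamped cubic spline, so a table with P proportional to sin(theta) gives
    an exactly constant energy and zero force.  Angles outside the table
    support are clamped to the boundary (with a logged warning): extreme
    geometry should not abort a simulation.
    """

    def __init__(self, table: FlexTable, kT: float):
        table.validate()
        e = -kT * np.log(table.prob / np.sin(table.grid))
        self._lo = float(table.grid[0])
        self._hi = float(table.grid[-1])
        self._spline = CubicSpline(table.grid, e, bc_type="clamped")
        self._deriv = self._spline.derivative()

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        clipped = np.clip(theta, self._lo, self._hi)
        if np.any(clipped != theta):
            log.warning("angle outside flexible-table support; clamped")
        e = self._spline(clipped)
        de = np.where((theta > self._lo) & (theta < self._hi),
                      self._deriv(clipped), 0.0)
        if e.ndim == 0:
            return float(e), float(de)
        return e, de


class FlexibleDihedralSpline:
    """Periodic energy spline -kB T ln P(phi) for a dihedral table.

    The table grid must span one full period (first and last grid points one
    period apart with equal probability).
    """

    def __init__(self, table: FlexTable, kT: float):
        table.validate()
        if not math.isclose(table.grid[-1] - table.grid[0], 2 * math.pi,
                            rel_tol=1e-9):
            raise ValueError("dihedral table grid must span 2*pi")
        if not math.isclose(table.prob[0], table.prob[-1], rel_tol=1e-9):
            raise ValueError("dihedral table must be periodic")
        e = -kT * np.log(table.prob)
        self._lo = float(table.grid[0])
        self._spline = CubicSpline(table.grid, e, bc_type="periodic")
        self._deriv = self._spline.derivative()

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        wrapped = self._lo + np.mod(phi - self._lo, 2 * math.pi)
        e = self._spline(wrapped)
        de = self._deriv(wrapped)
        if e.ndim == 0:
            return float(e), float(de)
        return e, de


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def angle_energy(x: float, style: str, params) -> tuple[float, float]:
    """Angle-class energy.

    ``flexible``: statistical table (``params`` is a FlexibleAngleSpline);
    ``gaussian_13``: Gaussian well on the 1-3 distance, x is r13 in Å;
    ``harmonic``: k(theta - theta0)^2.
    """
    if style == "flexible":
        if not 0.0 < x < math.pi:
            raise ValueError("angle must lie in (0, pi)")
        return params(x)
    if style == "gaussian_13":
        eps, r0, w = params
        if x <= 0:
            raise ValueError("1-3 distance must be positive")
        g = math.exp(-((x - r0) ** 2) / (2.0 * w * w))
        return -eps * g, eps * (x - r0) / (w * w) * g
    if style == "harmonic":
        k, th0 = params
        if not 0.0 < x < math.pi:
            raise ValueError("angle must lie in (0, pi)")
        d = x - th0
        return k * d * d, 2.0 * k * d
    raise ValueError(f"unknown angle style {style!r}")


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def _wrap_pi(x: float) -> float:
    return (x + math.pi) % (2.0 * math.pi) - math.pi


def dihedral_energy(phi: float, style: str, params) -> tuple[float, float]:
    """Dihedral energy on the periodic domain (-pi, pi].

    ``flexible``: statistical table (params is a FlexibleDihedralSpline);
    ``gaussian``: -eps exp(-dphi^2/2 sigma^2) with minimum-image dphi;
    ``periodic``: sum_n k_n [1 + cos(n (phi - phi0))].
    """
    if style == "flexible":
        return params(phi)
    if style == "gaussian":
        eps, phi0, sig = params
        d = _wrap_pi(phi - phi0)
        g = math.exp(-(d * d) / (2.0 * sig * sig))
        return -eps * g, eps * d / (sig * sig) * g
    if style == "periodic":
        terms = params if isinstance(params[0], (tuple, list, np.ndarray)) \
            else (params,)
        e = de = 0.0
        for k, phi0, n in terms:
            e += k * (1.0 + math.cos(n * (phi - phi0)))
            de += -k * n * math.sin(n * (phi - phi0))
        return e, de
    raise ValueError(f"unknown dihedral style {style!r}")


# ---------------------------------------------------------------------------
# nonbonded pair terms
# ---------------------------------------------------------------------------

def go_contact_energy(r: float, sigma: float, eps: float) -> tuple[float, float]:
    """12-10 structure-based contact: eps [5 (s/r)^12 - 6 (s/r)^10]."""
    if r <= 0:
        raise ValueError("distance must be positive")
    s = sigma / r
    s10 = s**10
    s12 = s**12
    e = eps * (5.0 * s12 - 6.0 * s10)
    de = eps * (-60.0 * s12 + 60.0 * s10) / r
    return e, de


def excluded_volume_energy(r: float, style: str, eps: float,
                           sigma: float) -> tuple[float, float]:
    """Excluded-volume repulsion.

    ``aicg``: eps (s/r)^12 shifted by -(1/2)^12 eps, zero for r >= 2 sigma;
    ``dna``: eps [(s/r)^12 - 2 (s/r)^6] + eps for r < sigma, else zero.
    Both vanish continuously at their cutoff.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    if style == "aicg":
        if r >= 2.0 * sigma:
            return 0.0, 0.0
        s = sigma / r
        e = eps * s**12 - eps * 0.5**12
        return e, -12.0 * eps * s**12 / r
    if style == "dna":
        if r >= sigma:
            return 0.0, 0.0
        s = sigma / r
        e = eps * (s**12 - 2.0 * s**6) + eps
        return e, eps * (-12.0 * s**12 + 12.0 * s**6) / r
    raise ValueError(f"unknown excluded-volume style {style!r}")


def hps_pair_energy(r: float, sigma: float, lam: float,
                    eps: float) -> tuple[float, float]:
    """Hydropathy-scale pair potential.

    Below the Lennard-Jones minimum 2^(1/6) sigma the energy is
    E_LJ + (1 - lambda) eps; beyond it, lambda * E_LJ.  Continuous at the
    switch where E_LJ = -eps.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    s6 = (sigma / r) ** 6
    elj = 4.0 * eps * (s6 * s6 - s6)
    delj = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
    if r <= TWO_16 * sigma:
        return elj + (1.0 - lam) * eps, delj
    return lam * elj, lam * delj


def debye_huckel_energy(r: float, qi: float, qj: float, eps_r: float,
                        lambda_d: float, r_cut: float | None = None
                        ) -> tuple[float, float]:
    """Screened Coulomb pair energy in kcal/mol (charges in e)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if r_cut is not None and r >= r_cut:
        return 0.0, 0.0
    e = COULOMB * qi * qj * math.exp(-r / lambda_d) / (eps_r * r)
    de = -e * (1.0 / r + 1.0 / lambda_d)
    return e, de


# ---------------------------------------------------------------------------
# DNA base-interaction building blocks
# ---------------------------------------------------------------------------

def morse_components(r: float, eps: float, alpha: float, r0: float
                     ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Repulsive / attractive split of the Morse potential.

    Returns ((rep, d_rep), (attr, d_attr)); rep is the full Morse plus eps
    restricted to r < r0, attr is the flat -eps inside r0 and the Morse tail
    outside.  rep + attr reproduces the full Morse everywhere.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    ex = math.exp(-alpha * (r - r0))
    full = eps * (1.0 - ex) ** 2 - eps
    dfull = 2.0 * eps * alpha * ex * (1.0 - ex)
    if r < r0:
        return (full + eps, dfull), (-eps, 0.0)
    return (0.0, 0.0), (full, dfull)


def angle_modulation(dtheta: float, gamma: float) -> tuple[float, float]:
    """Bell-shaped angular gate in [0, 1] with half-width gamma.

    1 inside |dtheta| < gamma, 1 - cos^2(pi dtheta / 2 gamma) on
    gamma <= |dtheta| <= 2 gamma, 0 beyond; continuous at both knots.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = abs(dtheta)
    if a < gamma:
        return 1.0, 0.0
    if a > 2.0 * gamma:
        return 0.0, 0.0
    u = math.pi * dtheta / (2.0 * gamma)
    f = 1.0 - math.cos(u) ** 2
    df = (math.pi / (2.0 * gamma)) * math.sin(2.0 * u)
    return f, df


def kbt(temperature: float) -> float:
    return KB * temperature
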