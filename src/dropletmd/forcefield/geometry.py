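"""Vectorized internal-coordinate values and gradients.

All functions accept arrays of shape (n, 3) and return the internal
coordinate plus its gradient with respect to each participating site.
Displacement vectors are taken with the minimum-image convention when a box
is given (orthorhombic boxes only).
"""

from __future__ import annotations

import numpy as np

_TINY = 1e-12


def minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def bond_vectors(xi: np.ndarray, xj: np.ndarray,
                 box: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-image r_ij = x_j - x_i and its norm."""
    v = minimum_image(np.atleast_2d(xj) - np.atleast_2d(xi), box)
    return v, np.linalg.norm(v, axis=-1)


def angle_value_grad(xi, xj, xk, box=None):
    """Bond angle at j for triples (i, j, k); returns theta, g_i, g_j, g_k."""
    u, nu = bond_vectors(xj, xi, box)
    v, nv = bond_vectors(xj, xk, box)
    nu = np.maximum(nu, _TINY)
    nv = np.maximum(nv, _TINY)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos = np.clip(np.sum(uh * vh, axis=-1), -1.0, 1.0)
    theta = np.arccos(cos)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, _TINY))
    gi = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
    gk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
    gj = -gi - gk
    return theta, gi, gj, gk


def vector_angle_grad(xa, xb, xc, xd, box=None):
    """Angle between u = b - a and v = d - c; gradients w.r.t. all four."""
    u, nu = bond_vectors(xa, xb, box)
    v, nv = bond_vectors(xc, xd, box)
    nu = np.maximum(nu, _TINY)
    nv = np.maximum(nv, _TINY)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos = np.clip(np.sum(uh * vh, axis=-1), -1.0, 1.0)
    theta = np.arccos(cos)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, _TINY))
    gb = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
    gd = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
    return theta, -gb, gb, -gd, gd


def dihedral_value_grad(xi, xj, xk, xl, box=None):
    """Torsion for quadruples (i, j, k, l); returns phi and four gradients.

    Blondel-Karplus form: singular only when three sites are collinear.
    """
    b1, _ = bond_vectors(xi, xj, box)
    b2, nb2 = bond_vectors(xj, xk, box)
    b3, _ = bond_vectors(xk, xl, box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.maximum(nb2, _TINY)
    b2h = b2 / nb2[:, None]
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2h, axis=-1)
    phi = np.arctan2(y, x)

    n1sq = np.maximum(np.sum(n1 * n1, axis=-1), _TINY)
    n2sq = np.maximum(np.sum(n2 * n2, axis=-1), _TINY)
    gi = -(nb2 / n1sq)[:, None] * n1
    gl = (nb2 / n2sq)[:, None] * n2
    t = (np.sum(b1 * b2, axis=-1) / (nb2 * nb2))[:, None]
    s = (np.sum(b3 * b2, axis=-1) / (nb2 * nb2))[:, None]
    gj = -(1.0 + t) * gi + s * gl
    gk = t * gi - (1.0 + s) * gl
    return phi, gi, gj, gk, gl


def wrap_angle(x: np.ndarray) -> np.ndarray:
    """Wrap angular differences into (-pi, pi]."""
    return x - 2.0 * np.pi * np.round(x / (2.0 * np.pi))
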