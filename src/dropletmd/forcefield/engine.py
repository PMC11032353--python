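"""Assembly of per-class energies and analytic forces.

Nonbonded pair loops run in numba kernels over the per-class neighbor
lists; bonded, base-interaction and protein-DNA terms are evaluated with
vectorized numpy over the style-grouped term blocks.  Forces are
accumulated in a fixed global order (term blocks in declaration order,
pairs in lexicographic index order), so results do not depend on any
domain partition.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..constants import COULOMB, KB
from ..params import ParameterSet
from ..topology import DNA_KINDS, ParticleKind, Topology
from . import environment, geometry
from .terms import (FlexibleAngleSpline, FlexibleDihedralSpline, TWO_16,
                    angle_modulation, morse_components)

ENERGY_CLASSES = ("bond", "angle", "dihedral", "go", "exv", "hps", "ele",
                  "dna_stack", "dna_pair", "dna_cross", "pwmcos")


# ---------------------------------------------------------------------------
# numba pair kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _minimg(d: float, box: float) -> float:
    if box > 0.0:
        d -= box * round(d / box)
    return d


@njit(cache=True)
def _hps_kernel(coords, bx, by, bz, pi, pj, sig, lam, eps, rc2, forces):
    e = 0.0
    for n in range(pi.shape[0]):
        i, j = pi[n], pj[n]
        dx = _minimg(coords[j, 0] - coords[i, 0], bx)
        dy = _minimg(coords[j, 1] - coords[i, 1], by)
        dz = _minimg(coords[j, 2] - coords[i, 2], bz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        r = math.sqrt(r2)
        s6 = (sig[n] * sig[n] / r2) ** 3
        elj = 4.0 * eps * (s6 * s6 - s6)
        delj = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
        if r2 <= 2.0 ** (1.0 / 3.0) * sig[n] * sig[n]:
            e += elj + (1.0 - lam[n]) * eps
            de = delj
        else:
            e += lam[n] * elj
            de = lam[n] * delj
        f = -de / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
    return e


@njit(cache=True)
def _ele_kernel(coords, bx, by, bz, pi, pj, qq, pref, lam_d, rc2, forces):
    e = 0.0
    for n in range(pi.shape[0]):
        i, j = pi[n], pj[n]
        dx = _minimg(coords[j, 0] - coords[i, 0], bx)
        dy = _minimg(coords[j, 1] - coords[i, 1], by)
        dz = _minimg(coords[j, 2] - coords[i, 2], bz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        r = math.sqrt(r2)
        epair = pref * qq[n] * math.exp(-r / lam_d) / r
        e += epair
        de = -epair * (1.0 / r + 1.0 / lam_d)
        f = -de / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
    return e


@njit(cache=True)
def _exv_kernel(coords, bx, by, bz, pi, pj, sig, styles, eps_a, eps_d, rc2,
                forces):
    # styles: 0 = shifted r^-12 (cutoff 2 sigma), 1 = DNA form (cutoff sigma)
    e = 0.0
    for n in range(pi.shape[0]):
        i, j = pi[n], pj[n]
        dx = _minimg(coords[j, 0] - coords[i, 0], bx)
        dy = _minimg(coords[j, 1] - coords[i, 1], by)
        dz = _minimg(coords[j, 2] - coords[i, 2], bz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        r = math.sqrt(r2)
        s = sig[n]
        if styles[n] == 0:
            if r >= 2.0 * s:
                continue
            sr12 = (s * s / r2) ** 6
            e += eps_a * sr12 - eps_a * 0.5 ** 12
            de = -12.0 * eps_a * sr12 / r
        else:
            if r >= s:
                continue
            sr6 = (s * s / r2) ** 3
            e += eps_d * (sr6 * sr6 - 2.0 * sr6) + eps_d
            de = eps_d * (-12.0 * sr6 * sr6 + 12.0 * sr6) / r
        f = -de / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
    return e


@njit(cache=True)
def _go_kernel(coords, bx, by, bz, pi, pj, sig, eps, forces):
    e = 0.0
    for n in range(pi.shape[0]):
        i, j = pi[n], pj[n]
        dx = _minimg(coords[j, 0] - coords[i, 0], bx)
        dy = _minimg(coords[j, 1] - coords[i, 1], by)
        dz = _minimg(coords[j, 2] - coords[i, 2], bz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            continue
        r = math.sqrt(r2)
        s2 = sig[n] * sig[n] / r2
        s10 = s2 ** 5
        s12 = s2 ** 6
        e += eps[n] * (5.0 * s12 - 6.0 * s10)
        de = eps[n] * (-60.0 * s12 + 60.0 * s10) / r
        f = -de / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
    return e


@njit(cache=True)
def _bond_kernel(coords, bx, by, bz, pi, pj, k2, k4, b0, forces):
    # quartic term with k4 = 0 reduces to the harmonic bond
    e = 0.0
    for n in range(pi.shape[0]):
        i, j = pi[n], pj[n]
        dx = _minimg(coords[j, 0] - coords[i, 0], bx)
        dy = _minimg(coords[j, 1] - coords[i, 1], by)
        dz = _minimg(coords[j, 2] - coords[i, 2], bz)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - b0[n]
        e += k2[n] * d * d + k4[n] * d ** 4
        de = 2.0 * k2[n] * d + 4.0 * k4[n] * d ** 3
        f = -de / r
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
    return e


# ---------------------------------------------------------------------------
# per-particle parameter tables and pair routing
# ---------------------------------------------------------------------------

def _particle_tables(topology: Topology, params: ParameterSet) -> dict:
    """Per-particle sigma/lambda/exv-sigma arrays resolved from the tables."""
    n = topology.n_particles
    sig_hps = np.zeros(n)
    lam = np.zeros(n)
    sig_exv = np.zeros(n)
    is_dna = np.isin(topology.kind, [int(k) for k in DNA_KINDS])
    for i in range(n):
        c = str(topology.code[i])
        if is_dna[i]:
            key = "P" if topology.kind[i] == int(ParticleKind.DNA_PHOSPHATE) \
                else ("S" if topology.kind[i] == int(ParticleKind.DNA_SUGAR) else c)
            sig_exv[i] = params.dna.exv_sigma[key]
        else:
            sig_hps[i] = params.hps.sigma.get(c, 6.0)
            lam[i] = params.hps.lam.get(c, 0.5)
            sig_exv[i] = params.aicg.sigma.get(c, 5.0)
    return {
        "sig_hps": sig_hps, "lam": lam, "sig_exv": sig_exv,
        "is_dna": is_dna,
        "is_ordered": topology.kind == int(ParticleKind.ORDERED_PROTEIN),
        "is_protein": ~is_dna,
        "charge": topology.charge.astype(np.float64),
    }


def _route_cache(topology: Topology, params: ParameterSet, nlists) -> dict:
    """Split class lists into evaluation routes with per-pair parameters.

    HPS covers protein pairs with at least one disordered partner (full
    potential including its own repulsion); pairs of two folded beads and
    anything involving DNA fall back to the excluded-volume class (with the
    DNA functional form when both sites are DNA).  Electrostatics runs over
    the charged-pair list regardless of kind.
    """
    tab = _particle_tables(topology, params)
    cache: dict = {"tables": tab}

    hp = nlists.pairs["hps"]
    if len(hp):
        i, j = hp[:, 0], hp[:, 1]
        m = tab["is_protein"][i] & tab["is_protein"][j] \
            & ~(tab["is_ordered"][i] & tab["is_ordered"][j])
        hi, hj = i[m], j[m]
        cache["hps"] = (hi, hj,
                        0.5 * (tab["sig_hps"][hi] + tab["sig_hps"][hj]),
                        0.5 * (tab["lam"][hi] + tab["lam"][hj]))
    else:
        z = np.empty(0, dtype=np.int64)
        cache["hps"] = (z, z, np.empty(0), np.empty(0))

    ev = nlists.pairs["exv"]
    if len(ev):
        i, j = ev[:, 0], ev[:, 1]
        hps_route = tab["is_protein"][i] & tab["is_protein"][j] \
            & ~(tab["is_ordered"][i] & tab["is_ordered"][j])
        m = ~hps_route
        ei, ej = i[m], j[m]
        style = (tab["is_dna"][ei] & tab["is_dna"][ej]).astype(np.int8)
        cache["exv"] = (ei, ej,
                        0.5 * (tab["sig_exv"][ei] + tab["sig_exv"][ej]),
                        style)
    else:
        z = np.empty(0, dtype=np.int64)
        cache["exv"] = (z, z, np.empty(0), np.empty(0, dtype=np.int8))

    el = nlists.pairs["ele"]
    if len(el):
        i, j = el[:, 0], el[:, 1]
        cache["ele"] = (i.copy(), j.copy(), tab["charge"][i] * tab["charge"][j])
    else:
        z = np.empty(0, dtype=np.int64)
        cache["ele"] = (z, z, np.empty(0))
    return cache


def _splines(params: ParameterSet, kT: float) -> dict:
    cache = getattr(params, "_spline_cache", None)
    if cache is None or cache.get("kT") != kT:
        cache = {"kT": kT, "angle": {}, "dihedral": {}}
        for key, tab in params.flex_angle.items():
            cache["angle"][key] = FlexibleAngleSpline(tab, kT)
        for key, tab in params.flex_dihedral.items():
            cache["dihedral"][key] = FlexibleDihedralSpline(tab, kT)
        params._spline_cache = cache
    return cache


# ---------------------------------------------------------------------------
# bonded terms (vectorized numpy)
# ---------------------------------------------------------------------------

def _eval_bonds(topology, coords, box, forces) -> float:
    bx, by, bz = (box if box is not None else (0.0, 0.0, 0.0))
    e = 0.0
    for blk in topology.bonds:
        if not len(blk):
            continue
        pi = np.ascontiguousarray(blk.indices[:, 0])
        pj = np.ascontiguousarray(blk.indices[:, 1])
        if blk.style == "harmonic":
            k2 = np.ascontiguousarray(blk.params[:, 0])
            k4 = np.zeros(len(blk))
            b0 = np.ascontiguousarray(blk.params[:, 1])
        elif blk.style == "quartic":
            k2 = np.ascontiguousarray(blk.params[:, 0])
            k4 = np.ascontiguousarray(blk.params[:, 1])
            b0 = np.ascontiguousarray(blk.params[:, 2])
        else:
            raise ValueError(f"unknown bond style {blk.style!r}")
        e += _bond_kernel(coords, bx, by, bz, pi, pj, k2, k4, b0, forces)
    return e


def _eval_angles(topology, coords, box, forces, splines) -> float:
    e = 0.0
    for blk in topology.angles:
        if not len(blk):
            continue
        if blk.style == "gaussian_13":
            # Gaussian well on the 1-3 distance
            i, k = blk.indices[:, 0], blk.indices[:, 1]
            v, r = geometry.bond_vectors(coords[i], coords[k], box)
            eps, r0, w = blk.params[:, 0], blk.params[:, 1], blk.params[:, 2]
            g = np.exp(-((r - r0) ** 2) / (2.0 * w * w))
            e += float(np.sum(-eps * g))
            de = eps * (r - r0) / (w * w) * g
            fvec = (-de / np.maximum(r, 1e-12))[:, None] * v
            np.add.at(forces, i, -fvec)
            np.add.at(forces, k, fvec)
            continue
        i, j, k = blk.indices[:, 0], blk.indices[:, 1], blk.indices[:, 2]
        theta, gi, gj, gk = geometry.angle_value_grad(
            coords[i], coords[j], coords[k], box)
        if blk.style == "harmonic":
            ka, th0 = blk.params[:, 0], blk.params[:, 1]
            d = theta - th0
            e += float(np.sum(ka * d * d))
            de = 2.0 * ka * d
        elif blk.style == "flexible":
            de = np.empty(len(blk))
            keys = np.asarray(blk.table_keys)
            for key in np.unique(keys):
                m = keys == key
                ev, dev = splines["angle"][key](theta[m])
                e += float(np.sum(ev))
                de[m] = dev
        else:
            raise ValueError(f"unknown angle style {blk.style!r}")
        np.add.at(forces, i, -de[:, None] * gi)
        np.add.at(forces, j, -de[:, None] * gj)
        np.add.at(forces, k, -de[:, None] * gk)
    return e


def _eval_dihedrals(topology, coords, box, forces, splines) -> float:
    e = 0.0
    for blk in topology.dihedrals:
        if not len(blk):
            continue
        i, j, k, l = (blk.indices[:, c] for c in range(4))
        phi, gi, gj, gk, gl = geometry.dihedral_value_grad(
            coords[i], coords[j], coords[k], coords[l], box)
        if blk.style == "periodic":
            kf, phi0, n = blk.params[:, 0], blk.params[:, 1], blk.params[:, 2]
            e += float(np.sum(kf * (1.0 + np.cos(n * (phi - phi0)))))
            de = -kf * n * np.sin(n * (phi - phi0))
        elif blk.style == "gaussian":
            eps, phi0, sig = blk.params[:, 0], blk.params[:, 1], blk.params[:, 2]
            d = geometry.wrap_angle(phi - phi0)
            g = np.exp(-(d * d) / (2.0 * sig * sig))
            e += float(np.sum(-eps * g))
            de = eps * d / (sig * sig) * g
        elif blk.style == "flexible":
            de = np.empty(len(blk))
            keys = np.asarray(blk.table_keys)
            for key in np.unique(keys):
                m = keys == key
                ev, dev = splines["dihedral"][key](phi[m])
                e += float(np.sum(ev))
                de[m] = dev
        else:
            raise ValueError(f"unknown dihedral style {blk.style!r}")
        np.add.at(forces, i, -de[:, None] * gi)
        np.add.at(forces, j, -de[:, None] * gj)
        np.add.at(forces, k, -de[:, None] * gk)
        np.add.at(forces, l, -de[:, None] * gl)
    return e


# ---------------------------------------------------------------------------
# DNA base interactions and protein-DNA recognition
# ---------------------------------------------------------------------------

def _morse_arrays(r, eps, alpha, r0):
    """Vectorized repulsive/attractive Morse split with derivatives."""
    ex = np.exp(-alpha * (r - r0))
    full = eps * (1.0 - ex) ** 2 - eps
    dfull = 2.0 * eps * alpha * ex * (1.0 - ex)
    inside = r < r0
    rep = np.where(inside, full + eps, 0.0)
    drep = np.where(inside, dfull, 0.0)
    attr = np.where(inside, -eps, full)
    dattr = np.where(inside, 0.0, dfull)
    return rep, drep, attr, dattr


def _mod_arrays(dtheta, gamma):
    a = np.abs(dtheta)
    u = np.pi * dtheta / (2.0 * gamma)
    mid = (a >= gamma) & (a <= 2.0 * gamma)
    f = np.where(a < gamma, 1.0, np.where(mid, 1.0 - np.cos(u) ** 2, 0.0))
    df = np.where(mid, (np.pi / (2.0 * gamma)) * np.sin(2.0 * u), 0.0)
    return f, df


def _eval_dna_multibody(topology, coords, box, forces) -> dict[str, float]:
    out = {"dna_stack": 0.0, "dna_pair": 0.0, "dna_cross": 0.0}

    blk = topology.dna_stack
    if blk is not None and len(blk):
        S, B1, B2 = (blk.indices[:, c] for c in range(3))
        eps, alpha, r0, th0, gam = (blk.params[:, c] for c in range(5))
        v, r = geometry.bond_vectors(coords[B1], coords[B2], box)
        rep, drep, attr, dattr = _morse_arrays(r, eps, alpha, r0)
        theta, gS, gB1, gB2 = geometry.angle_value_grad(
            coords[S], coords[B1], coords[B2], box)
        f, df = _mod_arrays(theta - th0, gam)
        out["dna_stack"] = float(np.sum(rep + f * attr))
        de_r = drep + f * dattr
        de_th = df * attr
        rhat = v / np.maximum(r, 1e-12)[:, None]
        np.add.at(forces, B1, de_r[:, None] * rhat)
        np.add.at(forces, B2, -de_r[:, None] * rhat)
        np.add.at(forces, S, -de_th[:, None] * gS)
        np.add.at(forces, B1, -de_th[:, None] * gB1)
        np.add.at(forces, B2, -de_th[:, None] * gB2)

    blk = topology.dna_pair
    if blk is not None and len(blk):
        S1, B1, B2, S2 = (blk.indices[:, c] for c in range(4))
        eps, alpha, r0, th10, th20, phi0, g1, g2 = \
            (blk.params[:, c] for c in range(8))
        v, r = geometry.bond_vectors(coords[B1], coords[B2], box)
        rep, drep, attr, dattr = _morse_arrays(r, eps, alpha, r0)
        t1, a1S, a1B1, a1B2 = geometry.angle_value_grad(
            coords[S1], coords[B1], coords[B2], box)
        t2, a2S, a2B2, a2B1 = geometry.angle_value_grad(
            coords[S2], coords[B2], coords[B1], box)
        phi, dS1, dB1, dB2, dS2 = geometry.dihedral_value_grad(
            coords[S1], coords[B1], coords[B2], coords[S2], box)
        f1, df1 = _mod_arrays(t1 - th10, g1)
        f2, df2 = _mod_arrays(t2 - th20, g2)
        dphi = geometry.wrap_angle(phi - phi0)
        cfac = 0.5 * (1.0 + np.cos(dphi))
        out["dna_pair"] = float(np.sum(rep + cfac * f1 * f2 * attr))
        de_r = drep + cfac * f1 * f2 * dattr
        de_t1 = cfac * df1 * f2 * attr
        de_t2 = cfac * f1 * df2 * attr
        de_phi = -0.5 * np.sin(dphi) * f1 * f2 * attr
        rhat = v / np.maximum(r, 1e-12)[:, None]
        np.add.at(forces, B1, de_r[:, None] * rhat)
        np.add.at(forces, B2, -de_r[:, None] * rhat)
        np.add.at(forces, S1, -de_t1[:, None] * a1S)
        np.add.at(forces, B1, -de_t1[:, None] * a1B1)
        np.add.at(forces, B2, -de_t1[:, None] * a1B2)
        np.add.at(forces, S2, -de_t2[:, None] * a2S)
        np.add.at(forces, B2, -de_t2[:, None] * a2B2)
        np.add.at(forces, B1, -de_t2[:, None] * a2B1)
        for site, grad in ((S1, dS1), (B1, dB1), (B2, dB2), (S2, dS2)):
            np.add.at(forces, site, -de_phi[:, None] * grad)

    blk = topology.dna_cross
    if blk is not None and len(blk):
        S1, B1, B2, S2 = (blk.indices[:, c] for c in range(4))
        eps, alpha, r0, th30, thcs0, g3, gcs = \
            (blk.params[:, c] for c in range(7))
        v, r = geometry.bond_vectors(coords[B1], coords[B2], box)
        _rep, _drep, attr, dattr = _morse_arrays(r, eps, alpha, r0)
        t3, a3S, a3B1, a3B2 = geometry.angle_value_grad(
            coords[S1], coords[B1], coords[B2], box)
        tcs, acB1, acB2, acS2 = geometry.angle_value_grad(
            coords[B1], coords[B2], coords[S2], box)
        f3, df3 = _mod_arrays(t3 - th30, g3)
        fcs, dfcs = _mod_arrays(tcs - thcs0, gcs)
        out["dna_cross"] = float(np.sum(f3 * fcs * attr))
        de_r = f3 * fcs * dattr
        de_t3 = df3 * fcs * attr
        de_tcs = f3 * dfcs * attr
        rhat = v / np.maximum(r, 1e-12)[:, None]
        np.add.at(forces, B1, de_r[:, None] * rhat)
        np.add.at(forces, B2, -de_r[:, None] * rhat)
        np.add.at(forces, S1, -de_t3[:, None] * a3S)
        np.add.at(forces, B1, -de_t3[:, None] * a3B1)
        np.add.at(forces, B2, -de_t3[:, None] * a3B2)
        np.add.at(forces, B1, -de_tcs[:, None] * acB1)
        np.add.at(forces, B2, -de_tcs[:, None] * acB2)
        np.add.at(forces, S2, -de_tcs[:, None] * acS2)
    return out


def _eval_pwmcos(topology, coords, box, forces) -> float:
    """Sequence-specific base / DNA-binding-Cα recognition energy.

    Each site term is Gaussian(r) f(dtheta1) f(dtheta2) f(dtheta3) with
    r the base-Cα distance, theta1 the sugar-base-Cα angle, theta2 the angle
    between the 5'->3' neighbor-base axis and the base->Cα vector, theta3
    the angle between the Cα chain axis and the base->Cα vector.
    """
    e_total = 0.0
    for s in topology.pwmcos_sites:
        xb = coords[[s.base]]
        xc = coords[[s.calpha]]
        v, r = geometry.bond_vectors(xb, xc, box)
        r = float(r[0])
        g = -s.eps_g * math.exp(-((r - s.r0) ** 2) / (2.0 * s.w * s.w))
        dg = s.eps_g * (r - s.r0) / (s.w * s.w) * \
            math.exp(-((r - s.r0) ** 2) / (2.0 * s.w * s.w))
        t1, g1S, g1B, g1C = geometry.angle_value_grad(
            coords[[s.sugar]], xb, xc, box)
        t2, g2a, g2b, g2c, g2d = geometry.vector_angle_grad(
            coords[[s.base5]], coords[[s.base3]], xb, xc, box)
        t3, g3a, g3b, g3c, g3d = geometry.vector_angle_grad(
            coords[[s.ca_prev]], coords[[s.ca_next]], xb, xc, box)
        f1, df1 = angle_modulation(float(t1[0]) - s.theta1_0, s.gamma)
        f2, df2 = angle_modulation(float(t2[0]) - s.theta2_0, s.gamma)
        f3, df3 = angle_modulation(float(t3[0]) - s.theta3_0, s.gamma)
        e_total += g * f1 * f2 * f3

        de_r = dg * f1 * f2 * f3
        de_1 = g * df1 * f2 * f3
        de_2 = g * f1 * df2 * f3
        de_3 = g * f1 * f2 * df3
        rhat = (v[0] / max(r, 1e-12))
        forces[s.base] += de_r * rhat
        forces[s.calpha] -= de_r * rhat
        forces[s.sugar] -= de_1 * g1S[0]
        forces[s.base] -= de_1 * g1B[0]
        forces[s.calpha] -= de_1 * g1C[0]
        for idx, grad in ((s.base5, g2a), (s.base3, g2b),
                          (s.base, g2c), (s.calpha, g2d)):
            forces[idx] -= de_2 * grad[0]
        for idx, grad in ((s.ca_prev, g3a), (s.ca_next, g3b),
                          (s.base, g3c), (s.calpha, g3d)):
            forces[idx] -= de_3 * grad[0]
    return e_total


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def total_energy_forces(topology: Topology, state, params: ParameterSet,
                        nlists) -> tuple[dict[str, float], np.ndarray]:
    """Per-class energy breakdown and total analytic force per particle.

    Neighbor lists must be current; a set rebuild flag raises.  Pair vectors
    use the minimum-image convention and every nonbonded class is truncated
    at its own cutoff radius.
    """
    if getattr(nlists, "stale", False):
        raise RuntimeError("neighbor lists are stale; rebuild before "
                           "evaluating energies")
    coords = np.ascontiguousarray(state.coords, dtype=np.float64)
    box = state.box
    bx, by, bz = (float(box[0]), float(box[1]), float(box[2])) \
        if box is not None else (0.0, 0.0, 0.0)
    n = topology.n_particles
    forces = np.zeros((n, 3))

    cache = nlists.cache.get("routes")
    if cache is None:
        cache = _route_cache(topology, params, nlists)
        nlists.cache["routes"] = cache

    kT = KB * params.env.temperature
    splines = _splines(params, kT)

    energies = dict.fromkeys(ENERGY_CLASSES, 0.0)
    energies["bond"] = _eval_bonds(topology, coords, (bx, by, bz)
                                   if box is not None else None, forces)
    boxarr = box if box is not None else None
    energies["angle"] = _eval_angles(topology, coords, boxarr, forces, splines)
    energies["dihedral"] = _eval_dihedrals(topology, coords, boxarr, forces,
                                           splines)

    nc = topology.native_contacts
    if len(nc):
        energies["go"] = _go_kernel(
            coords, bx, by, bz,
            np.ascontiguousarray(nc.indices[:, 0]),
            np.ascontiguousarray(nc.indices[:, 1]),
            np.ascontiguousarray(nc.sigma), np.ascontiguousarray(nc.eps),
            forces)

    ei, ej, esig, estyle = cache["exv"]
    if len(ei):
        energies["exv"] = _exv_kernel(
            coords, bx, by, bz, ei, ej, esig, estyle,
            params.aicg.eps_exv, params.dna.exv_eps,
            params.cutoffs.exv ** 2, forces)

    hi, hj, hsig, hlam = cache["hps"]
    if len(hi):
        energies["hps"] = _hps_kernel(
            coords, bx, by, bz, hi, hj, hsig, hlam, params.hps.eps,
            params.cutoffs.hps ** 2, forces)

    ci, cj, qq = cache["ele"]
    if len(ci):
        eps_r = environment.relative_permittivity(
            params.env.temperature, params.env.salt_molarity)
        lam_d = environment.debye_length(
            params.env.temperature, params.env.ionic, eps_r)
        energies["ele"] = _ele_kernel(
            coords, bx, by, bz, ci, cj, qq, COULOMB / eps_r, lam_d,
            params.cutoffs.ele ** 2, forces)

    energies.update(_eval_dna_multibody(topology, coords, boxarr, forces))
    if topology.pwmcos_sites:
        energies["pwmcos"] = _eval_pwmcos(topology, coords, boxarr, forces)
    return energies, forces


def pair_energies(topology: Topology, state, params: ParameterSet, nlists
                  ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-pair nonbonded energies, keyed by class.

    Returns ``{class: (pairs (m, 2), energies (m,))}`` for the exv, hps and
    ele routes; used to verify that midpoint-cell pair ownership reproduces
    the serial totals when pairs are summed per subdomain.
    """
    coords = np.ascontiguousarray(state.coords, dtype=np.float64)
    box = state.box
    cache = nlists.cache.get("routes")
    if cache is None:
        cache = _route_cache(topology, params, nlists)
        nlists.cache["routes"] = cache
    out = {}

    hi, hj, hsig, hlam = cache["hps"]
    v, r = geometry.bond_vectors(coords[hi], coords[hj], box)
    s6 = np.where(r > 0, (hsig / np.maximum(r, 1e-12)) ** 6, 0.0)
    elj = 4.0 * params.hps.eps * (s6 * s6 - s6)
    e = np.where(r <= TWO_16 * hsig,
                 elj + (1.0 - hlam) * params.hps.eps, hlam * elj)
    e = np.where(r < params.cutoffs.hps, e, 0.0)
    out["hps"] = (np.column_stack([hi, hj]), e)

    ei, ej, esig, estyle = cache["exv"]
    v, r = geometry.bond_vectors(coords[ei], coords[ej], box)
    rs = np.maximum(r, 1e-12)
    sr6 = (esig / rs) ** 6
    e_a = np.where(r < 2.0 * esig,
                   params.aicg.eps_exv * sr6 * sr6
                   - params.aicg.eps_exv * 0.5 ** 12, 0.0)
    e_d = np.where(r < esig,
                   params.dna.exv_eps * (sr6 * sr6 - 2.0 * sr6)
                   + params.dna.exv_eps, 0.0)
    e = np.where(estyle == 0, e_a, e_d)
    e = np.where(r < params.cutoffs.exv, e, 0.0)
    out["exv"] = (np.column_stack([ei, ej]), e)

    ci, cj, qq = cache["ele"]
    v, r = geometry.bond_vectors(coords[ci], coords[cj], box)
    eps_r = environment.relative_permittivity(
        params.env.temperature, params.env.salt_molarity)
    lam_d = environment.debye_length(
        params.env.temperature, params.env.ionic, eps_r)
    rs = np.maximum(r, 1e-12)
    e = COULOMB / eps_r * qq * np.exp(-rs / lam_d) / rs
    e = np.where(r < params.cutoffs.ele, e, 0.0)
    out["ele"] = (np.column_stack([ci, cj]), e)
    return out
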