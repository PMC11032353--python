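"""Seeded generators for droplet configurations and parameter tables.

Everything the tests and demos consume is generated here, deterministically
from a seed: packed droplets of self-avoiding chains (a direct geometric
stand-in for the shrink-and-equilibrate protocol that produces real
condensate configurations), two-droplet fusion setups, multi-droplet
dispersions, and physically plausible per-residue parameter tables with the
printed model constants fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .params import FlexTable, ParameterSet

BOND = 3.8          # Å, CG bond length
MIN_SEP = 2.0       # Å, hard lower bound on bead-bead separation
_MAX_BEAD_DENSITY = 0.01   # beads/Å^3 above which packing is refused


@dataclass
class GeneratorSpec:
    """Two-droplet system recipe."""

    seed: int = 0
    n_chains: int = 40          # total over both droplets
    chain_length: int = 10
    radius: float = 30.0        # Å per droplet
    gap: float = 10.0           # Å surface-to-surface
    box: tuple[float, float, float] = (160.0, 160.0, 220.0)
    min_sep: float = MIN_SEP    # Å, non-bonded packing clearance


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _sample_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.dot(p, p) <= radius * radius:
            return p


def _grow_chain(rng: np.random.Generator, length: int,
                min_sep: float = MIN_SEP, max_attempts: int = 2000
                ) -> np.ndarray:
    """Self-avoiding random walk with exact 3.8 Å steps around the origin.

    ``min_sep`` applies to non-adjacent beads (bonded neighbors sit at the
    fixed 3.8 Å bond length regardless).
    """
    for _attempt in range(50):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(length - 1):
            placed = False
            for _try in range(max_attempts // 10):
                cand = pts[-1] + BOND * _random_unit(rng)
                own = np.asarray(pts[:-1])
                if len(own) and np.min(
                        np.linalg.norm(own - cand, axis=1)) < min_sep:
                    continue
                placed = True
                break
            if not placed:
                ok = False
                break
            pts.append(cand)
        if ok:
            return np.asarray(pts)
    raise RuntimeError("could not grow a self-avoiding chain")


def gen_droplet(n_chains: int, chain_length: int, radius: float, seed: int,
                center: np.ndarray | None = None,
                rng: np.random.Generator | None = None,
                min_sep: float = MIN_SEP) -> np.ndarray:
    """Pack ``n_chains`` self-avoiding chains with COMs uniform in a ball.

    Bonds are exactly 3.8 Å; no non-bonded bead pair anywhere in the
    droplet comes closer than ``min_sep`` (default 2 Å).  Raises when the
    requested density is geometrically infeasible, reporting the smallest
    workable radius.
    """
    if n_chains < 1 or chain_length < 1 or radius <= 0:
        raise ValueError("droplet spec values must be positive")
    volume = 4.0 / 3.0 * math.pi * (radius + BOND) ** 3
    density = n_chains * chain_length / volume
    max_density = _MAX_BEAD_DENSITY * (MIN_SEP / min_sep) ** 3
    if density > max_density:
        r_min = ((n_chains * chain_length / max_density)
                 / (4.0 / 3.0 * math.pi)) ** (1.0 / 3.0) - BOND
        raise ValueError(
            f"infeasible packing density {density:.2e} beads/Å^3; "
            f"need radius >= {r_min:.1f} Å")
    rng = np.random.default_rng(seed) if rng is None else rng
    center = np.zeros(3) if center is None else np.asarray(center, float)

    placed: list[np.ndarray] = []
    for _c in range(n_chains):
        tree = cKDTree(np.concatenate(placed)) if placed else None
        for _try in range(200):
            chain = _grow_chain(rng, chain_length, min_sep)
            com_target = _sample_in_ball(rng, radius)
            chain = chain - chain.mean(axis=0) + com_target
            if tree is None or tree.query(chain)[0].min() >= min_sep:
                placed.append(chain)
                break
        else:
            raise ValueError(
                f"could not place chain {_c} at radius {radius} Å; "
                "reduce density or enlarge the droplet")
    return np.concatenate(placed) + center


def gen_two_droplet_system(spec: GeneratorSpec
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Two droplets stacked along z with a surface gap; returns coordinates
    and per-chain initial droplet labels (1 or 2)."""
    if spec.gap < 0:
        raise ValueError("droplets overlap: gap must be non-negative")
    box = np.asarray(spec.box, float)
    n1 = spec.n_chains // 2
    n2 = spec.n_chains - n1
    sep = 2.0 * spec.radius + spec.gap
    if sep + 2.0 * spec.radius > box[2]:
        raise ValueError("two-droplet stack does not fit the box")
    rng = np.random.default_rng(spec.seed)
    mid = box / 2.0
    c1 = mid + np.array([0.0, 0.0, -sep / 2.0])
    c2 = mid + np.array([0.0, 0.0, +sep / 2.0])
    d1 = gen_droplet(n1, spec.chain_length, spec.radius, spec.seed,
                     center=c1, rng=rng, min_sep=spec.min_sep)
    d2 = gen_droplet(n2, spec.chain_length, spec.radius, spec.seed,
                     center=c2, rng=rng, min_sep=spec.min_sep)
    coords = np.concatenate([d1, d2])
    labels = np.concatenate([np.ones(n1, dtype=np.int64),
                             np.full(n2, 2, dtype=np.int64)])
    return coords, labels


def gen_multi_droplet_system(n_droplets: int, radii: tuple[float, float],
                             box: np.ndarray, seed: int,
                             chain_length: int = 10,
                             chain_density: float = 2.0e-4
                             ) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Non-overlapping droplets with radii sampled in ``radii`` (Å).

    Droplet centers are rejection-sampled in the periodic box; each droplet
    is filled by :func:`gen_droplet` with a chain count proportional to its
    volume (``chain_density`` chains/Å^3).  Returns coordinates, per-chain
    index lists and per-chain droplet labels.
    """
    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    rlo, rhi = radii
    if not 0 < rlo <= rhi:
        raise ValueError("invalid radius range")
    rads = rng.uniform(rlo, rhi, size=n_droplets)
    vol_frac = float(np.sum(4.0 / 3.0 * math.pi * rads**3) / np.prod(box))
    if vol_frac >= 0.3:
        raise ValueError(f"droplet volume fraction {vol_frac:.2f} too high")
    centers = []
    for k in range(n_droplets):
        for _try in range(5000):
            c = rng.uniform(0, 1, size=3) * box
            ok = True
            for k2, c2 in enumerate(centers):
                d = c - c2
                d -= box * np.round(d / box)
                if np.linalg.norm(d) < rads[k] + rads[k2] + 2 * BOND:
                    ok = False
                    break
            if ok:
                centers.append(c)
                break
        else:
            raise ValueError("could not place droplets without overlap")

    coords_parts, chains, labels = [], [], []
    offset = 0
    for k, (c, r) in enumerate(zip(centers, rads)):
        n_chains = max(2, int(round(chain_density * 4.0 / 3.0 * math.pi
                                    * r**3)))
        pts = gen_droplet(n_chains, chain_length, r, seed, center=c, rng=rng)
        coords_parts.append(pts)
        for ch in range(n_chains):
            chains.append(np.arange(offset + ch * chain_length,
                                    offset + (ch + 1) * chain_length))
            labels.append(k)
        offset += n_chains * chain_length
    return (np.mod(np.concatenate(coords_parts), box), chains,
            np.asarray(labels, dtype=np.int64))


def gen_test_parameters(residues: str = "ACDEFGHIKLMNPQRSTVWY",
                        seed: int = 0) -> ParameterSet:
    """Physically plausible per-residue tables with the model constants fixed.

    sigma is drawn in [4, 7] Å, hydropathy lambda in [0, 1]; statistical
    angle tables are normalized von-Mises-like bumps and dihedral tables
    smooth periodic densities.  The printed constants (eps = 0.2, k_b =
    2.39, b0 = 3.8, eps_exv = 0.6) are not randomized.
    """
    rng = np.random.default_rng(seed)
    ps = ParameterSet()
    for r in residues:
        ps.hps.sigma[r] = float(rng.uniform(4.0, 7.0))
        ps.hps.lam[r] = float(rng.uniform(0.0, 1.0))
        ps.aicg.sigma[r] = float(rng.uniform(4.0, 6.0))

    tgrid = np.linspace(math.radians(5.0), math.radians(175.0), 91)
    pgrid = np.linspace(-math.pi, math.pi, 121)
    for r in residues:
        mu = rng.uniform(math.radians(80.0), math.radians(130.0))
        w = rng.uniform(0.25, 0.5)
        p = np.exp(-((tgrid - mu) ** 2) / (2 * w * w)) * np.sin(tgrid) + 1e-3
        p /= np.trapezoid(p, tgrid)
        ps.flex_angle[r] = FlexTable(tgrid, p)

        mu_d = rng.uniform(-math.pi, math.pi)
        kappa = rng.uniform(0.5, 2.0)
        pd = np.exp(kappa * np.cos(pgrid - mu_d))
        pd[-1] = pd[0]
        pd /= np.trapezoid(pd, pgrid)
        ps.flex_dihedral[r] = FlexTable(pgrid, pd, periodic=True)
    ps.validate()
    return ps
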