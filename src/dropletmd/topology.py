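"""Residue-level coarse-grained topologies.

Proteins are one bead per residue; DNA is three sites per nucleotide
(phosphate, sugar, base) with the 5'-terminal phosphate of each strand
omitted, so an n-nucleotide strand has 3n - 1 sites.  Bonded terms of the
same functional style are stored contiguously in style-tagged blocks,
mirroring how parameter arrays are laid out sequentially per potential type
in the engine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .params import ParameterSet


class ParticleKind(IntEnum):
    ORDERED_PROTEIN = 0
    DISORDERED_PROTEIN = 1
    DNA_PHOSPHATE = 2
    DNA_SUGAR = 3
    DNA_BASE = 4


PROTEIN_KINDS = (ParticleKind.ORDERED_PROTEIN, ParticleKind.DISORDERED_PROTEIN)
DNA_KINDS = (ParticleKind.DNA_PHOSPHATE, ParticleKind.DNA_SUGAR, ParticleKind.DNA_BASE)


@dataclass
class Particle:
    """Read-only view of one CG particle."""

    global_index: int
    chain_id: int
    residue_index: int
    kind: ParticleKind
    code: str
    charge: float
    mass: float


@dataclass
class TermBlock:
    """A contiguous block of bonded terms sharing one functional style.

    ``indices`` has shape (n_terms, arity); ``params`` shape (n_terms, n_par).
    Flexible (statistical-table) styles carry ``table_keys`` naming the
    per-residue table for each term instead of numeric parameters.
    """

    style: str
    indices: np.ndarray
    params: np.ndarray
    table_keys: list[str] | None = None

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class NativeContacts:
    indices: np.ndarray            # (n, 2)
    sigma: np.ndarray              # Å, reference bead-bead distance
    eps: np.ndarray                # kcal/mol, per-contact Gō depth

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class PWMcosSite:
    """One protein-DNA recognition term: a base read by one DNA-binding Cα.

    Geometry sites: the base, its own sugar, the 5' and 3' neighbor bases on
    the same strand, and the Cα with its two chain neighbors.  ``eps_g`` is
    the PWM-derived Gaussian depth for (base letter, PWM column).
    """

    base: int
    sugar: int
    base5: int
    base3: int
    calpha: int
    ca_prev: int
    ca_next: int
    eps_g: float
    w: float
    r0: float
    theta1_0: float
    theta2_0: float
    theta3_0: float
    gamma: float


_EMPTY2 = np.empty((0, 2), dtype=np.int64)


def _block(style: str, idx: list, par: list, table_keys: list[str] | None = None,
           arity: int = 2) -> TermBlock:
    indices = (np.asarray(idx, dtype=np.int64).reshape(-1, arity)
               if idx else np.empty((0, arity), dtype=np.int64))
    nppar = (np.asarray(par, dtype=np.float64).reshape(len(indices), -1)
             if par else np.empty((len(indices), 0)))
    return TermBlock(style, indices, nppar, table_keys)


@dataclass
class Topology:
    """Particles plus style-grouped bonded, contact and multi-body term lists."""

    chain_id: np.ndarray
    residue_index: np.ndarray
    kind: np.ndarray
    code: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    bonds: list[TermBlock] = field(default_factory=list)
    angles: list[TermBlock] = field(default_factory=list)
    dihedrals: list[TermBlock] = field(default_factory=list)
    native_contacts: NativeContacts = field(
        default_factory=lambda: NativeContacts(_EMPTY2.copy(), np.empty(0), np.empty(0)))
    dna_stack: TermBlock | None = None
    dna_pair: TermBlock | None = None
    dna_cross: TermBlock | None = None
    pwmcos_sites: list[PWMcosSite] = field(default_factory=list)
    ref_coords: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return len(self.chain_id)

    def particle(self, i: int) -> Particle:
        return Particle(i, int(self.chain_id[i]), int(self.residue_index[i]),
                        ParticleKind(int(self.kind[i])), str(self.code[i]),
                        float(self.charge[i]), float(self.mass[i]))

    def chains(self) -> list[np.ndarray]:
        """Particle index arrays, one per chain, in chain-id order."""
        ids = np.unique(self.chain_id)
        return [np.flatnonzero(self.chain_id == c) for c in ids]

    # -- derived pair sets -------------------------------------------------

    def bond_graph(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_particles)}
        for blk in self.bonds:
            for i, j in blk.indices:
                adj[int(i)].add(int(j))
                adj[int(j)].add(int(i))
        return adj

    def bonded_exclusions(self) -> np.ndarray:
        """1-2 and 1-3 pairs (i < j), excluded from every nonbonded class."""
        cached = getattr(self, "_excl_cache", None)
        if cached is not None:
            return cached
        adj = self.bond_graph()
        pairs = set()
        for i, nbrs in adj.items():
            for j in nbrs:
                pairs.add((min(i, j), max(i, j)))
                for k in adj[j]:
                    if k != i:
                        pairs.add((min(i, k), max(i, k)))
        out = (np.array(sorted(pairs), dtype=np.int64) if pairs
               else _EMPTY2.copy())
        self._excl_cache = out
        return out

    def special_pairs(self) -> np.ndarray:
        """Pairs handled by dedicated terms (Gō contacts, DNA base stacking,
        pairing and cross-stacking), excluded from the exv and HPS classes."""
        cached = getattr(self, "_spec_cache", None)
        if cached is not None:
            return cached
        pairs = set()
        for i, j in self.native_contacts.indices:
            pairs.add((min(int(i), int(j)), max(int(i), int(j))))
        for blk, cols in ((self.dna_stack, (1, 2)), (self.dna_pair, (1, 2)),
                          (self.dna_cross, (1, 2))):
            if blk is not None:
                for row in blk.indices:
                    a, b = int(row[cols[0]]), int(row[cols[1]])
                    pairs.add((min(a, b), max(a, b)))
        out = (np.array(sorted(pairs), dtype=np.int64) if pairs
               else _EMPTY2.copy())
        self._spec_cache = out
        return out

    def validate(self) -> None:
        n = self.n_particles
        for name in ("chain_id", "residue_index", "kind", "code", "charge", "mass"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"particle field {name} length mismatch")
        blocks = list(self.bonds) + list(self.angles) + list(self.dihedrals)
        for blk in (self.dna_stack, self.dna_pair, self.dna_cross):
            if blk is not None:
                blocks.append(blk)
        for blk in blocks:
            if len(blk) and (blk.indices.min() < 0 or blk.indices.max() >= n):
                raise ValueError(f"{blk.style} term indices out of range")
            for row in blk.indices:
                if len(set(int(x) for x in row)) != len(row):
                    raise ValueError(f"{blk.style} term has repeated indices {row}")
        nc = self.native_contacts
        if len(nc) and (nc.indices.min() < 0 or nc.indices.max() >= n):
            raise ValueError("native contact indices out of range")
        # base pairing/stacking participants must be DNA sites
        for blk in (self.dna_stack, self.dna_pair, self.dna_cross):
            if blk is not None and len(blk):
                kinds = self.kind[blk.indices]
                if not np.all((kinds >= ParticleKind.DNA_PHOSPHATE)
                              & (kinds <= ParticleKind.DNA_BASE)):
                    raise ValueError("non-DNA particle in a base interaction term")


# ---------------------------------------------------------------------------
# protein builder
# ---------------------------------------------------------------------------

def build_protein_topology(
    sequence: str,
    region_models: list[tuple[tuple[int, int], str]],
    params: ParameterSet,
    first_residue: int = 1,
    chain_id: int = 0,
) -> Topology:
    """Build a one-bead-per-residue protein topology.

    ``region_models`` maps inclusive residue-number ranges to a model tag,
    ``"HPS"`` for disordered stretches (bonds only) or ``"AICG2+"`` for
    folded stretches (bonds, statistical angles with a 1-3 Gaussian, and
    statistical plus Gaussian dihedrals).  Ranges must tile the sequence
    exactly.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    last_residue = first_residue + n - 1

    covered = np.zeros(n, dtype=np.int8)
    model_of = np.empty(n, dtype=object)
    for (lo, hi), model in region_models:
        if model not in ("HPS", "AICG2+"):
            raise ValueError(f"unknown region model {model!r}")
        if lo > hi or lo < first_residue or hi > last_residue:
            raise ValueError(f"region {lo}-{hi} outside sequence "
                             f"{first_residue}-{last_residue}")
        sl = slice(lo - first_residue, hi - first_residue + 1)
        if covered[sl].any():
            raise ValueError(f"region {lo}-{hi} overlaps another region")
        covered[sl] = 1
        model_of[sl] = model
    if not covered.all():
        gap = np.flatnonzero(covered == 0)
        raise ValueError(
            f"region ranges leave residues "
            f"{gap[0] + first_residue}-{gap[-1] + first_residue} uncovered")

    for aa in sequence:
        if aa not in params.masses:
            raise ValueError(f"unknown residue code {aa!r}")

    kind = np.where(model_of == "AICG2+",
                    int(ParticleKind.ORDERED_PROTEIN),
                    int(ParticleKind.DISORDERED_PROTEIN)).astype(np.int8)
    code = np.array(list(sequence), dtype="<U2")
    top = Topology(
        chain_id=np.full(n, chain_id, dtype=np.int32),
        residue_index=np.arange(first_residue, first_residue + n, dtype=np.int32),
        kind=kind,
        code=code,
        charge=np.array([params.residue_charge(a) for a in sequence]),
        mass=np.array([params.residue_mass(a) for a in sequence]),
    )

    hps_bonds, aicg_bonds = [], []
    for i in range(n - 1):
        if model_of[i] == "AICG2+" and model_of[i + 1] == "AICG2+":
            aicg_bonds.append((i, i + 1))
        else:
            hps_bonds.append((i, i + 1))
    top.bonds = [
        _block("harmonic",
               hps_bonds + aicg_bonds,
               [(params.hps.kb, params.hps.b0)] * len(hps_bonds)
               + [(params.aicg.bond_k, params.aicg.bond_b0)] * len(aicg_bonds)),
    ]

    flex_a_idx, flex_a_keys, g13_idx, g13_par = [], [], [], []
    flex_d_idx, flex_d_keys, gd_idx, gd_par = [], [], [], []
    a = params.aicg
    for i in range(n - 2):
        if all(model_of[i + k] == "AICG2+" for k in range(3)):
            flex_a_idx.append((i, i + 1, i + 2))
            flex_a_keys.append(str(code[i + 1]))
            # 1-3 Gaussian reference: ideal-helix-like 1-3 distance
            g13_idx.append((i, i + 2))
            g13_par.append((a.g13_eps, 5.5, a.g13_w))
    for i in range(n - 3):
        if all(model_of[i + k] == "AICG2+" for k in range(4)):
            quad = (i, i + 1, i + 2, i + 3)
            flex_d_idx.append(quad)
            flex_d_keys.append(str(code[i + 1]))
            gd_idx.append(quad)
            gd_par.append((a.dih_gauss_eps, math.radians(50.0), a.dih_gauss_sigma))
    top.angles = []
    if flex_a_idx:
        top.angles.append(_block("flexible", flex_a_idx,
                                 [() for _ in flex_a_idx], flex_a_keys, arity=3))
    if g13_idx:
        top.angles.append(_block("gaussian_13", g13_idx, g13_par, arity=2))
    top.dihedrals = []
    if flex_d_idx:
        top.dihedrals.append(_block("flexible", flex_d_idx,
                                    [() for _ in flex_d_idx], flex_d_keys, arity=4))
    if gd_idx:
        top.dihedrals.append(_block("gaussian", gd_idx, gd_par, arity=4))
    top.validate()
    return top


# ---------------------------------------------------------------------------
# native contact extraction
# ---------------------------------------------------------------------------

@dataclass
class ReferenceStructure:
    """Per-residue heavy-atom coordinates (Å) used for contact extraction.

    ``bead_coords`` (one point per residue) sets the contact reference
    distance sigma_ij; it defaults to the heavy-atom centroid.
    """

    residue_ids: list[int]
    heavy_atoms: list[np.ndarray]
    bead_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bead_coords is None:
            self.bead_coords = np.array(
                [np.mean(a, axis=0) if len(a) else np.full(3, np.nan)
                 for a in self.heavy_atoms])


def extract_native_contacts(
    ref: ReferenceStructure,
    params: ParameterSet,
    cutoff: float = 4.5,
    min_seq_sep: int = 3,
) -> NativeContacts:
    """Contacts between residues with any heavy-atom pair within ``cutoff`` Å.

    Pairs closer than ``min_seq_sep`` in sequence are skipped (those are
    covered by bond/angle terms).  sigma_ij is the reference bead-bead
    distance; the Gō depth is the uniform per-contact default.
    """
    ids = ref.residue_ids
    for ridx, atoms in zip(ids, ref.heavy_atoms):
        if len(atoms) == 0 or not np.all(np.isfinite(atoms)):
            raise ValueError(f"missing or non-finite coordinates for residue {ridx}")
    nres = len(ids)
    idx, sig = [], []
    for a in range(nres):
        for b in range(a + 1, nres):
            if abs(ids[b] - ids[a]) < min_seq_sep:
                continue
            d2 = np.sum((ref.heavy_atoms[a][:, None, :]
                         - ref.heavy_atoms[b][None, :, :]) ** 2, axis=-1)
            if d2.min() < cutoff * cutoff:
                idx.append((a, b))
                sig.append(float(np.linalg.norm(
                    ref.bead_coords[a] - ref.bead_coords[b])))
    eps = np.full(len(idx), params.aicg.go_eps_default)
    return NativeContacts(
        np.asarray(idx, dtype=np.int64).reshape(-1, 2), np.asarray(sig), eps)


# ---------------------------------------------------------------------------
# DNA builder
# ---------------------------------------------------------------------------

_RISE = 3.38        # Å helical rise per base pair
_TWIST = math.radians(36.0)
_R_P, _R_S, _R_B = 8.9, 6.9, 3.0   # site radii from the helix axis, Å


def _ideal_duplex_coords(seq: str) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
    """Idealized regular-helix site coordinates for a duplex.

    Returns coordinates and a site table (nucleotide index within strand,
    site letter P/S/B, base letter), strand 1 followed by strand 2.
    """
    from .constants import DNA_COMPLEMENT

    n = len(seq)
    coords, table = [], []
    glyco = math.radians(154.0)   # angular opening between paired bases

    def place(strand: int, k: int, base: str) -> None:
        # strand 1 runs 5'->3' with increasing base-pair index, strand 2
        # antiparallel on the same right-handed helix, rotated by the
        # glycosidic angle so the two backbones never meet.
        bp = k if strand == 0 else n - 1 - k
        z = bp * _RISE
        theta = bp * _TWIST
        sgn = 1.0 if strand == 0 else -1.0
        base_ang = theta if strand == 0 else theta + glyco
        for letter, rad, dz, dphi in (("P", _R_P, -1.9, -0.52),
                                      ("S", _R_S, -0.8, -0.35),
                                      ("B", _R_B, 0.0, 0.0)):
            if letter == "P" and k == 0:
                continue  # 5'-terminal phosphate omitted
            ang = base_ang + sgn * dphi
            coords.append((rad * math.cos(ang), rad * math.sin(ang),
                           z + sgn * dz))
            table.append((k, letter, base))

    for k, b in enumerate(seq):
        place(0, k, b)
    comp = "".join(DNA_COMPLEMENT[b] for b in reversed(seq))
    for k, b in enumerate(comp):
        place(1, k, b)
    return np.asarray(coords), table


def _geom_angle(c: np.ndarray, i: int, j: int, k: int) -> float:
    u = c[i] - c[j]
    v = c[k] - c[j]
    cosx = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.acos(min(1.0, max(-1.0, cosx)))


def _geom_dihedral(c: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1, b2, b3 = c[j] - c[i], c[k] - c[j], c[l] - c[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    return math.atan2(y, float(np.dot(n1, n2)))


def build_dsdna_topology(sequence: str, params: ParameterSet) -> Topology:
    """Three-site-per-nucleotide double-stranded DNA topology.

    The complementary strand is generated automatically.  Each strand of n
    nucleotides contributes 3n - 1 sites (no 5'-terminal phosphate), so a
    duplex has 2(3n - 1) particles; phosphates carry charge -1 e.  Reference
    bond lengths, angles and dihedrals are measured on an idealized regular
    helix stored in ``ref_coords``, which therefore sits at the minimum of
    every local and base-interaction term.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 1:
        raise ValueError("need at least one base pair")
    for b in sequence:
        if b not in "ACGT":
            raise ValueError(f"invalid base symbol {b!r}")

    from .constants import DNA_COMPLEMENT

    coords, table = _ideal_duplex_coords(sequence)
    per_strand = 3 * n - 1
    npart = 2 * per_strand

    chain = np.repeat([0, 1], per_strand).astype(np.int32)
    resi = np.array([t[0] for t in table], dtype=np.int32)
    codes, kinds, charges, masses = [], [], [], []
    phos_q = params.charges.get("P", -1.0)
    for k, letter, base in table:
        if letter == "P":
            codes.append("P")
            kinds.append(int(ParticleKind.DNA_PHOSPHATE))
            charges.append(phos_q)
            masses.append(params.residue_mass("P"))
        elif letter == "S":
            codes.append("S")
            kinds.append(int(ParticleKind.DNA_SUGAR))
            charges.append(0.0)
            masses.append(params.residue_mass("S"))
        else:
            codes.append(base)
            kinds.append(int(ParticleKind.DNA_BASE))
            charges.append(0.0)
            masses.append(params.residue_mass(base))

    top = Topology(chain_id=chain, residue_index=resi,
                   kind=np.asarray(kinds, dtype=np.int8),
                   code=np.array(codes, dtype="<U2"),
                   charge=np.asarray(charges), mass=np.asarray(masses),
                   ref_coords=coords)

    # per-strand site index lookup
    def site_index() -> list[dict[tuple[int, str], int]]:
        out: list[dict[tuple[int, str], int]] = [{}, {}]
        for gi, (k, letter, _b) in enumerate(table):
            out[0 if gi < per_strand else 1][(k, letter)] = gi
        return out

    sidx = site_index()
    strands = [sequence, "".join(DNA_COMPLEMENT[b] for b in reversed(sequence))]

    d = params.dna
    bond_idx, bond_par = [], []
    for s in range(2):
        for k in range(n):
            S = sidx[s][(k, "S")]
            B = sidx[s][(k, "B")]
            bond_idx.append((S, B))
            if (k, "P") in sidx[s]:
                bond_idx.append((sidx[s][(k, "P")], S))
            if k + 1 < n:
                bond_idx.append((S, sidx[s][(k + 1, "P")]))
    for i, j in bond_idx:
        b0 = float(np.linalg.norm(coords[i] - coords[j]))
        bond_par.append((d.bond_k2, d.bond_k4, b0))
    top.bonds = [_block("quartic", bond_idx, bond_par)]

    # harmonic angles on every bonded triple
    adj = top.bond_graph()
    ang_idx, ang_par = [], []
    for j in range(npart):
        nbrs = sorted(adj[j])
        for ai in range(len(nbrs)):
            for bi in range(ai + 1, len(nbrs)):
                i, k = nbrs[ai], nbrs[bi]
                ang_idx.append((i, j, k))
                ang_par.append((d.angle_k, _geom_angle(coords, i, j, k)))
    top.angles = [_block("harmonic", ang_idx, ang_par, arity=3)]

    # dihedrals on bonded 4-paths; backbone (P/S only) paths get an extra
    # Gaussian well
    is_backbone = top.kind != int(ParticleKind.DNA_BASE)
    per_idx, per_par, gau_idx, gau_par = [], [], [], []
    seen = set()
    for j in range(npart):
        for k in adj[j]:
            if k <= j:
                continue
            for i in adj[j]:
                if i == k:
                    continue
                for l in adj[k]:
                    if l == j or l == i:
                        continue
                    key = (i, j, k, l)
                    if key in seen:
                        continue
                    seen.add(key)
                    phi0 = _geom_dihedral(coords, i, j, k, l)
                    per_idx.append(key)
                    per_par.append((d.dih_periodic_k, phi0 + math.pi,
                                    float(d.dih_periodic_n)))
                    if all(is_backbone[x] for x in key):
                        gau_idx.append(key)
                        gau_par.append((d.dih_gauss_eps, phi0, d.dih_gauss_sigma))
    top.dihedrals = []
    if per_idx:
        top.dihedrals.append(_block("periodic", per_idx, per_par, arity=4))
    if gau_idx:
        top.dihedrals.append(_block("gaussian", gau_idx, gau_par, arity=4))

    # base stacking: consecutive bases within a strand, modulated by the
    # sugar-base-base angle
    stk_idx, stk_par = [], []
    for s in range(2):
        for k in range(n - 1):
            S = sidx[s][(k, "S")]
            B1 = sidx[s][(k, "B")]
            B2 = sidx[s][(k + 1, "B")]
            ms = d.stack[strands[s][k] + strands[s][k + 1]]
            r0 = float(np.linalg.norm(coords[B1] - coords[B2]))
            th0 = _geom_angle(coords, S, B1, B2)
            stk_par.append((ms.eps, ms.alpha, r0, th0, d.gamma_bs))
            stk_idx.append((S, B1, B2))
    top.dna_stack = _block("stack", stk_idx, stk_par, arity=3)

    # base pairing: complementary bases across strands
    bp_idx, bp_par = [], []
    for k in range(n):
        kc = n - 1 - k
        S1, B1 = sidx[0][(k, "S")], sidx[0][(k, "B")]
        S2, B2 = sidx[1][(kc, "S")], sidx[1][(kc, "B")]
        ms = d.pair[sequence[k] + DNA_COMPLEMENT[sequence[k]]]
        r0 = float(np.linalg.norm(coords[B1] - coords[B2]))
        th1 = _geom_angle(coords, S1, B1, B2)
        th2 = _geom_angle(coords, S2, B2, B1)
        phi0 = _geom_dihedral(coords, S1, B1, B2, S2)
        bp_par.append((ms.eps, ms.alpha, r0, th1, th2, phi0,
                       d.gamma_bp, d.gamma_bp))
        bp_idx.append((S1, B1, B2, S2))
    top.dna_pair = _block("pair", bp_idx, bp_par, arity=4)

    # cross stacking: base k on strand 1 with the base diagonally adjacent
    # to its partner (partner of pair k+1), and the mirrored term
    cs_idx, cs_par = [], []
    for k in range(n - 1):
        for (sa, ka, sb, kb) in (((0), k, (1), n - 2 - k),
                                 ((1), n - 1 - k, (0), k + 1)):
            Sa, Ba = sidx[sa][(ka, "S")], sidx[sa][(ka, "B")]
            Sb, Bb = sidx[sb][(kb, "S")], sidx[sb][(kb, "B")]
            ms = d.cross[strands[sa][ka] + strands[sb][kb]]
            r0 = float(np.linalg.norm(coords[Ba] - coords[Bb]))
            th3 = _geom_angle(coords, Sa, Ba, Bb)
            thcs = _geom_angle(coords, Ba, Bb, Sb)
            cs_par.append((ms.eps, ms.alpha, r0, th3, thcs,
                           d.gamma_cs, d.gamma_cs))
            cs_idx.append((Sa, Ba, Bb, Sb))
    top.dna_cross = _block("cross", cs_idx, cs_par, arity=4)

    top.validate()
    assert top.n_particles == 2 * (3 * n - 1)
    return top


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def replicate_system(
    topology: Topology,
    n_copies: int,
    placements: list[tuple[np.ndarray, np.ndarray]],
    box: np.ndarray | None = None,
) -> Topology:
    """Tile ``n_copies`` rigid-transformed copies of a topology.

    Each placement is a (rotation, translation) pair; rotations must be
    proper (orthogonal, det +1).  Chain ids are renumbered per copy and all
    term lists re-indexed; no bonded term crosses copies.
    """
    if len(placements) != n_copies:
        raise ValueError("need one placement per copy")
    for R, t in placements:
        R = np.asarray(R, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
                or not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("placement rotation is not a proper rigid rotation")

    n0 = topology.n_particles
    nchain = int(topology.chain_id.max()) + 1 if n0 else 0

    def tile(a: np.ndarray) -> np.ndarray:
        return np.concatenate([a] * n_copies)

    out = Topology(
        chain_id=np.concatenate(
            [topology.chain_id + c * nchain for c in range(n_copies)]).astype(np.int32),
        residue_index=tile(topology.residue_index),
        kind=tile(topology.kind),
        code=tile(topology.code),
        charge=tile(topology.charge),
        mass=tile(topology.mass),
    )

    def shift_block(blk: TermBlock) -> TermBlock:
        idx = np.concatenate([blk.indices + c * n0 for c in range(n_copies)])
        par = np.concatenate([blk.params] * n_copies)
        keys = blk.table_keys * n_copies if blk.table_keys is not None else None
        return TermBlock(blk.style, idx, par, keys)

    out.bonds = [shift_block(b) for b in topology.bonds]
    out.angles = [shift_block(b) for b in topology.angles]
    out.dihedrals = [shift_block(b) for b in topology.dihedrals]
    nc = topology.native_contacts
    out.native_contacts = NativeContacts(
        np.concatenate([nc.indices + c * n0 for c in range(n_copies)])
        if len(nc) else _EMPTY2.copy(),
        np.concatenate([nc.sigma] * n_copies) if len(nc) else np.empty(0),
        np.concatenate([nc.eps] * n_copies) if len(nc) else np.empty(0))
    for name in ("dna_stack", "dna_pair", "dna_cross"):
        blk = getattr(topology, name)
        setattr(out, name, shift_block(blk) if blk is not None else None)
    out.pwmcos_sites = [
        PWMcosSite(s.base + c * n0, s.sugar + c * n0, s.base5 + c * n0,
                   s.base3 + c * n0, s.calpha + c * n0, s.ca_prev + c * n0,
                   s.ca_next + c * n0, s.eps_g, s.w, s.r0,
                   s.theta1_0, s.theta2_0, s.theta3_0, s.gamma)
        for c in range(n_copies) for s in topology.pwmcos_sites]

    if topology.ref_coords is not None:
        parts = []
        for R, t in placements:
            parts.append(topology.ref_coords @ np.asarray(R, float).T
                         + np.asarray(t, float))
        out.ref_coords = np.concatenate(parts)
        if box is not None:
            box = np.asarray(box, float)
            if np.any(out.ref_coords < -1e-9) or np.any(out.ref_coords > box + 1e-9):
                warnings.warn("replicated coordinates extend beyond the box; "
                              "they will be wrapped periodically", stacklevel=2)
    out.validate()
    return out


def identity_placements(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(np.eye(3), np.zeros(3)) for _ in range(n)]
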