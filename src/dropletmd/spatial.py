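"""Cell grid and unified multi-cutoff neighbor lists.

One spatial pass builds the pair lists for every nonbonded class at once.
Classes are ordered by range (excluded volume < DNA pairing < HPS <
electrostatics); a pair within the shortest generation threshold enters the
three concurrent lists, a pair between thresholds only the longer-ranged
ones.  The electrostatic list is built separately over charged particles
only.  Generation thresholds are r_p = r_c + buffer; the search can then be
skipped until some particle has moved half the buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet
from .topology import ParticleKind, Topology

CLASS_ORDER = ("exv", "dna", "hps", "ele")


@dataclass
class CellGrid:
    """Regular periodic cell decomposition of an orthorhombic box.

    Cell edges are at least half of the electrostatic generation threshold,
    so particles interacting at that range are never more than two cells
    apart.
    """

    box: np.ndarray
    ncells: np.ndarray            # cells per axis
    edges: np.ndarray             # cell edge lengths, Å
    cell_of: np.ndarray           # flat cell id per particle
    order: np.ndarray             # particle indices sorted by cell id
    offsets: np.ndarray           # CSR offsets into ``order``, len ncells+1

    @property
    def total_cells(self) -> int:
        return int(np.prod(self.ncells))

    def flat(self, cx: int, cy: int, cz: int) -> int:
        nx, ny, nz = self.ncells
        return (cx % nx) * ny * nz + (cy % ny) * nz + (cz % nz)

    def unflat(self, cid: int) -> tuple[int, int, int]:
        nx, ny, nz = self.ncells
        return cid // (ny * nz), (cid // nz) % ny, cid % nz

    def particles_in(self, cid: int) -> np.ndarray:
        return self.order[self.offsets[cid]:self.offsets[cid + 1]]

    def counts(self) -> np.ndarray:
        """Particle count per cell, shaped (nx, ny, nz)."""
        return np.diff(self.offsets).reshape(tuple(self.ncells))

    def cell_index_of_points(self, pts: np.ndarray) -> np.ndarray:
        w = np.mod(pts, self.box)
        c = np.floor(w / self.edges).astype(np.int64)
        c = np.minimum(c, self.ncells - 1)
        nx, ny, nz = self.ncells
        return (c[:, 0] * ny + c[:, 1]) * nz + c[:, 2]


def build_cell_grid(coords: np.ndarray, box: np.ndarray,
                    r_p_ele: float) -> CellGrid:
    """Bin particles into cells of edge >= r_p_ele / 2.

    Every box edge must be at least 2 r_p_ele so that minimum-image
    distances are unique at the longest generation threshold.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box < 2.0 * r_p_ele):
        raise ValueError(
            f"box {box} too small; every edge must be >= 2 r_p,ele "
            f"= {2.0 * r_p_ele:g} Å")
    ncells = np.maximum(np.floor(box / (r_p_ele / 2.0)).astype(np.int64), 1)
    edges = box / ncells
    coords = np.atleast_2d(np.asarray(coords, dtype=float)).reshape(-1, 3)
    if len(coords):
        w = np.mod(coords, box)
        c = np.minimum(np.floor(w / edges).astype(np.int64), ncells - 1)
        cid = (c[:, 0] * ncells[1] + c[:, 1]) * ncells[2] + c[:, 2]
    else:
        cid = np.empty(0, dtype=np.int64)
    order = np.argsort(cid, kind="stable")
    total = int(np.prod(ncells))
    offsets = np.zeros(total + 1, dtype=np.int64)
    np.add.at(offsets, cid + 1, 1)
    offsets = np.cumsum(offsets)
    return CellGrid(box, ncells, edges, cid, order, offsets)


@dataclass
class NeighborLists:
    """Per-class pair lists plus the bookkeeping for buffered rebuilds."""

    pairs: dict[str, np.ndarray]          # class -> (m, 2) int64, i < j
    pwmcos: np.ndarray                    # ordered (base, calpha) candidates
    thresholds: dict[str, float]          # r_p per class
    buffer: float
    ref_coords: np.ndarray                # coordinates at build time
    box: np.ndarray
    stale: bool = False
    cache: dict = field(default_factory=dict)

    def sizes(self) -> dict[str, int]:
        out = {k: len(v) for k, v in self.pairs.items()}
        out["pwmcos"] = len(self.pwmcos)
        return out


def _pairs_to_set(arr: np.ndarray, n: int) -> np.ndarray:
    return arr[:, 0] * n + arr[:, 1]


# cell-adjacency topology depends only on (ncells, shells); cache it so
# repeated rebuilds during a run pay only for the particle gathering
_NEIGHBOR_CELL_CACHE: dict[tuple, np.ndarray] = {}


def _cell_pair_table(grid: CellGrid, shells: np.ndarray) -> np.ndarray:
    """Distinct cell-id pairs (a < b) within the periodic shell range."""
    key = (tuple(int(v) for v in grid.ncells), tuple(int(v) for v in shells))
    hit = _NEIGHBOR_CELL_CACHE.get(key)
    if hit is not None:
        return hit
    sx, sy, sz = (int(v) for v in shells)
    offs = [(dx, dy, dz)
            for dx in range(-sx, sx + 1)
            for dy in range(-sy, sy + 1)
            for dz in range(-sz, sz + 1)]
    pairs = set()
    for cid in range(grid.total_cells):
        cx, cy, cz = grid.unflat(cid)
        for dx, dy, dz in offs:
            nid = grid.flat(cx + dx, cy + dy, cz + dz)
            if nid > cid:
                pairs.add((cid, nid))
    table = (np.array(sorted(pairs), dtype=np.int64)
             if pairs else np.empty((0, 2), dtype=np.int64))
    _NEIGHBOR_CELL_CACHE[key] = table
    return table


def _candidate_pairs(grid: CellGrid, shells: np.ndarray) -> np.ndarray:
    """All particle pairs (i < j) whose cells are within ``shells`` cells
    per axis (periodic).  Each pair appears exactly once (every particle
    lives in one cell and cell pairs are distinct); actual distances are
    filtered by the caller."""
    out = []
    counts = np.diff(grid.offsets)
    # intra-cell pairs
    for cid in np.flatnonzero(counts > 1):
        mine = grid.particles_in(int(cid))
        ii, jj = np.triu_indices(len(mine), k=1)
        out.append(np.column_stack([mine[ii], mine[jj]]))
    # inter-cell pairs, fully vectorized over the cached cell-pair table
    table = _cell_pair_table(grid, shells)
    if len(table):
        ca, cb = table[:, 0], table[:, 1]
        na, nb = counts[ca], counts[cb]
        prod = na * nb
        keep = prod > 0
        ca, cb, na, nb, prod = ca[keep], cb[keep], na[keep], nb[keep], prod[keep]
        if len(prod):
            total = int(prod.sum())
            seg = np.repeat(np.arange(len(prod)), prod)
            start = np.concatenate([[0], np.cumsum(prod)[:-1]])
            local = np.arange(total) - start[seg]
            ia = grid.order[grid.offsets[ca][seg] + local // nb[seg]]
            ib = grid.order[grid.offsets[cb][seg] + local % nb[seg]]
            out.append(np.column_stack([np.minimum(ia, ib),
                                        np.maximum(ia, ib)]))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.concatenate(out)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def build_neighbor_lists(
    coords: np.ndarray,
    box: np.ndarray,
    grid: CellGrid,
    params: ParameterSet,
    charges: np.ndarray,
    kinds: np.ndarray,
    exclusions: np.ndarray | None = None,
    special_pairs: np.ndarray | None = None,
    with_pwmcos: bool = False,
) -> NeighborLists:
    """One unified search producing every class list.

    ``exclusions`` (1-2/1-3 bonded pairs) are dropped from all classes;
    ``special_pairs`` (native contacts, base pairing/stacking partners) are
    dropped from the exv, dna and hps lists, whose interactions are replaced
    by dedicated terms.
    """
    params.cutoffs.validate()
    rp = {c: params.cutoffs.threshold(c) for c in CLASS_ORDER}
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    box = np.asarray(box, dtype=float)

    shells_short = np.ceil(rp["dna"] / grid.edges).astype(np.int64)
    shells_long = np.ceil(rp["ele"] / grid.edges).astype(np.int64)
    # one candidate sweep at the longest range covers every class
    cand = _candidate_pairs(grid, np.maximum(shells_short, shells_long))

    excl_keys = set()
    if exclusions is not None and len(exclusions):
        excl_keys = set(_pairs_to_set(np.asarray(exclusions), n).tolist())
    spec_keys = set()
    if special_pairs is not None and len(special_pairs):
        spec_keys = set(_pairs_to_set(np.asarray(special_pairs), n).tolist())

    if len(cand):
        keys = _pairs_to_set(cand, n)
        keep = ~np.isin(keys, np.fromiter(excl_keys, dtype=np.int64,
                                          count=len(excl_keys))) \
            if excl_keys else np.ones(len(cand), dtype=bool)
        cand = cand[keep]
        keys = keys[keep]
        d = coords[cand[:, 1]] - coords[cand[:, 0]]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
    else:
        keys = np.empty(0, dtype=np.int64)
        r = np.empty(0)

    not_special = ~np.isin(keys, np.fromiter(spec_keys, dtype=np.int64,
                                             count=len(spec_keys))) \
        if spec_keys else np.ones(len(cand), dtype=bool)

    pairs = {}
    for cls in ("exv", "dna", "hps"):
        m = (r < rp[cls]) & not_special
        pairs[cls] = cand[m]

    charged = np.asarray(charges) != 0.0
    m_ele = (r < rp["ele"]) & charged[cand[:, 0]] & charged[cand[:, 1]]
    pairs["ele"] = cand[m_ele]

    if with_pwmcos:
        is_base = np.asarray(kinds) == int(ParticleKind.DNA_BASE)
        is_ca = np.asarray(kinds) == int(ParticleKind.ORDERED_PROTEIN)
        m = (r < rp["dna"]) \
            & ((is_base[cand[:, 0]] & is_ca[cand[:, 1]])
               | (is_base[cand[:, 1]] & is_ca[cand[:, 0]]))
        sub = cand[m]
        # ordered (base, calpha) pairs: action-reaction bookkeeping is
        # asymmetric for this class, so no i < j normalization
        base_first = is_base[sub[:, 0]]
        pw = np.where(base_first[:, None], sub, sub[:, ::-1])
    else:
        pw = np.empty((0, 2), dtype=np.int64)

    return NeighborLists(pairs=pairs, pwmcos=pw, thresholds=rp,
                         buffer=params.cutoffs.buffer,
                         ref_coords=coords.copy(), box=box.copy())


def neighbor_lists_for(topology: Topology, coords: np.ndarray,
                       box: np.ndarray, params: ParameterSet
                       ) -> tuple[CellGrid, NeighborLists]:
    """Convenience wrapper wiring topology-derived exclusions in."""
    grid = build_cell_grid(coords, box, params.cutoffs.threshold("ele"))
    nl = build_neighbor_lists(
        coords, box, grid, params, topology.charge, topology.kind,
        exclusions=topology.bonded_exclusions(),
        special_pairs=topology.special_pairs(),
        with_pwmcos=bool(topology.pwmcos_sites))
    return grid, nl


def max_displacement(coords: np.ndarray, lists: NeighborLists) -> float:
    d = coords - lists.ref_coords
    d -= lists.box * np.round(d / lists.box)
    if len(d) == 0:
        return 0.0
    return float(np.max(np.linalg.norm(d, axis=1)))


def needs_rebuild(coords: np.ndarray, lists: NeighborLists) -> bool:
    """True once any particle has moved at least half the buffer since the
    last build; until then no pair inside any cutoff can have been missed."""
    return max_displacement(coords, lists) >= 0.5 * lists.buffer


def brute_force_lists(coords: np.ndarray, box: np.ndarray,
                      params: ParameterSet, charges: np.ndarray,
                      exclusions: np.ndarray | None = None,
                      special_pairs: np.ndarray | None = None
                      ) -> dict[str, np.ndarray]:
    """O(N^2) reference scan with the same thresholds and exclusions."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    rp = {c: params.cutoffs.threshold(c) for c in CLASS_ORDER}
    ii, jj = np.triu_indices(n, k=1)
    d = coords[jj] - coords[ii]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    keys = ii * n + jj
    excl = np.zeros(len(ii), dtype=bool)
    if exclusions is not None and len(exclusions):
        excl |= np.isin(keys, _pairs_to_set(np.asarray(exclusions), n))
    spec = np.zeros(len(ii), dtype=bool)
    if special_pairs is not None and len(special_pairs):
        spec |= np.isin(keys, _pairs_to_set(np.asarray(special_pairs), n))
    charged = np.asarray(charges) != 0.0
    out = {}
    for cls in ("exv", "dna", "hps"):
        m = (r < rp[cls]) & ~excl & ~spec
        out[cls] = np.column_stack([ii[m], jj[m]])
    m = (r < rp["ele"]) & ~excl & charged[ii] & charged[jj]
    out["ele"] = np.column_stack([ii[m], jj[m]])
    return out
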