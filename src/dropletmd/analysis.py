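"""Droplet-level trajectory analysis.

Chains are clustered with DBSCAN on either a chain-chain contact criterion
(two chains are neighbors when any inter-chain residue pair is within the
contact cutoff; defaults eps = 0.5, min_pts = 20, min_cluster_size = 100
for two-droplet systems) or on center-of-mass distances (defaults
eps = 50 Å, min_pts = 5, min_cluster_size = 50 for multiple-droplet
systems).  Mixing between two initially separate droplets is tracked by the
mean inter-chain COM distances D_IJ and the mixing coordinate
m = sqrt(D_11 D_22)/D_12; droplet shape by the coordinate
eta = max(dx/dy, dy/dx) + max(dy/dz, dz/dy) + max(dz/dx, dx/dz), which is
3 for any axis-symmetric distribution and grows with asphericity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# periodic helpers
# ---------------------------------------------------------------------------

def _minimg(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def chain_coms(coords: np.ndarray, chains: list[np.ndarray],
               box: np.ndarray | None = None) -> np.ndarray:
    """Per-chain centers of mass (geometric; beads weighted equally).

    Under periodic boundaries each coordinate axis is averaged on the
    circle, which is wrap-artifact free for chains smaller than half the
    box.
    """
    out = np.empty((len(chains), 3))
    for c, idx in enumerate(chains):
        if len(idx) == 0:
            raise ValueError(f"chain {c} is empty")
        pts = coords[idx]
        if box is None:
            out[c] = pts.mean(axis=0)
        else:
            theta = 2.0 * np.pi * pts / box
            mean = np.arctan2(np.sin(theta).mean(axis=0),
                              np.cos(theta).mean(axis=0))
            out[c] = np.mod(mean / (2.0 * np.pi), 1.0) * box
    return out


# ---------------------------------------------------------------------------
# chain distance matrices
# ---------------------------------------------------------------------------

def chain_distance_matrix(coords: np.ndarray, chains: list[np.ndarray],
                          metric: str = "com", box: np.ndarray | None = None,
                          contact_cutoff: float = 10.0) -> np.ndarray:
    """Chain-pair matrix: boolean contact adjacency or COM distances.

    ``contact``: True where any inter-chain residue pair is within
    ``contact_cutoff`` Å.  ``com``: periodic minimum-image COM distance.
    """
    n = len(chains)
    for c, idx in enumerate(chains):
        if len(idx) == 0:
            raise ValueError(f"chain {c} is empty")
    if metric == "com":
        coms = chain_coms(coords, chains, box)
        d = _minimg(coms[:, None, :] - coms[None, :, :], box)
        return np.linalg.norm(d, axis=-1)
    if metric == "contact":
        adj = np.zeros((n, n), dtype=bool)
        cut2 = contact_cutoff * contact_cutoff
        for a in range(n):
            pa = coords[chains[a]]
            for b in range(a + 1, n):
                d = _minimg(pa[:, None, :] - coords[chains[b]][None, :, :], box)
                if np.min(np.sum(d * d, axis=-1)) < cut2:
                    adj[a, b] = adj[b, a] = True
        return adj
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# DBSCAN on chains
# ---------------------------------------------------------------------------

NOISE = -1


@dataclass
class ClusterResult:
    labels: np.ndarray          # per-chain cluster id, NOISE for noise
    n_droplets: int
    sizes: np.ndarray           # chains per droplet, label order


def cluster_chains(matrix: np.ndarray, metric: str, eps: float = 0.5,
                   min_pts: int = 20, min_cluster_size: int = 100
                   ) -> ClusterResult:
    """Deterministic DBSCAN over chains with a minimum-cluster-size filter.

    The neighborhood of a chain is the set of chains in contact (contact
    metric) or within ``eps`` (COM metric), plus the chain itself; a chain
    with at least ``min_pts`` neighborhood members is a core point.  Chains
    are visited in index order and border points join the first cluster
    that reaches them.  Clusters smaller than ``min_cluster_size`` are
    relabeled noise; surviving labels are renumbered contiguously from 0 in
    order of their smallest member index.
    """
    if eps <= 0 or min_pts <= 0 or min_cluster_size <= 0:
        raise ValueError("DBSCAN parameters must be positive")
    n = len(matrix)
    if metric == "contact":
        nbr = [np.flatnonzero(matrix[i]) for i in range(n)]
    elif metric == "com":
        nbr = [np.flatnonzero((matrix[i] < eps)
                              & (np.arange(n) != i)) for i in range(n)]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    core = np.array([len(nbr[i]) + 1 >= min_pts for i in range(n)])

    labels = np.full(n, NOISE, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        # BFS over density-reachable chains
        labels[i] = cluster
        queue = [i]
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in nbr[j]:
                if labels[k] == NOISE:
                    labels[k] = cluster
                    queue.append(int(k))
        cluster += 1

    # size filter, then contiguous relabeling
    keep = []
    for c in range(cluster):
        members = np.flatnonzero(labels == c)
        if len(members) >= min_cluster_size:
            keep.append((int(members[0]), c))
        else:
            labels[members] = NOISE
    keep.sort()
    remap = {old: new for new, (_first, old) in enumerate(keep)}
    labels = np.array([remap.get(int(l), NOISE) for l in labels],
                      dtype=np.int64)
    sizes = np.array([int(np.sum(labels == c)) for c in range(len(keep))],
                     dtype=np.int64)
    return ClusterResult(labels, len(keep), sizes)


# ---------------------------------------------------------------------------
# mixing metrics
# ---------------------------------------------------------------------------

@dataclass
class MixingMetrics:
    d11: float
    d22: float
    d12: float
    m: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.d11, self.d12], [self.d12, self.d22]])


def mixing_metrics(coords: np.ndarray, chains: list[np.ndarray],
                   labels_initial: np.ndarray,
                   box: np.ndarray | None = None) -> MixingMetrics:
    """Mean inter-chain COM distances between the two initial droplets.

    ``labels_initial`` maps each chain to droplet 1 or 2 (its droplet of
    origin, fixed for the whole trajectory).  D_IJ averages the COM
    distance over all pairs (i in C_I, j in C_J, i != j);
    m = sqrt(D_11 D_22)/D_12 approaches 1 at complete mixing.
    """
    labels_initial = np.asarray(labels_initial)
    coms = chain_coms(coords, chains, box)
    groups = {}
    for lab in (1, 2):
        groups[lab] = np.flatnonzero(labels_initial == lab)
        if len(groups[lab]) == 0:
            raise ValueError(f"no chains carry initial label {lab}")
        if len(groups[lab]) < 2:
            raise ValueError(
                f"initial label {lab} has fewer than 2 chains; its diagonal "
                "D is undefined")

    def dmean(a: np.ndarray, b: np.ndarray, same: bool) -> float:
        d = _minimg(coms[a][:, None, :] - coms[b][None, :, :], box)
        dist = np.linalg.norm(d, axis=-1)
        if same:
            iu = np.triu_indices(len(a), k=1)
            return float(dist[iu].mean())
        return float(dist.mean())

    d11 = dmean(groups[1], groups[1], True)
    d22 = dmean(groups[2], groups[2], True)
    d12 = dmean(groups[1], groups[2], False)
    return MixingMetrics(d11, d22, d12, math.sqrt(d11 * d22) / d12)


def shape_eta(coords: np.ndarray, indices: np.ndarray | None = None,
              box: np.ndarray | None = None, mode: str = "std") -> float:
    """Droplet shape coordinate from per-axis extents about the COM.

    Extents are the per-axis standard deviations of the droplet particles
    (``mode="std"``, the default: exactly 3 for any axis-symmetric cloud)
    or half the min-max extent (``mode="range"``).
    """
    pts = coords if indices is None else coords[indices]
    if len(pts) < 2:
        raise ValueError("need at least two particles for a shape")
    com = chain_coms(pts, [np.arange(len(pts))], box)[0]
    d = _minimg(pts - com, box)
    if mode == "std":
        ext = d.std(axis=0)
    elif mode == "range":
        ext = 0.5 * (d.max(axis=0) - d.min(axis=0))
    else:
        raise ValueError(f"unknown extent mode {mode!r}")
    if np.any(ext <= 0):
        raise ValueError("degenerate droplet: zero extent along an axis")
    dx, dy, dz = ext
    return float(max(dx / dy, dy / dx) + max(dy / dz, dz / dy)
                 + max(dz / dx, dx / dz))


def density_profile(frames: list[np.ndarray], box: np.ndarray, axis: int = 2,
                    bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged particle number density along one box axis (Å^-3)."""
    if bins < 2:
        raise ValueError("need at least two bins")
    edges = np.linspace(0.0, box[axis], bins + 1)
    slab_volume = np.prod([box[a] for a in range(3) if a != axis]) \
        * (edges[1] - edges[0])
    hist = np.zeros(bins)
    for f in frames:
        x = np.mod(f[:, axis], box[axis])
        h, _ = np.histogram(x, bins=edges)
        hist += h
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / (len(frames) * slab_volume)
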