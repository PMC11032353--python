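"""File formats: bead PDB coordinates, trajectories, TOML configuration.

Bead coordinate files use one ATOM record per CG particle with the bead
name equal to the residue/site code and TER records delimiting chains.
Chain identity is recovered from the TER structure (single-character PDB
chain IDs cycle and cannot distinguish thousands of chains); atom serials
wrap at the fixed-column limit.  Trajectories are written as XYZ text (or
DCD through MDAnalysis when requested); numeric outputs are TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import Cutoffs

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


# ---------------------------------------------------------------------------
# bead PDB
# ---------------------------------------------------------------------------

def write_structure(path: str | Path, coords: np.ndarray,
                    chain_id: np.ndarray, residue_index: np.ndarray,
                    code: np.ndarray, box: np.ndarray | None = None) -> None:
    """Write bead coordinates as PDB ATOM records (3-decimal precision)."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    lines = []
    if box is not None:
        lines.append(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                     f"  90.00  90.00  90.00 P 1           1")
    prev_chain = None
    for i in range(len(coords)):
        c = int(chain_id[i])
        if prev_chain is not None and c != prev_chain:
            lines.append("TER")
        prev_chain = c
        name = str(code[i])[:3]
        serial = (i % 99999) + 1
        resseq = (int(residue_index[i]) % 9999) + 1
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {name:<3s} "
            f"{_CHAIN_ALPHABET[c % len(_CHAIN_ALPHABET)]}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path: str | Path
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                              np.ndarray | None]:
    """Read a bead PDB; returns coords, chain ids, residue indices, codes, box.

    Chains are delimited by TER records; malformed fixed-column records are
    rejected with their line number.
    """
    coords, chains, resis, codes = [], [], [], []
    box = None
    chain = 0
    saw_atom_in_chain = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        rec = line[:6]
        if rec == "CRYST1":
            box = np.array([float(line[6:15]), float(line[15:24]),
                            float(line[24:33])])
        elif rec == "TER   " or line.strip() == "TER":
            if saw_atom_in_chain:
                chain += 1
                saw_atom_in_chain = False
        elif rec in ("ATOM  ", "HETATM"):
            try:
                name = line[12:16].strip()
                chain_field = line[21]
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: malformed ATOM record at line "
                                 f"{lineno}") from None
            if chain_field == " ":
                raise ValueError(f"{path}: missing chain ID at line {lineno}")
            if not name:
                raise ValueError(f"{path}: missing bead name at line {lineno}")
            coords.append((x, y, z))
            chains.append(chain)
            resis.append(resseq - 1)
            codes.append(name)
            saw_atom_in_chain = True
    return (np.asarray(coords, float).reshape(-1, 3),
            np.asarray(chains, dtype=np.int32),
            np.asarray(resis, dtype=np.int32),
            np.asarray(codes, dtype="<U4"), box)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

class TrajectoryWriter:
    """Appends frames to an XYZ text file (or DCD via MDAnalysis)."""

    def __init__(self, path: str | Path, fmt: str = "xyz",
                 names: np.ndarray | None = None):
        if fmt not in ("xyz", "dcd"):
            raise ValueError(f"unknown trajectory format {fmt!r}")
        self.path = Path(path)
        self.fmt = fmt
        self.names = names
        self.n_frames = 0
        self.box = None
        if fmt == "xyz":
            self._fh = open(self.path, "w")
        else:
            self._fh = None
            self._pending: list[tuple[np.ndarray, np.ndarray]] = []

    def write_frame(self, coords: np.ndarray,
                    box: np.ndarray | None = None) -> None:
        if self.closed:
            raise ValueError("trajectory writer is closed")
        coords = np.asarray(coords, float).reshape(-1, 3)
        self.box = box
        if self.fmt == "xyz":
            n = len(coords)
            comment = f"frame {self.n_frames}"
            if box is not None:
                comment += f" box {box[0]:.4f} {box[1]:.4f} {box[2]:.4f}"
            self._fh.write(f"{n}\n{comment}\n")
            for i in range(n):
                name = str(self.names[i]) if self.names is not None else "X"
                self._fh.write(f"{name} {coords[i, 0]:.5f} {coords[i, 1]:.5f} "
                               f"{coords[i, 2]:.5f}\n")
        else:
            self._pending.append((coords.copy(), box))
        self.n_frames += 1

    @property
    def closed(self) -> bool:
        if self.fmt == "xyz":
            return self._fh.closed
        return self._pending is None

    def close(self) -> None:
        if self.fmt == "xyz":
            self._fh.close()
            return
        if self._pending is None:
            return
        import MDAnalysis as mda
        frames = self._pending
        self._pending = None
        if not frames:
            Path(self.path).touch()
            return
        n = len(frames[0][0])
        u = mda.Universe.empty(n, trajectory=True)
        with mda.Writer(str(self.path), n) as w:
            for coords, box in frames:
                u.atoms.positions = coords
                if box is not None:
                    u.dimensions = [box[0], box[1], box[2], 90, 90, 90]
                w.write(u.atoms)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_xyz(path: str | Path) -> tuple[list[np.ndarray], np.ndarray | None]:
    """Read all frames of an XYZ trajectory (returns frames and last box)."""
    frames = []
    box = None
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k])
        comment = lines[k + 1]
        if " box " in comment:
            box = np.array([float(v) for v in
                            comment.split(" box ")[1].split()[:3]])
        block = lines[k + 2:k + 2 + n]
        frames.append(np.array([[float(v) for v in ln.split()[1:4]]
                                for ln in block]))
        k += 2 + n
    return frames, box


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated simulation configuration with model defaults filled in."""

    steps: int = 1000
    dt_fs: float = 10.0
    temperature_K: float = 300.0
    friction_per_ps: float = 0.01
    seed: int = 0
    nblist_update: int = 1          # steps between displacement checks
    balance_period: float = math.inf
    output_stride: int = 100
    n_subdomains: int = 1
    cutoffs: Cutoffs = field(default_factory=Cutoffs)

    def validate(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.output_stride < 1 or self.nblist_update < 1:
            raise ValueError("strides must be >= 1")
        self.cutoffs.validate()


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML run configuration; missing keys take the model defaults
    (dt 10 fs, friction 0.01 ps^-1, HPS/electrostatic cutoffs 20/35 Å,
    buffer 3 Å)."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = RunConfig()
    run = raw.get("run", {})
    for key in ("steps", "dt_fs", "temperature_K", "friction_per_ps", "seed",
                "nblist_update", "output_stride", "n_subdomains"):
        if key in run:
            setattr(cfg, key, run[key])
    if "balance_period" in raw.get("balance", {}):
        cfg.balance_period = float(raw["balance"]["balance_period"])
    cut = raw.get("cutoffs", {})
    for key in ("exv", "dna", "hps", "ele", "buffer"):
        if key in cut:
            setattr(cfg.cutoffs, key, float(cut[key]))
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to TOML."""
    bal = "" if math.isinf(cfg.balance_period) else \
        f"\n[balance]\nbalance_period = {cfg.balance_period}\n"
    return (
        "[run]\n"
        f"steps = {cfg.steps}\n"
        f"dt_fs = {cfg.dt_fs}\n"
        f"temperature_K = {cfg.temperature_K}\n"
        f"friction_per_ps = {cfg.friction_per_ps}\n"
        f"seed = {cfg.seed}\n"
        f"nblist_update = {cfg.nblist_update}\n"
        f"output_stride = {cfg.output_stride}\n"
        f"n_subdomains = {cfg.n_subdomains}\n"
        f"{bal}"
        "\n[cutoffs]\n"
        f"exv = {cfg.cutoffs.exv}\n"
        f"dna = {cfg.cutoffs.dna}\n"
        f"hps = {cfg.cutoffs.hps}\n"
        f"ele = {cfg.cutoffs.ele}\n"
        f"buffer = {cfg.cutoffs.buffer}\n")
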