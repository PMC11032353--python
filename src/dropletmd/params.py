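"""Force-field parameter containers.

A :class:`ParameterSet` collects every constant, per-residue table, and
cutoff radius the energy terms need.  The printed model constants (HPS well
depth 0.2 kcal/mol, bond force constant 2.39 kcal/mol/Å², reference bond
length 3.8 Å, excluded-volume coefficient 0.6 kcal/mol, cutoffs 20/35 Å,
pair-list buffer 3 Å) are defaults here; the per-residue hydropathy and size
tables and the statistical angle/dihedral tables are inputs, normally
produced by :mod:`dropletmd.synthetic` or read from TOML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants


@dataclass
class FlexTable:
    """Statistical (flexible) angle or dihedral table on a uniform grid.

    ``grid`` is in radians, ``prob`` a strictly positive density normalized
    so that the trapezoid integral over the grid equals 1.
    """

    grid: np.ndarray
    prob: np.ndarray
    periodic: bool = False

    def validate(self) -> None:
        if self.grid.ndim != 1 or self.grid.shape != self.prob.shape:
            raise ValueError("flexible table grid/prob shape mismatch")
        if np.any(self.prob <= 0):
            raise ValueError("flexible table probabilities must be strictly positive")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("flexible table grid must be strictly increasing")
        total = np.trapezoid(self.prob, self.grid)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"flexible table not normalized (integral {total:.6g})")


@dataclass
class Cutoffs:
    """Per-interaction-class cutoff radii (Å), ascending by class range."""

    exv: float = 12.0
    dna: float = 18.0
    hps: float = 20.0
    ele: float = 35.0
    buffer: float = 3.0

    def validate(self) -> None:
        vals = (self.exv, self.dna, self.hps, self.ele)
        if any(v <= 0 for v in vals) or self.buffer <= 0:
            raise ValueError("cutoffs and buffer must be positive")
        if not (self.exv <= self.dna <= self.hps <= self.ele):
            raise ValueError(
                "cutoffs must be in ascending order: "
                f"exv ({self.exv}) <= dna ({self.dna}) <= hps ({self.hps}) "
                f"<= ele ({self.ele})"
            )

    def threshold(self, cls: str) -> float:
        """Neighbor-list generation threshold r_p = r_c + buffer for a class."""
        return getattr(self, cls) + self.buffer


@dataclass
class HPSParams:
    """Hydropathy-scale model for disordered regions."""

    eps: float = 0.2            # kcal/mol, pair well depth
    kb: float = 2.39            # kcal/mol/Å^2, bond force constant
    b0: float = 3.8             # Å, reference bond length
    sigma: dict[str, float] = field(default_factory=dict)   # Å per residue
    lam: dict[str, float] = field(default_factory=dict)     # hydropathy per residue


@dataclass
class AICGParams:
    """Structure-based model for folded regions (local terms + Gō + exv)."""

    eps_exv: float = 0.6        # kcal/mol
    sigma: dict[str, float] = field(default_factory=dict)   # Å per residue (exv)
    bond_k: float = 110.0       # kcal/mol/Å^2
    bond_b0: float = 3.8        # Å
    g13_eps: float = 1.0        # kcal/mol, 1-3 distance Gaussian depth
    g13_w: float = 0.5          # Å, 1-3 Gaussian width
    dih_gauss_eps: float = 0.5  # kcal/mol
    dih_gauss_sigma: float = 0.3  # rad
    go_eps_default: float = 0.3   # kcal/mol per native contact


@dataclass
class MorseSet:
    """Depth (kcal/mol), width (1/Å) and reference distance (Å) of a Morse term."""

    eps: float
    alpha: float
    r0: float


@dataclass
class DNAParams:
    """Three-site-per-nucleotide DNA model parameters."""

    bond_k2: float = 30.0       # kcal/mol/Å^2
    bond_k4: float = 100.0      # kcal/mol/Å^4
    angle_k: float = 20.0       # kcal/mol/rad^2
    dih_periodic_k: float = 2.0   # kcal/mol
    dih_periodic_n: int = 1
    dih_gauss_eps: float = 1.0  # kcal/mol
    dih_gauss_sigma: float = 0.3  # rad
    # Morse parameters per base step / base pair / cross pair.
    stack: dict[str, MorseSet] = field(default_factory=dict)
    pair: dict[str, MorseSet] = field(default_factory=dict)
    cross: dict[str, MorseSet] = field(default_factory=dict)
    # Modulation half-widths gamma (rad) per angle class.
    gamma_bs: float = math.radians(18.0)
    gamma_bp: float = math.radians(18.0)
    gamma_cs: float = math.radians(18.0)
    exv_eps: float = 0.25       # kcal/mol
    exv_sigma: dict[str, float] = field(
        default_factory=lambda: {"P": 4.5, "S": 6.2, "A": 5.4, "C": 5.4,
                                 "G": 5.4, "T": 5.4}
    )

    def __post_init__(self) -> None:
        if not self.stack:
            steps = ["AA", "AC", "AG", "AT", "CA", "CC", "CG", "CT",
                     "GA", "GC", "GG", "GT", "TA", "TC", "TG", "TT"]
            self.stack = {s: MorseSet(3.5, 3.0, 3.8) for s in steps}
        if not self.pair:
            self.pair = {"AT": MorseSet(4.0, 2.0, 5.9), "TA": MorseSet(4.0, 2.0, 5.9),
                         "CG": MorseSet(5.0, 2.0, 5.9), "GC": MorseSet(5.0, 2.0, 5.9)}
        if not self.cross:
            self.cross = {b: MorseSet(0.8, 4.0, 6.2) for b in
                          ["AA", "AC", "AG", "AT", "CA", "CC", "CG", "CT",
                           "GA", "GC", "GG", "GT", "TA", "TC", "TG", "TT"]}


@dataclass
class PWMcosParams:
    """Sequence-specific protein-DNA recognition potential parameters."""

    gamma: float = math.radians(10.0)   # rad, modulation half-width
    w: float = 1.0                      # Å, Gaussian width
    # eps_G per (base letter, PWM column index): kcal/mol depths.
    eps_g: dict[tuple[str, int], float] = field(default_factory=dict)


@dataclass
class Environment:
    """Solution conditions."""

    temperature: float = 300.0    # K
    salt_molarity: float = 0.15   # mol/L, enters the permittivity polynomial
    ionic_strength: float | None = None  # mol/L; defaults to salt molarity (1:1 salt)

    @property
    def ionic(self) -> float:
        return self.salt_molarity if self.ionic_strength is None else self.ionic_strength


@dataclass
class ParameterSet:
    """All force-field constants, tables, and per-class cutoffs."""

    hps: HPSParams = field(default_factory=HPSParams)
    aicg: AICGParams = field(default_factory=AICGParams)
    dna: DNAParams = field(default_factory=DNAParams)
    pwmcos: PWMcosParams = field(default_factory=PWMcosParams)
    env: Environment = field(default_factory=Environment)
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    flex_angle: dict[str, FlexTable] = field(default_factory=dict)
    flex_dihedral: dict[str, FlexTable] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.masses:
            self.masses = dict(constants.AMINO_MASSES) | dict(constants.DNA_SITE_MASSES)
        if not self.charges:
            self.charges = dict(constants.AMINO_CHARGES)

    def validate(self) -> None:
        self.cutoffs.validate()
        for tab in (*self.flex_angle.values(), *self.flex_dihedral.values()):
            tab.validate()
        for name, d in (("hps.sigma", self.hps.sigma), ("aicg.sigma", self.aicg.sigma)):
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"{name} entries must be positive")

    def residue_mass(self, code: str) -> float:
        try:
            return self.masses[code]
        except KeyError:
            raise KeyError(f"no mass for residue/site code {code!r}") from None

    def residue_charge(self, code: str) -> float:
        return self.charges.get(code, 0.0)


def default_parameters(residues: str = "ACDEFGHIKLMNPQRSTVWY") -> ParameterSet:
    """A ParameterSet with mid-range per-residue tables, for quick starts.

    Hydropathy and size tables are model inputs; this fills every listed
    residue with sigma = 6.0 Å, lambda = 0.5 so small systems run out of the
    box.  Use :func:`dropletmd.synthetic.gen_test_parameters` for varied,
    seeded tables.
    """
    ps = ParameterSet()
    for r in residues:
        ps.hps.sigma[r] = 6.0
        ps.hps.lam[r] = 0.5
        ps.aicg.sigma[r] = 5.0
    return ps
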