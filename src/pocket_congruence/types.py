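"""Domain containers shared across the pipeline.

Residues are addressed throughout by the author triple (chain id, residue
number, insertion code) — never by sequential index — so that pocket lists,
alignment regions and coordinate files produced by different tools agree on
addressing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: one-letter codes of the 20 standard amino acids
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: a residue position inside one structure: (chain_id, seq_num, icode)
Position = tuple[str, int, str]


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A residue of one structure under PDB author numbering.

    ``icode`` is the insertion code ('' when absent).  ``aa`` is the
    one-letter amino-acid code, 'X' for anything outside the 20 standard
    residues.
    """

    chain_id: str
    seq_num: int
    icode: str = ""
    aa: str = "X"

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"unknown amino-acid code {self.aa!r}")

    @property
    def position(self) -> Position:
        """Identity triple used for set operations; the aa type is ignored."""
        return (self.chain_id, self.seq_num, self.icode)


@dataclass
class ProteinResidue:
    """One polymer residue with its named atoms (coordinates in Å)."""

    ref: ResidueRef
    atom_names: list[str] = field(default_factory=list)
    elements: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


@dataclass
class HetGroup:
    """A HETATM group (candidate ligand); waters are never stored."""

    name: str
    chain_id: str
    seq_num: int
    atom_names: list[str] = field(default_factory=list)
    elements: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


@dataclass
class Structure:
    """A parsed coordinate file: polymer chains plus ligand candidates."""

    structure_id: str
    chains: dict[str, list[ProteinResidue]] = field(default_factory=dict)
    het_groups: list[HetGroup] = field(default_factory=list)

    def residue_index(self) -> dict[Position, ProteinResidue]:
        out: dict[Position, ProteinResidue] = {}
        for residues in self.chains.values():
            for res in residues:
                out[res.ref.position] = res
        return out

    def longest_chain(self) -> str:
        """Chain with the most residues — the default comparison subject."""
        if not self.chains:
            raise ValueError(f"structure {self.structure_id} has no chains")
        return max(self.chains, key=lambda c: (len(self.chains[c]), c))


@dataclass(frozen=True)
class Pocket:
    """A predicted binding pocket as a residue set on one structure."""

    pocket_id: str
    structure_id: str
    residues: frozenset[ResidueRef]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"pocket {self.pocket_id} has no residues")

    @property
    def positions(self) -> frozenset[Position]:
        return frozenset(r.position for r in self.residues)


#: the two structural-alignment modes
MODES = ("flexible", "rigid")


@dataclass(frozen=True)
class SimilarRegion:
    """Residue positions of the structurally similar portion of a structure
    reported by one alignment mode (flexible or rigid)."""

    structure_id: str
    mode: str
    positions: frozenset[Position]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown alignment mode {self.mode!r}")


@dataclass(frozen=True)
class DockMode:
    index: int
    affinity: float  # kcal/mol
    rmsd_lb: float = 0.0
    rmsd_ub: float = 0.0


@dataclass
class DockingLog:
    """Scored modes of one ligand docked into one pocket."""

    ligand_id: str
    modes: list[DockMode]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("docking log has no modes")
        idx = [m.index for m in self.modes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("mode indices must be strictly increasing")
        if not all(math.isfinite(m.affinity) for m in self.modes):
            raise ValueError("non-finite affinity in docking log")


@dataclass
class LigandPose:
    """Named ligand atoms with coordinates and an optional binding affinity."""

    ligand_id: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray
    affinity: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atom_names) != len(self.coords):
            raise ValueError("atom names and coordinates disagree in length")
        if len(set(self.atom_names)) != len(self.atom_names):
            raise ValueError("duplicate atom names in pose")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass(frozen=True)
class MsWhimDescriptor:
    """Electrostatic (MS-WHIM) descriptor of a pocket: a point in 3-space."""

    pocket_id: str
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class PocketPairRecord:
    """One compared pocket pair with every field the battery consumes.

    Any analysis field may be ``None`` (missing); missing fields are excluded
    pairwise from correlations downstream.
    """

    ligand_id: str
    pocket_id_a: str
    pocket_id_b: str
    ps_score: Optional[float] = None
    affinity_a: Optional[float] = None
    affinity_b: Optional[float] = None
    abs_affinity_diff: Optional[float] = None
    conformer_rmsd: Optional[float] = None
    shared_contacts: Optional[int] = None
    mswhim_distance: Optional[float] = None
    overlap_sum: Optional[float] = None

    def __post_init__(self) -> None:
        if (
            self.abs_affinity_diff is None
            and self.affinity_a is not None
            and self.affinity_b is not None
        ):
            self.abs_affinity_diff = abs(self.affinity_a - self.affinity_b)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: int
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


@dataclass(frozen=True)
class SeqSimPair:
    """One printed structural-comparison row: alignment RMSDs (Å) and
    flexible/rigid sequence-similarity percentages."""

    pair_label: str
    rmsd_flex: float
    rmsd_rigid: float
    sim_flex: float
    sim_rigid: float

    def __post_init__(self) -> None:
        for s in (self.sim_flex, self.sim_rigid):
            if not 0.0 <= s <= 100.0:
                raise ValueError("sequence similarity must be in [0, 100]")


@dataclass(frozen=True)
class ControlRecord:
    """Docking-reliability control: conformer RMSD of a ligand pair from
    deposited complexes vs from re-docked poses."""

    pair_id: str
    rmsd_actual: float
    rmsd_docked: float

    def __post_init__(self) -> None:
        if self.rmsd_actual < 0 or self.rmsd_docked < 0:
            raise ValueError("RMSD values must be non-negative")


def positions_from_refs(refs: Sequence[ResidueRef]) -> frozenset[Position]:
    return frozenset(r.position for r in refs)
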