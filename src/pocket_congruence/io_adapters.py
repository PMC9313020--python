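"""Readers and writers for every external artifact the pipeline touches.

Coordinates travel as PDB-format files (parsed with gemmi).  Pocket lists and
alignment-region reports use a small documented tabular dialect defined by
this package; PS (pocket-similarity) reports and docking logs are tolerant
line-scanners keyed on labeled fields, because the upstream tools' formats
are versioned and under-specified.  All readers are deterministic and never
mutate their input.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Union

import gemmi
import numpy as np
import pandas as pd

from .types import (
    DockMode,
    DockingLog,
    HetGroup,
    LigandPose,
    Pocket,
    PocketPairRecord,
    Position,
    ProteinResidue,
    ResidueRef,
    SimilarRegion,
    Structure,
    ControlRecord,
    MODES,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed record in an input file (message names the line)."""


# --------------------------------------------------------------------------
# PDB coordinates

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def one_letter(resname: str) -> str:
    """Map a 3-letter residue name to a one-letter code, 'X' if unknown."""
    info = gemmi.find_tabulated_residue(resname.strip().upper())
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() and code != "?" else "X"


def _prevalidate_pdb(path: Path) -> None:
    # gemmi tolerates fixed-column damage silently; fail loudly instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path}:{lineno}: truncated coordinate record"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparseable coordinate columns"
                    ) from None


def read_structure(path: PathLike, structure_id: Optional[str] = None) -> Structure:
    """Read a PDB-format file into a :class:`Structure`.

    ATOM records are grouped into chains/residues preserving author numbering
    and insertion codes; non-water HETATM groups become ligand candidates.
    Only the first altloc conformer is kept and waters are always dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ParseError(f"{path}: {exc}") from exc
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    if len(st) == 0:
        raise ParseError(f"{path}: no ATOM or HETATM records")
    sid = structure_id or (st.name.strip() or path.stem)
    out = Structure(structure_id=sid)
    model = st[0]
    n_atoms = 0
    for chain in model:
        for res in chain:
            names = [a.name for a in res]
            elements = [a.element.name for a in res]
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
            if not np.all(np.isfinite(coords)):
                raise ParseError(f"{path}: non-finite coordinates in {res.name}")
            n_atoms += len(names)
            icode = res.seqid.icode.strip()
            if res.het_flag == "H" or not gemmi.find_tabulated_residue(
                res.name
            ) or not gemmi.find_tabulated_residue(res.name).is_amino_acid():
                if res.name.strip().upper() in _WATER_NAMES:
                    continue
                out.het_groups.append(
                    HetGroup(
                        name=res.name.strip(),
                        chain_id=chain.name,
                        seq_num=res.seqid.num,
                        atom_names=names,
                        elements=elements,
                        coords=coords,
                    )
                )
            else:
                ref = ResidueRef(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    icode=icode,
                    aa=one_letter(res.name),
                )
                out.chains.setdefault(chain.name, []).append(
                    ProteinResidue(
                        ref=ref, atom_names=names, elements=elements, coords=coords
                    )
                )
    if n_atoms == 0:
        raise ParseError(f"{path}: no ATOM or HETATM records")
    return out


def write_structure(structure: Structure, path: PathLike) -> None:
    """Write a :class:`Structure` back to PDB format (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for chain_id in sorted(structure.chains):
        chain = gemmi.Chain(chain_id)
        for res in structure.chains[chain_id]:
            chain.add_residue(
                _gemmi_residue(
                    _ONE_TO_THREE.get(res.ref.aa, "UNK"),
                    res.ref.seq_num,
                    res.ref.icode,
                    "A",
                    res.atom_names,
                    res.elements,
                    res.coords,
                )
            )
        model.add_chain(chain)
    for het in structure.het_groups:
        chain = gemmi.Chain(het.chain_id or "L")
        chain.add_residue(
            _gemmi_residue(
                het.name, het.seq_num, "", "H", het.atom_names, het.elements, het.coords
            )
        )
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _gemmi_residue(name, seq_num, icode, het_flag, atom_names, elements, coords):
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(seq_num, icode or " ")
    res.het_flag = het_flag
    for an, el, xyz in zip(atom_names, elements, coords):
        at = gemmi.Atom()
        at.name = an
        at.element = gemmi.Element(el)
        at.pos = gemmi.Position(*map(float, xyz))
        res.add_atom(at)
    return res


# --------------------------------------------------------------------------
# Ligand poses (PDB HETATM groups)

def read_pose(
    path: PathLike,
    ligand_id: Optional[str] = None,
    affinity: Optional[float] = None,
) -> LigandPose:
    """Read a docked/deposited ligand pose from a PDB-format HETATM file."""
    st = read_structure(path, structure_id="pose")
    if not st.het_groups:
        raise ParseError(f"{path}: no HETATM ligand group found")
    het = st.het_groups[0]
    return LigandPose(
        ligand_id=ligand_id or het.name,
        atom_names=het.atom_names,
        elements=het.elements,
        coords=het.coords,
        affinity=affinity,
    )


def write_pose(pose: LigandPose, path: PathLike) -> None:
    st = Structure(structure_id=pose.ligand_id)
    st.het_groups.append(
        HetGroup(
            name=pose.ligand_id[:3].upper() or "LIG",
            chain_id="L",
            seq_num=1,
            atom_names=pose.atom_names,
            elements=pose.elements,
            coords=pose.coords,
        )
    )
    write_structure(st, path)


# --------------------------------------------------------------------------
# Pocket residue lists

def read_pocket_file(path: PathLike) -> Pocket:
    """Read a pocket residue list (chain, resnum, icode, resname per row).

    Duplicate rows collapse to one residue; residue names outside the
    standard 20 are kept with aa='X' and a logged warning.
    """
    path = Path(path)
    pocket_id = path.stem
    structure_id = None
    residues: set[ResidueRef] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(pocket_id|structure_id)\s*:\s*(\S+)", line)
                if m:
                    if m.group(1) == "pocket_id":
                        pocket_id = m.group(2)
                    else:
                        structure_id = m.group(2)
                continue
            fields = re.split(r"[,\s]+", line)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected chain resnum [icode] resname")
            if len(fields) == 3:
                chain, num, name = fields
                icode = ""
            else:
                chain, num, icode, name = fields[:4]
                icode = "" if icode in ("-", ".") else icode
            try:
                seq_num = int(num)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad residue number {num!r}") from None
            aa = one_letter(name) if len(name) > 1 else (
                name.upper() if name.upper() in _ONE_TO_THREE else "X"
            )
            if aa == "X":
                logger.warning("%s:%d: unknown residue name %r kept as 'X'", path, lineno, name)
            residues.add(ResidueRef(chain_id=chain, seq_num=seq_num, icode=icode, aa=aa))
    if not residues:
        raise ParseError(f"{path}: pocket file lists no residues")
    if structure_id is None:
        structure_id = pocket_id.rsplit(".", 1)[0]
    return Pocket(pocket_id=pocket_id, structure_id=structure_id, residues=frozenset(residues))


def write_pocket_file(pocket: Pocket, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# pocket residue list\n")
        fh.write(f"# pocket_id: {pocket.pocket_id}\n")
        fh.write(f"# structure_id: {pocket.structure_id}\n")
        fh.write("# chain resnum icode resname\n")
        for ref in sorted(pocket.residues):
            fh.write(
                f"{ref.chain_id} {ref.seq_num} {ref.icode or '-'} "
                f"{_ONE_TO_THREE.get(ref.aa, 'UNK')}\n"
            )


# --------------------------------------------------------------------------
# Structural-alignment region reports

def read_region_report(path: PathLike) -> list[SimilarRegion]:
    """Read aligned-region ranges, one row per range.

    Row format: ``structure_id mode chain start end``; ranges are inclusive
    on both ends and overlapping ranges union silently.
    """
    path = Path(path)
    grouped: dict[tuple[str, str], set[Position]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"[,\s]+", line)
            if len(fields) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 'structure mode chain start end'"
                )
            sid, mode, chain, start, end = fields
            if mode not in MODES:
                raise ParseError(f"{path}:{lineno}: unknown alignment mode {mode!r}")
            try:
                lo, hi = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad range bounds") from None
            if hi < lo:
                raise ParseError(f"{path}:{lineno}: range end precedes start")
            key = (sid, mode)
            if key not in grouped:
                grouped[key] = set()
                order.append(key)
            grouped[key].update((chain, n, "") for n in range(lo, hi + 1))
    return [
        SimilarRegion(structure_id=sid, mode=mode, positions=frozenset(grouped[(sid, mode)]))
        for sid, mode in order
    ]


def write_region_report(regions: Iterable[SimilarRegion], path: PathLike) -> None:
    """Write regions as maximal consecutive ranges per chain."""
    with open(path, "w") as fh:
        fh.write("# structural-alignment similar regions\n")
        fh.write("# structure mode chain start end\n")
        for reg in regions:
            by_chain: dict[str, list[int]] = {}
            for chain, num, _ in sorted(reg.positions):
                by_chain.setdefault(chain, []).append(num)
            for chain in sorted(by_chain):
                nums = sorted(set(by_chain[chain]))
                start = prev = nums[0]
                for n in nums[1:] + [None]:
                    if n is not None and n == prev + 1:
                        prev = n
                        continue
                    fh.write(f"{reg.structure_id} {reg.mode} {chain} {start} {prev}\n")
                    if n is not None:
                        start = prev = n


# --------------------------------------------------------------------------
# Pocket-comparison (PS-score) reports

_PAIR_RE = re.compile(r">>>\s*Pair\s*:?\s*(\S+)\s+(?:vs\.?|and)\s+(\S+)", re.I)
_PS_RE = re.compile(r"PS-score\s*[=:]?\s*(-?[\d.]+(?:[eE][-+]?\d+)?)")
_RMSD_RE = re.compile(r"\bRMSD\s*[=:]?\s*(-?[\d.]+(?:[eE][-+]?\d+)?)")


def read_ps_report(path: PathLike) -> list[tuple[str, str, float, float]]:
    """Read pocket-pair blocks: (pocket_id_a, pocket_id_b, ps_score, align_rmsd).

    A block without a PS-score line is skipped with a warning.
    """
    path = Path(path)
    text = Path(path).read_text()
    blocks = []
    current = None
    for line in text.splitlines():
        m = _PAIR_RE.search(line)
        if m:
            if current is not None:
                blocks.append(current)
            current = {"a": m.group(1), "b": m.group(2), "ps": None, "rmsd": float("nan")}
            continue
        if current is None:
            continue
        mp = _PS_RE.search(line)
        if mp:
            current["ps"] = float(mp.group(1))
            continue
        mr = _RMSD_RE.search(line)
        if mr:
            current["rmsd"] = float(mr.group(1))
    if current is not None:
        blocks.append(current)
    if not blocks:
        raise ParseError(f"{path}: no pocket-pair blocks found")
    out = []
    for blk in blocks:
        if blk["ps"] is None:
            logger.warning("%s: pair %s vs %s lacks a PS-score line; skipped",
                           path, blk["a"], blk["b"])
            continue
        out.append((blk["a"], blk["b"], blk["ps"], blk["rmsd"]))
    return out


def write_ps_report(
    pairs: Iterable[tuple[str, str, float, float]], path: PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("# pocket-comparison report\n")
        for a, b, ps, rmsd in pairs:
            fh.write(f">>> Pair: {a} vs {b}\n")
            fh.write(f"PS-score = {ps:.5f}\n")
            fh.write(f"RMSD = {rmsd:.3f}\n\n")


# --------------------------------------------------------------------------
# Docking logs

_MODE_ROW_RE = re.compile(
    r"^\s*(\d+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s+(-?[\d.]+)\s*$"
)


def read_docking_log(path: PathLike) -> DockingLog:
    """Read a docking log's mode table (index, affinity kcal/mol, two
    auxiliary RMSD columns)."""
    path = Path(path)
    ligand_id = path.stem
    modes: list[DockMode] = []
    with open(path) as fh:
        for line in fh:
            m = re.match(r"\s*Ligand\s*[:=]\s*(\S+)", line, re.I)
            if m:
                ligand_id = m.group(1)
                continue
            row = _MODE_ROW_RE.match(line)
            if row:
                modes.append(
                    DockMode(
                        index=int(row.group(1)),
                        affinity=float(row.group(2)),
                        rmsd_lb=float(row.group(3)),
                        rmsd_ub=float(row.group(4)),
                    )
                )
    if not modes:
        raise ParseError(f"{path}: no mode table found")
    return DockingLog(ligand_id=ligand_id, modes=modes)


def write_docking_log(log: DockingLog, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"Ligand: {log.ligand_id}\n")
        fh.write("mode |   affinity | dist from best mode\n")
        fh.write("     | (kcal/mol) | rmsd l.b.| rmsd u.b.\n")
        fh.write("-----+------------+----------+----------\n")
        for m in log.modes:
            fh.write(f"{m.index:>5} {m.affinity:>12.3f} {m.rmsd_lb:>10.3f} {m.rmsd_ub:>10.3f}\n")


# --------------------------------------------------------------------------
# Record / control CSV tables

RECORD_COLUMNS = [
    "ligand_id", "pocket_id_a", "pocket_id_b", "ps_score",
    "affinity_a", "affinity_b", "abs_affinity_diff", "conformer_rmsd",
    "shared_contacts", "mswhim_distance", "overlap_sum",
]


def records_to_frame(records: Iterable[PocketPairRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[PocketPairRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in RECORD_COLUMNS:
            v = row.get(c)
            if pd.isna(v):
                v = None
            elif c == "shared_contacts":
                v = int(v)
            elif c not in ("ligand_id", "pocket_id_a", "pocket_id_b"):
                v = float(v)
            kwargs[c] = v
        records.append(PocketPairRecord(**kwargs))
    return records


def write_records_csv(records: Iterable[PocketPairRecord], path: PathLike) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.6g")


def read_records_csv(path: PathLike) -> list[PocketPairRecord]:
    return frame_to_records(pd.read_csv(path))


def write_control_csv(records: Iterable[ControlRecord], path: PathLike) -> None:
    pd.DataFrame(
        [{"pair_id": r.pair_id, "rmsd_actual": r.rmsd_actual, "rmsd_docked": r.rmsd_docked}
         for r in records]
    ).to_csv(path, index=False, float_format="%.6g")


def read_control_csv(path: PathLike) -> list[ControlRecord]:
    df = pd.read_csv(path)
    return [
        ControlRecord(str(r.pair_id), float(r.rmsd_actual), float(r.rmsd_docked))
        for r in df.itertuples()
    ]
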