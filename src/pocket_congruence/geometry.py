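"""Ligand-pose geometry: best-mode selection, distance-based contact
detection, shared-residue counting, and conformer RMSD after optimal rigid
superposition.
"""
from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .types import DockingLog, LigandPose, ResidueRef, Structure

logger = logging.getLogger(__name__)

#: distance criterion for a protein-ligand contact, in Å
DEFAULT_CONTACT_CUTOFF = 5.0


def select_best_mode(log: DockingLog, poses: Sequence[LigandPose]) -> LigandPose:
    """The docked mode with the most negative binding affinity.

    ``poses`` is indexed consistently with ``log.modes`` (same order).  Ties
    break toward the lowest mode index.  The returned pose carries the
    winning affinity.
    """
    if len(poses) != len(log.modes):
        raise ValueError(
            f"{len(poses)} poses for {len(log.modes)} scored modes"
        )
    best = min(range(len(log.modes)), key=lambda i: (log.modes[i].affinity, log.modes[i].index))
    pose = poses[best]
    return LigandPose(
        ligand_id=pose.ligand_id,
        atom_names=list(pose.atom_names),
        elements=list(pose.elements),
        coords=pose.coords.copy(),
        affinity=log.modes[best].affinity,
    )


def contact_residues(
    structure: Structure,
    pose: LigandPose,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> frozenset[ResidueRef]:
    """Protein residues with ≥1 heavy atom within ``cutoff`` Å of ≥1 ligand atom.

    Hydrogens are ignored on both sides (docking outputs are heavy-atom).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_mask = [el.upper() != "H" for el in pose.elements]
    lig = pose.coords[np.asarray(lig_mask, dtype=bool)]
    if lig.size == 0:
        raise ValueError("ligand pose has no (heavy) atoms")
    tree = cKDTree(lig)
    contacts: set[ResidueRef] = set()
    for residues in structure.chains.values():
        for res in residues:
            heavy = np.asarray(
                [el.upper() != "H" for el in res.elements], dtype=bool
            )
            coords = res.coords[heavy]
            if coords.size == 0:
                continue
            dist, _ = tree.query(coords, k=1)
            if np.min(dist) <= cutoff:
                contacts.add(res.ref)
    return frozenset(contacts)


def shared_contact_count(
    contacts_a: Iterable[ResidueRef], contacts_b: Iterable[ResidueRef]
) -> int:
    """Number of type-matched residue pairs across two contact sets.

    The two pockets live on different proteins, so "same residue" means same
    amino-acid type; the count is the multiset intersection of the two
    amino-acid-type multisets (each residue used at most once).
    """
    counts_a = Counter(r.aa for r in contacts_a)
    counts_b = Counter(r.aa for r in contacts_b)
    return sum((counts_a & counts_b).values())


def superpose_rmsd(pose_a: LigandPose, pose_b: LigandPose) -> float:
    """RMSD between two poses of the same ligand after optimal rigid
    superposition (rotation + translation, reflections excluded).

    Atoms are paired by identical atom name; ≥3 matched pairs are required.
    """
    names_b = {n: i for i, n in enumerate(pose_b.atom_names)}
    pairs = [(i, names_b[n]) for i, n in enumerate(pose_a.atom_names) if n in names_b]
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} atom-name-matched pairs between "
            f"{pose_a.ligand_id} and {pose_b.ligand_id}; need ≥3"
        )
    ia, ib = zip(*pairs)
    a = pose_a.coords[list(ia)]
    b = pose_b.coords[list(ib)]
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    if np.linalg.matrix_rank(a_c, tol=1e-8) < 2 or np.linalg.matrix_rank(b_c, tol=1e-8) < 2:
        logger.warning("collinear atom coordinates; superposition is degenerate")
    # Kabsch via scipy: finds the proper rotation minimizing |a - R b|.
    # Residuals are measured explicitly (the library's reported rssd loses
    # precision to cancellation for near-exact rigid copies).
    rot, _ = Rotation.align_vectors(a_c, b_c)
    diff = a_c - rot.apply(b_c)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
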