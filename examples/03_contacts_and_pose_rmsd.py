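"""Ligand contacts at 5 Å and conformer RMSD between docked poses.

Generates a small synthetic bundle (coordinates, docking logs, poses), picks
one pocket, detects the protein residues within 5 Å of the best-scored
docked pose, and superposes the deposited vs docked ligand conformers.
"""
from pathlib import Path
from tempfile import TemporaryDirectory

from pocket_congruence import (
    SyntheticConfig,
    contact_residues,
    gen_structure_bundle,
    select_best_mode,
    superpose_rmsd,
)
from pocket_congruence import io_adapters as io

with TemporaryDirectory() as tmp:
    bundle = Path(tmp)
    truth = gen_structure_bundle(SyntheticConfig(seed=5, n_gpcrs=2), bundle)

    pid = sorted(truth.pockets)[0]
    sid = truth.pockets[pid].structure_id
    structure = io.read_structure(bundle / "structures" / f"{sid}.pdb", structure_id=sid)
    log = io.read_docking_log(bundle / "docking" / f"{pid}.log")
    poses = [io.read_pose(bundle / "poses" / f"{pid}_mode{m.index}.pdb")
             for m in log.modes]

    best = select_best_mode(log, poses)
    print(f"pocket {pid}: best of {len(log.modes)} modes has affinity "
          f"{best.affinity:.3f} kcal/mol (most negative = strongest binding)")

    contacts = contact_residues(structure, best, cutoff=5.0)
    aa_types = "".join(sorted(r.aa for r in contacts))
    print(f"{len(contacts)} residues within 5 Å of the ligand (types: {aa_types})")

    deposited = io.read_pose(bundle / "poses" / f"{pid}_deposited.pdb")
    rmsd = superpose_rmsd(deposited, best)
    print(f"conformer RMSD deposited vs docked: {rmsd:.3f} Å "
          f"(after optimal rigid superposition of name-matched atoms)")
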