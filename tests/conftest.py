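"""Shared fixtures: small random generators for pockets, regions and poses.

All randomness is seeded; hypothesis runs derandomized so the suite is
reproducible everywhere.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from pocket_congruence.types import (
    LigandPose,
    Pocket,
    Position,
    ProteinResidue,
    ResidueRef,
    SimilarRegion,
    Structure,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_pocket(
    rng: np.random.Generator,
    structure_id: str = "SYN1",
    size: int | None = None,
    pocket_id: str | None = None,
    chain: str = "A",
) -> Pocket:
    size = size if size is not None else int(rng.integers(1, 30))
    nums = rng.choice(np.arange(1, 200), size=size, replace=False)
    residues = frozenset(
        ResidueRef(chain, int(n), "", str(rng.choice(list(AA)))) for n in nums
    )
    return Pocket(
        pocket_id=pocket_id or f"{structure_id}.1",
        structure_id=structure_id,
        residues=residues,
    )


def random_region(
    rng: np.random.Generator,
    structure_id: str = "SYN1",
    mode: str = "flexible",
    chain: str = "A",
) -> SimilarRegion:
    size = int(rng.integers(0, 120))
    nums = rng.choice(np.arange(1, 200), size=size, replace=False)
    positions: frozenset[Position] = frozenset((chain, int(n), "") for n in nums)
    return SimilarRegion(structure_id=structure_id, mode=mode, positions=positions)


def random_pose(
    rng: np.random.Generator, n_atoms: int = 10, ligand_id: str = "LIG1"
) -> LigandPose:
    return LigandPose(
        ligand_id=ligand_id,
        atom_names=[f"C{i + 1}" for i in range(n_atoms)],
        elements=["C"] * n_atoms,
        coords=rng.normal(0.0, 2.0, (n_atoms, 3)),
    )


def random_structure(
    rng: np.random.Generator, n_res: int = 50, structure_id: str = "SYN1"
) -> Structure:
    st = Structure(structure_id=structure_id)
    residues = []
    for i in range(n_res):
        center = rng.uniform(-20, 20, 3)
        n_at = int(rng.integers(1, 5))
        names = ["CA", "CB", "CG", "CD"][:n_at]
        residues.append(
            ProteinResidue(
                ref=ResidueRef("A", i + 1, "", str(rng.choice(list(AA)))),
                atom_names=names,
                elements=["C"] * n_at,
                coords=center + rng.normal(0, 1.0, (n_at, 3)),
            )
        )
    st.chains["A"] = residues
    return st


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small structure-level bundle shared by pipeline tests."""
    from pocket_congruence.synthetic_data import SyntheticConfig, gen_structure_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    config = SyntheticConfig(seed=11, n_gpcrs=3, pockets_per_structure=2)
    truth = gen_structure_bundle(config, outdir)
    return outdir, config, truth
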