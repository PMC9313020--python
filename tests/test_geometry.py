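"""Geometry: mode selection, contact detection, shared residues, RMSD."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pocket_congruence import geometry
from pocket_congruence.types import (
    DockMode,
    DockingLog,
    LigandPose,
    ResidueRef,
)

from conftest import random_pose, random_structure


def make_log(affinities):
    return DockingLog(
        "L", [DockMode(i + 1, a) for i, a in enumerate(affinities)]
    )


def make_poses(n, rng):
    return [random_pose(rng, n_atoms=5) for _ in range(n)]


class TestSelectBestMode:
    def test_most_negative_wins(self, rng):
        log = make_log([-7.2, -8.1, -6.5])
        poses = make_poses(3, rng)
        best = geometry.select_best_mode(log, poses)
        np.testing.assert_array_equal(best.coords, poses[1].coords)
        assert best.affinity == -8.1

    def test_single_mode(self, rng):
        log = make_log([-5.0])
        (pose,) = make_poses(1, rng)
        assert geometry.select_best_mode(log, [pose]).affinity == -5.0

    def test_tie_breaks_to_lowest_index(self, rng):
        log = make_log([-8.0, -8.0])
        poses = make_poses(2, rng)
        best = geometry.select_best_mode(log, poses)
        np.testing.assert_array_equal(best.coords, poses[0].coords)

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            geometry.select_best_mode(make_log([-8.0]), make_poses(2, rng))


def brute_force_contacts(structure, pose, cutoff):
    """All-pairs distance scan, no spatial index."""
    found = set()
    for residues in structure.chains.values():
        for res in residues:
            hit = False
            for rc in res.coords:
                for lc in pose.coords:
                    if np.linalg.norm(rc - lc) <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                found.add(res.ref)
    return frozenset(found)


class TestContactResidues:
    def test_coincident_atom_included(self, rng):
        st = random_structure(rng, n_res=5)
        coord = st.chains["A"][2].coords[0]
        pose = LigandPose("L", ["C1", "C2", "C3"], ["C"] * 3,
                          np.vstack([coord, coord + 30.0, coord + 40.0]))
        assert st.chains["A"][2].ref in geometry.contact_residues(st, pose)

    def test_just_outside_cutoff_excluded(self):
        from pocket_congruence.types import ProteinResidue, Structure

        st = Structure("S")
        st.chains["A"] = [
            ProteinResidue(
                ResidueRef("A", 1, "", "G"), ["CA"], ["C"],
                np.array([[6.0, 0.0, 0.0]]),
            )
        ]
        pose = LigandPose("L", ["C1", "C2", "C3"], ["C"] * 3,
                          np.array([[0.0, 0, 0], [0, 50, 0], [0, 0, 50.0]]))
        assert geometry.contact_residues(st, pose, cutoff=5.0) == frozenset()

    def test_hydrogens_ignored(self, rng):
        from pocket_congruence.types import ProteinResidue, Structure

        st = Structure("S")
        st.chains["A"] = [
            ProteinResidue(
                ResidueRef("A", 1, "", "G"), ["H1", "CA"], ["H", "C"],
                np.array([[1.0, 0, 0], [20.0, 0, 0]]),
            )
        ]
        pose = LigandPose("L", ["C1", "C2", "C3"], ["C"] * 3,
                          np.array([[0.0, 0, 0], [0, 50, 0], [0, 0, 50.0]]))
        # only the hydrogen is near; it must not create a contact
        assert geometry.contact_residues(st, pose) == frozenset()

    @pytest.mark.parametrize("seed", range(20))
    def test_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        st = random_structure(rng, n_res=50)
        pose = random_pose(rng, n_atoms=10)
        pose.coords = rng.uniform(-20, 20, 3) + rng.normal(0, 3, (10, 3))
        for cutoff in (3.0, 5.0, 8.0):
            assert geometry.contact_residues(st, pose, cutoff) == brute_force_contacts(
                st, pose, cutoff
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        st = random_structure(rng, n_res=40)
        pose = random_pose(rng, n_atoms=8)
        at4 = geometry.contact_residues(st, pose, 4.0)
        at5 = geometry.contact_residues(st, pose, 5.0)
        assert at4 <= at5


def refs(aas):
    return [ResidueRef("A", i + 1, "", aa) for i, aa in enumerate(aas)]


class TestSharedContactCount:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("SK", "SA", 1),      # serine shared
            ("SKA", "SKA", 3),    # identical sets
            ("SSK", "S", 1),
            ("SS", "SSS", 2),
        ],
    )
    def test_multiset_intersection(self, a, b, expected):
        # refs on different proteins: position differs, type decides
        ca = refs(a)
        cb = [ResidueRef("B", 100 + i, "", aa) for i, aa in enumerate(b)]
        assert geometry.shared_contact_count(ca, cb) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        aas = list("ACDEFG")
        a = refs(rng.choice(aas, size=rng.integers(0, 10)))
        b = refs(rng.choice(aas, size=rng.integers(0, 10)))
        n = geometry.shared_contact_count(a, b)
        assert n == geometry.shared_contact_count(b, a)
        assert 0 <= n <= min(len(a), len(b))


def grid_oracle_rmsd(pose_a, pose_b, n_starts=400):
    """Minimum RMSD over rotations by dense quasi-random search + polish.

    Independent of the SVD-based path: translations are removed by
    centering and the rotation is optimized numerically."""
    a = pose_a.coords - pose_a.coords.mean(axis=0)
    b = pose_b.coords - pose_b.coords.mean(axis=0)

    def f(rotvec):
        d = a - Rotation.from_rotvec(rotvec).apply(b)
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    rng = np.random.default_rng(0)
    best_val, best_rv = np.inf, None
    for q in rng.normal(size=(n_starts, 4)):
        rv = Rotation.from_quat(q / np.linalg.norm(q)).as_rotvec()
        v = f(rv)
        if v < best_val:
            best_val, best_rv = v, rv
    res = minimize(
        f, best_rv, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
    )
    return min(best_val, float(res.fun))


class TestSuperposeRmsd:
    def test_identical_poses_zero(self, rng):
        pose = random_pose(rng)
        assert geometry.superpose_rmsd(pose, pose) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_copy_zero(self, rng):
        pose = random_pose(rng)
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7])
        moved = LigandPose(
            pose.ligand_id, list(pose.atom_names), list(pose.elements),
            rot.apply(pose.coords) + np.array([5.0, -3.0, 2.0]),
        )
        assert geometry.superpose_rmsd(pose, moved) == pytest.approx(0.0, abs=1e-8)

    def test_symmetric(self, rng):
        a, b = random_pose(rng), random_pose(rng)
        assert geometry.superpose_rmsd(a, b) == pytest.approx(
            geometry.superpose_rmsd(b, a), abs=1e-10
        )

    def test_invariant_under_rigid_motion_of_either(self, rng):
        a, b = random_pose(rng), random_pose(rng)
        base = geometry.superpose_rmsd(a, b)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5])
        b2 = LigandPose(b.ligand_id, list(b.atom_names), list(b.elements),
                        rot.apply(b.coords) + 7.0)
        assert geometry.superpose_rmsd(a, b2) == pytest.approx(base, abs=1e-8)

    def test_reflection_not_allowed(self):
        # a chiral 4-point set vs its mirror image: RMSD must stay positive
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0, 0, 1.8]])
        a = LigandPose("L", ["C1", "C2", "C3", "C4"], ["C"] * 4, coords)
        mirrored = coords.copy()
        mirrored[:, 0] *= -1
        b = LigandPose("L", ["C1", "C2", "C3", "C4"], ["C"] * 4, mirrored)
        assert geometry.superpose_rmsd(a, b) > 0.1

    def test_pairs_matched_by_atom_name(self, rng):
        pose = random_pose(rng, n_atoms=6)
        perm = [3, 1, 4, 0, 5, 2]
        shuffled = LigandPose(
            pose.ligand_id,
            [pose.atom_names[i] for i in perm],
            [pose.elements[i] for i in perm],
            pose.coords[perm],
        )
        assert geometry.superpose_rmsd(pose, shuffled) == pytest.approx(0.0, abs=1e-10)

    def test_too_few_matches_errors(self, rng):
        a = random_pose(rng, n_atoms=5)
        b = LigandPose("L", ["Z1", "Z2", "Z3", "C1", "C2"], ["C"] * 5,
                       rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="need ≥3"):
            geometry.superpose_rmsd(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_grid_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        a = random_pose(rng, n_atoms=6)
        jitter = rng.normal(0, 0.4, (6, 3))
        b = LigandPose(
            a.ligand_id, list(a.atom_names), list(a.elements),
            Rotation.from_rotvec(rng.normal(size=3)).apply(a.coords) + jitter,
        )
        assert geometry.superpose_rmsd(a, b) == pytest.approx(
            grid_oracle_rmsd(a, b), abs=1e-3
        )
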