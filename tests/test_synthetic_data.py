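"""Synthetic generators: determinism, planted correlations, bundle truth."""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pytest

from pocket_congruence import io_adapters as io
from pocket_congruence import geometry
from pocket_congruence.association_stats import pearson
from pocket_congruence.overlap_scoring import overlap_score
from pocket_congruence.synthetic_data import (
    SyntheticConfig,
    gen_control_records,
    gen_pair_records,
    gen_structure_bundle,
)
from pocket_congruence.types import Pocket, ResidueRef, SimilarRegion


def field_vector(records, name):
    return np.array([getattr(r, name) for r in records], dtype=float)


class TestGenPairRecords:
    def test_same_seed_identical(self):
        config = SyntheticConfig(seed=42, n_pairs=50)
        r1, _ = gen_pair_records(config)
        r2, _ = gen_pair_records(SyntheticConfig(seed=42, n_pairs=50))
        assert r1 == r2

    def test_different_seed_differs(self):
        r1, _ = gen_pair_records(SyntheticConfig(seed=1, n_pairs=50))
        r2, _ = gen_pair_records(SyntheticConfig(seed=2, n_pairs=50))
        assert r1 != r2

    def test_null_plant_small_sample_correlations(self):
        config = SyntheticConfig(
            seed=0, n_pairs=5000,
            planted_correlations={
                "abs_affinity_diff": 0.0, "conformer_rmsd": 0.0,
                "shared_contacts": 0.0, "mswhim_distance": 0.0,
                "overlap_sum": 0.0,
            },
        )
        records, _ = gen_pair_records(config)
        s = field_vector(records, "ps_score")
        for name in config.planted_correlations:
            r = pearson(s, field_vector(records, name)).r
            assert abs(r) < 0.05, name

    def test_strong_negative_plant_within_sampling_band(self):
        config = SyntheticConfig(
            seed=0, n_pairs=5000,
            planted_correlations={"abs_affinity_diff": -0.9},
        )
        records, _ = gen_pair_records(config)
        r = pearson(
            field_vector(records, "ps_score"),
            field_vector(records, "abs_affinity_diff"),
        ).r
        assert -0.93 <= r <= -0.87

    def test_abs_affinity_diff_consistent_with_affinities(self):
        records, _ = gen_pair_records(SyntheticConfig(seed=3, n_pairs=100))
        for rec in records:
            assert rec.abs_affinity_diff == pytest.approx(
                abs(rec.affinity_a - rec.affinity_b)
            )
            assert rec.abs_affinity_diff >= 0
            assert 0 <= rec.shared_contacts <= 10

    def test_infeasible_contact_correlation_reports_range(self):
        config = SyntheticConfig(
            seed=0, n_pairs=10,
            planted_correlations={"shared_contacts": 0.99},
        )
        with pytest.raises(ValueError, match="feasible range"):
            gen_pair_records(config)

    def test_ligand_labels_cycle(self):
        records, _ = gen_pair_records(SyntheticConfig(seed=0, n_pairs=16))
        assert len({r.ligand_id for r in records}) == 8


class TestControls:
    def test_shape_and_nonnegative(self):
        controls = gen_control_records(n=27, seed=1)
        assert len(controls) == 27
        assert all(c.rmsd_actual >= 0 and c.rmsd_docked >= 0 for c in controls)


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth_bundle")
    config = SyntheticConfig(seed=21, n_gpcrs=3, pockets_per_structure=2)
    truth = gen_structure_bundle(config, outdir)
    return outdir, config, truth


class TestStructureBundle:
    def test_pocket_files_round_trip_truth(self, bundle):
        outdir, _, truth = bundle
        for pid, pocket in truth.pockets.items():
            back = io.read_pocket_file(outdir / "pockets" / f"{pid}.pocket")
            assert back.residues == pocket.residues

    def test_region_reports_round_trip_truth(self, bundle):
        outdir, _, truth = bundle
        for pair_key, per_sid in truth.regions.items():
            a, b = sorted(pair_key)
            regions = io.read_region_report(outdir / "regions" / f"{a}__{b}.regions")
            got = {(r.structure_id, r.mode): r.positions for r in regions}
            for sid, per_mode in per_sid.items():
                for mode, reg in per_mode.items():
                    assert got[(sid, mode)] == reg.positions

    def test_ps_report_recovers_planted_scores(self, bundle):
        outdir, _, truth = bundle
        rows = io.read_ps_report(outdir / "ps_reports" / "pairs.psr")
        assert len(rows) == len(truth.ps_scores)
        for a, b, ps, _ in rows:
            assert ps == pytest.approx(truth.ps_scores[(a, b)], abs=1e-5)

    def test_overlap_truth_recomputable_from_files(self, bundle):
        outdir, _, truth = bundle
        for (pa, pb), entry in truth.overlap.items():
            pocket = io.read_pocket_file(outdir / "pockets" / f"{pa}.pocket")
            sid = pocket.structure_id
            other = truth.pockets[pb].structure_id
            a, b = sorted((sid, other))
            regions = [
                r for r in io.read_region_report(outdir / "regions" / f"{a}__{b}.regions")
                if r.structure_id == sid
            ]
            per_mode = {r.mode: r for r in regions}
            assert overlap_score(pocket, per_mode["flexible"]) == entry["s_flex_a"]
            assert overlap_score(pocket, per_mode["rigid"]) == entry["s_rigid_a"]

    def test_contact_truth_matches_pipeline_recomputation(self, bundle):
        outdir, _, truth = bundle
        structures = {}
        for pid, expected in truth.contacts.items():
            sid = truth.pockets[pid].structure_id
            if sid not in structures:
                structures[sid] = io.read_structure(
                    outdir / "structures" / f"{sid}.pdb", structure_id=sid
                )
            log = io.read_docking_log(outdir / "docking" / f"{pid}.log")
            poses = [
                io.read_pose(outdir / "poses" / f"{pid}_mode{m.index}.pdb")
                for m in log.modes
            ]
            best = geometry.select_best_mode(log, poses)
            assert geometry.contact_residues(structures[sid], best) == expected

    def test_zero_jitter_pose_superposes_exactly(self, tmp_path):
        config = SyntheticConfig(seed=4, n_gpcrs=2, jitter_sd=0.0)
        truth = gen_structure_bundle(config, tmp_path)
        for pid in truth.pockets:
            dep = io.read_pose(tmp_path / "poses" / f"{pid}_deposited.pdb")
            log = io.read_docking_log(tmp_path / "docking" / f"{pid}.log")
            poses = [
                io.read_pose(tmp_path / "poses" / f"{pid}_mode{m.index}.pdb")
                for m in log.modes
            ]
            best = geometry.select_best_mode(log, poses)
            assert geometry.superpose_rmsd(dep, best) == pytest.approx(0.0, abs=1e-8)

    def test_jittered_pose_rmsd_near_expectation(self, bundle):
        outdir, _, truth = bundle
        ratios = []
        for pid in truth.pockets:
            dep = io.read_pose(outdir / "poses" / f"{pid}_deposited.pdb")
            log = io.read_docking_log(outdir / "docking" / f"{pid}.log")
            poses = [
                io.read_pose(outdir / "poses" / f"{pid}_mode{m.index}.pdb")
                for m in log.modes
            ]
            best = geometry.select_best_mode(log, poses)
            ratios.append(geometry.superpose_rmsd(dep, best) / truth.expected_rmsd[pid])
        assert all(0.3 < r < 2.0 for r in ratios)
        assert 0.7 < float(np.mean(ratios)) < 1.3

    def test_byte_identical_regeneration(self, bundle, tmp_path):
        outdir, config, _ = bundle
        gen_structure_bundle(config, tmp_path)
        for path in sorted(Path(outdir).rglob("*")):
            if path.is_file():
                twin = tmp_path / path.relative_to(outdir)
                assert twin.read_bytes() == path.read_bytes(), path.name

    def test_planted_half_overlap_example(self):
        # a pocket built with exactly 6 of its 12 residues inside the region
        pocket = Pocket(
            "S1.1", "S1",
            frozenset(ResidueRef("A", n, "", "G") for n in range(1, 13)),
        )
        region = SimilarRegion(
            "S1", "flexible", frozenset(("A", n, "") for n in range(1, 7))
        )
        assert overlap_score(pocket, region) == 0.5

    def test_oversized_pocket_rejected(self):
        with pytest.raises(ValueError, match="pocket_size"):
            SyntheticConfig(seed=0, residues_per_chain=10, pocket_size=12)
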