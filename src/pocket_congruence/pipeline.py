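"""End-to-end orchestration: ingest a directory of pipeline inputs, assemble
one analysis record per compared pocket pair, run the statistical battery and
emit a structured, deterministic report.

Expected input layout (all subdirectories optional except pockets/ and
ps_reports/; missing artifacts degrade the affected record fields to
"missing" with a logged warning):

    structures/<SID>.pdb
    pockets/<pocket_id>.pocket
    regions/<SID_A>__<SID_B>.regions
    ps_reports/*.psr
    docking/<pocket_id>.log
    poses/<pocket_id>_mode<i>.pdb
    controls.csv                     (optional paired-RMSD control data)
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import association_stats as stats
from . import geometry
from . import io_adapters as io
from .overlap_scoring import mean_overlap, pair_overlap_sum
from .pocket_descriptors import chebyshev_distance, mswhim_descriptor
from .types import ControlRecord, Pocket, PocketPairRecord, SimilarRegion, Structure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: Path
    output_dir: Path
    contact_cutoff: float = 5.0
    seqsim_threshold: float = 30.0
    strict_threshold: bool = True
    all_pairs: bool = False       # cross-product pockets when no PS report
    per_ligand: bool = True
    ligand_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class _Inputs:
    """Lazy view over the input directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        root = config.input_dir
        self.pockets: dict[str, Pocket] = {}
        for path in sorted((root / "pockets").glob("*.pocket")):
            pocket = io.read_pocket_file(path)
            self.pockets[pocket.pocket_id] = pocket
        self._structures: dict[str, Structure] = {}
        self._regions: dict[frozenset, dict[str, dict[str, SimilarRegion]]] = {}
        for path in sorted((root / "regions").glob("*.regions")) if (root / "regions").is_dir() else []:
            regions = io.read_region_report(path)
            sids = frozenset(r.structure_id for r in regions)
            entry = self._regions.setdefault(sids, {})
            for reg in regions:
                entry.setdefault(reg.structure_id, {})[reg.mode] = reg

    def structure(self, sid: str) -> Optional[Structure]:
        if sid not in self._structures:
            path = self.config.input_dir / "structures" / f"{sid}.pdb"
            self._structures[sid] = io.read_structure(path, structure_id=sid) if path.exists() else None
        return self._structures[sid]

    def regions_for(self, sid: str, other: str) -> Optional[dict[str, SimilarRegion]]:
        entry = self._regions.get(frozenset({sid, other}))
        if entry is None:
            return None
        return entry.get(sid)

    def best_pose(self, pocket_id: str):
        """(pose with affinity, ligand_id) of the retained docking mode."""
        log_path = self.config.input_dir / "docking" / f"{pocket_id}.log"
        if not log_path.exists():
            return None, None
        log = io.read_docking_log(log_path)
        poses = []
        for mode in log.modes:
            pose_path = self.config.input_dir / "poses" / f"{pocket_id}_mode{mode.index}.pdb"
            if not pose_path.exists():
                logger.warning("pose file missing for %s mode %d", pocket_id, mode.index)
                return None, log.ligand_id
            poses.append(io.read_pose(pose_path, ligand_id=log.ligand_id))
        return geometry.select_best_mode(log, poses), log.ligand_id

    def ps_pairs(self) -> list[tuple[str, str, float, float]]:
        ps_dir = self.config.input_dir / "ps_reports"
        pairs: list[tuple[str, str, float, float]] = []
        if ps_dir.is_dir():
            for path in sorted(ps_dir.iterdir()):
                if path.is_file():
                    pairs.extend(io.read_ps_report(path))
        if not pairs and self.config.all_pairs:
            pids = sorted(self.pockets)
            for i in range(len(pids)):
                for j in range(i + 1, len(pids)):
                    a, b = pids[i], pids[j]
                    if self.pockets[a].structure_id != self.pockets[b].structure_id:
                        pairs.append((a, b, float("nan"), float("nan")))
        if not pairs:
            raise ValueError("no pocket pairs: PS reports empty and --all-pairs not set")
        return pairs


def assemble_records(config: RunConfig) -> list[PocketPairRecord]:
    """One analysis record per compared pocket pair, every computable field
    populated and every missing field flagged (None)."""
    inputs = _Inputs(config)
    records: list[PocketPairRecord] = []
    for pid_a, pid_b, ps, _align_rmsd in inputs.ps_pairs():
        pocket_a = inputs.pockets.get(pid_a)
        pocket_b = inputs.pockets.get(pid_b)
        if pocket_a is None or pocket_b is None:
            missing = pid_a if pocket_a is None else pid_b
            logger.warning("pocket id %s unresolved; pair (%s, %s) skipped",
                           missing, pid_a, pid_b)
            continue

        overlap_sum = None
        regions_a = inputs.regions_for(pocket_a.structure_id, pocket_b.structure_id)
        regions_b = inputs.regions_for(pocket_b.structure_id, pocket_a.structure_id)
        if regions_a and regions_b:
            overlap_sum = pair_overlap_sum(
                mean_overlap(pocket_a, regions_a.values()).mean_score,
                mean_overlap(pocket_b, regions_b.values()).mean_score,
            )
        else:
            logger.warning("no alignment regions for pair (%s, %s)", pid_a, pid_b)

        pose_a, ligand_a = inputs.best_pose(pid_a)
        pose_b, ligand_b = inputs.best_pose(pid_b)
        ligand = ligand_a or ligand_b or config.ligand_id or "UNKNOWN"

        affinity_a = pose_a.affinity if pose_a is not None else None
        affinity_b = pose_b.affinity if pose_b is not None else None

        conformer_rmsd = None
        if pose_a is not None and pose_b is not None:
            conformer_rmsd = geometry.superpose_rmsd(pose_a, pose_b)

        shared = None
        st_a = inputs.structure(pocket_a.structure_id)
        st_b = inputs.structure(pocket_b.structure_id)
        if pose_a is not None and pose_b is not None and st_a is not None and st_b is not None:
            contacts_a = geometry.contact_residues(st_a, pose_a, config.contact_cutoff)
            contacts_b = geometry.contact_residues(st_b, pose_b, config.contact_cutoff)
            shared = geometry.shared_contact_count(contacts_a, contacts_b)

        mswhim_d = chebyshev_distance(
            mswhim_descriptor(pocket_a), mswhim_descriptor(pocket_b)
        )

        records.append(
            PocketPairRecord(
                ligand_id=ligand,
                pocket_id_a=pid_a,
                pocket_id_b=pid_b,
                ps_score=None if ps != ps else float(ps),  # NaN -> missing
                affinity_a=affinity_a,
                affinity_b=affinity_b,
                conformer_rmsd=conformer_rmsd,
                shared_contacts=shared,
                mswhim_distance=mswhim_d,
                overlap_sum=overlap_sum,
            )
        )
    if not records:
        raise ValueError("no records could be assembled from the inputs")
    return records


def run_report(
    records: Sequence[PocketPairRecord],
    output_dir: str | Path,
    controls: Optional[Sequence[ControlRecord]] = None,
    per_ligand: bool = True,
) -> dict[str, Path]:
    """Emit the full report: records, per-ligand PS summaries, the
    correlation battery (with affinity and electrostatic views), the control
    t-test when control records are supplied, and a text + JSON-lines
    summary.  Re-running on identical inputs reproduces identical bytes."""
    if not records:
        raise ValueError("no records to report")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["records"] = outdir / "records.csv"
    io.write_records_csv(records, paths["records"])

    summary_lines = [f"pocket congruence report (schema v1); {len(records)} pocket pairs"]
    jsonl: list[dict] = []

    try:
        ps_summary = stats.summarize_ps(records)
    except ValueError:
        ps_summary = None
    if ps_summary is not None:
        paths["ps_summary"] = outdir / "ps_summary.csv"
        ps_summary.to_csv(paths["ps_summary"], index=False, float_format="%.6g")

    battery = stats.correlation_battery(records, per_ligand=per_ligand)
    paths["correlations"] = outdir / "correlations.csv"
    battery.to_csv(paths["correlations"], index=False, float_format="%.6g")
    for view, assoc in (
        ("affinity_correlations", "ps_vs_abs_affinity_diff"),
        ("mswhim_correlations", "ps_vs_mswhim_distance"),
    ):
        sub = battery[battery["association"] == assoc]
        paths[view] = outdir / f"{view}.csv"
        sub.to_csv(paths[view], index=False, float_format="%.6g")

    for row in battery.itertuples():
        if row.status != "ok":
            summary_lines.append(
                f"  [{row.scope}/{row.ligand_id}] {row.association}: not computed (n={row.n})"
            )
            continue
        summary_lines.append(
            f"  [{row.scope}/{row.ligand_id}] {row.association}: "
            f"r={row.r:+.4f}, p={row.p_value:.4g}, n={row.n}"
        )
        jsonl.append(
            {"scope": row.scope, "ligand_id": row.ligand_id,
             "association": row.association, "r": round(row.r, 6),
             "p_value": float(f"{row.p_value:.6g}"), "n": int(row.n)}
        )

    if controls:
        t = stats.control_t_test(controls)
        paths["control_ttest"] = outdir / "control_ttest.txt"
        text = (
            "paired t-test, deposited vs re-docked conformer RMSD\n"
            f"RMSD_actual: {t.mean_a:.4f} ± {t.sd_a:.4f}\n"
            f"RMSD_docked: {t.mean_b:.4f} ± {t.sd_b:.4f}\n"
            f"t = {t.t:.4f}, df = {t.df}, p = {t.p_value:.4g}\n"
        )
        paths["control_ttest"].write_text(text)
        summary_lines.append(
            f"  [control] paired t-test: t={t.t:.4f}, df={t.df}, p={t.p_value:.4g}"
        )
        jsonl.append({"scope": "control", "t": round(t.t, 6), "df": t.df,
                      "p_value": float(f"{t.p_value:.6g}")})

    paths["summary_txt"] = outdir / "summary.txt"
    paths["summary_txt"].write_text("\n".join(summary_lines) + "\n")
    paths["summary_jsonl"] = outdir / "summary.jsonl"
    with open(paths["summary_jsonl"], "w") as fh:
        for obj in jsonl:
            fh.write(json.dumps(obj, sort_keys=True) + "\n")
    return paths


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """assemble_records + run_report, reading controls.csv when present."""
    records = assemble_records(config)
    controls_path = config.input_dir / "controls.csv"
    controls = io.read_control_csv(controls_path) if controls_path.exists() else None
    return run_report(
        records, config.output_dir, controls=controls, per_ligand=config.per_ligand
    )
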