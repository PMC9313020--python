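"""Synthetic inputs with known ground truth.

Two levels are generated:

* record level — pocket-pair analysis records in which one latent pocket
  similarity ``s`` (the PS-score) drives every analysis field with a planted
  population Pearson correlation.  The construction keeps the conditional
  mean of each field linear in ``s`` (Gaussian noise for continuous fields,
  a Binomial success probability linear in ``s`` for contact counts), so the
  planted correlations hold exactly, in closed form.

* structure level — toy coordinate bundles (PDB files on smooth helical
  traces, pocket lists, flexible/rigid region reports, PS reports, docking
  logs and ligand pose files) that exercise every reader and geometric
  operation, with exact overlap scores, 5 Å contact sets and pose transforms
  recorded as ground truth.

All randomness flows from the single seed in :class:`SyntheticConfig`;
identical configs give byte-identical bundles.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import io_adapters as io
from .overlap_scoring import mean_overlap, pair_overlap_sum
from .types import (
    DockMode,
    DockingLog,
    LigandPose,
    Pocket,
    PocketPairRecord,
    Position,
    ProteinResidue,
    ResidueRef,
    SimilarRegion,
    Structure,
    ControlRecord,
)

#: amino-acid alphabet used when drawing residue types
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: the eight ligand labels of the study, cycled over record-level pairs
LIGAND_IDS = ("AJLF", "CLQV", "DTZD", "IKSH", "NKOP", "USZP", "XLWJ", "YKMS")

#: planted population correlations between the PS-score and each field:
#: negative for dissimilarity measures (affinity gap, conformer RMSD,
#: electrostatic distance), positive for shared contacts and overlap
DEFAULT_PLANTED: dict[str, float] = {
    "abs_affinity_diff": -0.5,
    "conformer_rmsd": -0.3,
    "shared_contacts": +0.4,
    "mswhim_distance": -0.4,
    "overlap_sum": +0.3,
}

#: residual noise standard deviations of the continuous fields
DEFAULT_NOISE_SD: dict[str, float] = {
    "abs_affinity_diff": 0.8,   # kcal/mol
    "conformer_rmsd": 0.6,      # Å
    "mswhim_distance": 0.15,    # dimensionless, MS-WHIM units
    "overlap_sum": 0.2,
}


@dataclass
class SyntheticConfig:
    """Study conditions for both generation levels."""

    seed: int = 0
    # record level
    n_pairs: int = 2000
    planted_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED)
    )
    ps_range: tuple[float, float] = (0.11, 0.90)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    contact_trials: int = 10
    mean_contact_prob: float = 0.45
    affinity_range: tuple[float, float] = (-12.0, -4.0)
    # structure level
    n_gpcrs: int = 8
    residues_per_chain: int = 60
    pockets_per_structure: int = 3
    pocket_size: int = 12
    ligand_atoms: int = 12
    jitter_sd: float = 0.5
    n_modes: int = 6

    def __post_init__(self) -> None:
        lo, hi = self.ps_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("ps_range must satisfy 0 <= lo < hi <= 1")
        for name, r in self.planted_correlations.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"planted r for {name} must be in (-1, 1)")
        if self.pocket_size > self.residues_per_chain:
            raise ValueError("pocket_size cannot exceed residues_per_chain")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


# --------------------------------------------------------------------------
# record level

@dataclass
class RecordTruth:
    """Generator-side truth for a record-level dataset."""

    planted_correlations: dict[str, float]
    ps_range: tuple[float, float]
    slopes: dict[str, float]
    intercepts: dict[str, float]
    latent_s: np.ndarray


def _linear_coefficients(
    r: float, sigma: float, lo: float, hi: float
) -> tuple[float, float]:
    """Slope and intercept making Pearson(s, alpha + beta*s + N(0, sigma^2))
    exactly ``r`` for s ~ Uniform(lo, hi), with the conditional mean kept
    at least 3.5 sigma above zero over the whole s range."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"planted r must be in (-1, 1), got {r}")
    sd_s = (hi - lo) / math.sqrt(12.0)
    beta = 0.0 if r == 0 else sigma * r / (sd_s * math.sqrt(1.0 - r * r))
    # anchor the smallest conditional mean at 3.5 sigma so truncation at
    # zero has negligible (<3e-4) mass
    s_at_min = hi if beta < 0 else lo
    alpha = 3.5 * sigma - beta * s_at_min
    return beta, alpha


def _contact_slope(config: SyntheticConfig, r: float) -> float:
    """Slope c1 of p(s) = p_mean + c1 (s - s_mean) giving Pearson(s, X) = r
    for X | s ~ Binomial(m, p(s)); exact because E[X|s] is linear in s."""
    lo, hi = config.ps_range
    v = (hi - lo) ** 2 / 12.0
    m = config.contact_trials
    pbar = config.mean_contact_prob
    denom = v * (m - (m - 1) * r * r)
    c1 = math.copysign(math.sqrt(r * r * pbar * (1 - pbar) / denom), r)
    c1_max = min(pbar, 1 - pbar) / ((hi - lo) / 2.0)
    if abs(c1) > c1_max:
        r_max = _max_contact_r(config)
        raise ValueError(
            f"planted contact correlation r={r} is infeasible for "
            f"{m} trials at mean success {pbar}; feasible range is "
            f"[-{r_max:.4f}, {r_max:.4f}]"
        )
    return c1


def _max_contact_r(config: SyntheticConfig) -> float:
    lo, hi = config.ps_range
    v = (hi - lo) ** 2 / 12.0
    m = config.contact_trials
    pbar = config.mean_contact_prob
    c1_max = min(pbar, 1 - pbar) / ((hi - lo) / 2.0)
    # invert c1(r) at c1_max
    num = c1_max**2 * v * m
    den = pbar * (1 - pbar) + c1_max**2 * v * (m - 1)
    return math.sqrt(num / den)


def gen_pair_records(
    config: SyntheticConfig,
) -> tuple[list[PocketPairRecord], RecordTruth]:
    """Pocket-pair records with planted PS-score correlations.

    The latent similarity ``s`` ~ Uniform(ps_range) is reported verbatim as
    the PS-score; every analysis field is a monotone (linear-conditional-
    mean) transform of ``s`` plus noise calibrated so the population Pearson
    correlation equals the planted value.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    lo, hi = config.ps_range
    s = rng.uniform(lo, hi, n)

    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    values: dict[str, np.ndarray] = {}
    for name in ("abs_affinity_diff", "conformer_rmsd", "mswhim_distance", "overlap_sum"):
        r = config.planted_correlations.get(name, 0.0)
        sigma = config.noise_sd[name]
        beta, alpha = _linear_coefficients(r, sigma, lo, hi)
        slopes[name], intercepts[name] = beta, alpha
        v = alpha + beta * s + rng.normal(0.0, sigma, n)
        v = np.clip(v, 0.0, 2.0 if name == "overlap_sum" else None)
        values[name] = v

    r_contacts = config.planted_correlations.get("shared_contacts", 0.0)
    c1 = _contact_slope(config, r_contacts)
    slopes["shared_contacts"] = c1
    intercepts["shared_contacts"] = config.mean_contact_prob
    p = config.mean_contact_prob + c1 * (s - (lo + hi) / 2.0)
    contacts = rng.binomial(config.contact_trials, p)

    base_aff = rng.uniform(*config.affinity_range, n)
    sign = rng.choice([-1.0, 1.0], n)

    records = []
    for i in range(n):
        d = float(values["abs_affinity_diff"][i])
        records.append(
            PocketPairRecord(
                ligand_id=LIGAND_IDS[i % len(LIGAND_IDS)],
                pocket_id_a=f"SYN{2 * i + 1}.1",
                pocket_id_b=f"SYN{2 * i + 2}.1",
                ps_score=float(s[i]),
                affinity_a=float(base_aff[i]),
                affinity_b=float(base_aff[i] + sign[i] * d),
                abs_affinity_diff=d,
                conformer_rmsd=float(values["conformer_rmsd"][i]),
                shared_contacts=int(contacts[i]),
                mswhim_distance=float(values["mswhim_distance"][i]),
                overlap_sum=float(values["overlap_sum"][i]),
            )
        )
    truth = RecordTruth(
        planted_correlations=dict(config.planted_correlations),
        ps_range=config.ps_range,
        slopes=slopes,
        intercepts=intercepts,
        latent_s=s,
    )
    return records, truth


def gen_control_records(
    n: int = 27, seed: int = 0
) -> list[ControlRecord]:
    """Docking-reliability control pairs: deposited vs re-docked conformer
    RMSDs with a shared pattern, emulating a no-mean-difference control."""
    rng = np.random.default_rng(seed)
    actual = np.abs(rng.normal(1.24, 0.77, n))
    docked = np.abs(1.39 + 0.35 * (actual - 1.24) + rng.normal(0.0, 0.35, n))
    return [
        ControlRecord(pair_id=f"CTRL{i + 1}", rmsd_actual=float(a), rmsd_docked=float(d))
        for i, (a, d) in enumerate(zip(actual, docked))
    ]


# --------------------------------------------------------------------------
# structure level

@dataclass
class BundleTruth:
    """Exact generator-side quantities for a structure-level bundle."""

    pockets: dict[str, Pocket]
    regions: dict[frozenset, dict[str, dict[str, SimilarRegion]]]
    ps_scores: dict[tuple[str, str], float]
    overlap: dict[tuple[str, str], dict[str, float]]
    contacts: dict[str, frozenset[ResidueRef]]
    best_affinity: dict[str, float]
    pose_transforms: dict[str, dict]
    expected_rmsd: dict[str, float]
    ligand_id: str


def _helical_structure(
    sid: str, n_res: int, aa_seq: str, origin: np.ndarray
) -> Structure:
    """A smooth helical residue trace with 5 heavy atoms per residue.

    Not a physical fold — geometry only needs to exercise distance and
    superposition code."""
    st = Structure(structure_id=sid)
    radius, twist, rise = 2.3, math.radians(100.0), 1.5
    offsets = {
        "N": np.array([-1.2, 0.3, -0.4]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.1, 0.6, 0.3]),
        "O": np.array([1.6, 1.5, -0.3]),
        "CB": np.array([0.2, -1.3, 0.8]),
    }
    residues = []
    for i in range(n_res):
        ca = origin + np.array(
            [radius * math.cos(i * twist), radius * math.sin(i * twist), rise * i]
        )
        names = list(offsets)
        # 3-decimal coordinates survive the PDB fixed-column round trip exactly
        coords = np.round(np.array([ca + offsets[nm] for nm in names]), 3)
        ref = ResidueRef(chain_id="A", seq_num=10 + i, icode="", aa=aa_seq[i])
        residues.append(
            ProteinResidue(
                ref=ref,
                atom_names=names,
                elements=[nm[0] for nm in names],
                coords=coords,
            )
        )
    st.chains["A"] = residues
    return st


def _ca(res: ProteinResidue) -> np.ndarray:
    return res.coords[res.atom_names.index("CA")]


def _random_rotation(rng: np.random.Generator) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def _signed_permutation(rng: np.random.Generator) -> np.ndarray:
    """A random proper rotation that permutes/flips axes.

    Such rotations map 3-decimal coordinates to 3-decimal coordinates, so a
    rigidly moved pose written to PDB fixed columns stays an exact rigid copy
    of the original."""
    perm = rng.permutation(3)
    p = np.zeros((3, 3))
    signs = rng.choice([-1.0, 1.0], 3)
    for row, col in enumerate(perm):
        p[row, col] = signs[row]
    if np.linalg.det(p) < 0:
        p[0] *= -1.0
    return p


def gen_structure_bundle(
    config: SyntheticConfig, outdir: str | Path
) -> BundleTruth:
    """Write a complete toy input bundle under ``outdir`` and return truth.

    Layout: structures/, pockets/, regions/, ps_reports/, docking/, poses/,
    controls.csv and a truth/ directory of CSV sidecars.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    for sub in ("structures", "pockets", "regions", "ps_reports", "docking", "poses", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    ligand_id = "LIG1"
    sids = [f"SYN{i + 1}" for i in range(config.n_gpcrs)]
    structures: dict[str, Structure] = {}
    pockets: dict[str, Pocket] = {}
    pocket_members: dict[str, list[ProteinResidue]] = {}
    for k, sid in enumerate(sids):
        aa_seq = "".join(rng.choice(list(_AA), config.residues_per_chain))
        origin = np.array([120.0 * k, 0.0, 0.0])  # well separated
        st = _helical_structure(sid, config.residues_per_chain, aa_seq, origin)
        structures[sid] = st
        io.write_structure(st, outdir / "structures" / f"{sid}.pdb")
        residues = st.chains["A"]
        cas = np.array([_ca(r) for r in residues])
        center_idx = rng.choice(len(residues), config.pockets_per_structure, replace=False)
        for p_i, ci in enumerate(sorted(int(i) for i in center_idx), start=1):
            dist = np.linalg.norm(cas - cas[ci], axis=1)
            nearest = np.argsort(dist, kind="stable")[: config.pocket_size]
            members = [residues[int(j)] for j in sorted(int(j) for j in nearest)]
            pid = f"{sid}.{p_i}"
            pocket = Pocket(
                pocket_id=pid,
                structure_id=sid,
                residues=frozenset(r.ref for r in members),
            )
            pockets[pid] = pocket
            pocket_members[pid] = members
            io.write_pocket_file(pocket, outdir / "pockets" / f"{pid}.pocket")

    # flexible/rigid similar regions per structure pair
    regions: dict[frozenset, dict[str, dict[str, SimilarRegion]]] = {}
    for i in range(len(sids)):
        for j in range(i + 1, len(sids)):
            pair_key = frozenset({sids[i], sids[j]})
            per_sid: dict[str, dict[str, SimilarRegion]] = {}
            region_list = []
            for sid in (sids[i], sids[j]):
                per_mode: dict[str, SimilarRegion] = {}
                for mode in ("flexible", "rigid"):
                    n_ranges = int(rng.integers(1, 3))
                    positions: set[Position] = set()
                    for _ in range(n_ranges):
                        length = int(rng.integers(10, 25))
                        start = int(rng.integers(0, config.residues_per_chain - length))
                        positions.update(
                            ("A", 10 + n, "") for n in range(start, start + length)
                        )
                    reg = SimilarRegion(
                        structure_id=sid, mode=mode, positions=frozenset(positions)
                    )
                    per_mode[mode] = reg
                    region_list.append(reg)
                per_sid[sid] = per_mode
            regions[pair_key] = per_sid
            io.write_region_report(
                region_list, outdir / "regions" / f"{sids[i]}__{sids[j]}.regions"
            )

    # docking logs and poses per pocket; best mode = known rigid motion of
    # the deposited pose about its centroid, plus jitter
    best_affinity: dict[str, float] = {}
    pose_transforms: dict[str, dict] = {}
    expected_rmsd: dict[str, float] = {}
    contacts: dict[str, frozenset[ResidueRef]] = {}
    atom_names = [f"C{i + 1}" for i in range(config.ligand_atoms)]
    for pid in sorted(pockets):
        members = pocket_members[pid]
        centroid = np.mean([_ca(r) for r in members], axis=0)
        cloud = rng.normal(0.0, 1.5, (config.ligand_atoms, 3))
        cloud -= cloud.mean(axis=0)
        dep_coords = np.round(centroid + cloud, 3)
        deposited = LigandPose(
            ligand_id=ligand_id,
            atom_names=list(atom_names),
            elements=["C"] * config.ligand_atoms,
            coords=dep_coords,
        )
        io.write_pose(deposited, outdir / "poses" / f"{pid}_deposited.pdb")

        affinities = np.sort(rng.uniform(*config.affinity_range, config.n_modes))
        # the retained mode is a recorded rigid motion of the deposited pose
        # (axis permutation/flip, so the motion survives PDB 3-decimal
        # columns exactly) plus optional jitter
        p_rot = _signed_permutation(rng)
        base = dep_coords @ p_rot.T
        shift = np.round(centroid - base.mean(axis=0), 3)
        jitter = rng.normal(0.0, config.jitter_sd, (config.ligand_atoms, 3))
        poses = []
        for m in range(config.n_modes):
            if m == 0:  # the retained (most negative affinity) mode
                coords = base + shift
                if config.jitter_sd > 0:
                    coords = np.round(coords + jitter, 3)
            else:
                off = rng.normal(0.0, 2.0, 3)
                coords = np.round(centroid + off + _random_rotation(rng).apply(cloud), 3)
            poses.append(coords)
        log = DockingLog(
            ligand_id=ligand_id,
            modes=[
                DockMode(index=m + 1, affinity=float(affinities[m]))
                for m in range(config.n_modes)
            ],
        )
        io.write_docking_log(log, outdir / "docking" / f"{pid}.log")
        for m, coords in enumerate(poses, start=1):
            io.write_pose(
                LigandPose(
                    ligand_id=ligand_id,
                    atom_names=list(atom_names),
                    elements=["C"] * config.ligand_atoms,
                    coords=coords,
                ),
                outdir / "poses" / f"{pid}_mode{m}.pdb",
            )
        best_affinity[pid] = float(affinities[0])
        pose_transforms[pid] = {
            "rotation": p_rot.tolist(),
            "shift": shift.tolist(),
            "jitter_sd": config.jitter_sd,
        }
        n_at = config.ligand_atoms
        expected_rmsd[pid] = config.jitter_sd * math.sqrt(3.0 * max(n_at - 2, 1) / n_at)

        # exact 5 Å contact set of the best pose, by direct all-pairs scan
        sid = pockets[pid].structure_id
        best_coords = poses[0]
        found: set[ResidueRef] = set()
        for res in structures[sid].chains["A"]:
            d = np.linalg.norm(
                res.coords[:, None, :] - best_coords[None, :, :], axis=2
            )
            if d.min() <= 5.0:
                found.add(res.ref)
        contacts[pid] = frozenset(found)

    # PS report over all cross-structure pocket pairs
    ps_scores: dict[tuple[str, str], float] = {}
    ps_rows = []
    pids = sorted(pockets)
    for a_i in range(len(pids)):
        for b_i in range(a_i + 1, len(pids)):
            pa, pb = pids[a_i], pids[b_i]
            if pockets[pa].structure_id == pockets[pb].structure_id:
                continue
            ps = float(rng.uniform(*config.ps_range))
            ps_scores[(pa, pb)] = ps
            ps_rows.append((pa, pb, ps, float(rng.uniform(0.5, 4.0))))
    io.write_ps_report(ps_rows, outdir / "ps_reports" / "pairs.psr")

    # exact overlap truth per compared pair
    overlap: dict[tuple[str, str], dict[str, float]] = {}
    for pa, pb in ps_scores:
        entry = {}
        means = {}
        for side, pid in (("a", pa), ("b", pb)):
            sid = pockets[pid].structure_id
            other = pockets[pb if side == "a" else pa].structure_id
            per_mode = regions[frozenset({sid, other})][sid]
            res = mean_overlap(pockets[pid], per_mode.values())
            entry[f"s_flex_{side}"] = res.s_flexible
            entry[f"s_rigid_{side}"] = res.s_rigid
            entry[f"mean_{side}"] = res.mean_score
            means[side] = res.mean_score
        entry["overlap_sum"] = pair_overlap_sum(means["a"], means["b"])
        overlap[(pa, pb)] = entry

    controls = gen_control_records(n=27, seed=int(rng.integers(2**31)))
    io.write_control_csv(controls, outdir / "controls.csv")

    truth = BundleTruth(
        pockets=pockets,
        regions=regions,
        ps_scores=ps_scores,
        overlap=overlap,
        contacts=contacts,
        best_affinity=best_affinity,
        pose_transforms=pose_transforms,
        expected_rmsd=expected_rmsd,
        ligand_id=ligand_id,
    )
    _write_truth_sidecars(truth, outdir / "truth")
    with open(outdir / "truth" / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    return truth


def _write_truth_sidecars(truth: BundleTruth, tdir: Path) -> None:
    rows = []
    for (pa, pb), entry in sorted(truth.overlap.items()):
        rows.append(
            {"pocket_id_a": pa, "pocket_id_b": pb,
             "ps_score": truth.ps_scores[(pa, pb)], **entry}
        )
    pd.DataFrame(rows).to_csv(tdir / "overlap.csv", index=False, float_format="%.10g")
    crows = [
        {"pocket_id": pid, "chain": r.chain_id, "seq_num": r.seq_num,
         "icode": r.icode, "aa": r.aa}
        for pid in sorted(truth.contacts)
        for r in sorted(truth.contacts[pid])
    ]
    pd.DataFrame(crows).to_csv(tdir / "contacts.csv", index=False)
    rrows = [
        {"pocket_id": pid, "best_affinity": truth.best_affinity[pid],
         "jitter_sd": truth.pose_transforms[pid]["jitter_sd"],
         "expected_rmsd": truth.expected_rmsd[pid]}
        for pid in sorted(truth.expected_rmsd)
    ]
    pd.DataFrame(rrows).to_csv(tdir / "docking.csv", index=False, float_format="%.10g")
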