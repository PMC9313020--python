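"""The statistical battery.

Pearson correlations (two-sided p from the t-transform with n−2 df), the
paired t-test used as the docking-reliability control, per-ligand PS-score
summaries, the sequence-similarity fraction over the shipped pairwise
structural-comparison table, and the correlation battery that links pocket
similarity to affinity differences, conformer RMSD, shared ligand contacts,
electrostatic (MS-WHIM) distance and structural-overlap scores.

Raw p-values are reported (no correction); a Benjamini–Hochberg column is
emitted additionally, clearly labeled as an extension.  Sample (n−1)
standard deviations are used throughout.
"""
from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import (
    ControlRecord,
    CorrelationResult,
    PairedTTestResult,
    PocketPairRecord,
    SeqSimPair,
)

# association name -> PocketPairRecord field correlated against ps_score,
# with the sign the congruence hypothesis predicts
ASSOCIATIONS: dict[str, tuple[str, int]] = {
    "abs_affinity_diff": ("abs_affinity_diff", -1),
    "conformer_rmsd": ("conformer_rmsd", -1),
    "shared_contacts": ("shared_contacts", +1),
    "mswhim_distance": ("mswhim_distance", -1),
    "overlap_sum": ("overlap_sum", +1),
}


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value.

    p is from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if len(xv) != len(yv):
        raise ValueError("x and y must have equal length")
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant; correlation undefined")
    if np.ptp(yv) == 0:
        raise ValueError("y is constant; correlation undefined")
    res = sps.pearsonr(xv, yv)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def paired_t_test(a, b) -> PairedTTestResult:
    """Paired-sample t-test on matched vectors, df = n−1.

    Identical vectors give t = 0, p = 1; nonzero differences with zero
    variance leave t undefined and raise.
    """
    av = _as_vector(a, "a")
    bv = _as_vector(b, "b")
    if len(av) != len(bv):
        raise ValueError("a and b must have equal length")
    n = len(av)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = av - bv
    stats = dict(
        mean_a=float(np.mean(av)),
        sd_a=float(np.std(av, ddof=1)),
        mean_b=float(np.mean(bv)),
        sd_b=float(np.std(bv, ddof=1)),
    )
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return PairedTTestResult(t=0.0, df=n - 1, p_value=1.0, **stats)
        raise ValueError("differences have zero variance; t undefined")
    res = sps.ttest_rel(av, bv)
    return PairedTTestResult(
        t=float(res.statistic), df=n - 1, p_value=float(res.pvalue), **stats
    )


def summarize_ps(records: Iterable[PocketPairRecord]) -> pd.DataFrame:
    """Per-ligand min/mean/sd/max of the PS-scores, one row per ligand.

    The standard deviation uses the n−1 denominator and is reported missing
    for a single score.
    """
    rows = [
        {"ligand_id": r.ligand_id, "ps_score": r.ps_score}
        for r in records
        if r.ps_score is not None
    ]
    if not rows:
        raise ValueError("no records with a PS-score")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("ligand_id")["ps_score"]
        .agg(min="min", mean="mean", sd=lambda s: s.std(ddof=1), max="max", n="count")
        .reset_index()
        .sort_values("ligand_id", ignore_index=True)
    )
    return out


# --------------------------------------------------------------------------
# Pairwise structural-comparison (sequence similarity) table

@lru_cache(maxsize=1)
def load_seqsim_table() -> pd.DataFrame:
    """The shipped pairwise flexible/rigid structural-comparison table."""
    with resources.files(__package__).joinpath("data/table2_seqsim.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def seqsim_pairs_from_frame(df: pd.DataFrame) -> list[SeqSimPair]:
    return [
        SeqSimPair(
            pair_label=str(row.uniprot_pair),
            rmsd_flex=float(row.rmsd_flex),
            rmsd_rigid=float(row.rmsd_rigid),
            sim_flex=float(row.sim_flex),
            sim_rigid=float(row.sim_rigid),
        )
        for row in df.itertuples()
    ]


def seqsim_fraction_below(
    pairs: Sequence[SeqSimPair], threshold: float = 30.0, strict: bool = True
) -> float:
    """Fraction of pairs whose flexible AND rigid sequence similarities are
    below ``threshold`` percent (strict ``<`` by default, ``<=`` otherwise)."""
    if not pairs:
        raise ValueError("need at least one pair")
    if strict:
        hits = sum(1 for p in pairs if p.sim_flex < threshold and p.sim_rigid < threshold)
    else:
        hits = sum(1 for p in pairs if p.sim_flex <= threshold and p.sim_rigid <= threshold)
    return hits / len(pairs)


# --------------------------------------------------------------------------
# Correlation battery

def _battery_rows(
    records: Sequence[PocketPairRecord], scope: str, ligand: Optional[str]
) -> list[dict]:
    subset = [r for r in records if ligand is None or r.ligand_id == ligand]
    rows = []
    for name, (field, expected_sign) in ASSOCIATIONS.items():
        pairs = [
            (r.ps_score, getattr(r, field))
            for r in subset
            if r.ps_score is not None and getattr(r, field) is not None
        ]
        row = {
            "scope": scope,
            "ligand_id": ligand if ligand is not None else "all",
            "association": f"ps_vs_{name}",
            "expected_sign": expected_sign,
            "n": len(pairs),
        }
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if len(pairs) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            row.update(r=np.nan, p_value=np.nan, status="not computed")
        else:
            res = pearson(x, y)
            row.update(r=res.r, p_value=res.p_value, status="ok")
        rows.append(row)
    return rows


def correlation_battery(
    records: Sequence[PocketPairRecord], per_ligand: bool = True
) -> pd.DataFrame:
    """PS-score correlations against every analysis field, pooled and
    (optionally) per ligand.

    Missing fields are excluded pairwise per association, so per-association
    n's differ.  A Benjamini–Hochberg adjusted column ``q_bh`` is appended as
    an extension; the raw p-values are the primary report.
    """
    if not records:
        raise ValueError("no records")
    rows = _battery_rows(records, "pooled", None)
    if per_ligand:
        for ligand in sorted({r.ligand_id for r in records}):
            rows.extend(_battery_rows(records, "per_ligand", ligand))
    df = pd.DataFrame(rows)
    df["q_bh"] = np.nan
    ok = df["status"] == "ok"
    if ok.any():
        df.loc[ok, "q_bh"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    return df


def control_t_test(controls: Sequence[ControlRecord]) -> PairedTTestResult:
    """Paired t-test of deposited vs re-docked conformer RMSDs."""
    a = [c.rmsd_actual for c in controls]
    b = [c.rmsd_docked for c in controls]
    return paired_t_test(a, b)
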