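"""Pocket vs structurally-similar-region overlap scoring.

For a pocket PK on structure A and the portion P of A found structurally
similar to a partner structure, the overlap score is

    S = N(aaP ∩ aaPK) / N(aaPK)

where N(.) counts residue positions — i.e. the fraction of the pocket's
residues that fall inside the similar region.  The score is asymmetric by
construction: it is normalized by pocket size, never region size.  Scores
are averaged over the flexible and rigid alignment modes and the two
per-pocket averages of a compared pocket pair are summed, giving a pair
score in [0, 2].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .types import Pocket, SimilarRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Per-mode overlap scores of one pocket and their mean."""

    pocket_id: str
    s_flexible: Optional[float]
    s_rigid: Optional[float]
    mean_score: float


def overlap_score(pocket: Pocket, region: SimilarRegion) -> float:
    """Fraction of the pocket's residue positions inside the region.

    Intersection is on (chain, residue number, insertion code) triples;
    amino-acid type plays no role.
    """
    if pocket.structure_id != region.structure_id:
        raise ValueError(
            f"pocket {pocket.pocket_id} is on {pocket.structure_id!r} but the "
            f"region describes {region.structure_id!r}"
        )
    n_pocket = len(pocket.positions)
    if n_pocket == 0:  # unreachable through Pocket invariant, kept for safety
        raise ValueError(f"pocket {pocket.pocket_id} is empty")
    return len(pocket.positions & region.positions) / n_pocket


def mean_overlap(pocket: Pocket, regions: Iterable[SimilarRegion]) -> OverlapResult:
    """Arithmetic mean of the overlap score over the provided alignment modes.

    With both flexible and rigid regions present this is their average; when
    only one mode is available its score is returned and a warning logged.
    """
    per_mode: dict[str, float] = {}
    for region in regions:
        if region.mode in per_mode:
            raise ValueError(f"duplicate region for mode {region.mode!r}")
        per_mode[region.mode] = overlap_score(pocket, region)
    if not per_mode:
        raise ValueError("at least one similar region is required")
    if len(per_mode) == 1:
        mode = next(iter(per_mode))
        logger.warning(
            "pocket %s: only the %s alignment mode is available; "
            "mean overlap degrades to that single score", pocket.pocket_id, mode,
        )
    mean = sum(per_mode.values()) / len(per_mode)
    return OverlapResult(
        pocket_id=pocket.pocket_id,
        s_flexible=per_mode.get("flexible"),
        s_rigid=per_mode.get("rigid"),
        mean_score=mean,
    )


def pair_overlap_sum(mean_a: float, mean_b: float) -> float:
    """Summed average overlap score of a compared pocket pair, in [0, 2]."""
    for label, v in (("mean_a", mean_a), ("mean_b", mean_b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{label}={v} outside [0, 1]")
    return mean_a + mean_b


def pocket_pair_overlap(
    pocket_a: Pocket,
    regions_a: Iterable[SimilarRegion],
    pocket_b: Pocket,
    regions_b: Iterable[SimilarRegion],
) -> float:
    """Summed overlap score for a pocket pair given each side's regions."""
    mean_a = mean_overlap(pocket_a, regions_a).mean_score
    mean_b = mean_overlap(pocket_b, regions_b).mean_score
    return pair_overlap_sum(mean_a, mean_b)
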