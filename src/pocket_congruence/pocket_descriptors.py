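"""MS-WHIM electrostatic pocket descriptors and the Chebyshev distance.

Each of the 20 standard amino acids carries a three-component MS-WHIM score
(principal components of molecular electrostatic-potential surface
properties).  A pocket's descriptor is the component-wise aggregate — by
default the arithmetic mean — of the scores of its residues, seen as a point
(x, y, z) in 3-space.  Two pockets are compared with the Chebyshev (L∞)
distance

    D = max(|x1 − x2|, |y1 − y2|, |z1 − z2|).

The descriptor depends only on amino-acid composition: two pockets with the
same residue-type multiset are at distance 0 regardless of geometry.  This
sequence-only behaviour is deliberate and documented.
"""
from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .types import MsWhimDescriptor, Pocket, STANDARD_AA

logger = logging.getLogger(__name__)

MsWhimTable = dict[str, tuple[float, float, float]]


@lru_cache(maxsize=1)
def mswhim_table() -> MsWhimTable:
    """The embedded 20x3 MS-WHIM table, keyed by one-letter code."""
    with resources.files(__package__).joinpath("data/mswhim_scores.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    table = {
        str(row.aa): (float(row.x), float(row.y), float(row.z))
        for row in df.itertuples()
    }
    if set(table) != STANDARD_AA:
        raise RuntimeError("embedded MS-WHIM table does not cover the 20 standard residues")
    return table


def mswhim_descriptor(
    pocket: Pocket,
    table: MsWhimTable | None = None,
    aggregate: str = "mean",
) -> MsWhimDescriptor:
    """Descriptor of a pocket: component-wise aggregate over its residues.

    Residues are count-weighted (each occurrence of an amino-acid type
    contributes once).  Non-standard residues (aa='X') are excluded with a
    logged warning.  ``aggregate`` is "mean" (default) or "sum" — the latter
    is offered for sensitivity analysis only.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    table = table if table is not None else mswhim_table()
    rows = [table[r.aa] for r in sorted(pocket.residues) if r.aa in table]
    n_excluded = len(pocket.residues) - len(rows)
    if n_excluded:
        logger.warning(
            "pocket %s: %d non-standard residue(s) excluded from the MS-WHIM descriptor",
            pocket.pocket_id, n_excluded,
        )
    if not rows:
        raise ValueError(f"pocket {pocket.pocket_id} has no standard residues")
    arr = np.asarray(rows, dtype=float)
    agg = arr.mean(axis=0) if aggregate == "mean" else arr.sum(axis=0)
    return MsWhimDescriptor(pocket_id=pocket.pocket_id, x=agg[0], y=agg[1], z=agg[2])


def chebyshev_distance(d1: MsWhimDescriptor, d2: MsWhimDescriptor) -> float:
    """L∞ distance between two pocket descriptors."""
    a, b = d1.as_array(), d2.as_array()
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("descriptors must be finite")
    return float(np.max(np.abs(a - b)))
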