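"""Overlap between a predicted pocket and structurally similar regions.

Builds a 10-residue pocket and flexible/rigid similar regions on the same
structure, then scores how much of the pocket falls inside each region.
"""
from pocket_congruence import (
    Pocket,
    ResidueRef,
    SimilarRegion,
    mean_overlap,
    pair_overlap_sum,
)

# a pocket of residues 5..14 on chain A of structure "R1"
pocket = Pocket(
    pocket_id="R1.1",
    structure_id="R1",
    residues=frozenset(ResidueRef("A", n, "", "S") for n in range(5, 15)),
)

# the flexible alignment found residues 1..8 similar, the rigid one 1..12
flexible = SimilarRegion("R1", "flexible", frozenset(("A", n, "") for n in range(1, 9)))
rigid = SimilarRegion("R1", "rigid", frozenset(("A", n, "") for n in range(1, 13)))

result = mean_overlap(pocket, [flexible, rigid])
print(f"S_flexible = {result.s_flexible:.2f}   # 4 of 10 pocket residues in the flexible region")
print(f"S_rigid    = {result.s_rigid:.2f}   # 8 of 10 in the rigid region")
print(f"mean       = {result.mean_score:.2f}   # averaged over the two alignment modes")

# pairing with a partner pocket whose mean overlap is 0.25 gives the summed
# pair score in [0, 2]: high values mean both pockets sit inside the
# structurally similar parts of their proteins
print(f"pair sum   = {pair_overlap_sum(result.mean_score, 0.25):.2f}")
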