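"""The correlation battery on records with planted correlations.

Generates 2,000 pocket-pair records in which one latent pocket similarity
drives the affinity gap, conformer RMSD, shared contacts, electrostatic
distance and structural overlap, then checks that the battery recovers the
planted sign pattern: similar pockets bind with similar affinities and
conformations, share contacting residue types, have close electrostatics,
and sit inside structurally similar regions.
"""
from pocket_congruence import SyntheticConfig, correlation_battery, gen_pair_records

config = SyntheticConfig(seed=1, n_pairs=2000)
records, truth = gen_pair_records(config)

battery = correlation_battery(records, per_ligand=False)
print(battery[["association", "r", "p_value", "n"]].to_string(index=False))
print()
for name, planted in truth.planted_correlations.items():
    row = battery[battery["association"] == f"ps_vs_{name}"].iloc[0]
    print(f"planted r = {planted:+.2f}, recovered r = {row['r']:+.4f}  ({name})")
print("# negative rows: dissimilarity measures shrink as PS-score grows;")
print("# positive rows: shared contacts and overlap grow with PS-score.")
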