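"""Locate the residues whose backbone torsions differ between two states.

Builds the synthetic bistable loop, generates its wrapped and unwrapped
endpoint conformations, and prints the per-residue combined torsion
deviation sqrt(dphi^2 + dpsi^2) — the same statistic used to spot
secondary-structure changes between two crystal structures of one protein.
"""

from loopstring import build_toy_loop, generate_endpoint_conformations
from loopstring.geometry import deviation_table, torsion_deviation_profile

model = build_toy_loop(11, seed=3)
pair = generate_endpoint_conformations(model, [(5, "psi", 180.0), (6, "psi", 180.0)])

profiles = torsion_deviation_profile(pair.state_a, pair.state_b)
print(deviation_table(profiles).to_string(index=False, float_format="%.1f"))
print()
print("Residues 5 and 6 carry the designed ~180 degree psi flips, so their")
print("combined deviation peaks near 180 while the rest of the chain relaxes")
print("by only a few degrees — the signature of a local wrapping change.")
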