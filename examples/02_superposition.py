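"""Superpose a synthetic helix bundle onto a noisy, displaced copy.

Generates a 6-helix CA bundle, adds 0.5 A Gaussian noise plus a rigid
motion, then recovers the motion with the Kabsch fit and outlier-rejection
refinement.  A second run restricts the comparison to two TM spans only.
"""

from qtykit import (
    BundleSpec, generate_bundle_structure, generate_membrane_protein,
    perturb_structure, superpose_structures,
)

spec = BundleSpec(n_helices=6, helix_len=22, loop_len=6, seed=42)
seq, topo = generate_membrane_protein(spec)
native = generate_bundle_structure(spec)
moved = perturb_structure(native, sigma=0.5, rigid=((30.0, -45.0, 60.0), (10.0, -5.0, 3.0)), seed=43)

res, _ = superpose_structures(native, moved)
print(f"whole bundle: {res.n_used_pairs}/{res.n_input_pairs} CA pairs kept, "
      f"RMSD all {res.rmsd_all:.3f} A, refined {res.rmsd_refined:.3f} A")

tm_res, _ = superpose_structures(native, moved, tm_only=True,
                                 topo=type(topo)(topo.sequence_id, topo.spans[:2]))
print(f"first 2 helices only: {tm_res.n_used_pairs}/{tm_res.n_input_pairs} pairs, "
      f"refined RMSD {tm_res.rmsd_refined:.3f} A")
print()
print("With sigma = 0.5 A per coordinate the fitted RMSD sits near")
print("sigma*sqrt(3) ~ 0.87 A; refinement trims the few worst pairs.")
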