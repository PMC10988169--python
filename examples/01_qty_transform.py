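"""Apply the QTY code to a small membrane protein and inspect the result.

Builds a toy sequence with two annotated transmembrane helices, replaces
L/I/V/F inside them with Q/T/T/Y, and prints the alignment plus the
sequence characteristics (variation %, pI, MW, GRAVY) of the pair.
"""

from qtykit import ProteinSequence, TMTopology, qty_transform, render_alignment

seq = ProteinSequence(
    id="toy",
    residues="MSKDE" + "LLIVAFLAGLLIVAFLAGLV" + "GKDNS" + "FFLIVGAVILFAVGLIVALF" + "QDESK",
    description="toy 2-helix membrane protein",
)
topo = TMTopology(sequence_id="toy", spans=((6, 25), (31, 50)))

rec = qty_transform(seq, topo)
print(render_alignment(rec, topo, width=60))

m = rec.metrics
print(f"substitutions:      {len(rec.substitutions)}")
print(f"total variation:    {m.total_variation_pct:.2f} %   (all positions)")
print(f"TM variation:       {m.tm_variation_pct:.2f} %   (inside the helices)")
print(f"pI:                 {m.pI_native:.2f} -> {m.pI_variant:.2f}")
print(f"MW (Da):            {m.mw_native:.2f} -> {m.mw_variant:.2f}")
print(f"GRAVY:              {m.gravy_native:.3f} -> {m.gravy_variant:.3f}")
print()
print("The TM helices change heavily while loops are untouched; the pI is")
print("almost unchanged (Q/T are non-ionizable) and the mean hydropathy")
print("drops sharply, which is what makes the variant water-soluble.")
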