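"""PPR motif scanning and P/PLS-class calling on one protein.

Builds a protein with three exact copies of the P-motif consensus, scans
it with the packaged P/L/S profiles, and classifies the chained model
with the family score thresholds (P-class: summed score > 100 with no
L/S motifs).
"""

from rflscan.motif_model import chain_and_classify, load_packaged_profiles, scan_protein

profiles = load_packaged_profiles()
consensus = profiles["P"].consensus

protein = "G" * 10 + consensus + "A" * 10 + consensus + "W" * 10 + consensus + "K" * 10
hits = scan_protein(protein, profiles.values(), hit_threshold=8.0)
model = chain_and_classify(hits, "demo_orf", len(protein))

print(f"protein length: {len(protein)} aa")
for h in hits:
    print(f"  motif {h.class_label} at {h.start_aa}-{h.end_aa}, {h.score:.1f} bits")
print(f"summed protein score: {model.protein_score:.1f} bits")
print(f"family class: {model.family_class}")
print(f"motif structure: {model.structure_string}")
# The structure string reads like the published gene tables: integer
# tokens are inter-motif segment lengths in aa, letters are motif classes.
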