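"""Scan protein sequences for CxxCH heme-binding motifs and classify
cytochromes.

CxxCH is the covalent heme-c attachment site of c-type cytochromes; proteins
with >= 4 sites are called multi-heme and, in secreted compartments, often
mediate extracellular electron transfer. Classification as a cytochrome needs
supporting evidence: a cytochrome gene name, a respiration-related functional
descriptor, a cytochrome-type conserved domain, or (for multi-heme proteins)
a "heat shock protein" descriptor — a recurrent mis-annotation of heme-rich
proteins that is collected deliberately.
"""
from secretome_profiler import classify_heme_protein, scan_heme_motifs

sequences = {
    "mono_heme": "MKTAAGVLDECAACHTEQFGG",
    "penta_heme": "MGTE" + "CAACH" * 5 + "AGGT",
    "no_heme": "MKTAAGVLDEQFGGSATT",
}
for name, seq in sequences.items():
    positions = scan_heme_motifs(seq)
    print(f"{name}: {len(positions)} motif(s) at {positions}")

profile = classify_heme_protein(
    "penta_heme", scan_heme_motifs(sequences["penta_heme"]),
    descriptor="cytochrome c family protein",
)
print(f"\npenta_heme: multi-heme={profile.is_multiheme}, "
      f"cytochrome={profile.is_cytochrome}, rules fired={sorted(profile.rule_fired)}")

hsp = classify_heme_protein(
    "hsp_like", scan_heme_motifs(sequences["penta_heme"]),
    descriptor="heat shock protein Hsp70",
)
print(f"hsp_like:   multi-heme={hsp.is_multiheme}, "
      f"cytochrome={hsp.is_cytochrome}, rules fired={sorted(hsp.rule_fired)}")
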