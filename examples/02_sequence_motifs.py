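"""Charged-dipeptide motifs and charged composition of human ubiquitin.

Uses the canonical 76-residue sequence bundled with the package. Adjacent
charged residues (KE, EK, DK, ED, ...) are the sequence-level signature of
charge pairing; the KE/EK motif appears exactly twice in ubiquitin.
"""

from chargenet import charged_composition, scan_charged_dipeptides
from chargenet.datasets import human_ubiquitin

seq, numbers = human_ubiquitin()
comp = charged_composition(seq)
print(f"human ubiquitin: {len(seq)} residues")
print("charged composition:",
      ", ".join(f"{aa}: {comp[aa]}" for aa in "DEHKR"),
      f"(total {comp['total']})")

hits = scan_charged_dipeptides(seq, numbers)
print(f"charged dipeptides ({len(hits)}):")
for h in hits:
    print(f"  {h.dipeptide} at {h.positions[0]}-{h.positions[1]}"
          f"  [{h.sign_class}]")
ke_ek = [h for h in hits if set(h.dipeptide) == {"K", "E"}]
print(f"KE/EK motifs: {len(ke_ek)} "
      f"({', '.join(f'{h.dipeptide}{h.positions[0]}' for h in ke_ek)})")
# The two KE hits (K33E34, K63E64) are lysine-glutamate charge dipoles in
# direct sequence contact.
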