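"""Why natural QTY substitutions are single second-position base changes.

Enumerates the single-nucleotide codon paths behind each QTY pair and shows
that V<->T is different: no single-base path exists, which is why V->T is
absent among natural variants even though the QTY design uses it.
"""

import qtycode as q

for ref, alt in [("L", "Q"), ("I", "T"), ("F", "Y")]:
    paths = q.single_change_paths(ref, alt)
    print(f"{ref}->{alt}: {len(paths)} single-nucleotide path(s)")
    for p in paths:
        print(f"   {p.codon_from} -> {p.codon_to}  position {p.position}  "
              f"{p.base_from}->{p.base_to}  ({p.change_class.value})")

print(f"\nV->T minimum nucleotide changes: {q.min_nt_changes('V', 'T')}"
      "  (no single-base path: V codons GUx vs T codons ACx differ at two positions)")

# Every path above sits at codon position 2 — the base that sets an amino
# acid's chemistry — so each QTY/rQTY swap is one transition or transversion
# at the codon's chemical switch.
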