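"""Motif counting on a reduced physicochemical alphabet.

Grouping residues (e.g. the small hydrophobics A/V/I/L) generalizes motifs:
any full-alphabet motif projects onto its group version, so group-motif
frequencies can only be higher.  The enc7 alphabet uses 7 groups, enc8
splits serine/threonine from asparagine/glutamine, enc10 isolates R and A.
"""

from pepmotifs import builtin_alphabet, count_matrix, frequency_table, generate, preset

alpha = builtin_alphabet("enc7")
print("enc7 groups:", ", ".join(alpha.groups))
print("recode('MASSLR') ->", " ".join(alpha.render_symbol(s) for s in alpha.recode("MASSLR")))

records, _ = generate(preset("SP-like", n=300, seed=3))
full = frequency_table(count_matrix(records, k_range=(2,))).set_index("motif")
reduced = frequency_table(count_matrix(records, k_range=(2,), alphabet=alpha)).set_index("motif")

print("\nLL presence on the full alphabet: "
      f"{100 * full.loc['LL', 'fraction']:.1f}%")
print("[AVIL][AVIL] presence on enc7:     "
      f"{100 * reduced.loc['[AVIL][AVIL]', 'fraction']:.1f}%")
print("The group motif is at least as frequent: every LL is an [AVIL][AVIL].")
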