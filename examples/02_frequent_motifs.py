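"""Most frequent gapped motifs in a serine-rich cTP-like set.

Presence frequency = fraction of sequences containing a motif at least
once.  The cTP-like preset plants SS, S_S and an MA prefix, so serine
bigrams should dominate the table, as they do in real chloroplast transit
peptides.
"""

from pepmotifs import count_matrix, frequency_table, generate, preset, repeat_analysis, top_motifs

records, _ = generate(preset("cTP-like", n=400, seed=2))
cm = count_matrix(records, k_range=(2, 3), mode="count")
table = frequency_table(cm)
print("top motifs by presence frequency (percent of sequences):")
print(table.head(8)[["motif", "k", "fraction", "percent"]].to_string(index=False))

top = top_motifs(table, {2: 0.25, 3: 0.10})
print(f"\n{len(top)} motifs clear the per-size reporting cutoffs (25% / 10%)")

repeats = repeat_analysis(records, cm=cm)
row = repeats.set_index("motif").loc["SS"]
print(f"\nSS occurs up to {row.max_repeats} times in a single sequence; "
      f"{100 * row.frac_ge2:.1f}% of sequences carry it at least twice.")
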