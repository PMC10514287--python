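"""Taxon-specific motifs: Mann-Whitney U with BH correction.

The two-taxon demo plants S_S at 60% in one taxon vs 10% in the other, and
WCW only in the first.  The comparison should flag S_S as significantly
enriched and WCW as exclusive (present in one group, absent from the
other — exclusivity bypasses the test).
"""

from pepmotifs import count_matrix, generate, group_by_taxon, mann_whitney_bh, preset, taxon_specific_motifs

records, _ = generate(preset("two-taxon-demo", n=300, seed=5))
groups, n_unassigned = group_by_taxon(records, ["Streptophyta", "Chlorophyta"])
print({name: len(recs) for name, recs in groups.items()})

cm = count_matrix(records, k_range=(2, 3), mode="count")
table = mann_whitney_bh(
    cm, {name: [r.id for r in recs] for name, recs in groups.items()}, alpha=0.05
)
print(f"tested {len(table)} motifs; {int(table.significant.sum())} significant after BH")

calls = taxon_specific_motifs(table, min_fraction=0.2).set_index("motif")
for motif in ("S_S", "WCW"):
    row = calls.loc[motif]
    print(f"{motif}: {row.call}, enriched in {row.enriched_group} "
          f"({100 * row.frac_a:.1f}% vs {100 * row.frac_b:.1f}%, p_adj = {row.p_adj:.2e})")
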