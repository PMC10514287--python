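"""Generate a synthetic AMP-like dataset and run the standard filters.

The filters drop sequences with non-standard residues, shorter than 10,
longer than 100 (AMP sets only) and exact duplicates, in that order, and
tally each step.  On a freshly generated set nothing should be removed.
"""

from pepmotifs import PeptideRecord, filter_dataset, generate, preset

records, truth = generate(preset("AMP-like", n=200, seed=1))
print(f"generated {len(records)} AMP-like peptides, e.g. {records[0].sequence}")

# corrupt a few records so each filter has work to do
records[0] = PeptideRecord(records[0].id, records[0].sequence[:4] + "X" + records[0].sequence[5:], "AMP")
records[1] = PeptideRecord(records[1].id, "KKLLK", "AMP")
records[2] = PeptideRecord(records[2].id, "K" * 120, "AMP")
records[3] = PeptideRecord(records[3].id, records[4].sequence, "AMP")

kept, report = filter_dataset(records, min_len=10, max_len=100)
print(report.to_json())
# One sequence fell to each rule: the ledger counts sum back to the input.
assert report.n_output == 196
print(f"{report.n_output} sequences survive; counts sum exactly to n_input.")
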