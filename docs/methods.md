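# Methods

## Motif model

A gapped motif is an ordered tuple of residue classes with fixed
inter-class gap lengths; its span is the number of specified residues plus
the summed gaps. Admissible shapes: sizes k = 2 and 3 allow 0–3 unspecified
residues in each gap slot independently, k = 4 allows 0–2 per slot, and
k = 5 allows either no gap or exactly one gap of length 1; every shape
spans ≤ 10 positions. That census is 4 + 16 + 27 + 5 = 52 gap shapes. The
per-slot (rather than total) reading of the gap budget is deliberate: it is
the only reading under which wide printed patterns such as a lysine
tetragram with three double gaps (span 10) are admissible, and the bound is
exposed should a different budget ever be needed. Contiguous motifs (gap 0)
are a special case of the same machinery, not a separate code path.

Matching is exact set membership at each specified offset; unspecified
positions match anything; overlapping occurrences count at distinct start
positions (the standard k-mer convention — a run of four leucines contains
three `LL`). Coordinates are 0-based half-open internally; report writers
and examples print 1-based positions.

## Counting

`count_matrix` instantiates motifs lazily from the sequences themselves:
for each sequence, each shape is slid across and the residues at the
specified offsets form the motif key. Motifs never observed are never
materialized — no Cartesian product over the alphabet is ever formed. The
result is a sparse motif × sequence matrix in presence (0/1) or occurrence-
count mode with a deterministic row order (size, then gap shape, then
residue string). Presence frequency is the fraction of sequences containing
the motif at least once; the repeats table keeps motifs reaching ≥ 2
occurrences in at least one sequence and reports the maximum repeat count
and the fractions of sequences with ≥ 2 and ≥ 3 occurrences. Reporting
cutoffs (defaults: bigrams 0.25, trigrams 0.10, tetragrams/pentagrams 0.05)
are presentation-layer only; the full tables are always written.

## Reduced alphabets

enc7 partitions the 20 residues into {AVIL, STNQ, RHK, DE, FYW, CGP, M};
enc8 splits ST from NQ; enc10 further isolates A and R and splits HK from
R. These groupings are reconstructed to be consistent with every
reduced-alphabet motif the analyses print (e.g. `[AVIL][ST][ST]`,
`[VIL]_R_[VIL]`, `[AVIL][AVIL][CGP]`); since the authoritative table of
group memberships is not otherwise fixed, custom partitions can be loaded
from a one-group-per-line text file and are validated as exact partitions.
Internally each group maps to a single lowercase symbol so the motif engine
is alphabet-agnostic; externally groups render bracketed in definition
order (`[AVIL]`), singleton groups bare. Any full-alphabet occurrence
projects onto a group-motif occurrence at the same start, so group-motif
frequencies dominate those of their pre-images — a property the test suite
asserts on every preset.

## Positional profiles

A start s in a sequence of length L maps to 100·(s + ½)/L — the start
midpoint, chosen so positions never land exactly on 0 or 100 and the first
residue of any sequence maps near but not at the origin. Profiles are
histograms over 20 width-5 bins (configurable), normalized to unit mass.
Region calls apply a fixed rule ladder on the first/middle/last thirds:
N-terminus if ≥ 50% of mass is in the first two bins; first-part / middle
if ≥ 60% of mass sits in that third; C-depleted if the last third holds
< 5%; C-enriched if the last third is ≥ 2× each other third; otherwise
whole. Profiles with fewer than 20 occurrences (configurable) are labelled
whole with a low-support flag rather than over-interpreted. The one
positional claim that warrants an exact statistic — the fraction of
sequences beginning with a given prefix such as MA — is computed as a
string-prefix test, not from the histogram.

## Taxon comparison

Records are grouped by exact, case-sensitive membership of a taxon name in
their lineage; taxa compared at one level must be disjoint (validated), and
records matching none are tallied as unassigned. For each motif observed in
either group, the per-sequence occurrence counts (zeros included) are
compared with a two-sided Mann–Whitney U. Counts, not presence flags, are
the default observable: on 0/1 data the rank test collapses toward a
two-proportion test with extreme ties, while counts retain resolution;
presence mode remains available. The asymptotic path uses the tie-corrected
normal approximation without continuity correction, so identical groups
yield p = 1 exactly; groups of ≤ 8 per side with no ties use the exact U
distribution; rows constant across both groups carry no rank information
and are assigned p = 1 directly. BH adjustment runs within each (motif
size, gap shape) family of one pairwise comparison by default — mirroring
per-motif-type reporting — with a global family mode available. Multi-group
designs are handled as all pairwise comparisons, each corrected within its
own family. Motifs with nonzero frequency in exactly one group are called
exclusive and bypass the test, since a rank test on a motif absent from one
group conflates effect size with sample size.

## Synthetic data

The generator draws sequence lengths uniformly within type-specific bounds
(cTP 20–100, mTP 15–80, SP 15–40, AMP 10–100), fills residues i.i.d. from a
stated composition, then plants motifs: per sequence and motif, with the
configured probability, a start is drawn from the positional law (prefix,
first-third, middle, uniform, last-third, defined on the same scaled axis
the positional module uses) and the specified residues are written in
place — gap positions keep their background letters and lengths are never
changed. Collisions resolve later-wins; only insertions still verifiable in
the final sequence enter the ground truth, which records every insertion
position and the realized planting fraction per motif and taxon. Generation
is a pure function of (spec, seed).

Preset compositions are qualitative emulations of the families they are
named for — serine/alanine-rich cTP-like, arginine/leucine-rich mTP-like,
leucine-rich SP-like with mid-sequence planting, lysine-rich AMP-like —
with planting rates chosen so the planted structure clearly exceeds
background coincidence at a few hundred sequences. They are not fits to any
empirical dataset: real presequences have length-dependent composition,
positional autocorrelation and phylogenetic dependence that i.i.d.
backgrounds lack, so green tests demonstrate that the pipeline recovers
known structure, not that any biological claim holds.

## Numerical and scale choices

Deterministic orderings everywhere (lexicographic shape order, stable sorts
with canonical-string tie-breaks) make every table and report bundle a pure
function of inputs and config, which the pipeline tests verify by hashing.
Simulation-based checks run at desk scale: a few hundred sequences per
preset, 100–200 replicates for the null-rate and power studies with
bigram-only counting (the differential test's behaviour does not depend on
motif size), chosen to keep the full suite in the low minutes on one CPU
while leaving the assertions comfortably away from their thresholds
(observed power is ~100% against the 95% bound; the post-BH null rejection
rate is near zero against the α + 3·SE bound). The "p = 1 for identical
groups" contract is asserted at 10⁻¹⁰. Binomial/multinomial interval checks
on the generator use 99% intervals at n = 1000 (or per-letter 99.95%
intervals jointly over 20 letters).

## Limitations

No probabilistic motif models (PWMs), discovery algorithms or background-
corrected enrichment ratios: frequencies are raw presence fractions, as in
the analyses this package operationalizes. Real-data headline percentages
depend on the curated input datasets and are not bundled; the pipeline
consumes any local FASTA + metadata TSV of the documented dialect. The
exact group memberships of the reduced alphabets beyond what printed motifs
pin down, and the original per-figure frequency cutoffs, are configuration,
not constants.
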