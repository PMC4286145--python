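# Methods

## Composition metrics

Codons are read as consecutive non-overlapping triplets from the first
position of each CDS. A trailing partial codon (draft-genome feature
tables contain CDS records whose length is not divisible by 3) is dropped
with a logged warning rather than rejecting the record. Triplets
containing ambiguity characters (N and the other IUPAC codes) are excluded
from counting and tallied separately, so they dilute neither GC nor RSCU.

GC is computed over all counted codon positions and equals the mean of the
positional fractions GC1/GC2/GC3. Two third-position variants are kept:
`gc3_all` over every counted codon (stops included) and `gc3_syn` (GC3s)
over the degenerate universe only — the 59 codons of amino acids with at
least two synonymous codons under translation table 11 (61 sense codons
minus ATG and TGG; the size is asserted at code construction). GC3s is the
screen's default because it is the headline third-position statistic of
codon-usage tools; both are reported. The genetic code is configurable by
NCBI table id, with the degenerate universe recomputed per table.

RSCU follows the standard definition, `n_c k_a / Σ n_c'` within each
synonymous family. When an amino acid is entirely absent from a gene its
codons' RSCU is *undefined* and represented explicitly as missing (NA on
disk), never as 0 — the screen must distinguish "unused amino acid" from
"avoided codon". Stop codons never receive RSCU values. The background is
the profile of the element-wise **pooled** counts of all protein-coding
genes, not a mean of per-gene profiles, and includes the screened gene
itself; for genome-scale gene sets the self-contribution is negligible and
inclusion keeps the background independent of which gene is being
screened.

## The atypicality screen

Per codon, the fold change against the background is the symmetric ratio
`max(g/b, b/g)`; direction is deliberately ignored so over- and
under-representation count equally. A codon enters the comparison
(`n_used`) only if the gene uses it and the background value is defined;
a background RSCU of exactly 0 yields an infinite fold change (the gene
uses a codon the genome avoids — maximal signal). The gene flag requires
strictly more than `fraction_threshold` (default 0.25) of the used codons
to change strictly more than `fold_threshold` (default 2.0); both
inequalities are configurable to non-strict. The denominator of the
fraction is `n_used` (authoritative); the fraction over the full 59-codon
universe is emitted alongside for comparison.

GC deviations are reported as signed percentage-point differences
(gene − background) for GC and GC3s. The GC flag threshold defaults to
5.0 points: conservative relative to the ~9-point GC and ~20-point GC3
deviations typical of clear transfer candidates in high-GC genomes, and
the raw deltas are always reported so users can apply their own cutoff.

Taxonomy classification takes the genus as the first whitespace token of
the closest-relative organism name (so "Halomonas sp." resolves by
genus), looks it up in a packaged genus→family table covering the
Halomonadaceae genera and the common hit genera, and calls the hit
foreign when the family differs from `self_family`. Unknown genera are
excluded from tallies and logged — never silently counted as self. The
two evidence channels are combined only into an evidence class; the
package deliberately does not force a single HGT boolean, since
composition-only and taxonomy-only candidates warrant different follow-up.

## Genome report statistics

Percentages are recomputed from counts, rounded to two decimals with
half-up rounding (report convention), never trusted from input. "DNA
coding" is the union footprint of all annotated genes, so overlapping
features are counted once. N50 is the first length, in descending order,
whose cumulative sum reaches half the assembly. The COG table implements
the dual-denominator convention of published report tables: category
percentages divide by the total number of category assignments (a gene in
two categories contributes twice), while the not-in-COGs percentage
divides by the total gene count; a uniform-denominator mode is available.
Genome G+C is counted from the sequence; published report rows whose
printed bp and percentage disagree are therefore reproduced from the
consistent numerators rather than matched blindly.

## Phylogenetics

Distances use the Kimura 2-parameter model,
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with transition proportion P and
transversion proportion Q over comparable sites. Gap handling is pairwise
deletion (the common default of distance-based tree tools): a site is
compared only when both rows carry unambiguous bases. Saturation
(non-positive log argument) raises an error naming the pair; during
bootstrap such replicates are skipped and counted.

Neighbor joining is the Saitou–Nei agglomeration on the Q-criterion.
Ties are broken by the lowest index pair under the current node ordering,
so runs are reproducible; negative estimated branch lengths are clamped
to zero with the deficit logged. The final three nodes are joined at a
basal trifurcation (unrooted tree). Bootstrap resamples alignment columns
with replacement; support for each internal bipartition of the full-data
tree is the percentage of successful replicates containing it (the
denominator excludes skipped replicates, whose count is returned).
Supports below a display cutoff (default 60, the usual "values above 60%
are shown" convention) can be hidden in the written newick while the tree
object retains all values.

## Synthetic data generator

The generator emulates the compositional contrast the screen targets: a
background population drawn from a GC3-rich codon profile and planted
"alien" genes from a divergent profile. Within each synonymous family,
probability mass `gc3_bias` is spread uniformly over G/C-ending codons
and the remainder over A/T-ending ones (families lacking one class put
all mass on the other), so the expected GC3s of long genes approximates
`gc3_bias`. Optional Dirichlet jitter perturbs the family probabilities
with concentration `base/alpha`, so `alpha → 0` recovers the
deterministic base profile. Amino-acid frequencies default to uniform
over the 20 amino acids because the screen is RSCU-based and insensitive
to amino-acid composition by design. Gene lengths are uniform in a codon
range — the simplest model exposing the length dependence of RSCU
sampling noise. Each gene is `ATG + codons + stop`; genes are laid on one
synthetic contig with 5–50 nt random spacers and random strands so
coordinate and strand handling is exercised end to end. All randomness
derives from one seed through `SeedSequence.spawn` per-gene substreams:
appending genes never changes earlier genes' sequences.

Default study conditions for recovery checks: 200 background genes (GC3
bias 0.85, matching a high-GC halophile's third-position bias) plus 10
planted genes (bias 0.25), 300–600 codons. Under these conditions the
default screen flags all planted genes and no background genes; the
flagged rate is monotone in profile divergence. What the generator does
*not* emulate: amelioration of transferred genes over time, amino-acid
composition differences, operon structure, and genuinely intermediate
donors — passing recovery tests therefore shows the screen separates
strongly divergent codon usage from sampling noise at realistic gene
lengths, not that it would detect anciently acquired or
weakly-contrasting transfers in real genomes.

## Numerical and interface choices

Tabular output is TSV (header, UTF-8, NA for undefined); nested
summaries are JSON. Every CLI run writes a provenance JSON (parameters,
seed, input SHA-256 checksums, package version) sufficient to re-run
seeded stages bit-identically. Coordinates are 1-based inclusive on both
annotation dialects, kept internally (no half-open conversion) so
published gene tables can be audited directly; descending coordinate
pairs are normalized to `start ≤ end` with strand `-`. Published
annotation tables occasionally contain internally inconsistent rows
(coordinates that disagree with the stated protein length); the readers
load them as printed and never silently repair them.

## Problem sizes

The test suite and the acceptance script run entirely on packaged
published tables and simulated genomes: the recovery analysis uses
200+10 genes of 300–600 codons, property checks use 1,000 random genes /
length lists, and tree checks enumerate all unrooted topologies up to
six taxa. These sizes give stable statistics while keeping the whole
suite in well under a minute.
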