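# Methods

## Scope and data model

The package builds pairwise ortholog exon annotations: one reference
annotation (species 1) is projected onto a second genome and progressively
filtered so that what remains is comparable between the species at the
read-mapping level. All coordinates are internally 0-based half-open on
named chromosomes; GTF (1-based inclusive) and UCSC chain conventions
(including '-'-strand query coordinates counted from the sequence end) are
converted exactly at the I/O boundary. The unit of identity throughout is
the *exon key* (gene, transcript, index-in-original-transcript), which is
preserved verbatim through every filter so that the three stage outputs are
strictly comparable. Overlapping exons within a transcript are merged on
read (they would otherwise make "exonic length of the union" ambiguous);
only `exon` features are consumed.

## Stage 1 — reciprocal chain lifting

An interval is lifted through the highest-scoring chain overlapping it; no
multi-chain stitching is attempted, because stitching would silently accept
rearrangements that the transcript-consistency rule is meant to catch. The
lift succeeds when at least `min_match` of the interval's bases fall in
aligned blocks of that chain; the image spans the outermost aligned bases.
When the best chain fails but the union of overlapping chains would have
reached `min_match`, the result is classed `split` rather than
`below_min_match`. An exon is kept only when the forward lift succeeds, the
back lift succeeds, and the back-lifted interval equals the original
*exactly* — chains are deterministic, so a tolerance window would only mask
real rearrangements. Transcripts whose surviving exons land on more than
one Sp2 chromosome or strand are removed whole; genes and transcripts
emptied of exons are dropped rather than kept as stubs.

Defaults for `min_match` are 0.98 (close species pair) and 0.913 (distant
pair). `select_min_match` chooses a value from a grid by bootstrap: exons
are resampled with replacement (default 100 replicates), and for each grid
value the mean retention (fraction surviving the reciprocal filter) and mean
fidelity (fraction of forward-lifted exons whose back lift is exact) are
estimated; the selected value maximises retention among values with
fidelity ≥ 0.99, ties going to the stricter value. The retention/fidelity
statistic is this package's own formalisation of "pick the strictest setting
that does not cost exons"; it is deliberately simple and fully seeded.

## Stage 2 — local-alignment filtering

Each exon is aligned against both genomes by exact seed-and-extend: 12-mer
exact matches are clustered by diagonal (band 40), and each cluster window
is aligned with an affine-gap local aligner (Biopython `PairwiseAligner`,
match +2, mismatch −3, gap open −7, extend −2). Windows are *not* merged
across clusters, so co-located near-identical copies each produce their own
hit; duplicate hits at the same locus are collapsed. Hits shorter than
`min_seed` (20 bp, also the minimum query length) or with PID below a
reporting floor of 0.88 (= the lowest qualifying threshold in use, 0.90,
minus 0.02) are suppressed as noise. A 21-column PSL import path allows
substituting an external aligner's hits; PID is computed from hit fields
alone (the non-mRNA milliBad variant with both gap counts in the insert
factor) precisely so that internal and imported hits score identically.

The inter-species filter keeps an exon iff *exactly one* hit on the other
genome has PID and PL at or above the inter thresholds **and** that hit
overlaps the stage-1 lifted interval on the same chromosome and strand.
Overlap (rather than coordinate equality) is used because local-alignment
endpoints jitter by a few bases against lifted coordinates. The
intra-species filter removes an exon when a second qualifying hit exists on
its own genome — in either species: the ortholog model must be clean on
both sides. Shipped thresholds: inter PID/PL 0.95 (close pair) or 0.90
(distant pair), intra PID 0.97 / PL 0.95. `choose_thresholds` grid-searches
each pair separately for the combination maximising retained exons, ties to
the stricter values; like the minMatch bootstrap, it is a documented,
deterministic stand-in for an otherwise informal calibration.

A consequence worth knowing: whether a planted copy at nominal identity
*i* is caught is binomial in the realised per-exon identity, so copies near
a threshold (e.g. nominal 0.98 against intra PID 0.97) are occasionally
missed for a single exon. This is the filter working as specified, not a
defect; the gene-level recovery targets tolerate it.

## Stage 3 — mappability-difference and truncation filters

Reads are simulated from the *stage-1* annotations of both species (so the
two stages can run in parallel) and expression is computed for stage-2
survivors. Per transcript of spliced length L, each lane carries
`round(coverage·L/read_length)` reads (100 bp, 10X, 10 lanes per species by
default), uniform start positions, each base substituted with probability
0.002 to a uniformly chosen different base. The read count is deterministic
rather than Poisson: variability enters through start positions and errors,
which keeps the equal-expression null tight at fixture scale. Substitution
errors with constant quality stand in for platform-calibrated noise; the
filter needs realistic multimapping ambiguity, not platform fidelity.
Transcripts shorter than the read length are skipped and logged.

Mapping is exact-seed (three disjoint ~L/3 seeds, pigeonhole-complete for
2 mismatches), full-length verification without indels, both orientations,
over the genome plus a spliced junction library (read_length−1 exonic bases
per side of every annotated intron). A read is kept only when exactly one
genomic footprint attains the minimal mismatch count (≤ 2); ties are
discarded — strict uniqueness is precisely the property whose asymmetry the
filter measures. The simulated branch maps with the junction library of the
annotation under test (symmetric for both species); de-novo junction
discovery is out of scope. Counting is unstranded; a read increments every
exon it overlaps by ≥ 1 base (configurable) and each gene once.

The differential machinery is a conditioned negative-binomial exact test:
size factors are median-of-ratios; per-feature dispersion is the maximum of
a method-of-moments estimate from normalised counts and a pooled trend (the
median of positive per-feature estimates), floored at 1e-8; the p-value of
a feature is the total probability of all splits (a, b) of the pooled count
sum whose joint NB probability does not exceed the observed split's,
computed in log space over the full support (pooled sums at fixture scale
are a few thousand, so exhaustive summation is exact and cheap). Exons and
genes with BH FDR < 0.01 are removed; genes with zero counts in every lane
of one species are reported in a separate `silent` category rather than
silently dropped. Finally, a gene is removed as truncated when its current
exonic length is below ⅓ of its pre-pipeline length **and** below 1 kb.
The conjunction is deliberate — a disjunction would purge every short gene,
truncated or not; an `or` mode exists behind a flag for users who want the
aggressive reading.

## Assessment statistics

Inter-species expression difference per gene is
log2(RPKM₁+1) − log2(RPKM₂+1) on mean RPKM across lanes. The bias test is
a one-sided F test (upper tail of F with group-size−1 d.f.) that the log2FC
variance of mappability-different genes exceeds that of consistent genes.
`bias_assessment` runs the equal-expression simulation with optional
lane-level lognormal expression noise (sd 0.2 on the log scale, mean 1) —
identical in distribution for both species — so the mapping-free fold
changes have a common nonzero variance while mapped fold changes
additionally carry any mappability loss; the generated read counts per gene
serve as the mapping-free measure. The in/out-exon comparison uses the
paired Wilcoxon signed-rank test on |exonFC_in| − |exonFC_out| with the
one-sided "less" alternative: exact null for n ≤ 25 without ties, normal
approximation with continuity correction otherwise; all-zero differences
return p = 1 by convention. DEX calling between real (or simulated) count
matrices uses the same NB machinery at FDR < 0.01, and `dex_and_intersect`
reports genes significant in both pairwise comparisons with agreeing
Sp1-relative direction.

## Synthetic fixtures

The generator writes a segment script — aligned blocks (substitutions
only), Sp1-only and Sp2-only segments — and realises genomes, annotation,
truth labels and *both* chain files from that script, never from alignment:
chain correctness is a construction property, and the back chain is the
exact block-wise inverse of the forward chain. Defaults emulate a close
species pair at desk scale: 120–240 bp exons (2–5 per gene), 60–300 bp
introns, 300–800 bp intergenic spacers, 1% substitution divergence, indels
(1–10 bp, rate 5e-4/base) restricted to non-exonic sequence so ortholog
truth lengths are stable (an exonic-gap gene class exercises PL < 1 and
sub-unity lift fractions when asked for). Genes alternate strands.
Hazard classes: Sp2-only/Sp1-only/both-species paralog copies (copies of
the *host species'* exonic sequence at configurable identity, unannotated
and chain-invisible — the pipeline must find them from sequence alone),
single-exon deletions (lift-fail), mostly-deleted genes (truncation cases,
5 exons of ~250 bp with all but one deleted), single-exon translocations to
a second chromosome (emitted as a separate high-scoring chain), and genes
with a true expression fold change for DEX tests. Sp2-only copies
duplicate the *Sp2* gene sequence, since the hazard being modelled is
multimapping within species 2.

What the fixtures do **not** model: repeat landscapes, GC/coverage bias,
indel sequencing errors, chromosomal rearrangements beyond the single-exon
translocation, multi-transcript genes in generated fixtures (the data model
and GTF I/O support them; hand-built fixtures cover that path). Passing
tests therefore demonstrate the pipeline's logic and calibration under
controlled hazards, not performance on repeat-rich mammalian genomes, where
an external aligner via the PSL path and real chains would be used.

## Numerical and design choices

* Determinism everywhere: one master seed; simulation lanes use
  `default_rng([seed, lane])` substreams; the bootstrap and the generators
  take explicit seeds; reruns are byte-identical.
* NB exact-test split inclusion uses a 1e-8 relative tolerance on the
  observed probability to make the ≤ comparison robust to log/exp rounding.
* `rpkm` refuses zero-length features and empty libraries; `junction_coverage`
  of an empty observed set is an error, not 0/0.
* Problem sizes in the test and acceptance runs (10–100 genes, 10 lanes,
  10X) were chosen as the smallest sizes at which the planted effects are
  comfortably detectable by the prescribed tests.
* Known limitations: the seed-and-extend aligner reports one best alignment
  per diagonal cluster, so two copies closer than ~40 bp apart on near
  diagonals could shadow each other; the mapper does not align across
  indels; chain parsing requires '+' target strands (the UCSC convention).
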